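"""Time-dependent AUC, Brier curves, .632+ and stability tables."""

import warnings

import numpy as np
import pytest

from conftest import make_dataset, pairwise_auc_oracle
from sparsehaz.data_model import SurvivalDataset
from sparsehaz.evaluation import (
    CensoringKM,
    EvalCurve,
    auc_t,
    baseline_cumhaz,
    brier_curve,
    error632plus,
    median_auc,
    overfit_weight,
    predict_survival,
    stability_replicates,
)
from sparsehaz.synthetic import SyntheticConfig, generate


def _uncensored(rng, n, p=2):
    return make_dataset(rng, n, p, event_prob=1.0)


class TestCensoringKM:
    def test_matches_lifelines_reverse_km(self, rng):
        lifelines = pytest.importorskip("lifelines")
        ds = make_dataset(rng, 40, 1, event_prob=0.5)
        km = CensoringKM(ds.time, ds.status)
        fitter = lifelines.KaplanMeierFitter()
        fitter.fit(ds.time, event_observed=1 - ds.status)
        grid = np.linspace(0.01, ds.time.max(), 25)
        ours = km(grid)
        theirs = fitter.survival_function_at_times(grid).to_numpy()
        # conventions at tied event/censor times may differ by one factor;
        # with continuous times there are no ties and the curves must agree
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_no_censoring_is_one(self, rng):
        ds = _uncensored(rng, 20)
        km = CensoringKM(ds.time, ds.status)
        assert np.all(km(np.linspace(0, ds.time.max(), 10)) == 1.0)


class TestBaselineCumHaz:
    def test_nelson_aalen_first_step(self, rng):
        ds = _uncensored(rng, 10, 1)
        ch = baseline_cumhaz(ds, np.zeros(1))
        t1 = np.sort(ds.time)[0]
        assert np.isclose(ch(t1), 1 / 10)
        # full Nelson-Aalen at the k-th distinct time: sum 1/(n-i+1)
        ts = np.sort(ds.time)
        na = np.cumsum(1.0 / (10 - np.arange(10)))
        assert np.allclose(ch(ts), na, atol=1e-12)

    def test_no_events_zero(self, rng):
        ds = make_dataset(rng, 8, 1, event_prob=0.0)
        ch = baseline_cumhaz(ds, np.zeros(1))
        assert np.allclose(ch(np.linspace(0.01, ds.time.max(), 5)), 0.0)

    def test_between_event_slope(self, rng):
        ds = make_dataset(rng, 12, 2, event_prob=0.7)
        beta = rng.normal(size=2) * 0.1
        ch = baseline_cumhaz(ds, beta)
        ts = np.sort(np.unique(ds.time))
        # numerical derivative strictly inside an inter-event interval
        lo, hi = ts[1], ts[2]
        m1, m2 = lo + 0.3 * (hi - lo), lo + 0.6 * (hi - lo)
        deriv = (ch(m2) - ch(m1)) / (m2 - m1)
        at_risk = ds.time >= hi
        expected = -(ds.covariates[at_risk] @ beta).sum() / at_risk.sum()
        assert np.isclose(deriv, expected, rtol=1e-8)

    def test_flat_extrapolation_warns(self, rng):
        ds = make_dataset(rng, 6, 1)
        ch = baseline_cumhaz(ds, np.zeros(1))
        with pytest.warns(UserWarning, match="extrapolating"):
            v = ch(ds.time.max() * 2)
        assert v == ch(ds.time.max())


class TestPredictSurvival:
    def test_time_zero_is_one(self, rng):
        ds = make_dataset(rng, 15, 3)
        beta = rng.normal(size=3) * 0.1
        ch = baseline_cumhaz(ds, beta)
        S = predict_survival(beta, ch, ds.covariates, np.array([0.0, 1.0]))
        assert np.allclose(S[:, 0], 1.0)

    def test_zero_beta_is_baseline_survival(self, rng):
        ds = make_dataset(rng, 15, 3)
        ch = baseline_cumhaz(ds, np.zeros(3))
        ts = np.linspace(0.1, ds.time.max(), 7)
        S = predict_survival(np.zeros(3), ch, ds.covariates[0], ts)
        assert np.allclose(S, np.exp(-ch(ts)))

    def test_monotone_and_bounded(self, rng):
        ds = make_dataset(rng, 20, 3)
        beta = rng.normal(size=3)
        ch = baseline_cumhaz(ds, beta)
        S = predict_survival(beta, ch, ds.covariates, np.linspace(0.05, ds.time.max(), 12))
        assert np.all(S >= 0) and np.all(S <= 1)
        assert np.all(np.diff(S, axis=1) <= 0)

    def test_constant_hazard_closed_form(self):
        # generator truth: S(t|z) = exp(-(lambda0 + beta'z) t)
        beta_true = np.zeros(3)
        beta_true[0] = 0.5
        cfg = SyntheticConfig(
            n=2000, p=3, beta_true=beta_true, target_events=None, seed=11
        )
        data, truth = generate(cfg)
        from sparsehaz.suffstats import compute_suffstats, unpenalized_fit

        beta = unpenalized_fit(compute_suffstats(data))
        ch = baseline_cumhaz(data, beta)
        z = np.array([0.3, 0.0, 0.0])  # central covariate vector
        ts = np.linspace(0.1, 1.0, 5)
        S = predict_survival(beta, ch, z, ts)
        S_true = np.exp(-(truth.lambda0 + beta_true @ z) * ts)
        assert np.abs(S - S_true).max() < 0.05


class TestAucT:
    def test_perfect_marker_uncensored(self, rng):
        ds = _uncensored(rng, 12)
        marker = -ds.time  # shorter survival = higher risk, perfectly ordered
        times = np.sort(ds.time)[2:-2]
        curve = auc_t(marker, ds, times)
        assert np.allclose(curve.values, 1.0)

    def test_constant_marker_half(self, rng):
        ds = _uncensored(rng, 12)
        curve = auc_t(np.zeros(12), ds, np.sort(ds.time)[3:-3])
        assert np.allclose(curve.values, 0.5)

    def test_exhaustive_pairwise_oracle_n8(self):
        rng = np.random.default_rng(88)
        ds = _uncensored(rng, 8)
        marker = rng.normal(size=8)
        times = np.sort(ds.time)[1:-1]
        curve = auc_t(marker, ds, times)
        for t, v in zip(curve.times, curve.values):
            oracle = pairwise_auc_oracle(marker, ds.time, ds.status, t)
            assert np.isclose(v, oracle, atol=1e-12)

    def test_undefined_times_dropped_with_warning(self, rng):
        ds = _uncensored(rng, 10)
        with pytest.warns(UserWarning, match="undefined"):
            curve = auc_t(rng.normal(size=10), ds, np.array([ds.time.max() + 1.0]))
        assert curve.values.size == 0

    def test_invariance_under_monotone_transform(self, rng):
        ds = make_dataset(rng, 30, 1, event_prob=0.6)
        marker = rng.normal(size=30)
        times = np.sort(ds.time[ds.status == 1])[1:-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = auc_t(marker, ds, times)
            c2 = auc_t(np.exp(2 * marker), ds, times)
        assert np.allclose(c1.values, c2.values, atol=1e-12)

    def test_values_within_unit_interval_censored(self, rng):
        ds = make_dataset(rng, 50, 1, event_prob=0.4)
        times = np.sort(ds.time[ds.status == 1])[1:-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = auc_t(rng.normal(size=50), ds, times)
        assert np.all((curve.values >= 0) & (curve.values <= 1))

    def test_matches_scikit_survival_uno_estimator(self, rng):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        ds = make_dataset(rng, 60, 1, event_prob=0.6)
        marker = rng.normal(size=60)
        times = np.sort(ds.time[ds.status == 1])[3:-3]
        y = np.array(
            [(bool(s), t) for s, t in zip(ds.status, ds.time)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        theirs, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, marker, times)
        ours = auc_t(marker, ds, times)
        assert np.allclose(ours.values, theirs, atol=1e-8)


class TestMedianAuc:
    def test_constant_curve(self):
        c = EvalCurve(np.array([1.0, 2.0]), np.array([0.8, 0.8]))
        assert median_auc(c) == 0.8

    def test_odd_length(self):
        c = EvalCurve(np.array([1.0, 2.0, 3.0]), np.array([0.6, 0.7, 0.9]))
        assert median_auc(c) == 0.7

    def test_even_length_midpoint(self):
        c = EvalCurve(np.array([1.0, 2.0]), np.array([0.6, 0.8]))
        assert np.isclose(median_auc(c), 0.7)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            median_auc(EvalCurve(np.array([]), np.array([])))


class TestBrierCurve:
    def test_perfect_oracle_zero(self, rng):
        ds = _uncensored(rng, 10)
        times = np.sort(ds.time)[1:-1]
        S = np.array([[0.0 if x <= t else 1.0 for t in times] for x in ds.time])
        curve = brier_curve(S, ds, times)
        assert np.allclose(curve.values, 0.0)

    def test_constant_half_quarter(self, rng):
        ds = _uncensored(rng, 10)
        times = np.sort(ds.time)[1:-1]
        curve = brier_curve(np.full((10, times.size), 0.5), ds, times)
        assert np.allclose(curve.values, 0.25)

    def test_hand_computed_uncensored(self):
        ds = SurvivalDataset(
            time=[1.0, 2.0, 3.0], status=[1, 1, 1],
            covariates=np.zeros((3, 1)), feature_ids=["g"],
        )
        times = np.array([1.5])
        S = np.array([[0.2], [0.7], [0.9]])
        # subject 1: event by 1.5, err (1-0.8)^2; subjects 2,3 event-free: (0.3)^2, (0.1)^2
        expected = ((1 - 0.8) ** 2 + 0.3**2 + 0.1**2) / 3
        curve = brier_curve(S, ds, times)
        assert np.isclose(curve.values[0], expected, atol=1e-12)

    def test_early_time_error_vanishes(self, rng):
        ds = _uncensored(rng, 20)
        t0 = ds.time.min() * 0.01
        S = np.ones((20, 1))
        curve = brier_curve(S, ds, np.array([t0]))
        assert curve.values[0] == 0.0

    def test_out_of_range_predictions_rejected(self, rng):
        ds = _uncensored(rng, 5)
        with pytest.raises(ValueError):
            brier_curve(np.full((5, 1), 1.5), ds, np.array([1.0]))


class TestError632Plus:
    def test_weight_algebra(self):
        assert np.isclose(overfit_weight(0.0), 0.632)
        assert np.isclose(overfit_weight(1.0), 1.0)
        # monotone in R
        Rs = np.linspace(0, 1, 11)
        assert np.all(np.diff(overfit_weight(Rs)) > 0)

    def test_degenerate_constant_predictor_returns_apparent(self, rng):
        # constant predictions, uncensored: err_oob = err_app = gamma pointwise
        ds = _uncensored(rng, 30)
        times = np.sort(ds.time)[5:-5:3]

        def proc(train):
            def predictor(covariates, ts):
                return np.full((covariates.shape[0], len(ts)), 0.5)

            return predictor

        curve = error632plus(ds, proc, times, B=10, seed=0)
        assert np.allclose(curve.values, 0.25)

    def test_bounded_by_component_curves(self, rng):
        beta_true = np.zeros(4)
        beta_true[:2] = [0.8, -0.6]
        cfg = SyntheticConfig(n=60, p=4, beta_true=beta_true, target_events=40, seed=5)
        data, _ = generate(cfg)
        times = np.sort(data.time[data.status == 1])[2:-2:2]

        from sparsehaz.suffstats import compute_suffstats, unpenalized_fit

        def proc(train):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta = unpenalized_fit(compute_suffstats(train))
            ch = baseline_cumhaz(train, beta)

            def predictor(covariates, ts):
                return predict_survival(beta, ch, covariates, ts)

            return predictor

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve, comp = error632plus(
                data, proc, times, B=25, seed=3, return_components=True
            )
        err_app, err_oob, gamma = comp["err_app"], comp["err_oob"], comp["gamma"]
        # convex combination of err_app and min(err_oob, gamma), so it lies
        # between err_app and max(err_oob, gamma) pointwise
        hi = np.maximum(err_app, np.maximum(err_oob, gamma))
        lo = np.minimum(err_app, np.minimum(err_oob, gamma))
        assert np.all(curve.values <= hi + 1e-12)
        assert np.all(curve.values >= lo - 1e-12)
        # weights respect the algebra of the overfitting ratio
        assert np.all((comp["w"] >= 0.632 - 1e-12) & (comp["w"] <= 1.0 + 1e-12))

    def test_deterministic_under_seed(self, rng):
        ds = _uncensored(rng, 25)
        times = np.sort(ds.time)[5:-5:4]

        def proc(train):
            mean_t = train.time.mean()

            def predictor(covariates, ts):
                return np.tile(np.exp(-np.asarray(ts) / mean_t), (covariates.shape[0], 1))

            return predictor

        c1 = error632plus(ds, proc, times, B=8, seed=42)
        c2 = error632plus(ds, proc, times, B=8, seed=42)
        assert np.array_equal(c1.values, c2.values)


class TestStabilityReplicates:
    def test_constant_selection_summary(self, rng):
        ds = make_dataset(rng, 20, 4)
        beta_fixed = np.array([0.0, 1.5, 0.0, -0.2])

        def selector(train, seed):
            return beta_fixed

        tab = stability_replicates(ds, selector, R=10, seed=0)
        assert set(tab.table.index) == {"g1", "g3"}
        row = tab.table.loc["g1"]
        assert row["frequency"] == 10
        assert row["mean_coef"] == 1.5
        assert row["se_coef"] == 0.0

    def test_never_selected_absent(self, rng):
        ds = make_dataset(rng, 20, 3)

        def selector(train, seed):
            return np.zeros(3)

        tab = stability_replicates(ds, selector, R=5, seed=0)
        assert len(tab.table) == 0

    def test_failed_replicates_excluded_and_counted(self, rng):
        ds = make_dataset(rng, 20, 2)
        calls = {"k": 0}

        def selector(train, seed):
            calls["k"] += 1
            if calls["k"] % 3 == 0:
                raise RuntimeError("unstable")
            return np.array([1.0, 0.0])

        with pytest.warns(UserWarning, match="failed"):
            tab = stability_replicates(ds, selector, R=9, seed=0)
        assert tab.n_failed == 3
        assert tab.n_replicates == 6
        assert tab.table.loc["g0", "frequency"] == 6

    def test_strong_signal_features_selected_frequently(self):
        # every true-support feature should appear in >= 80% of replicates
        from sparsehaz.data_model import standardize_columns
        from sparsehaz.model_selection import fit_cv

        R = 25
        fail = 0
        for seed in range(20):
            beta_true = np.zeros(30)
            beta_true[[2, 9, 17, 23, 28]] = [10.0, -10.0, 10.0, -10.0, 10.0]
            # strong signal: coefficient-to-baseline ratio near the positivity
            # limit, light censoring, n comfortably above p
            cfg = SyntheticConfig(
                n=300, p=30, beta_true=beta_true, target_events=240, seed=seed,
                lambda0=34.0,
            )
            data, truth = generate(cfg)
            Zs, _, _ = standardize_columns(data.covariates)
            std = data.with_covariates(Zs, data.feature_ids)

            def selector(train, rep_seed):
                res, _ = fit_cv(train, "lasso", K=5, seed=rep_seed)
                return res.beta

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab = stability_replicates(std, selector, R=R, seed=seed)
            ids = np.asarray(std.feature_ids)[truth.support]
            freqs = [
                tab.table.loc[f, "frequency"] if f in tab.table.index else 0
                for f in ids
            ]
            if min(freqs) < 0.8 * R:
                fail += 1
        assert fail <= 2  # stochastic bound: nearly all seeds fully stable
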