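"""Predictive evaluation for additive-hazards survival models.

Contents:

* a baseline cumulative hazard estimator for the additive model (the
  Lin–Ying analogue of the Breslow estimator), from which predicted survival
  probabilities S(t | z) = exp(-Lambda0(t) - beta'z * t) follow;
* time-dependent ROC AUC(t) in the cumulative-case / dynamic-control sense,
  with inverse-probability-of-censoring weights (IPCW) from the Kaplan–Meier
  estimate of the censoring distribution;
* Brier-type prediction-error curves: the time-indexed, IPCW-weighted mean
  squared difference between the observed event state at t (1 if the event
  has occurred, 0 if known event-free) and the predicted event probability
  1 - S(t | z);
* the bootstrap .632+ estimator combining apparent and out-of-sample error
  curves with a weight adapted to the estimated overfitting; resampling draws
  floor(0.632 * n) training samples *without* replacement so the expected
  holdout fraction matches the classical out-of-bag fraction (a
  with-replacement flag restores the classical scheme);
* selection-stability tables: per-feature selection frequency, mean
  coefficient and standard error across repeated subsample refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import SurvivalDataset

__all__ = [
    "EvalCurve",
    "StabilityTable",
    "CensoringKM",
    "BaselineCumHaz",
    "baseline_cumhaz",
    "predict_survival",
    "auc_t",
    "median_auc",
    "brier_curve",
    "error632plus",
    "overfit_weight",
    "stability_replicates",
    "plot_curves",
]

_G_FLOOR = 1e-12  # guard against division by an exactly-zero censoring survival


def overfit_weight(R):
    """.632+ weight w(R) = .632 / (1 - .368 R): w(0) = .632, w(1) = 1."""
    R = np.clip(np.asarray(R, dtype=float), 0.0, 1.0)
    return 0.632 / (1.0 - 0.368 * R)


@dataclass
class EvalCurve:
    """A time grid paired with evaluation values (AUC(t) or prediction error)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-d arrays")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


@dataclass
class StabilityTable:
    """Per-feature selection frequency and coefficient summary over replicates.

    ``frequency`` counts the replicates in which the feature entered the
    model; ``mean_coef`` and ``se_coef`` summarize its coefficient over those
    replicates only (SE = SD / sqrt(frequency)). Features never selected do
    not appear. ``n_replicates`` is the effective denominator (failed
    replicates are excluded and reported).
    """

    table: pd.DataFrame
    n_replicates: int
    n_failed: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True)


class CensoringKM:
    """Kaplan–Meier estimate G(t) of the censoring survival distribution.

    Built by reversing the roles of event and censoring. Right-continuous;
    ``left`` gives the left limit G(t-) used to weight subjects at their own
    event time. At tied times, events are taken to precede censorings (the
    standard convention), so censorings at t leave a risk set that excludes
    subjects whose events occurred at t.
    """

    def __init__(self, time: np.ndarray, status: np.ndarray) -> None:
        time = np.asarray(time, dtype=float)
        status = np.asarray(status, dtype=float)
        order = np.argsort(time, kind="stable")
        t_sorted = time[order]
        cens_sorted = 1.0 - status[order]
        distinct, start = np.unique(t_sorted, return_index=True)
        n = time.shape[0]
        surv = []
        g = 1.0
        for k, t_k in enumerate(distinct):
            stop = start[k + 1] if k + 1 < distinct.size else n
            c_k = cens_sorted[start[k]:stop].sum()
            d_k = (stop - start[k]) - c_k  # events at t_k
            at_risk = n - start[k] - d_k  # events precede censorings at ties
            if at_risk > 0 and c_k > 0:
                g *= 1.0 - c_k / at_risk
            surv.append(g)
        self._times = distinct
        self._surv = np.asarray(surv)

    def __call__(self, t) -> np.ndarray:
        """G(t), right-continuous."""
        idx = np.searchsorted(self._times, np.asarray(t, dtype=float), side="right")
        out = np.concatenate(([1.0], self._surv))[idx]
        return out

    def left(self, t) -> np.ndarray:
        """G(t-), the left limit."""
        idx = np.searchsorted(self._times, np.asarray(t, dtype=float), side="left")
        return np.concatenate(([1.0], self._surv))[idx]


class BaselineCumHaz:
    """Estimated baseline cumulative hazard Lambda0(t) of the additive model.

    Lambda0hat(t) = int_0^t [ sum_i dN_i(s) - sum_i Y_i(s) beta'Z_i ds ]
                             / sum_i Y_i(s):
    a step of (events at t_k) / (risk-set size) at each event time, minus a
    piecewise-linear drift given by the risk-set mean of the linear predictor.
    Right-continuous in the step part; evaluation beyond the last at-risk time
    extrapolates flat (with a warning).
    """

    def __init__(self, data: SurvivalDataset, beta: np.ndarray) -> None:
        beta = np.asarray(beta, dtype=float)
        X, d = data.time, data.status
        eta = data.covariates @ beta  # linear predictor per subject
        distinct = np.unique(X)
        K = distinct.size
        # risk sets on (t_{k-1}, t_k] are {X >= t_k}
        steps = np.zeros(K)
        slopes = np.zeros(K)
        for k, t_k in enumerate(distinct):
            at_risk = X >= t_k
            m = at_risk.sum()
            d_k = ((X == t_k) & (d == 1.0)).sum()
            steps[k] = d_k / m
            slopes[k] = eta[at_risk].sum() / m  # subtracted linearly over the interval
        self._t = distinct
        self._steps = steps
        self._slopes = slopes
        # cumulative value right after each t_k
        dt = np.diff(np.concatenate(([0.0], distinct)))
        self._cum = np.cumsum(steps - slopes * dt)
        self._tmax = float(distinct[-1])

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if np.any(t > self._tmax):
            warnings.warn(
                f"evaluating baseline hazard beyond the last at-risk time "
                f"{self._tmax:g}; extrapolating flat",
                stacklevel=2,
            )
        out = np.empty(t.shape)
        # index of interval: t in (t_{k-1}, t_k]
        k = np.searchsorted(self._t, t, side="left")
        for i, (ti, ki) in enumerate(zip(t, k)):
            if ti <= 0:
                out[i] = 0.0
            elif ki >= self._t.size:
                out[i] = self._cum[-1]
            else:
                base = self._cum[ki - 1] if ki > 0 else 0.0
                prev_t = self._t[ki - 1] if ki > 0 else 0.0
                # within the interval only the drift accrues; the step lands at t_k
                out[i] = base - self._slopes[ki] * (ti - prev_t)
                if ti == self._t[ki]:
                    out[i] += self._steps[ki]
        return out[0] if scalar else out


def baseline_cumhaz(data: SurvivalDataset, beta: np.ndarray) -> BaselineCumHaz:
    """Estimate the baseline cumulative hazard given fitted coefficients."""
    return BaselineCumHaz(data, beta)


def predict_survival(
    beta: np.ndarray, cumhaz: BaselineCumHaz, z: np.ndarray, times
) -> np.ndarray:
    """Predicted survival S(t | z) = exp(-Lambda0(t) - (beta'z) t).

    ``z`` may be a single covariate vector or an (m, p) matrix (rows =
    subjects, on the training standardization scale). Returns probabilities
    clipped to [0, 1] and forced nonincreasing in t (running minimum), shape
    (len(times),) or (m, len(times)).
    """
    beta = np.asarray(beta, dtype=float)
    z = np.asarray(z, dtype=float)
    times = np.asarray(times, dtype=float)
    single = z.ndim == 1
    Z = z[None, :] if single else z
    eta = Z @ beta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Lam0 = cumhaz(times)
    S = np.exp(-(Lam0[None, :] + np.outer(eta, times)))
    S = np.clip(S, 0.0, 1.0)
    S = np.minimum.accumulate(S, axis=1)
    return S[0] if single else S


def auc_t(
    marker: np.ndarray,
    data: SurvivalDataset,
    times,
    G: CensoringKM | None = None,
) -> EvalCurve:
    """Cumulative-case / dynamic-control time-dependent AUC of a risk marker.

    At each t, cases are subjects with an observed event by t and controls
    those still event-free beyond t; concordance is the IPCW-weighted fraction
    of case/control pairs the marker orders correctly (ties count 1/2). Case i
    is weighted 1/G(X_i-), control j by 1/G(t), with G the Kaplan–Meier
    censoring survival. Times with no cases or no controls are dropped from
    the curve (with a warning). Higher marker must mean higher risk.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    X, d = data.time, data.status
    if G is None:
        G = CensoringKM(X, d)
    w_case_all = 1.0 / np.maximum(G.left(X), _G_FLOOR)

    out_t, out_v = [], []
    for t in times:
        cases = (X <= t) & (d == 1.0)
        controls = X > t
        if not cases.any() or not controls.any():
            warnings.warn(f"AUC undefined at t={t:g} (no cases or no controls)",
                          stacklevel=2)
            continue
        wi = w_case_all[cases]
        wj = np.full(controls.sum(), 1.0 / max(float(G(t)), _G_FLOOR))
        mi = marker[cases][:, None]
        mj = marker[controls][None, :]
        conc = (mi > mj) + 0.5 * (mi == mj)
        num = float(wi @ conc @ wj)
        den = float(wi.sum() * wj.sum())
        out_t.append(t)
        out_v.append(num / den)
    return EvalCurve(np.asarray(out_t), np.asarray(out_v))


def median_auc(curve: EvalCurve) -> float:
    """Median of AUC(t) over the curve's grid (even length: midpoint)."""
    if curve.values.size == 0:
        raise ValueError("empty AUC curve")
    return float(np.median(curve.values))


def brier_curve(
    surv_pred: np.ndarray,
    data: SurvivalDataset,
    times,
    G: CensoringKM | None = None,
) -> EvalCurve:
    """IPCW Brier prediction-error curve.

    ``surv_pred`` is the (n_samples, len(times)) matrix of predicted survival
    probabilities S_i(t). At each t the error is the mean over samples of
    w_i(t) * (state_i(t) - (1 - S_i(t)))^2 with state 1 for events by t,
    state 0 for subjects known event-free at t, and weight 0 for subjects
    censored by t (they enter through the IPCW reweighting of the others).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    surv_pred = np.asarray(surv_pred, dtype=float)
    X, d = data.time, data.status
    n = X.shape[0]
    if surv_pred.shape != (n, times.size):
        raise ValueError(
            f"surv_pred shape {surv_pred.shape} != (n={n}, T={times.size})"
        )
    if np.any(surv_pred < -1e-9) or np.any(surv_pred > 1 + 1e-9):
        raise ValueError("survival predictions must lie in [0, 1]")
    if G is None:
        G = CensoringKM(X, d)
    w_event = 1.0 / np.maximum(G.left(X), _G_FLOOR)

    values = np.empty(times.size)
    for it, t in enumerate(times):
        event_by_t = (X <= t) & (d == 1.0)
        event_free = X > t
        ehat = 1.0 - surv_pred[:, it]  # predicted event probability
        err = np.zeros(n)
        err[event_by_t] = w_event[event_by_t] * (1.0 - ehat[event_by_t]) ** 2
        w_free = 1.0 / max(float(G(t)), _G_FLOOR)
        err[event_free] = w_free * ehat[event_free] ** 2
        values[it] = err.sum() / n
    return EvalCurve(times, values)


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(k)]).generate_state(1)[0] % (2**31))


def error632plus(
    data: SurvivalDataset,
    fit_procedure,
    times,
    B: int = 100,
    seed: int = 0,
    with_replacement: bool = False,
    return_components: bool = False,
) -> EvalCurve:
    """Bootstrap .632+ prediction-error curve.

    ``fit_procedure(train: SurvivalDataset) -> predictor`` must return a
    callable ``predictor(covariates, times) -> survival matrix`` encapsulating
    the entire training pipeline (tuning included), so each replicate re-runs
    selection on its own training draw. Each of the B replicates draws
    floor(0.632 n) training samples without replacement (or n samples with
    replacement when ``with_replacement``); its holdout yields an
    out-of-sample Brier curve. With apparent error err_app (train = evaluate =
    full data), no-information error gamma from all prediction/outcome
    pairings, and relative overfitting R = (err_oob - err_app) /
    (gamma - err_app) clipped to [0, 1], the returned curve is
    (1 - w) err_app + w min(err_oob, gamma) with w = .632 / (1 - .368 R).

    Replicates whose training draw has fewer than 2 events are redrawn with a
    derived seed. With ``return_components`` the apparent, out-of-sample and
    no-information curves plus the overfitting ratio and weight are returned
    alongside the combined curve.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    n = data.n
    G = CensoringKM(data.time, data.status)

    predictor_full = fit_procedure(data)
    S_full = np.asarray(predictor_full(data.covariates, times), dtype=float)
    err_app = brier_curve(S_full, data, times, G=G).values

    gamma = _no_information_error(S_full, data, times, G)

    m_train = int(np.floor(0.632 * n))
    oob_curves = []
    b_done = 0
    draw = 0
    while b_done < B:
        rep_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), draw])
        )
        draw += 1
        if with_replacement:
            tr = rep_rng.choice(n, size=n, replace=True)
            te = np.setdiff1d(np.arange(n), np.unique(tr))
        else:
            tr = rep_rng.choice(n, size=m_train, replace=False)
            te = np.setdiff1d(np.arange(n), tr)
        if data.status[tr].sum() < 2 or te.size == 0:
            warnings.warn(
                f"replicate draw {draw - 1}: <2 events in training (or empty "
                "holdout); redrawn",
                stacklevel=2,
            )
            continue
        train = data.subset(tr)
        test = data.subset(te)
        predictor = fit_procedure(train)
        S_te = np.asarray(predictor(test.covariates, times), dtype=float)
        oob_curves.append(brier_curve(S_te, test, times, G=G).values)
        b_done += 1
    err_oob = np.mean(oob_curves, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        R = (err_oob - err_app) / (gamma - err_app)
    R = np.where((err_oob > err_app) & (gamma > err_app), R, 0.0)
    w = overfit_weight(R)
    values = (1.0 - w) * err_app + w * np.minimum(err_oob, gamma)
    curve = EvalCurve(times, values)
    if return_components:
        return curve, {
            "err_app": err_app,
            "err_oob": err_oob,
            "gamma": gamma,
            "R": np.clip(R, 0.0, 1.0),
            "w": w,
        }
    return curve


def _no_information_error(
    S_full: np.ndarray, data: SurvivalDataset, times: np.ndarray, G: CensoringKM
) -> np.ndarray:
    """gamma(t): Brier error over all (prediction_i, outcome_j) pairings."""
    X, d = data.time, data.status
    n = X.shape[0]
    w_event = 1.0 / np.maximum(G.left(X), _G_FLOOR)
    gamma = np.empty(times.size)
    for it, t in enumerate(times):
        ehat = 1.0 - S_full[:, it]
        sum_e = ehat.sum()
        sum_e2 = (ehat**2).sum()
        event_by_t = (X <= t) & (d == 1.0)
        event_free = X > t
        w_free = 1.0 / max(float(G(t)), _G_FLOOR)
        # sum_i (state_j - e_i)^2 = n*state_j^2 - 2*state_j*sum_e + sum_e2
        tot = 0.0
        for j in range(n):
            if event_by_t[j]:
                tot += w_event[j] * (n - 2.0 * sum_e + sum_e2)
            elif event_free[j]:
                tot += w_free * sum_e2
        gamma[it] = tot / (n * n)
    return gamma


def plot_curves(curves: dict, ylabel: str, path) -> None:
    """Plot a family of evaluation curves (AUC(t) or prediction error) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in sorted(curves.items()):
        ax.step(curve.times, curve.values, where="post", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stability_replicates(
    data: SurvivalDataset,
    fit_selector,
    R: int = 100,
    seed: int = 0,
    subsample: float = 0.8,
) -> StabilityTable:
    """Selection-stability table over repeated subsample refits.

    ``fit_selector(train: SurvivalDataset, seed: int) -> coefficient vector``
    runs the full tuning + fit on a replicate (e.g. CV-selected lasso). Each
    of the R replicates draws ``subsample`` * n samples without replacement.
    A replicate that raises is logged and excluded; the effective denominator
    is reported on the table.
    """
    n = data.n
    m = int(np.floor(subsample * n))
    freq = np.zeros(data.p, dtype=np.int64)
    sum_c = np.zeros(data.p)
    sum_c2 = np.zeros(data.p)
    n_failed = 0
    for r in range(R):
        rep_seed = _derive_seed(seed, r)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        idx = rng.choice(n, size=m, replace=False)
        try:
            beta = np.asarray(fit_selector(data.subset(idx), rep_seed), dtype=float)
        except Exception as e:  # noqa: BLE001 - replicate failure is data-dependent
            warnings.warn(f"stability replicate {r} failed ({e}); excluded",
                          stacklevel=2)
            n_failed += 1
            continue
        sel = beta != 0.0
        freq[sel] += 1
        sum_c[sel] += beta[sel]
        sum_c2[sel] += beta[sel] ** 2

    selected = freq > 0
    mean_c = np.zeros(data.p)
    se_c = np.zeros(data.p)
    mean_c[selected] = sum_c[selected] / freq[selected]
    multi = freq > 1
    # SD over the replicates in which the feature was selected (ddof=1)
    var = np.zeros(data.p)
    var[multi] = np.maximum(
        (sum_c2[multi] - freq[multi] * mean_c[multi] ** 2) / (freq[multi] - 1), 0.0
    )
    se_c[multi] = np.sqrt(var[multi] / freq[multi])

    table = pd.DataFrame(
        {
            "frequency": freq[selected],
            "mean_coef": mean_c[selected],
            "se_coef": se_c[selected],
        },
        index=pd.Index(np.asarray(data.feature_ids)[selected], name="feature_id"),
    ).sort_values("frequency", ascending=False)
    return StabilityTable(table=table, n_replicates=R - n_failed, n_failed=n_failed)
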