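"""Sufficient statistics b, V and the least-squares-type loss."""

import numpy as np
import pytest

from conftest import make_dataset, make_suffstats, riemann_suffstats
from sparsehaz.data_model import SurvivalDataset
from sparsehaz.suffstats import compute_suffstats, loss, unpenalized_fit


def _ds(time, status, Z, tau=None):
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(time):
        Z = Z.T
    return SurvivalDataset(
        time=time, status=status, covariates=Z,
        feature_ids=[f"g{j}" for j in range(Z.shape[1])], tau=tau,
    )


class TestComputeSuffstats:
    def test_single_subject_centers_to_zero(self):
        ds = _ds([2.0], [1.0], [[3.5]])
        ss = compute_suffstats(ds)
        assert np.allclose(ss.b, 0) and np.allclose(ss.V, 0)

    def test_identical_covariate_rows_vanish(self):
        ds = _ds([1.0, 2.0], [1.0, 1.0], [[1.7], [1.7]])
        ss = compute_suffstats(ds)
        assert np.allclose(ss.b, 0) and np.allclose(ss.V, 0)

    def test_riemann_oracle_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            p = int(rng.integers(1, 4))
            ds = make_dataset(rng, n, p)
            ss = compute_suffstats(ds)
            b_o, V_o = riemann_suffstats(ds)
            scale_b = max(np.abs(b_o).max(), 1e-12)
            scale_V = max(np.abs(V_o).max(), 1e-12)
            assert np.abs(ss.b - b_o).max() / scale_b < 1e-3
            assert np.abs(ss.V - V_o).max() / scale_V < 1e-3

    def test_three_subject_one_feature_oracle(self):
        ds = _ds([1.0, 2.0, 3.0], [1.0, 1.0, 0.0], [[0.5], [-1.2], [2.0]])
        ss = compute_suffstats(ds)
        b_o, V_o = riemann_suffstats(ds)
        assert np.abs(ss.b - b_o).max() < 1e-3 * max(1, abs(b_o).max())
        assert np.abs(ss.V - V_o).max() < 1e-3 * max(1, abs(V_o).max())

    def test_symmetry_and_psd(self, rng):
        ds = make_dataset(rng, 15, 4)
        V = compute_suffstats(ds).V
        assert np.abs(V - V.T).max() < 1e-10
        eigs = np.linalg.eigvalsh(V)
        assert eigs.min() >= -1e-8 * np.trace(V)

    def test_location_invariance(self, rng):
        ds = make_dataset(rng, 12, 3)
        ss = compute_suffstats(ds)
        shifted = SurvivalDataset(
            time=ds.time, status=ds.status, covariates=ds.covariates + 5.0,
            feature_ids=ds.feature_ids,
        )
        ss2 = compute_suffstats(shifted)
        assert np.allclose(ss.b, ss2.b, atol=1e-10)
        assert np.allclose(ss.V, ss2.V, atol=1e-9)

    def test_time_scaling_scales_V_not_b(self, rng):
        ds = make_dataset(rng, 12, 3)
        ss = compute_suffstats(ds)
        c = 3.7
        scaled = SurvivalDataset(
            time=c * ds.time, status=ds.status, covariates=ds.covariates,
            feature_ids=ds.feature_ids,
        )
        ss2 = compute_suffstats(scaled)
        assert np.allclose(ss2.b, ss.b, atol=1e-12)
        assert np.allclose(ss2.V, c * ss.V, atol=1e-10)

    def test_zero_events_warns_and_b_zero(self, rng):
        ds = make_dataset(rng, 6, 2, event_prob=0.0)
        with pytest.warns(UserWarning, match="zero events"):
            ss = compute_suffstats(ds)
        assert np.allclose(ss.b, 0)

    def test_tau_beyond_last_time_truncates_with_warning(self, rng):
        ds = make_dataset(rng, 6, 2)
        big_tau = SurvivalDataset(
            time=ds.time, status=ds.status, covariates=ds.covariates,
            feature_ids=ds.feature_ids, tau=ds.time.max() * 2,
        )
        with pytest.warns(UserWarning, match="truncated"):
            ss2 = compute_suffstats(big_tau)
        ss = compute_suffstats(ds)
        assert np.allclose(ss.V, ss2.V)

    def test_tau_mid_interval(self, rng):
        # partial last interval must enter V exactly as in the Riemann oracle
        ds = make_dataset(rng, 8, 2)
        tau = float(np.sort(ds.time)[-2] + 0.3 * (ds.time.max() - np.sort(ds.time)[-2]))
        mid = SurvivalDataset(
            time=ds.time, status=ds.status, covariates=ds.covariates,
            feature_ids=ds.feature_ids, tau=tau,
        )
        ss = compute_suffstats(mid)
        b_o, V_o = riemann_suffstats(mid)
        assert np.abs(ss.V - V_o).max() < 1e-3 * max(1e-12, np.abs(V_o).max())
        assert np.abs(ss.b - b_o).max() < 1e-9

    def test_factored_matches_dense(self, rng):
        ds = make_dataset(rng, 20, 5)
        ss = compute_suffstats(ds)
        x = rng.normal(size=5)
        assert np.allclose(ss.V_matvec(x), ss.V @ x, atol=1e-12)
        assert np.allclose(ss.V_diag(), np.diag(ss.V), atol=1e-12)
        for j in range(5):
            assert np.allclose(ss.V_row(j), ss.V[j], atol=1e-12)


class TestLoss:
    def test_zero_beta_gives_zero(self, rng):
        ss = compute_suffstats(make_dataset(rng, 10, 3))
        assert loss(np.zeros(3), ss) == 0.0

    def test_identity_V_closed_form(self, rng):
        beta = rng.normal(size=4)
        ss = make_suffstats(np.zeros(4), np.eye(4))
        assert np.isclose(loss(beta, ss), 0.5 * beta @ beta, atol=1e-10)

    def test_independent_arithmetic_oracle(self, rng):
        for _ in range(10):
            M = rng.normal(size=(5, 5))
            V = M @ M.T
            b = rng.normal(size=5)
            beta = rng.normal(size=5)
            ss = make_suffstats(b, V)
            # element-wise double loop, written independently of the matmul path
            expected = -sum(b[i] * beta[i] for i in range(5))
            for i in range(5):
                for j in range(5):
                    expected += 0.5 * beta[i] * V[i, j] * beta[j]
            assert abs(loss(beta, ss) - expected) < 1e-12

    def test_dimension_mismatch(self, rng):
        ss = compute_suffstats(make_dataset(rng, 10, 3))
        with pytest.raises(ValueError):
            loss(np.zeros(4), ss)


class TestUnpenalizedFit:
    def test_zero_b_gives_zero(self):
        ss = make_suffstats(np.zeros(3), np.eye(3))
        assert np.allclose(unpenalized_fit(ss), 0)

    def test_diagonal_solve(self):
        ss = make_suffstats([2.0, -4.0], 2 * np.eye(2))
        assert np.allclose(unpenalized_fit(ss), [1.0, -2.0])

    def test_residual_small_for_nonsingular(self, rng):
        M = rng.normal(size=(4, 4))
        V = M @ M.T + 0.5 * np.eye(4)
        b = rng.normal(size=4)
        ss = make_suffstats(b, V)
        beta = unpenalized_fit(ss)
        assert np.linalg.norm(V @ beta - b) < 1e-10

    def test_score_vanishes_at_fit(self, rng):
        ss = compute_suffstats(make_dataset(rng, 30, 4))
        beta = unpenalized_fit(ss)
        assert np.linalg.norm(ss.b - ss.V @ beta) < 1e-8

    def test_singular_V_warns_min_norm(self):
        V = np.array([[1.0, 1.0], [1.0, 1.0]])
        b = np.array([2.0, 2.0])
        ss = make_suffstats(b, V)
        with pytest.warns(UserWarning, match="rank deficient"):
            beta = unpenalized_fit(ss)
        assert np.allclose(beta, [1.0, 1.0], atol=1e-6)  # minimum-norm solution
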