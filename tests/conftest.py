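"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sparsehaz.data_model import SurvivalDataset
from sparsehaz.suffstats import SuffStats


def make_dataset(rng, n, p, event_prob=0.6, tmax=3.0):
    """A small random right-censored dataset."""
    time = rng.uniform(0.2, tmax, n)
    status = (rng.random(n) < event_prob).astype(float)
    Z = rng.normal(size=(n, p))
    return SurvivalDataset(
        time=time, status=status, covariates=Z,
        feature_ids=[f"g{j}" for j in range(p)],
    )


def make_suffstats(b, V):
    """Build a SuffStats carrying an arbitrary symmetric PSD V (for solver
    tests that need exact control over the quadratic form)."""
    b = np.asarray(b, dtype=float)
    V = np.asarray(V, dtype=float)
    p = b.shape[0]
    # factor V = Zw'Zw / n with n = p rows and no risk-set correction
    L = np.linalg.cholesky(V + 1e-14 * np.eye(p))
    Zw = np.sqrt(p) * L.T
    return SuffStats(b=b, n=p, tau=1.0, Zw=Zw, A=np.zeros((0, p)), _V=V)


def riemann_suffstats(data, step_frac=1e-4):
    """Brute-force discretized-time integration of b and V (midpoint rule).

    Independent of the production path: risk sets are rebuilt at every grid
    point straight from the definitions.
    """
    X, d, Z, tau = data.time, data.status, data.covariates, data.tau
    n, p = Z.shape
    b = np.zeros(p)
    for i in range(n):
        if d[i] == 1 and X[i] <= tau:
            at_risk = X >= X[i]
            b += Z[i] - Z[at_risk].mean(axis=0)
    b /= n
    V = np.zeros((p, p))
    dt = step_frac * tau
    upper = min(tau, X.max())
    for t in np.arange(dt / 2, upper, dt):
        at_risk = X >= t
        if not at_risk.any():
            break
        Zc = Z[at_risk] - Z[at_risk].mean(axis=0)
        V += Zc.T @ Zc * dt
    V /= n
    return b, V


def pairwise_auc_oracle(marker, time, status, t):
    """Exhaustive concordant-pair count for uncensored data at time t."""
    cases = np.where((time <= t) & (status == 1))[0]
    controls = np.where(time > t)[0]
    if cases.size == 0 or controls.size == 0:
        return None
    total = 0.0
    for i in cases:
        for j in controls:
            if marker[i] > marker[j]:
                total += 1.0
            elif marker[i] == marker[j]:
                total += 0.5
    return total / (cases.size * controls.size)


def penalty_oracle(kind, lam, a, theta):
    """Independent vectorized penalty evaluation (textbook formulas)."""
    theta = np.asarray(theta, dtype=float)
    if kind == "lasso":
        return lam * theta
    if kind == "sica":
        return lam * (a + 1) * theta / (a + theta)
    # scad: piecewise integral of lam * rho'
    out = np.where(
        theta <= lam,
        lam * theta,
        np.where(
            theta <= a * lam,
            -(theta**2 - 2 * a * lam * theta + lam**2) / (2 * (a - 1)),
            (a + 1) * lam**2 / 2,
        ),
    )
    return out


def grid_univariate_oracle(spec, v, vjj, lo=-10.0, hi=10.0, step=1e-4):
    """Grid search over the univariate penalized objective; returns min value."""
    bs = np.arange(lo, hi, step)
    pen = penalty_oracle(spec.kind, spec.lam, spec.a, np.abs(bs))
    obj = 0.5 * vjj * bs**2 - v * bs + pen
    return float(obj.min())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
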