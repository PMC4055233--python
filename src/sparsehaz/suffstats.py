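"""Sufficient statistics of the additive hazards pseudo-score.

Under the Lin–Ying additive hazards model lambda(t|Z) = lambda0(t) + beta'Z,
the semiparametric estimating function is linear in beta,

    U(beta) = b - V beta,

with

    b = (1/n) sum_i  int_0^tau (Z_i - Zbar(t)) dN_i(t)
    V = (1/n) sum_i  int_0^tau Y_i(t) (Z_i - Zbar(t))(Z_i - Zbar(t))' dt,

where N_i counts subject i's observed event, Y_i(t) = I(X_i >= t) is the
at-risk indicator, and Zbar(t) is the covariate mean over the current risk
set. Integrating -U gives the least-squares-type loss
L(beta) = beta'V beta / 2 - b'beta, which stands in for a likelihood in both
penalization and cross-validation.

Both integrals are computed exactly: between consecutive distinct observed
times the risk set is constant, so the time integral collapses to a finite sum
of interval lengths times centered moments of the current risk set.

For large p the p x p matrix V is never formed: it admits the factorization

    V = (Zw' Zw - A' A) / n,

with Zw = sqrt(w) * Z row-scaled by each subject's at-risk duration
w_i = min(X_i, tau), and A the (intervals x p) matrix whose k-th row is
sqrt(dt_k / m_k) times the risk-set covariate sum on interval k (m_k = risk
set size). :class:`SuffStats` stores the factors and materializes the dense V
only on request; matrix-vector products, single rows and the diagonal are
available in O(np) without it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import SurvivalDataset

__all__ = ["SuffStats", "compute_suffstats", "loss", "unpenalized_fit"]


@dataclass
class SuffStats:
    """b, V and bookkeeping for the least-squares-type loss L(beta)."""

    b: np.ndarray  # (p,)
    n: int
    tau: float
    Zw: np.ndarray  # (n, p)  sqrt(duration)-scaled covariates
    A: np.ndarray  # (K, p)   sqrt(dt/m)-scaled risk-set sums
    _V: np.ndarray | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.b.shape[0]

    @property
    def V(self) -> np.ndarray:
        """Dense V, materialized (and cached) on first access."""
        if self._V is None:
            self._V = (self.Zw.T @ self.Zw - self.A.T @ self.A) / self.n
        return self._V

    def V_diag(self) -> np.ndarray:
        if self._V is not None:
            return np.diag(self._V).copy()
        return ((self.Zw**2).sum(axis=0) - (self.A**2).sum(axis=0)) / self.n

    def V_matvec(self, x: np.ndarray) -> np.ndarray:
        if self._V is not None:
            return self._V @ x
        return (self.Zw.T @ (self.Zw @ x) - self.A.T @ (self.A @ x)) / self.n

    def V_row(self, j: int) -> np.ndarray:
        if self._V is not None:
            return self._V[j]
        return (self.Zw[:, j] @ self.Zw - self.A[:, j] @ self.A) / self.n


def compute_suffstats(data: SurvivalDataset, dense: bool = False) -> SuffStats:
    """Compute b and V from a dataset, exactly (no time discretization).

    ``dense=True`` additionally materializes V up front. If ``tau`` exceeds the
    last observed time the duration integral is truncated there (the risk set
    is empty beyond it) with a warning; a dataset with zero events yields b = 0
    with a warning.
    """
    X = data.time
    delta = data.status
    Z = data.covariates
    n, p = Z.shape
    tau = data.tau

    if delta.sum() == 0:
        warnings.warn("dataset has zero events: b is identically 0", stacklevel=2)

    t_max = float(X.max())
    if tau > t_max:
        warnings.warn(
            f"tau={tau} exceeds the last observed time {t_max}; risk set is empty "
            "beyond it, integration truncated",
            stacklevel=2,
        )

    # distinct observed times; risk set on (t_{k-1}, t_k] is {X >= t_k}
    distinct = np.unique(X)

    # order subjects by time descending so risk sets grow incrementally
    order = np.argsort(-X, kind="stable")
    Xs = X[order]

    b = np.zeros(p)
    K = distinct.shape[0]
    A = np.zeros((K, p))
    csum = np.zeros(p)  # running risk-set covariate sum
    ptr = 0
    # walk distinct times from the largest down, but intervals need ascending
    # order for the prefix lengths; build risk-set sums descending first
    risk_sums = np.zeros((K, p))
    risk_sizes = np.zeros(K, dtype=np.int64)
    for k in range(K - 1, -1, -1):
        t_k = distinct[k]
        while ptr < n and Xs[ptr] >= t_k:
            csum += Z[order[ptr]]
            ptr += 1
        risk_sums[k] = csum
        risk_sizes[k] = ptr

    # b: event subjects contribute Z_i - Zbar(X_i); events at tau included
    ev = (delta == 1.0) & (X <= tau)
    kidx = np.searchsorted(distinct, X[ev])
    for i, k in zip(np.where(ev)[0], kidx):
        b += Z[i] - risk_sums[k] / risk_sizes[k]
    b /= n

    # V factor A: interval (t_{k-1}, t_k] clipped to [0, tau], risk set of t_k
    prev = 0.0
    for k in range(K):
        t_k = min(float(distinct[k]), tau)
        dt = t_k - prev
        prev = t_k
        m = risk_sizes[k]
        if dt <= 0 or m == 0:
            continue
        A[k] = np.sqrt(dt / m) * risk_sums[k]

    # row-scale Z by sqrt of each subject's total at-risk duration min(X, tau)
    w = np.minimum(X, tau)
    Zw = Z * np.sqrt(w)[:, None]

    ss = SuffStats(b=b, n=n, tau=tau, Zw=Zw, A=A)
    if dense:
        _ = ss.V
    return ss


def loss(beta: np.ndarray, ss: SuffStats) -> float:
    """Least-squares-type loss L(beta) = beta'V beta / 2 - b'beta; L(0) = 0."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (ss.p,):
        raise ValueError(f"beta has shape {beta.shape}, expected ({ss.p},)")
    return float(0.5 * beta @ ss.V_matvec(beta) - ss.b @ beta)


def unpenalized_fit(ss: SuffStats) -> np.ndarray:
    """Root of the pseudo-score: solve V beta = b (intended for p <= n).

    For singular V returns the minimum-norm least-squares solution and warns
    about the rank deficiency.
    """
    V = ss.V
    beta, _, rank, _ = np.linalg.lstsq(V, ss.b, rcond=None)
    if rank < ss.p:
        warnings.warn(
            f"V is rank deficient (rank {rank} < p={ss.p}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    return beta
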