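"""Cross-validated tuning of the regularization parameters.

The CV score follows the least-squares-type loss: with the data split into K
folds, CV(lambda) = (1/K) sum_m L^(m)(betahat^(-m)(lambda)), where
betahat^(-m) is fitted on the data with fold m removed and L^(m) is the loss
built from fold m's own sufficient statistics. K = 10 by default. Since
L(0) = 0, any lambda large enough to zero out every fold's fit scores exactly
0 — the score of the empty model.

Folds are stratified by event status so that every fold contains events (at
n = 86 with 35 events, unstratified folds can easily end up event-free).

SCAD's shape parameter defaults to a = 3.7; SICA has no canonical default, so
its shape is tuned jointly with lambda over a small log-spaced grid
{0.01, 0.1, 1, 10, 100}. A SICA grid point whose fit fails to converge in any
fold (small a can be numerically unstable) receives a +inf score and is never
selected.

Ties in the CV minimum break toward larger lambda — the sparsest model among
equals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_model import SurvivalDataset
from .penalties import PenaltySpec
from .solver import FitResult, default_lambda_grid, fit, lambda_max
from .suffstats import compute_suffstats, loss

__all__ = ["CVResult", "cross_validate", "default_shape", "SICA_SHAPE_GRID"]

SICA_SHAPE_GRID = np.array([0.01, 0.1, 1.0, 10.0, 100.0])


@dataclass
class CVResult:
    """CV score surface and the selected tuning point."""

    kind: str
    lambdas: np.ndarray
    a_values: np.ndarray  # length 1 except for SICA
    score_grid: np.ndarray  # shape (len(a_values), len(lambdas))
    selected_lambda: float
    selected_a: float
    fold_assignment: np.ndarray  # per-sample fold index
    seed: int

    @property
    def selected_spec(self) -> PenaltySpec:
        return PenaltySpec(self.kind, self.selected_lambda, self.selected_a)

    @property
    def scores(self) -> np.ndarray:
        """CV(lambda) at the selected shape (1-d view of the score surface)."""
        i = int(np.argmin(np.abs(self.a_values - self.selected_a)))
        return self.score_grid[i]


def default_shape(kind: str):
    """Default shape parameter: 3.7 for SCAD; the joint-CV grid for SICA."""
    if kind == "scad":
        return 3.7
    if kind == "sica":
        return SICA_SHAPE_GRID.copy()
    raise ValueError(f"penalty {kind!r} has no shape parameter")


def _stratified_folds(status: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Per-sample fold labels, stratified on event status; every fold must
    contain at least one event (re-drawn with a derived seed up to 10 times)."""
    n = status.shape[0]
    y = status.astype(int)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=int(seed) + attempt)
        assign = np.empty(n, dtype=np.int64)
        if K > n:
            raise ValueError(f"K={K} folds exceed n={n} samples")
        try:
            for m, (_, test_idx) in enumerate(skf.split(np.zeros(n), y)):
                assign[test_idx] = m
        except ValueError as e:
            raise ValueError(f"cannot build {K} stratified folds: {e}") from e
        ok = all(status[assign == m].sum() > 0 for m in range(K))
        if ok:
            return assign
    raise ValueError(
        f"could not build {K} folds with at least one event each in 10 attempts "
        f"({int(status.sum())} events, n={n})"
    )


def cross_validate(
    data: SurvivalDataset,
    kind: str,
    lambdas: np.ndarray | None = None,
    a_values=None,
    K: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_sweeps: int = 500,
    n_lambdas: int = 50,
) -> CVResult:
    """K-fold cross-validation of lambda (and the SICA shape a).

    The lambda grid defaults to the full-data path grid (log-spaced from
    lambda_max down to 0.01 * lambda_max). Within each fold the path is
    warm-started from large to small lambda. Deterministic given ``seed``.

    With p >> n the penalized objective can be unbounded below once lambda is
    small enough (V has rank < p); such grid points fail to converge and are
    scored +inf, so they are never selected. ``max_sweeps`` is capped lower
    here than in a one-off fit since those runs are abandoned anyway.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    full_ss = compute_suffstats(data)
    if a_values is None:
        if kind == "sica":
            a_values = default_shape("sica")
        elif kind == "scad":
            a_values = np.array([default_shape("scad")])
        else:
            a_values = np.array([np.nan])
    a_values = np.atleast_1d(np.asarray(a_values, dtype=float))

    assign = _stratified_folds(data.status, K, seed)
    fold_train_ss = []
    fold_test_ss = []
    for m in range(K):
        fold_train_ss.append(compute_suffstats(data.subset(np.where(assign != m)[0])))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-event warnings in tiny test folds
            fold_test_ss.append(compute_suffstats(data.subset(np.where(assign == m)[0])))

    if lambdas is None:
        # grid top: the all-zero threshold across every shape AND every fold
        # (a fold whose threshold exceeds the full-data one would otherwise
        # start its warm path from a divergent nonconvex fit)
        top = 0.0
        for a in a_values:
            av = 3.7 if np.isnan(a) else float(a)
            for ss in [full_ss, *fold_train_ss]:
                top = max(top, lambda_max(ss, kind=kind, a=av))
        if top == 0.0:
            lambdas = np.array([0.0])
        else:
            lambdas = np.geomspace(top, 0.01 * top, n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)

    score = np.zeros((a_values.size, lambdas.size))
    n_nonconverged = 0
    for m in range(K):
        ss_train = fold_train_ss[m]
        ss_test = fold_test_ss[m]
        for ia, a in enumerate(a_values):
            beta = np.zeros(ss_train.p)
            for il, lam in enumerate(lambdas):
                spec = PenaltySpec(kind, float(lam), 3.7 if np.isnan(a) else float(a))
                res = fit(
                    ss_train, spec, beta_init=beta, tol=tol, max_sweeps=max_sweeps
                )
                beta = res.beta
                if not res.converged or not np.all(np.isfinite(beta)):
                    # either certifiably unbounded below (diverged) or past the
                    # practical convergence boundary; difficulty only grows as
                    # lambda shrinks, so the rest of this fold's grid is
                    # abandoned (all scored +inf, never selected)
                    n_nonconverged += lambdas.size - il
                    score[ia, il:] = np.inf
                    break
                if np.isfinite(score[ia, il]):
                    score[ia, il] += loss(beta, ss_test) / K

    if n_nonconverged:
        warnings.warn(
            f"{n_nonconverged} CV grid evaluations did not converge "
            "(small lambda / unstable shape); scored +inf and never selected",
            stacklevel=2,
        )

    # minimum; ties toward larger lambda (grid is decreasing -> smaller index)
    flat_best = np.inf
    best_ia, best_il = 0, 0
    for ia in range(a_values.size):
        for il in range(lambdas.size):
            if score[ia, il] < flat_best - 0.0:  # strict: keeps earliest (largest) lambda
                flat_best = score[ia, il]
                best_ia, best_il = ia, il
    if not np.isfinite(flat_best):
        raise RuntimeError("every CV grid point failed to converge")

    return CVResult(
        kind=kind,
        lambdas=lambdas,
        a_values=a_values,
        score_grid=score,
        selected_lambda=float(lambdas[best_il]),
        selected_a=float(a_values[best_ia]) if not np.isnan(a_values[best_ia]) else 3.7,
        fold_assignment=assign,
        seed=int(seed),
    )


def fit_cv(
    data: SurvivalDataset,
    kind: str,
    K: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    a_values=None,
    tol: float = 1e-7,
) -> tuple[FitResult, CVResult]:
    """Convenience: cross-validate, then fit the selected spec on all the data."""
    cv = cross_validate(
        data, kind, lambdas=lambdas, a_values=a_values, K=K, seed=seed, tol=tol
    )
    ss = compute_suffstats(data)
    # warm start down the path to the selected lambda for the nonconvex penalties
    lams = cv.lambdas[cv.lambdas >= cv.selected_lambda]
    beta = np.zeros(ss.p)
    res = None
    for lam in lams:
        res = fit(ss, PenaltySpec(kind, float(lam), cv.selected_a), beta_init=beta, tol=tol)
        beta = res.beta
    return res, cv
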