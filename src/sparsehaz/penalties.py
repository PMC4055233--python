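"""Penalty families for sparse additive-hazards regression.

Three penalties p_lambda(theta), theta = |beta_j| >= 0:

* lasso:  p(theta) = lambda * theta  (the L1 penalty, rho(theta) = theta)
* SCAD:   defined through its derivative
          rho'(theta) = I(theta <= lambda) + (a*lambda - theta)_+ /
          ((a-1)*lambda) * I(theta > lambda),  shape a > 2 (default 3.7);
          the penalty value is the closed-form piecewise integral of
          lambda * rho' with p(0) = 0:
            theta <= lambda:          lambda * theta
            lambda < theta <= a*l:    (2*a*lambda*theta - theta^2 - lambda^2)
                                      / (2*(a-1))
            theta > a*lambda:         lambda^2 * (a+1) / 2
* SICA:   rho(theta) = (a+1)*theta / (a + theta), shape a > 0; interpolates
          from L0-like behaviour (small a) to the L1 penalty (a -> inf).

The coordinate-descent solver needs, per coordinate, the exact global
minimizer of the one-dimensional problem

    g(beta) = vjj * beta^2 / 2 - v * beta + p_lambda(|beta|),  vjj > 0.

For the lasso this is soft thresholding. For SCAD and SICA the minimizer is
found by enumerating the stationary points of the smooth pieces (plus the
junctions and 0) and picking the best; ties between a nonzero candidate and 0
resolve to 0, preferring sparsity. For SICA the stationary equation on
beta > 0 is a cubic whose relevant root is isolated by exploiting that
g'(beta) = vjj*beta - v + lambda*a*(a+1)/(a+beta)^2 is convex on beta > 0
(so it has at most two roots and only the up-crossing one can be a local
minimum); the root is then polished by bisection to machine precision.

All scalar kernels are numba-compiled so the solver's inner loop can call
them without Python overhead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "PenaltySpec",
    "rho",
    "rho_prime",
    "penalty_value",
    "univariate_minimize",
    "KIND_CODES",
]

KIND_CODES = {"lasso": 0, "scad": 1, "sica": 2}


@dataclass(frozen=True)
class PenaltySpec:
    """A penalty family with its tuning parameters.

    ``lam`` is the regularization strength (lambda >= 0); ``a`` the shape
    parameter, required > 2 for SCAD (default 3.7) and > 0 for SICA, ignored
    for the lasso.
    """

    kind: str
    lam: float
    a: float = 3.7

    def __post_init__(self) -> None:
        if self.kind not in KIND_CODES:
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.kind == "scad" and not self.a > 2:
            raise ValueError("SCAD requires shape a > 2")
        if self.kind == "sica" and not self.a > 0:
            raise ValueError("SICA requires shape a > 0")

    @property
    def code(self) -> int:
        return KIND_CODES[self.kind]


# ---------------------------------------------------------------- scalar kernels


@njit(cache=True)
def _penalty_value(code: int, lam: float, a: float, theta: float) -> float:
    """p_lambda(theta) for theta >= 0."""
    if code == 0:  # lasso
        return lam * theta
    if code == 2:  # sica: lambda * rho(theta)
        return lam * (a + 1.0) * theta / (a + theta)
    # scad: piecewise integral of lambda * rho'
    if lam == 0.0:
        return 0.0
    if theta <= lam:
        return lam * theta
    if theta <= a * lam:
        return (2.0 * a * lam * theta - theta * theta - lam * lam) / (2.0 * (a - 1.0))
    return lam * lam * (a + 1.0) / 2.0


@njit(cache=True)
def _rho_prime(code: int, lam: float, a: float, theta: float) -> float:
    """rho'(theta) for theta > 0 (the lambda-free derivative factor)."""
    if code == 0:
        return 1.0
    if code == 2:
        return a * (a + 1.0) / ((a + theta) * (a + theta))
    # scad
    if theta <= lam:
        return 1.0
    num = a * lam - theta
    if num <= 0.0:
        return 0.0
    return num / ((a - 1.0) * lam)


@njit(cache=True)
def _g_obj(code: int, lam: float, a: float, v: float, vjj: float, beta: float) -> float:
    return 0.5 * vjj * beta * beta - v * beta + _penalty_value(code, lam, a, abs(beta))


@njit(cache=True)
def _umin_scad(lam: float, a: float, v: float, vjj: float) -> float:
    """Exact minimizer of the SCAD-penalized univariate quadratic."""
    s = 1.0 if v >= 0.0 else -1.0
    av = abs(v)
    # candidates on [0, inf): stationary points of the three pieces + junctions
    cand = np.empty(6)
    nc = 0
    cand[nc] = 0.0
    nc += 1
    # piece 1 (0, lam]: vjj*b - av + lam = 0
    b1 = (av - lam) / vjj
    if 0.0 < b1 <= lam:
        cand[nc] = b1
        nc += 1
    # piece 2 (lam, a*lam]: vjj*b - av + (a*lam - b)/(a-1) = 0
    den = vjj - 1.0 / (a - 1.0)
    if den != 0.0:
        b2 = (av - a * lam / (a - 1.0)) / den
        if lam < b2 <= a * lam:
            cand[nc] = b2
            nc += 1
    # piece 3 (a*lam, inf): penalty constant -> unpenalized
    b3 = av / vjj
    if b3 > a * lam:
        cand[nc] = b3
        nc += 1
    # junctions (cover non-stationary pieces / nonconvex den <= 0)
    cand[nc] = lam
    nc += 1
    cand[nc] = a * lam
    nc += 1

    best = 0.0
    fbest = 0.0  # g(0) = 0
    for i in range(nc):
        b = cand[i]
        f = _g_obj(1, lam, a, av, vjj, b)
        if f < fbest:  # strict: ties stay at the sparser candidate seen first (0)
            fbest = f
            best = b
    return s * best


@njit(cache=True)
def _umin_sica(lam: float, a: float, v: float, vjj: float) -> float:
    """Exact minimizer of the SICA-penalized univariate quadratic.

    On beta > 0 (after reducing to v >= 0), g'(beta) = vjj*beta - av +
    lam*a*(a+1)/(a+beta)^2 is convex, so it has at most two roots; only the
    larger (up-crossing) root is a local minimum of g. Bracket it and bisect.
    """
    s = 1.0 if v >= 0.0 else -1.0
    av = abs(v)
    if av == 0.0:
        return 0.0
    hi = av / vjj  # penalty nondecreasing => minimizer in [0, av/vjj]
    c = lam * a * (a + 1.0)

    # g'' = vjj - 2c/(a+beta)^3 rises in beta; g' minimized at bstar
    if c > 0.0:
        bstar = (2.0 * c / vjj) ** (1.0 / 3.0) - a
    else:
        bstar = 0.0
    if bstar < 0.0:
        bstar = 0.0
    if bstar > hi:
        bstar = hi

    gp_star = vjj * bstar - av + c / ((a + bstar) * (a + bstar))
    if gp_star > 0.0:
        return 0.0  # g' > 0 everywhere on (0, hi]: g increasing, minimum at 0

    # up-crossing root lies in [bstar, hi] (g'(hi) >= 0 since penalty' >= 0)
    lo2 = bstar
    hi2 = hi
    for _ in range(200):
        mid = 0.5 * (lo2 + hi2)
        gp = vjj * mid - av + c / ((a + mid) * (a + mid))
        if gp <= 0.0:
            lo2 = mid
        else:
            hi2 = mid
        if hi2 - lo2 <= 1e-15 * (1.0 + hi2):
            break
    b = 0.5 * (lo2 + hi2)

    f = _g_obj(2, lam, a, av, vjj, b)
    if f < 0.0:  # g(0) = 0; strict comparison resolves ties to 0
        return s * b
    return 0.0


@njit(cache=True)
def _umin(code: int, lam: float, a: float, v: float, vjj: float) -> float:
    if lam == 0.0:
        return v / vjj
    if code == 0:
        av = abs(v) - lam
        if av <= 0.0:
            return 0.0
        return (av / vjj) if v > 0.0 else (-av / vjj)
    if code == 1:
        return _umin_scad(lam, a, v, vjj)
    return _umin_sica(lam, a, v, vjj)


# ---------------------------------------------------------------- public API


def rho(spec: PenaltySpec, theta: float) -> float:
    """The lambda-free penalty factor rho(theta), theta >= 0; rho(0) = 0.

    For SCAD, where the family is defined through its derivative, this is
    p_lambda(theta) / lambda (so that p = lambda * rho holds for all three).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0 (pass |beta|)")
    if spec.kind == "lasso":
        return float(theta)
    if spec.kind == "sica":
        return float((spec.a + 1.0) * theta / (spec.a + theta))
    if spec.lam == 0:
        raise ValueError("SCAD rho is defined relative to lambda; need lam > 0")
    return _penalty_value(1, spec.lam, spec.a, float(theta)) / spec.lam


def rho_prime(spec: PenaltySpec, theta: float) -> float:
    """rho'(theta) for theta > 0 (lasso: 1; SICA: a(a+1)/(a+theta)^2; SCAD piecewise)."""
    if theta <= 0:
        raise ValueError("theta must be > 0 (the origin is handled by thresholding)")
    return float(_rho_prime(spec.code, spec.lam, spec.a, float(theta)))


def penalty_value(spec: PenaltySpec, theta: float) -> float:
    """p_lambda(theta) for theta >= 0 (= lambda * rho except written closed-form)."""
    if theta < 0:
        raise ValueError("theta must be >= 0 (pass |beta|)")
    return float(_penalty_value(spec.code, spec.lam, spec.a, float(theta)))


def univariate_minimize(spec: PenaltySpec, v: float, vjj: float) -> float:
    """argmin over beta of vjj*beta^2/2 - v*beta + p_lambda(|beta|).

    The exact coordinate-descent update: soft thresholding for the lasso,
    stationary-point enumeration for SCAD/SICA. Odd in v; ties with 0 resolve
    to 0.
    """
    if vjj <= 0:
        raise ValueError("vjj must be > 0")
    return float(_umin(spec.code, float(spec.lam), float(spec.a), float(v), float(vjj)))
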