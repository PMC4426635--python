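"""Closed-form quantities of the supercritical constant-rate birth-death model.

All formulas follow from Kendall's solution of the linear birth-death process
started from a single individual: with ``r = lambda - mu`` and
``E(t) = exp(-r t)``,

* ``p0(t) = mu (1 - E) / (lambda - mu E)`` — extinction by time ``t``;
* ``p1(t) = r^2 E / (lambda - mu E)^2`` — exactly one survivor at ``t``;
* the number of survivors, conditioned on survival, is geometric with
  failure probability ``beta(t) = lambda (1 - E) / (lambda - mu E)``.

``beta`` doubles as the node-depth distribution of the reconstructed
genealogy: the tree of individuals extant at ``T`` is a coalescent point
process whose inter-tip node depths are i.i.d. with CDF
``beta(tau) / beta(T)`` and whose tip count (given survival) is geometric
with failure probability ``beta(T)``.  The pairwise coalescent-time
distribution :func:`F_bd` below is the exact mixture of maxima of those
depths over the gap between two uniformly chosen tips.  Everything is
expressed through ``exp(-r t)``, so the expressions neither overflow for
large ``r t`` nor degenerate at ``mu = 0`` (where ``beta(t) = 1 - e^{-lambda
t}`` reproduces the Yule case exactly).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .params import BDParams

__all__ = [
    "p0",
    "p1",
    "depth_cdf",
    "expected_popsize",
    "expected_popsize_conditioned",
    "origin_time_for_N",
    "f_bd",
    "F_bd",
]


def _check_nonneg(t: np.ndarray, name: str = "t") -> None:
    if np.any(t < 0):
        raise ValueError(f"{name} must be non-negative")


def p0(t, params: BDParams):
    """Probability that a single founder has no extant descendant after ``t``.

    Identically zero for ``mu = 0``.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    lam, mu = params.birth_rate, params.death_rate
    e = np.exp(-params.growth_rate * t)
    out = mu * (1.0 - e) / (lam - mu * e)
    return out if out.ndim else float(out)


def p1(t, params: BDParams):
    """Probability that a single founder has exactly one extant descendant."""
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    lam, mu = params.birth_rate, params.death_rate
    r = params.growth_rate
    e = np.exp(-r * t)
    out = r * r * e / (lam - mu * e) ** 2
    return out if out.ndim else float(out)


def depth_cdf(t, params: BDParams):
    """CDF ``beta(t) = lambda (1 - e^{-rt}) / (lambda - mu e^{-rt})``.

    This is both the geometric failure probability of the survivor count and
    the node-depth CDF of the reconstructed genealogy (up to normalization by
    ``beta(T)``).  Equals ``(lambda/mu) p0(t)`` for ``mu > 0`` and
    ``1 - e^{-lambda t}`` for ``mu = 0``.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    lam, mu = params.birth_rate, params.death_rate
    # -expm1 keeps precision for small r*t
    one_minus_e = -np.expm1(-params.growth_rate * t)
    out = lam * one_minus_e / (lam - mu * (1.0 - one_minus_e))
    return out if out.ndim else float(out)


def expected_popsize(t, params: BDParams):
    """Unconditional expected population size ``e^{rt}``.

    Extinct trajectories contribute zero to this mean.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    out = np.exp(params.growth_rate * t)
    return out if out.ndim else float(out)


def expected_popsize_conditioned(t, params: BDParams):
    """Expected size at ``t`` given survival of the process until ``T``.

    Conditioning on survival inflates the early growth relative to ``e^{rt}``
    (the "push of the past"); the two means coincide when ``mu = 0``.
    Derived from the geometric law of the survivor count:

    ``E[N(t) | N(T) > 0] = (e^{rt} - p1(t) a / (1 - beta(t) a)^2) / (1 - p0(T))``

    with ``a = p0(T - t)`` the probability that a time-``t`` individual leaves
    no descendant at ``T``.
    """
    t = np.asarray(t, dtype=float)
    T = params.origin_time
    if np.any(t < 0) or np.any(t > T):
        raise ValueError("t must lie in [0, T] (conditioning is on survival to T)")
    a = p0(T - t, params)
    num = np.exp(params.growth_rate * t) - p1(t, params) * a / (
        1.0 - depth_cdf(t, params) * a
    ) ** 2
    out = num / (1.0 - p0(T, params))
    return out if out.ndim else float(out)


def origin_time_for_N(
    N: float, birth_rate: float, death_rate: float, *, method: str = "analytic"
) -> float:
    """Origin time ``T`` such that ``E[N(T) | survival to T] = N``.

    At ``t = T`` the conditioned mean reduces to ``(lambda e^{rT} - mu) / r``,
    which inverts in closed form::

        T = ln(((lambda - mu) N + mu) / lambda) / (lambda - mu)

    For ``mu = 0`` this is ``ln(N) / lambda``.  ``method="brent"`` instead
    solves the same equation by bracketed root finding on
    ``[ln N / lambda, ln N / r]`` (the Yule and deterministic bounds); the two
    agree to ~1e-12 relative and the analytic route is the default.
    """
    if not N > 1:
        raise ValueError(f"N must exceed 1, got {N}")
    lam, mu = birth_rate, death_rate
    r = lam - mu
    if not (lam > 0 and 0 <= mu < lam):
        raise ValueError("need lambda > 0 and 0 <= mu < lambda")
    if method == "analytic":
        return math.log((r * N + mu) / lam) / r
    if method == "brent":
        lo, hi = math.log(N) / lam, math.log(N) / r

        def objective(T: float) -> float:
            p = BDParams(lam, mu, T)
            return expected_popsize_conditioned(T, p) - N

        if mu == 0:
            return lo
        return brentq(objective, lo * (1 - 1e-12), hi * (1 + 1e-12), xtol=1e-13, rtol=1e-14)
    raise ValueError(f"unknown method {method!r}")


# -- pairwise coalescent-time distribution -----------------------------------
#
# Let b = beta(T), u = beta(tau)/beta(T).  Mixing the max-of-gap depth law over
# the (survival-conditioned, >= 2 tips) geometric tip count gives
#
#   F_BD = 2 u (1-b) / (b^2 (1-u)^2) * [ (1-bu) ln((1-bu)/(1-b)) - b (1-u) ]
#   f_BD = 2 (1-b) / b^2 * [ (1+u-2bu) L - b (1-u^2) ] / (1-u)^3 * u'(tau)
#
# with L = ln((1-bu)/(1-b)) and u'(tau) = lambda p1(tau) / beta(T).  Both
# brackets vanish to high order as u -> 1, so near tau = T they are replaced
# by their series in eps = 1 - u (a = b/(1-b)):
#
#   F_BD = u (1 - a eps / 3 + (a eps)^2 / 6 + ...)
#   f_BD = [(3 - 2b) - a (2 - b) eps] / (3 (1-b)) * u'(tau) + O(eps^2)

_SERIES_CUTOFF = 1e-3


def _fbd_u_and_b(tau, params: BDParams):
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    _check_nonneg(tau, "tau")
    T = params.origin_time
    b = depth_cdf(T, params)
    u = np.where(tau >= T, 1.0, depth_cdf(np.minimum(tau, T), params) / b)
    return tau, u, float(b), T


def F_bd(tau, params: BDParams):
    """CDF of the coalescence time of two random extant individuals.

    Exact under the BD model conditioned on at least two survivors at ``T``;
    all mass lies in ``[0, T]`` so ``F_bd(T) = 1``.
    """
    tau_arr, u, b, _T = _fbd_u_and_b(tau, params)
    if 1.0 - b == 0.0:
        # beta(T) indistinguishable from 1: the expected population is so
        # large that the pair coalescence time degenerates to a point mass
        # at T (the CDF at any fixed u < 1 vanishes like (1-b) ln(1/(1-b)))
        out = (u >= 1.0).astype(float)
        return out if np.ndim(tau) else float(out[0])
    a = b / (1.0 - b)
    eps = 1.0 - u
    out = np.empty_like(u)
    small = a * eps < _SERIES_CUTOFF
    if np.any(small):
        ae = a * eps[small]
        out[small] = u[small] * (1.0 - ae / 3.0 + ae * ae / 6.0)
    big = ~small
    if np.any(big):
        ub, eb = u[big], eps[big]
        L = np.log1p(a * eb)
        bracket = (1.0 - b * ub) * L - b * eb
        out[big] = 2.0 * ub * (1.0 - b) / (b * b * eb * eb) * bracket
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(tau) else float(out[0])


def f_bd(tau, params: BDParams):
    """Density of the pairwise coalescence time; zero for ``tau > T``."""
    tau_arr, u, b, T = _fbd_u_and_b(tau, params)
    if 1.0 - b == 0.0:
        # degenerate point mass at T (see F_bd); no finite density to report
        out = np.zeros_like(u)
        return out if np.ndim(tau) else float(out[0])
    a = b / (1.0 - b)
    eps = 1.0 - u
    w = params.birth_rate * p1(np.minimum(tau_arr, T), params) / b
    out = np.zeros_like(u)
    inside = tau_arr <= T
    small = inside & (a * eps < _SERIES_CUTOFF)
    if np.any(small):
        ae = a * eps[small]
        out[small] = ((3.0 - 2.0 * b) - (2.0 - b) * ae) / (3.0 * (1.0 - b)) * w[small]
    big = inside & ~small
    if np.any(big):
        ub, eb = u[big], eps[big]
        L = np.log1p(a * eb)
        numer = (1.0 + ub - 2.0 * b * ub) * L - b * (1.0 - ub * ub)
        out[big] = 2.0 * (1.0 - b) / (b * b) * numer / eb**3 * w[big]
    out = np.maximum(out, 0.0)
    return out if np.ndim(tau) else float(out[0])
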