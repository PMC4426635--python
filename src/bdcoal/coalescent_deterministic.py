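"""Deterministic-growth coalescent models for a pair of lineages.

Two variants are implemented.

CD — coalescent with deterministic exponential growth.  The pair coalesces
with hazard ``1/(N(tau) rho)``, ``N(tau) = N0 e^{-r tau}``, giving the
cumulative hazard ``(e^{r tau} - 1)/(r N0 rho)`` and hence closed-form
density/CDF with support ``(0, inf)``: a pair may coalesce at ``tau > T``,
i.e. before the origin of the matched birth-death process.  The mass beyond
``T = ln(N0)/r`` does not vanish even as ``N0 -> inf``
(:func:`ancestral_mass_limit`), which is the model's characteristic
pathology.

CDN — the same construction with ``N(tau)`` replaced by the survival-
conditioned birth-death mean ("push of the past" curve).  That size function
is only defined on ``[0, T]``, so the distribution is defective: the deficit
``1 - F_cdn(T)`` is reported as an explicit no-coalescence atom.  Its
cumulative hazard has no elementary closed form and is evaluated by adaptive
quadrature (abs tol 1e-12, rel tol 1e-10); tests verify it against an
independent fixed-order integration.

Both variants support the ``N - 1`` pair-rate convention (hazard
``1/((N(tau)-1) rho)``), under which the hazard diverges as ``N(tau) -> 1``
at ``tau -> T`` and every pair coalesces within ``[0, T]``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from . import bd_analytic
from .params import BDParams, CDParams

__all__ = [
    "from_bd",
    "f_cd",
    "F_cd",
    "prob_coal_within_T",
    "ancestral_mass_limit",
    "conditioned_popsize_backward",
    "f_cdn",
    "F_cdn",
    "cdn_no_coalescence_mass",
]

_VARIANTS = ("per_N", "per_N_minus_1")


def _check_variant(variant: str) -> None:
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")


def from_bd(params: BDParams) -> CDParams:
    """Map BD parameters to the matched CD parameterization.

    ``r = lambda - mu``, ``N0 = e^{rT}`` and ``rho = 1/(2 lambda)``.
    """
    r = params.growth_rate
    return CDParams(
        growth_rate=r,
        present_size=math.exp(r * params.origin_time),
        generation_time=params.generation_time,
    )


def _cum_hazard_cd(tau: np.ndarray, params: CDParams, variant: str) -> np.ndarray:
    r, theta = params.growth_rate, params.theta
    if variant == "per_N":
        return np.expm1(r * tau) / (r * theta)
    # per_N_minus_1: integral of e^{rs} / ((N0 - e^{rs}) rho) on [0, tau];
    # diverges as tau -> ln(N0)/r where the deterministic size hits 1
    N0, rho = params.present_size, params.generation_time
    e = np.minimum(np.exp(np.minimum(r * tau, np.log(N0))), N0)
    with np.errstate(divide="ignore"):
        out = (math.log(N0 - 1.0) - np.log(N0 - e)) / (r * rho)
    return np.where(e >= N0, np.inf, out)


def F_cd(tau, params: CDParams, *, variant: str = "per_N"):
    """Probability that the pair has coalesced by backward time ``tau``."""
    _check_variant(variant)
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("tau must be non-negative")
    out = -np.expm1(-_cum_hazard_cd(t, params, variant))
    return out if out.ndim else float(out)


def f_cd(tau, params: CDParams, *, variant: str = "per_N"):
    """Density of the pair coalescence time under the CD model."""
    _check_variant(variant)
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("tau must be non-negative")
    r, rho, N0 = params.growth_rate, params.generation_time, params.present_size
    e = np.exp(r * t)
    size = N0 / e
    if variant == "per_N":
        hazard = 1.0 / (size * rho)
    else:
        with np.errstate(divide="ignore"):
            hazard = np.where(size > 1.0, 1.0 / ((size - 1.0) * rho), np.inf)
    surv = np.exp(-_cum_hazard_cd(t, params, variant))
    out = np.where(np.isfinite(hazard), hazard * surv, 0.0)
    return out if out.ndim else float(out)


def prob_coal_within_T(params: CDParams, T: float, *, variant: str = "per_N") -> float:
    """Probability the pair coalesces within ``[0, T]``; strictly below 1 for per_N."""
    if not T > 0:
        raise ValueError("T must be positive")
    return float(F_cd(T, params, variant=variant))


def ancestral_mass_limit(params, death_rate: float | None = None) -> float:
    """Large-``N0`` limit of the probability of coalescing at ``tau > T``.

    With ``T = ln(N0)/r`` the within-``[0, T]`` coalescence probability is
    ``1 - exp(-(N0 - 1)/(r N0 rho))``, whose complement tends to
    ``exp(-1/(r rho))`` as ``N0 -> inf``.  Under the BD mapping
    ``rho = 1/(2 lambda)`` this is ``exp(-2 lambda / (lambda - mu))``:
    ``e^{-2} ~= 0.135`` at ``mu = 0`` and decreasing to 0 as ``mu -> lambda``.

    Accepts either a :class:`BDParams` or the pair ``(birth_rate, death_rate)``.
    """
    if isinstance(params, BDParams):
        lam, mu = params.birth_rate, params.death_rate
    else:
        lam, mu = float(params), float(death_rate)
        if not (lam > 0 and 0 <= mu < lam):
            raise ValueError("need lambda > 0 and 0 <= mu < lambda")
    return math.exp(-2.0 * lam / (lam - mu))


# -- CDN: coalescent driven by the survival-conditioned BD mean size ---------


def conditioned_popsize_backward(tau, params: BDParams):
    """Survival-conditioned BD mean size as a function of backward time."""
    t = np.asarray(tau, dtype=float)
    return bd_analytic.expected_popsize_conditioned(params.origin_time - t, params)


def _cdn_hazard(params: BDParams, variant: str):
    rho = params.generation_time

    def hazard(s: float) -> float:
        n = conditioned_popsize_backward(s, params)
        if variant == "per_N":
            return 1.0 / (n * rho)
        return np.inf if n <= 1.0 else 1.0 / ((n - 1.0) * rho)

    return hazard


def _cdn_cum_hazard(tau: np.ndarray, params: BDParams, variant: str) -> np.ndarray:
    """Cumulative CDN hazard by adaptive quadrature, accumulated over sorted tau."""
    hazard = _cdn_hazard(params, variant)
    T = params.origin_time
    flat = np.atleast_1d(tau).ravel()
    order = np.argsort(flat)
    out = np.empty_like(flat)
    acc, prev = 0.0, 0.0
    for idx in order:
        x = min(flat[idx], T)
        if variant == "per_N_minus_1" and x >= T:
            # hazard is non-integrable at tau = T; the value is exactly inf
            out[idx] = np.inf
            continue
        if x > prev:
            val, _err = quad(hazard, prev, x, epsabs=1e-12, epsrel=1e-10, limit=200)
            acc += val
            prev = x
        out[idx] = acc if flat[idx] < T or variant == "per_N" else np.inf
    # per_N_minus_1 hazard diverges (logarithmically) at tau = T: F(T) = 1
    return out.reshape(np.shape(tau))


def F_cdn(tau, params: BDParams, *, variant: str = "per_N"):
    """Defective CDF of the CDN coalescence time on ``[0, T]``.

    ``F_cdn(T) < 1`` under ``per_N``; the deficit is
    :func:`cdn_no_coalescence_mass`.  For ``tau > T`` the CDF stays at its
    value at ``T`` (no coalescence can occur before the origin).
    """
    _check_variant(variant)
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("tau must be non-negative")
    out = -np.expm1(-_cdn_cum_hazard(np.minimum(t, params.origin_time), params, variant))
    if variant == "per_N_minus_1":
        out = np.where(t >= params.origin_time, 1.0, out)
    return out if out.ndim else float(out)


def f_cdn(tau, params: BDParams, *, variant: str = "per_N"):
    """CDN coalescence-time density; zero outside ``[0, T]``."""
    _check_variant(variant)
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("tau must be non-negative")
    T = params.origin_time
    hazard = _cdn_hazard(params, variant)
    flat = np.atleast_1d(t).ravel()
    surv = np.exp(-_cdn_cum_hazard(np.minimum(flat, T), params, variant)).ravel()
    h = np.array([hazard(min(x, T)) for x in flat])
    out = np.where(
        (flat > T) | ~np.isfinite(h), 0.0, np.where(np.isfinite(h), h, 0.0) * surv
    )
    return out.reshape(np.shape(t)) if np.ndim(tau) else float(out[0])


def cdn_no_coalescence_mass(params: BDParams, *, variant: str = "per_N") -> float:
    """Probability that the pair never coalesces within ``[0, T]`` (the atom)."""
    _check_variant(variant)
    if variant == "per_N_minus_1":
        return 0.0
    return float(np.exp(-_cdn_cum_hazard(np.asarray(params.origin_time), params, variant)))
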