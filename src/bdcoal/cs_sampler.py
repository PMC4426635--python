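"""Stochastic coalescent (CS): pairwise coalescence along BD trajectories.

Given one realized birth-death trajectory conditioned to have at least two
individuals at the present ``T``, the pair of sampled lineages coalesces
backward in time with the piecewise-constant hazard ``1/(N_hat(tau) rho)``
(or ``1/((N_hat(tau)-1) rho)`` under the ``N - 1`` rate convention), where
``N_hat`` is the trajectory's size.  Sampling is exact: a standard
exponential is inverted through the piecewise-linear cumulative hazard, with
no time discretization.  If the required hazard exceeds the total accumulated
by ``tau = T`` the pair fails to coalesce within ``[0, T]``; that outcome is
the sentinel :data:`NO_COALESCENCE`, never a number.  Under the ``N - 1``
convention a segment with ``N_hat = 1`` has infinite hazard, so the pair
coalesces at the most recent endpoint of that segment and no-coalescence is
impossible.

The ensemble estimator draws one coalescence time per independent
conditioned trajectory (draws within one trajectory would be dependent
through it), yielding a binomial standard error at each grid point.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .bd_simulator import Trajectory, simulate_trajectories
from .params import BDParams

__all__ = [
    "NO_COALESCENCE",
    "CoalCDF",
    "default_tau_grid",
    "trajectory_cumulative_hazard",
    "sample_cs_time",
    "sample_cs_times",
    "estimate_cs_cdf",
]


class _NoCoalescence(Enum):
    NO_COALESCENCE = "no_coalescence"

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_COALESCENCE"


NO_COALESCENCE = _NoCoalescence.NO_COALESCENCE
"""Sentinel for a pair that fails to coalesce within ``[0, T]``."""


@dataclass
class CoalCDF:
    """A model-labelled pairwise coalescent-time CDF on a backward-time grid.

    ``cdf_values[i]`` is the probability of coalescence by ``tau_grid[i]``;
    ``no_coalescence_mass`` is the atom of pairs that never coalesce within
    ``[0, T]`` (zero for the BD model, positive for CDN and possibly CS).
    ``n_replicates`` is 0 for analytic curves.
    """

    model: str
    rate_variant: str
    tau_grid: np.ndarray
    cdf_values: np.ndarray
    no_coalescence_mass: float
    n_replicates: int
    params: BDParams
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.cdf_values = np.asarray(self.cdf_values, dtype=float)
        if self.tau_grid.shape != self.cdf_values.shape:
            raise ValueError("tau_grid and cdf_values must be parallel")
        if np.any(np.diff(self.cdf_values) < -1e-12):
            raise ValueError("cdf_values must be monotone non-decreasing")

    @property
    def coalesced_by_T(self) -> float:
        """Fraction of pairs having coalesced within ``[0, T]``."""
        return float(self.cdf_values[-1])

    def normalized_at_T(self) -> "CoalCDF":
        """Renormalize so the CDF reaches 1 at ``T`` (drops the atom)."""
        top = self.coalesced_by_T
        if top <= 0:
            raise ValueError("cannot normalize an all-zero CDF")
        return CoalCDF(
            self.model, self.rate_variant, self.tau_grid, self.cdf_values / top,
            0.0, self.n_replicates, self.params, self.seed,
        )

    def to_frame(self):
        """Long-format table: one row per grid point plus shared metadata."""
        import pandas as pd

        p = self.params
        return pd.DataFrame(
            {
                "model": self.model,
                "rate_variant": self.rate_variant,
                "tau": self.tau_grid,
                "cdf": self.cdf_values,
                "no_coalescence_mass": self.no_coalescence_mass,
                "n_replicates": self.n_replicates,
                "lambda": p.birth_rate,
                "mu": p.death_rate,
                "T": p.origin_time,
                "seed": -1 if self.seed is None else self.seed,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.10g")


def default_tau_grid(T: float, n: int = 512) -> np.ndarray:
    """``n`` equally spaced backward times on ``[0, T)`` plus the exact ``T``."""
    return np.append(np.linspace(0.0, T, n, endpoint=False), T)


def trajectory_cumulative_hazard(
    traj: Trajectory, rho: float, variant: str = "per_N"
):
    """Backward segment boundaries and cumulative pair-coalescence hazard.

    Returns ``(tau_bounds, cum_hazard)``: ``tau_bounds[0] = 0`` at the
    present, ``tau_bounds[-1] = T`` at the origin, and ``cum_hazard[i]`` the
    hazard accumulated walking backward to ``tau_bounds[i]``.  Entries become
    ``inf`` from the first ``N_hat = 1`` segment onward under
    ``per_N_minus_1``.
    """
    T = traj.duration
    # forward segment starts: 0, event times; sizes on each segment
    sizes = np.concatenate(([1], traj.sizes()))
    starts = np.concatenate(([0.0], traj.event_times))
    ends = np.concatenate((traj.event_times, [T]))
    # walk backward: reverse segments
    seg_len = (ends - starts)[::-1]
    seg_n = sizes[::-1].astype(float)
    if variant == "per_N":
        rates = 1.0 / (seg_n * rho)
    elif variant == "per_N_minus_1":
        with np.errstate(divide="ignore"):
            rates = np.where(seg_n > 1, 1.0 / ((seg_n - 1.0) * rho), np.inf)
    else:
        raise ValueError(f"unknown rate variant {variant!r}")
    tau_bounds = np.concatenate(([0.0], np.cumsum(seg_len)))
    tau_bounds[-1] = T
    cum = np.concatenate(([0.0], np.cumsum(rates * seg_len)))
    return tau_bounds, cum


def _invert_hazard(tau_bounds, cum, draws):
    """Map standard-exponential draws to coalescence times (or inf)."""
    idx = np.searchsorted(cum, draws, side="right") - 1
    out = np.full(draws.shape, np.inf)
    inside = idx < len(tau_bounds) - 1
    i = idx[inside]
    with np.errstate(invalid="ignore"):
        rate = (cum[i + 1] - cum[i]) / (tau_bounds[i + 1] - tau_bounds[i])
        frac = (draws[inside] - cum[i]) / rate
    # infinite-rate segment: coalesce at its most recent endpoint
    frac = np.where(np.isfinite(rate), frac, 0.0)
    out[inside] = tau_bounds[i] + frac
    return out


def sample_cs_time(
    traj: Trajectory, rho: float, variant: str = "per_N", rng_seed=0
):
    """One pairwise coalescence time along ``traj``; may be NO_COALESCENCE."""
    if traj.final_size < 2:
        raise ValueError(
            "trajectory must have at least two individuals at T to sample a pair"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    tau_bounds, cum = trajectory_cumulative_hazard(traj, rho, variant)
    tau = _invert_hazard(tau_bounds, cum, rng.standard_exponential(1))[0]
    return NO_COALESCENCE if np.isinf(tau) else float(tau)


def sample_cs_times(
    traj: Trajectory, rho: float, n: int, variant: str = "per_N", rng_seed=0
) -> np.ndarray:
    """``n`` i.i.d. draws along one fixed trajectory (``inf`` = no coalescence).

    Useful for validating the sampler against the trajectory's closed-form
    piecewise-exponential distribution; for ensemble CDF estimation use one
    draw per trajectory instead (draws here share the trajectory and are
    exchangeable but not independent across trajectories).
    """
    if traj.final_size < 2:
        raise ValueError("trajectory must have at least two individuals at T")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    tau_bounds, cum = trajectory_cumulative_hazard(traj, rho, variant)
    return _invert_hazard(tau_bounds, cum, rng.standard_exponential(n))


def estimate_cs_cdf(
    params: BDParams,
    n_traj: int,
    variant: str = "per_N",
    tau_grid: np.ndarray | None = None,
    rng_seed: int = 0,
    condition: str = "at_least_two_at_T",
    draws_per_traj: int = 1,
    progress: bool = False,
) -> CoalCDF:
    """Monte-Carlo estimate of the CS coalescent-time CDF.

    Simulates ``n_traj`` conditioned trajectories (rejection sampling) and
    draws ``draws_per_traj`` coalescence times per trajectory (default 1, so
    grid-point standard errors are at most ``0.5 / sqrt(n_traj)``).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be at least 1")
    if tau_grid is None:
        tau_grid = default_tau_grid(params.origin_time)
    rho = params.generation_time
    taus = np.empty(n_traj * draws_per_traj)
    for k in range(n_traj):
        traj = None
        # trajectory and CS draw share replicate seed rng_seed + k
        rng = np.random.default_rng(rng_seed + k)
        trajs, _ = simulate_trajectories(params, 1, condition, rng)
        traj = trajs[0]
        taus[k * draws_per_traj : (k + 1) * draws_per_traj] = sample_cs_times(
            traj, rho, draws_per_traj, variant, rng
        )
        if progress and (k + 1) % 1000 == 0:  # pragma: no cover
            print(f"  cs: {k + 1}/{n_traj} trajectories", file=sys.stderr)
    cdf = np.searchsorted(np.sort(taus), tau_grid, side="right") / taus.size
    atom = float(np.mean(np.isinf(taus)))
    return CoalCDF(
        "CS", variant, tau_grid, cdf, atom, n_traj, params, seed=rng_seed
    )
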