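"""Parameterizations of the birth-death process and the growth coalescent.

Two parameter sets describe the same exponentially growing population:

* :class:`BDParams` — the forward-time constant-rate birth-death (BD)
  process: per-capita birth rate ``lambda``, per-capita death rate ``mu``
  (``0 <= mu < lambda``) and the time ``T`` since the origin (one initial
  individual).
* :class:`CDParams` — the backward-time coalescent with deterministic
  exponential growth: net growth rate ``r``, present-day size ``N0`` and
  generation time ``rho``, entering only through the pair-coalescence rate
  ``1/(N(tau) * rho)`` with ``N(tau) = N0 * exp(-r * tau)``.

The standard mapping between them is ``r = lambda - mu``,
``N0 = exp(r * T)`` and ``rho = 1 / (2 * lambda)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BDParams", "CDParams"]


@dataclass(frozen=True)
class BDParams:
    """Constant-rate birth-death process started from one individual.

    Parameters
    ----------
    birth_rate
        Per-individual birth (transmission) rate ``lambda > 0``.
    death_rate
        Per-individual death (removal) rate ``mu`` with ``0 <= mu < lambda``;
        only supercritical processes are considered.
    origin_time
        Forward duration ``T > 0`` of the process; in backward time the
        population consisted of a single individual at ``tau = T``.
    """

    birth_rate: float
    death_rate: float
    origin_time: float

    def __post_init__(self) -> None:
        if not self.birth_rate > 0:
            raise ValueError(f"birth_rate must be positive, got {self.birth_rate}")
        if not 0 <= self.death_rate < self.birth_rate:
            raise ValueError(
                "death_rate must satisfy 0 <= mu < lambda, got "
                f"mu={self.death_rate}, lambda={self.birth_rate}"
            )
        if not self.origin_time > 0:
            raise ValueError(f"origin_time must be positive, got {self.origin_time}")

    @property
    def growth_rate(self) -> float:
        """Net growth rate ``r = lambda - mu`` (positive)."""
        return self.birth_rate - self.death_rate

    @property
    def R0(self) -> float:
        """Basic reproductive number ``lambda / mu``; ``inf`` when ``mu = 0``."""
        if self.death_rate == 0:
            return math.inf
        return self.birth_rate / self.death_rate

    @property
    def generation_time(self) -> float:
        """Coalescent generation time ``rho = 1 / (2 * lambda)``."""
        return 1.0 / (2.0 * self.birth_rate)

    @classmethod
    def from_R0(cls, birth_rate: float, R0: float, origin_time: float) -> "BDParams":
        """Build parameters from ``(lambda, R0, T)`` with ``mu = lambda / R0``."""
        if not R0 > 1:
            raise ValueError(f"R0 must exceed 1 for a supercritical process, got {R0}")
        return cls(birth_rate, birth_rate / R0, origin_time)


@dataclass(frozen=True)
class CDParams:
    """Coalescent with deterministic exponential growth.

    ``theta = N0 * rho`` is the only combination in which ``N0`` and ``rho``
    enter the coalescent-time distribution.
    """

    growth_rate: float
    present_size: float
    generation_time: float

    def __post_init__(self) -> None:
        if not self.growth_rate > 0:
            raise ValueError(f"growth_rate must be positive, got {self.growth_rate}")
        if not self.present_size > 1:
            raise ValueError(f"present_size must exceed 1, got {self.present_size}")
        if not self.generation_time > 0:
            raise ValueError(
                f"generation_time must be positive, got {self.generation_time}"
            )

    @property
    def theta(self) -> float:
        """Coalescent scale ``theta = N0 * rho``."""
        return self.present_size * self.generation_time

    @property
    def origin_time(self) -> float:
        """Time ``T = ln(N0) / r`` at which the deterministic size reaches 1."""
        return math.log(self.present_size) / self.growth_rate

    def popsize(self, tau):
        """Deterministic backward-time population size ``N0 * exp(-r * tau)``."""
        import numpy as np

        return self.present_size * np.exp(-self.growth_rate * np.asarray(tau, float))
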