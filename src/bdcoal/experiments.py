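"""Grid experiments comparing BD, CD, CDN and CS coalescent-time CDFs.

The comparison fixes ``lambda = 0.5`` (setting the time unit, so
``rho = 1``), scans ``R0`` over {1.05, 1.3, 1.6, 2, 4, 10, 20} and target
present-day sizes ``N0`` over {10, 100, 1000, 10000}, and for each cell sets
``mu = lambda / R0`` and the origin time ``T`` so that the survival-
conditioned expected size at ``T`` equals ``N0``.  Per cell it produces the
four models' CDF curves (the stochastic CS curve by Monte Carlo, the rest
analytically), the dashed ``N - 1``-rate variants, CSV artefacts, an overlay
plot, and a summary row with each model's coalesced-by-``T`` fraction and
the CD model's large-``N0`` ancestral mass.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bd_analytic, coalescent_deterministic as cd
from .cs_sampler import CoalCDF, default_tau_grid, estimate_cs_cdf
from .params import BDParams

__all__ = [
    "ExperimentConfig",
    "cell_params",
    "bd_cdf_curve",
    "cd_cdf_curve",
    "cdn_cdf_curve",
    "run_cell",
    "run_grid",
    "limit_table",
]

logger = logging.getLogger("bdcoal")

DEFAULT_R0 = (1.05, 1.3, 1.6, 2.0, 4.0, 10.0, 20.0)
DEFAULT_N0 = (10.0, 100.0, 1000.0, 10000.0)


@dataclass
class ExperimentConfig:
    """Settings of one comparison run; defaults reproduce the standard grid."""

    birth_rate: float = 0.5
    R0_list: tuple = DEFAULT_R0
    N0_list: tuple = DEFAULT_N0
    n_traj: int = 10_000
    rate_variants: tuple = ("per_N", "per_N_minus_1")
    seed: int = 0
    output_dir: str = "bdcoal_out"
    normalize_at_T: bool = False
    grid_points: int = 512
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.R0_list or not self.N0_list:
            raise ValueError("R0_list and N0_list must be non-empty")
        if any(r <= 1 for r in self.R0_list):
            raise ValueError("all R0 values must exceed 1")
        if any(n <= 1 for n in self.N0_list):
            raise ValueError("all N0 values must exceed 1")

    @classmethod
    def from_json(cls, path: str, **overrides) -> "ExperimentConfig":
        """Load from a JSON file; keyword overrides win on conflict."""
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("R0_list", "N0_list", "rate_variants"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def cell_params(birth_rate: float, R0: float, N0: float) -> BDParams:
    """BD parameters of one grid cell: ``mu = lambda/R0``, ``T`` from ``N0``."""
    mu = birth_rate / R0
    T = bd_analytic.origin_time_for_N(N0, birth_rate, mu)
    return BDParams(birth_rate, mu, T)


def bd_cdf_curve(params: BDParams, tau_grid=None) -> CoalCDF:
    """Analytic BD pairwise-coalescence CDF on the reporting grid."""
    if tau_grid is None:
        tau_grid = default_tau_grid(params.origin_time)
    return CoalCDF(
        "BD", "per_N", tau_grid, bd_analytic.F_bd(tau_grid, params),
        0.0, 0, params,
    )


def cd_cdf_curve(params: BDParams, tau_grid=None, variant: str = "per_N") -> CoalCDF:
    """Analytic CD CDF; its mass beyond ``T`` appears as no_coalescence_mass."""
    if tau_grid is None:
        tau_grid = default_tau_grid(params.origin_time)
    cdp = cd.from_bd(params)
    values = cd.F_cd(tau_grid, cdp, variant=variant)
    return CoalCDF(
        "CD", variant, tau_grid, values, float(1.0 - values[-1]), 0, params
    )


def cdn_cdf_curve(params: BDParams, tau_grid=None, variant: str = "per_N") -> CoalCDF:
    """Analytic CDN CDF with its explicit no-coalescence atom."""
    if tau_grid is None:
        tau_grid = default_tau_grid(params.origin_time)
    values = cd.F_cdn(tau_grid, params, variant=variant)
    return CoalCDF(
        "CDN", variant, tau_grid, values,
        cd.cdn_no_coalescence_mass(params, variant=variant), 0, params,
    )


def run_cell(
    config: ExperimentConfig, R0: float, N0: float
) -> tuple[list[CoalCDF], dict]:
    """All curves and the summary row for one ``(R0, N0)`` grid cell."""
    t0 = time.perf_counter()
    params = cell_params(config.birth_rate, R0, N0)
    grid = default_tau_grid(params.origin_time, config.grid_points)
    curves = [bd_cdf_curve(params, grid)]
    for variant in config.rate_variants:
        curves.append(cd_cdf_curve(params, grid, variant))
        curves.append(cdn_cdf_curve(params, grid, variant))
        curves.append(
            estimate_cs_cdf(
                params, config.n_traj, variant, grid, rng_seed=config.seed
            )
        )
    if config.normalize_at_T:
        curves = [c.normalized_at_T() for c in curves]
    summary = {
        "R0": R0,
        "N0": N0,
        "lambda": params.birth_rate,
        "mu": params.death_rate,
        "T": params.origin_time,
        "cd_ancestral_mass_limit": cd.ancestral_mass_limit(params),
    }
    for c in curves:
        key = f"{c.model}_{c.rate_variant}_coalesced_by_T".lower()
        summary[key] = c.coalesced_by_T
    # runtime is logged, not stored: summary files must be seed-reproducible
    logger.info(
        "cell R0=%g N0=%g mu=%g T=%g seed=%d runtime=%.2fs",
        R0, N0, params.death_rate, params.origin_time, config.seed,
        time.perf_counter() - t0,
    )
    return curves, summary


def _plot_cell(curves: list[CoalCDF], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"BD": "black", "CD": "tab:blue", "CDN": "lightblue", "CS": "tab:red"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        style = ":" if c.rate_variant == "per_N_minus_1" else "-"
        label = c.model + (" (N-1)" if c.rate_variant == "per_N_minus_1" else "")
        ax.plot(c.tau_grid, c.cdf_values, style, color=colors[c.model], label=label)
        ax.plot(c.tau_grid[-1], c.coalesced_by_T, "o", ms=3, color=colors[c.model])
        if c.n_replicates:  # +-2 SE Monte-Carlo band
            se = np.sqrt(
                np.clip(c.cdf_values * (1 - c.cdf_values), 0, None) / c.n_replicates
            )
            ax.fill_between(
                c.tau_grid, c.cdf_values - 2 * se, c.cdf_values + 2 * se,
                color=colors[c.model], alpha=0.15, linewidth=0,
            )
    p = curves[0].params
    ax.set_xlabel("backward time tau")
    ax.set_ylabel("P(coalesced by tau)")
    ax.set_title(
        f"R0={p.R0:.3g}, T={p.origin_time:.3g} (lambda={p.birth_rate:g})"
    )
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_grid(config: ExperimentConfig):
    """Run every grid cell; write CSVs, plots and a summary table.

    Returns ``(curves_by_cell, summary_frame)``.  Cells whose rejection guard
    trips are recorded with ``status='failed'`` in the summary and skipped.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    curves_by_cell: dict[tuple, list[CoalCDF]] = {}
    for R0 in config.R0_list:
        for N0 in config.N0_list:
            tag = f"r0_{R0:g}_n0_{N0:g}"
            try:
                curves, summary = run_cell(config, R0, N0)
            except RuntimeError as exc:
                logger.error("cell %s failed: %s", tag, exc)
                rows.append({"R0": R0, "N0": N0, "status": "failed", "error": str(exc)})
                continue
            summary["status"] = "ok"
            rows.append(summary)
            curves_by_cell[(R0, N0)] = curves
            frame = pd.concat([c.to_frame() for c in curves], ignore_index=True)
            frame.to_csv(outdir / f"cdf_{tag}.csv", index=False, float_format="%.10g")
            if config.make_plots:
                _plot_cell(curves, outdir / f"cdf_{tag}.png")
    summary_frame = pd.DataFrame(rows)
    summary_frame.to_csv(outdir / "summary.csv", index=False, float_format="%.10g")
    return curves_by_cell, summary_frame


def limit_table(birth_rate: float = 0.5, n_mu: int = 21) -> pd.DataFrame:
    """Large-``N0`` ancestral mass versus ``mu`` at fixed ``lambda``.

    The column decreases monotonically from ``e^{-2} ~= 0.135`` at ``mu = 0``
    toward 0 as ``mu -> lambda``.
    """
    mus = np.linspace(0.0, 0.999 * birth_rate, n_mu)
    mass = [cd.ancestral_mass_limit(birth_rate, m) for m in mus]
    return pd.DataFrame(
        {
            "lambda": birth_rate,
            "mu": mus,
            "R0": [math.inf if m == 0 else birth_rate / m for m in mus],
            "ancestral_mass": mass,
            "coal_within_T": [1.0 - v for v in mass],
        }
    )
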