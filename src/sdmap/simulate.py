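"""Synthetic paired somatic/germline counts and calibration experiments.

The default design is a scaled-down single chromosome: sites scattered
uniformly on 25 Mb, constant per-library depth, and a linear 1 cM/Mb
map — small enough that the full power/coverage experiment runs on one
CPU in minutes.  Somatic read counts are binomial draws at the
Mendelian ratio (plus error/bias); germline counts are binomial at the
distortion-decay probability implied by the distorter position, the
segregation ratio ``k`` and Haldane recombination distances.

All randomness flows through one seeded generator; replicate ``r`` of
an experiment uses a deterministic child seed so every run is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genmap import GeneticMap, MapAnchor, fit_map
from .likelihood import ancestry_prob, read_prob
from .scan import ScanResult, bootstrap_ci, scan_chromosome

__all__ = [
    "SimulationConfig",
    "SimulatedCounts",
    "simulate_counts",
    "run_null_calibration",
    "run_power_experiment",
    "NullCalibration",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated chromosome.

    ``positions``/``depth`` may be arrays for empirical-like designs;
    ``distorter_pos=None`` draws the distorter uniformly among the
    simulated sites (per replicate).
    """

    n_sites: int = 5000
    chrom_length: int = 25_000_000
    depth: int | np.ndarray = 40
    k: float = 0.5
    distorter_pos: int | None = None
    error_rate: float = 0.001
    bias: float = 1.0
    cm_per_mb: float = 1.0
    chromosome: str = "sim1"
    positions: np.ndarray | None = None
    depth_model: str = "constant"  # "constant" or "poisson" (mean = depth)

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValueError("k must lie in (0, 1)")
        if np.any(np.asarray(self.depth) < 0):
            raise ValueError("depths must be non-negative")
        if self.depth_model not in ("constant", "poisson"):
            raise ValueError("depth_model must be 'constant' or 'poisson'")
        if self.distorter_pos is not None and not (
            1 <= self.distorter_pos <= self.chrom_length
        ):
            raise ValueError("distorter position lies off the simulated chromosome")

    def genetic_map(self) -> GeneticMap:
        total_cm = self.chrom_length / 1e6 * self.cm_per_mb
        return fit_map([
            MapAnchor(self.chromosome, 1, 0.0),
            MapAnchor(self.chromosome, self.chrom_length, total_cm),
        ])


@dataclass(frozen=True)
class SimulatedCounts:
    counts: pd.DataFrame = field(repr=False)  # 8-column dialect
    distorter_pos: int
    config: SimulationConfig

    @property
    def gmap(self) -> GeneticMap:
        return self.config.genetic_map()


def _draw_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.positions is not None:
        pos = np.sort(np.asarray(config.positions, dtype=np.int64))
        if pos[0] < 1 or pos[-1] > config.chrom_length:
            raise ValueError("site positions lie off the simulated chromosome")
        return pos
    # uniform scatter; oversample then deduplicate to keep exactly n_sites
    want = config.n_sites
    pos = np.unique(rng.integers(1, config.chrom_length + 1, size=int(want * 1.1) + 16))
    while pos.size < want:
        extra = rng.integers(1, config.chrom_length + 1, size=want)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=want, replace=False))


def _depths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    base = np.broadcast_to(np.asarray(config.depth), (n,))
    if config.depth_model == "poisson":
        return rng.poisson(base)
    return base.astype(np.int64)


def simulate_counts(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SimulatedCounts:
    """Draw one paired somatic/germline counts table under the model."""
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = _draw_positions(config, rng)
    n = pos.size
    if config.distorter_pos is None:
        distorter = int(rng.choice(pos))
    else:
        distorter = int(config.distorter_pos)
    gmap = config.genetic_map()
    r = np.asarray(gmap.recomb_fraction(config.chromosome, distorter, pos))
    p_germ = read_prob(ancestry_prob(config.k, r), config.error_rate, config.bias)
    p_soma = read_prob(0.5, config.error_rate, config.bias)

    depth_soma = _depths(config, n, rng)
    depth_germ = _depths(config, n, rng)
    soma_lyr = rng.binomial(depth_soma, p_soma)
    germ_lyr = rng.binomial(depth_germ, p_germ)
    counts = pd.DataFrame({
        "chrom": config.chromosome,
        "pos": pos,
        "allele_lyr": "L",
        "allele_hal": "H",
        "soma_lyr": soma_lyr,
        "soma_hal": depth_soma - soma_lyr,
        "germ_lyr": germ_lyr,
        "germ_hal": depth_germ - germ_lyr,
    })
    return SimulatedCounts(counts, distorter, config)


def _split(sim: SimulatedCounts):
    from .io import library_frame

    return library_frame(sim.counts, "germ"), library_frame(sim.counts, "soma")


@dataclass(frozen=True)
class NullCalibration:
    k_g: np.ndarray
    lr: np.ndarray
    p_value: np.ndarray

    @property
    def max_abs_deviation(self) -> float:
        return float(np.max(np.abs(self.k_g - 0.5)))

    @property
    def max_k(self) -> float:
        return float(np.max(self.k_g))

    @property
    def max_lr(self) -> float:
        return float(np.max(self.lr))


def run_null_calibration(
    n_replicates: int,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    max_grid: int = 96,
) -> NullCalibration:
    """Scan Mendelian (k = 0.5) simulations to calibrate false positives."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    config = replace(config or SimulationConfig(), k=0.5)
    gmap = config.genetic_map()
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    k_g = np.empty(n_replicates)
    lr = np.empty(n_replicates)
    p = np.empty(n_replicates)
    for rep, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        sim = simulate_counts(config, rng=rng)
        germ, soma = _split(sim)
        res = scan_chromosome(germ, soma, gmap, config.chromosome,
                              error_rate=config.error_rate, max_grid=max_grid)
        k_g[rep], lr[rep], p[rep] = res.k_g, res.lr, res.p_value
    return NullCalibration(k_g, lr, p)


def _run_one_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_bootstraps: int,
    level: float,
    max_grid: int,
    boot_grid: int,
) -> tuple[ScanResult, float, float, bool, int]:
    sim = simulate_counts(config, rng=rng)
    germ, soma = _split(sim)
    gmap = sim.gmap
    res = scan_chromosome(germ, soma, gmap, config.chromosome,
                          error_rate=config.error_rate, max_grid=max_grid)
    ci_width = np.nan
    covered = False
    if n_bootstraps > 0:
        ci = bootstrap_ci(
            germ, soma, gmap, config.chromosome, n_boot=n_bootstraps,
            level=level, rng=rng, error_rate=config.error_rate,
            max_grid=boot_grid, base=res,
        )
        res.ci_lower, res.ci_upper, res.n_bootstrap = ci.lower, ci.upper, n_bootstraps
        ci_width = ci.upper - ci.lower
        covered = ci.lower <= sim.distorter_pos <= ci.upper
    pos_err = abs(res.position - sim.distorter_pos)
    return res, pos_err, ci_width, covered, sim.distorter_pos


def run_power_experiment(
    k_values: Sequence[float],
    n_replicates: int = 100,
    n_bootstraps: int = 200,
    alpha: float = 0.0005,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    level: float = 0.95,
    max_grid: int = 128,
    boot_grid: int = 64,
) -> pd.DataFrame:
    """Power / position-error / CI-coverage experiment across effect sizes.

    For each ``k``: simulate ``n_replicates`` chromosomes with a
    randomly placed distorter, scan each, bootstrap its position CI,
    and tabulate detection power at ``alpha``, mean absolute position
    error, mean CI width, CI coverage of the true position, and the
    mean/SD of the estimated ratio.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base_config = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    k_seeds = root.spawn(len(list(k_values)))
    rows = []
    for ki, k in enumerate(k_values):
        cfg = replace(base_config, k=float(k))
        children = k_seeds[ki].spawn(n_replicates)
        stats = {"p": [], "err": [], "width": [], "cover": [], "k_g": []}
        for ss in children:
            rng = np.random.default_rng(ss)
            res, pos_err, ci_width, covered, _ = _run_one_replicate(
                cfg, rng, n_bootstraps, level, max_grid, boot_grid
            )
            stats["p"].append(res.p_value)
            stats["err"].append(pos_err)
            stats["width"].append(ci_width)
            stats["cover"].append(covered)
            stats["k_g"].append(res.k_g)
        rows.append({
            "k": float(k),
            "n_replicates": n_replicates,
            "n_bootstraps": n_bootstraps,
            "power": float(np.mean(np.asarray(stats["p"]) <= alpha)),
            "mean_abs_position_error": float(np.mean(stats["err"])),
            "mean_ci_width": float(np.nanmean(stats["width"])) if n_bootstraps else np.nan,
            "ci_coverage": float(np.mean(stats["cover"])) if n_bootstraps else np.nan,
            "k_g_mean": float(np.mean(stats["k_g"])),
            "k_g_sd": float(np.std(stats["k_g"], ddof=1)) if n_replicates > 1 else 0.0,
        })
    return pd.DataFrame(rows)
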