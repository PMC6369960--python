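"""Likelihood-ratio position scan and bootstrap mapping confidence intervals.

For each candidate distorter position the segregation ratio ``k`` is
profiled out by maximum likelihood and compared to the somatic-
calibrated null (``k = 0.5`` with mapping-bias odds ``K_s/(1-K_s)``,
i.e. a constant lyrata-read fraction of ``K_s`` at every site).  The
maximum likelihood-ratio statistic across candidate positions locates
the distorter; its nominal p-value uses the chi-square(1) distribution.

Because the statistic is maximised over positions the nominal p-value
is anti-conservative; use it with a stringent cutoff (default 5e-4 in
:func:`significance_report`).

Mapping confidence intervals come from a site bootstrap: ancestry-
informative sites are resampled with replacement (paired somatic and
germline counts move together), the scan is rerun, and the percentile
interval of the replicate position estimates is reported.  The
percentile interval is not guaranteed to contain the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genmap import GeneticMap
from .likelihood import (
    DistortionModel,
    _site_params,
    estimate_null_ratio,
    profile_kmax,
)

__all__ = ["ScanResult", "scan_chromosome", "bootstrap_ci", "significance_report", "scan_genome"]

_MAXGRID_DEFAULT = 256


@dataclass
class ScanResult:
    chromosome: str
    position: int
    k_s: float
    k_g: float
    lr: float
    p_value: float
    n_sites: int
    profile: pd.DataFrame = field(repr=False)  # columns: position, k, lr
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "position": int(self.position),
            "k_s": self.k_s,
            "k_g": self.k_g,
            "lr": self.lr,
            "p_value": self.p_value,
            "n_sites": self.n_sites,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_bootstrap": self.n_bootstrap,
        }


def _check_paired(germ: pd.DataFrame, soma: pd.DataFrame, chromosome: str | None):
    for name, df in (("germline", germ), ("somatic", soma)):
        for col in ("chrom", "pos", "lyr", "hal"):
            if col not in df.columns:
                raise ValueError(f"{name} counts need a {col!r} column")
    if len(germ) != len(soma) or not (
        np.array_equal(germ["chrom"].to_numpy(), soma["chrom"].to_numpy())
        and np.array_equal(germ["pos"].to_numpy(), soma["pos"].to_numpy())
    ):
        raise ValueError("germline and somatic counts must cover the same site set")
    chroms = pd.unique(germ["chrom"])
    if chromosome is None:
        if len(chroms) != 1:
            raise ValueError("multiple chromosomes present; pass chromosome= explicitly")
        chromosome = str(chroms[0])
    else:
        keep = germ["chrom"] == chromosome
        germ, soma = germ[keep], soma[keep]
        if len(germ) == 0:
            raise ValueError(f"no sites on chromosome {chromosome!r}")
    order = np.argsort(germ["pos"].to_numpy(), kind="mergesort")
    return germ.iloc[order], soma.iloc[order], chromosome


def _candidate_grid(positions: np.ndarray, grid, max_grid: int) -> np.ndarray:
    if grid is not None:
        grid = np.asarray(grid)
        if grid.size == 0:
            raise ValueError("candidate-position grid is empty")
        return np.sort(grid)
    uniq = np.unique(positions)
    if uniq.size > max_grid:
        idx = np.unique(np.round(np.linspace(0, uniq.size - 1, max_grid)).astype(int))
        uniq = uniq[idx]
    return uniq


def _profile_matrices(site_morgans, grid_morgans, error_rate):
    d = np.abs(grid_morgans[:, None] - site_morgans[None, :])
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return _site_params(r, error_rate)


def scan_chromosome(
    germ: pd.DataFrame,
    soma: pd.DataFrame,
    gmap: GeneticMap,
    chromosome: str | None = None,
    error_rate: float = 0.001,
    grid=None,
    max_grid: int = _MAXGRID_DEFAULT,
    bias: float | None = None,
    k_s: float | None = None,
) -> ScanResult:
    """Maximum-likelihood position scan of one chromosome.

    ``germ``/``soma`` are per-library count frames with columns
    (chrom, pos, lyr, hal) over an identical site set.  ``grid``
    defaults to the informative-site positions, evenly subsampled to at
    most ``max_grid`` candidates.  ``bias``/``k_s`` may be supplied to
    skip somatic re-estimation (used by the bootstrap).
    """
    germ, soma, chromosome = _check_paired(germ, soma, chromosome)
    pos = germ["pos"].to_numpy()
    g_lyr = germ["lyr"].to_numpy(dtype=float)
    g_hal = germ["hal"].to_numpy(dtype=float)
    if k_s is None:
        k_s = estimate_null_ratio(soma["lyr"].to_numpy(), soma["hal"].to_numpy(), error_rate)
    if bias is None:
        bias = DistortionModel.bias_from_null_ratio(k_s)

    grid_pos = _candidate_grid(pos, grid, max_grid)
    used = (g_lyr + g_hal) > 0
    n_used = int(used.sum())
    site_m = np.asarray(gmap.genetic_position(chromosome, pos[used]), dtype=float)
    grid_m = np.asarray(gmap.genetic_position(chromosome, grid_pos), dtype=float)
    # warm start near the bias/error-corrected pooled germline fraction
    f_pool = g_lyr[used].sum() / (g_lyr[used].sum() + g_hal[used].sum())
    q_pool = f_pool / (bias * (1.0 - f_pool) + f_pool)
    k0 = float(np.clip((q_pool - error_rate) / (1.0 - 2.0 * error_rate), 0.01, 0.99))
    # chunk candidate positions so per-buffer size stays below the glibc
    # mmap threshold (large one-shot buffers get returned to the OS on free
    # and re-faulted every scan, which dominates run time at genome scale)
    wl, wh = g_lyr[used], g_hal[used]
    chunk = max(1, int(3e6 // max(n_used, 1)))
    k_hat = np.empty(grid_m.size)
    ll = np.empty(grid_m.size)
    for start in range(0, grid_m.size, chunk):
        stop = min(start + chunk, grid_m.size)
        alpha, beta = _profile_matrices(site_m, grid_m[start:stop], error_rate)
        k_hat[start:stop], ll[start:stop] = profile_kmax(
            alpha, beta, wl, wh, bias=bias, init=k0
        )
    # under the null (k = 0.5) the post-error ancestry probability is 0.5 at
    # every site regardless of position, so the null log-likelihood is the
    # constant-ratio model at the somatic ratio b/(1+b)
    pi0 = bias / (1.0 + bias)
    null_ll = float(g_lyr[used].sum() * np.log(pi0) + g_hal[used].sum() * np.log1p(-pi0))
    lr = np.maximum(2.0 * (ll - null_ll), 0.0)
    best = int(np.argmax(lr))  # first (= smallest-position) maximum
    p_value = float(chi2.sf(lr[best], df=1))
    profile = pd.DataFrame({"position": grid_pos, "k": k_hat, "lr": lr})
    return ScanResult(
        chromosome=chromosome,
        position=int(grid_pos[best]),
        k_s=float(k_s),
        k_g=float(k_hat[best]),
        lr=float(lr[best]),
        p_value=p_value,
        n_sites=n_used,
        profile=profile,
    )


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    positions: np.ndarray = field(repr=False)


def _parabolic_peak(vals: np.ndarray) -> np.ndarray:
    """Refined per-(grid,boot) maximum over the k axis of ``vals`` (G, K, B)."""
    j = np.argmax(vals, axis=1)  # (G, B)
    K = vals.shape[1]
    jc = np.clip(j, 1, K - 2)
    take = np.take_along_axis
    v0 = take(vals, (jc - 1)[:, None, :], axis=1)[:, 0, :]
    v1 = take(vals, jc[:, None, :], axis=1)[:, 0, :]
    v2 = take(vals, (jc + 1)[:, None, :], axis=1)[:, 0, :]
    denom = v0 - 2.0 * v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (v0 - v2) / denom
        refined = v1 - 0.25 * (v0 - v2) * delta
    bad = ~np.isfinite(refined) | (denom >= 0) | (j != jc)
    peak = np.where(bad, take(vals, j[:, None, :], axis=1)[:, 0, :], refined)
    return peak  # (G, B)


def bootstrap_ci(
    germ: pd.DataFrame,
    soma: pd.DataFrame,
    gmap: GeneticMap,
    chromosome: str | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    error_rate: float = 0.001,
    grid=None,
    max_grid: int = 96,
    n_k: int = 49,
    k_halfwidth: float = 0.08,
    bootstrap_null: bool = False,
    base: ScanResult | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI for the distorter position.

    Sites are resampled with replacement (paired libraries move
    together) and the position scan rerun per replicate.  The default
    fast path keeps the somatic ratio fixed and evaluates the profile
    on a (position, k) grid, turning every bootstrap into one weighted
    matrix product; ``bootstrap_null=True`` re-estimates K_s from the
    resampled somatic counts and reruns the full scan per replicate.
    The RNG is fully determined by ``seed`` (or a supplied generator).
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    germ, soma, chromosome = _check_paired(germ, soma, chromosome)
    n_sites = len(germ)
    if n_sites == 0:
        raise ValueError("no sites to resample")
    if rng is None:
        rng = np.random.default_rng(seed)
    alpha_q = 0.5 * (1.0 - level)

    if bootstrap_null:
        positions = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n_sites, size=n_sites)
            res = scan_chromosome(
                germ.iloc[idx], soma.iloc[idx], gmap, chromosome,
                error_rate=error_rate, grid=grid, max_grid=max_grid,
            )
            positions[b] = res.position
    else:
        if base is None:
            base = scan_chromosome(
                germ, soma, gmap, chromosome,
                error_rate=error_rate, grid=grid, max_grid=max(max_grid, 128),
            )
        bias = DistortionModel.bias_from_null_ratio(base.k_s)
        grid_pos = _candidate_grid(base.profile["position"].to_numpy(), grid, max_grid)
        center = float(np.clip(base.k_g, 0.02 + k_halfwidth, 0.98 - k_halfwidth))
        k_grid = np.linspace(center - k_halfwidth, center + k_halfwidth, n_k)

        pos = germ["pos"].to_numpy()
        g_lyr = germ["lyr"].to_numpy(dtype=float)
        g_hal = germ["hal"].to_numpy(dtype=float)
        site_m = np.asarray(gmap.genetic_position(chromosome, pos), dtype=float)
        grid_m = np.asarray(gmap.genetic_position(chromosome, grid_pos), dtype=float)

        weights = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites), size=n_boot)
        weights = weights.T.astype(np.float32)  # (N, B)

        G, K, N = grid_pos.size, k_grid.size, n_sites
        vals = np.empty((G, K, n_boot), dtype=np.float32)
        cl32 = g_lyr.astype(np.float32)
        ch32 = g_hal.astype(np.float32)
        cn32 = cl32 + ch32
        kg32 = k_grid.astype(np.float32)
        # per-site log-likelihood terms in float32 (differences near the peak
        # are O(1), far above float32 noise); chunked over grid rows
        chunk = max(1, int(8e6 // max(K * N, 1)))
        for start in range(0, G, chunk):
            stop = min(start + chunk, G)
            a, bta = _profile_matrices(site_m, grid_m[start:stop], error_rate)
            u = a.astype(np.float32)[:, None, :] + bta.astype(np.float32)[:, None, :] * kg32[None, :, None]
            np.clip(u, 1e-6, 1.0 - 1e-6, out=u)
            if bias != 1.0:
                d = (np.float32(bias) - 1.0) * u + 1.0
                np.log(d, out=d)
                d *= cn32
            om = 1.0 - u
            np.log(om, out=om)
            om *= ch32
            np.log(u, out=u)
            u *= cl32
            u += om
            if bias != 1.0:
                u -= d
            vals[start:stop] = (u.reshape(-1, N) @ weights).reshape(stop - start, K, n_boot)
        peak = _parabolic_peak(vals)  # (G, B)
        positions = grid_pos[np.argmax(peak, axis=0)].astype(float)

    lower, upper = np.quantile(positions, [alpha_q, 1.0 - alpha_q])
    return BootstrapCI(float(lower), float(upper), positions)


def significance_report(results, alpha: float = 0.0005) -> pd.DataFrame:
    """Flag per-chromosome scan results at a stringent nominal cutoff.

    Emits nominal and Bonferroni-across-chromosomes p-values; a result
    is ``significant`` iff its nominal p-value is <= ``alpha``.
    """
    results = list(results)
    m = max(len(results), 1)
    rows = []
    for res in results:
        p_bonf = min(res.p_value * m, 1.0)
        rows.append({
            "chromosome": res.chromosome,
            "position": res.position,
            "k_s": res.k_s,
            "k_g": res.k_g,
            "lr": res.lr,
            "p_value": res.p_value,
            "p_bonferroni": p_bonf,
            "significant": res.p_value <= alpha,
            "significant_bonferroni": p_bonf <= alpha,
        })
    return pd.DataFrame(rows)


def scan_genome(
    counts: pd.DataFrame,
    gmap: GeneticMap,
    error_rate: float = 0.001,
    max_grid: int = _MAXGRID_DEFAULT,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int | None = None,
    **boot_kwargs,
) -> list[ScanResult]:
    """Scan every chromosome of a paired counts table (dialect columns)."""
    from .io import library_frame

    results = []
    rng = np.random.default_rng(seed)
    for chrom in pd.unique(counts["chrom"]):
        sub = counts[counts["chrom"] == chrom]
        germ = library_frame(sub, "germ")
        soma = library_frame(sub, "soma")
        res = scan_chromosome(germ, soma, gmap, str(chrom), error_rate=error_rate, max_grid=max_grid)
        if n_boot > 0:
            ci = bootstrap_ci(
                germ, soma, gmap, str(chrom), n_boot=n_boot, level=level,
                rng=rng, error_rate=error_rate, base=res, **boot_kwargs,
            )
            res.ci_lower, res.ci_upper, res.n_bootstrap = ci.lower, ci.upper, n_boot
        results.append(res)
    return results
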