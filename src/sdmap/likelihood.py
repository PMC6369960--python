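"""Probabilistic model for pooled-gamete allele counts.

A candidate distorter at position ``i`` transmits the lyrata-lineage
allele to a fraction ``k`` of functional gamete chromosomes.  At a
marker separated from ``i`` by recombination probability ``r`` the
chance a sampled gamete chromosome carries the lyrata allele is

    q = k (1 - r) + (1 - k) r,

i.e. either the chromosome carries the driven allele and no odd number
of crossovers separated marker and distorter, or it carries the other
allele and recombination swapped the marker.  A uniform per-read
sequencing/mapping error ``E`` mixes the two allele classes,

    q' = q (1 - E) + (1 - q) E,

and a genome-wide reference-mapping bias is applied as a read-sampling
odds ``b`` (lyrata reads recovered at relative rate ``b``):

    P(lyrata read) = b q' / (b q' + (1 - q')).

With ``b = 1`` this reduces to the plain four-configuration sum
``k(1-r)(1-E) + (1-k)r(1-E) + k r E + (1-k)(1-r)E``.  The somatic
library, which cannot carry distortion, calibrates the bias: its
maximum-likelihood lyrata-read ratio ``K_s`` gives ``b = K_s/(1-K_s)``,
so the null hypothesis "germline ratio equals the somatic ratio" is the
model with ``k = 0.5`` and that ``b``, which predicts a constant
lyrata-read fraction of ``K_s`` at every site.

NOTE: the decomposition of the somatic ratio into a post-error
read-sampling odds is a modelling choice: it makes the null a
constant-ratio model equal to the somatic ratio at every site.  The
unbiased four-configuration model is always available via ``b = 1``.

Likelihoods are binomial per site with the combinatorial coefficient
omitted throughout (it is constant in ``k``, and omitting it makes the
site likelihood identical to the per-read product).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .genmap import GeneticMap

__all__ = [
    "DistortionModel",
    "LikelihoodResult",
    "ancestry_prob",
    "read_prob",
    "estimate_null_ratio",
    "loglik_germline",
    "optimize_k",
]

_K_BOUNDS = (1e-6, 1.0 - 1e-6)
_TINY = 1e-300


@dataclass(frozen=True)
class DistortionModel:
    """A candidate distorter: position, segregation ratio, error, bias."""

    position: int
    k: float
    error_rate: float = 0.001
    bias: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"k must lie in (0, 1), got {self.k}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error rate must lie in [0, 0.5), got {self.error_rate}")
        if not self.bias > 0:
            raise ValueError(f"bias odds must be positive, got {self.bias}")

    @staticmethod
    def bias_from_null_ratio(k_s: float) -> float:
        """Read-sampling odds reproducing somatic ratio ``k_s`` under k = 0.5."""
        if not 0.0 < k_s < 1.0:
            raise ValueError(f"null ratio must lie in (0, 1), got {k_s}")
        return k_s / (1.0 - k_s)


@dataclass(frozen=True)
class LikelihoodResult:
    loglik: float
    k: float
    n_sites: int


def ancestry_prob(k, r):
    """P(sampled gamete chromosome carries the lyrata allele) at recombination distance r."""
    k = np.asarray(k, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination probability r must lie in [0, 0.5]")
    q = k * (1.0 - r) + (1.0 - k) * r
    return float(q) if q.ndim == 0 else q

def read_prob(q, error_rate=0.0, bias=1.0):
    """P(one sequenced read shows the lyrata allele) after error mixing and mapping bias."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("ancestry probability q must lie in [0, 1]")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error rate must lie in [0, 0.5)")
    if not bias > 0:
        raise ValueError("bias odds must be positive")
    qe = q * (1.0 - error_rate) + (1.0 - q) * error_rate
    p = bias * qe / (bias * qe + (1.0 - qe))
    return float(p) if p.ndim == 0 else p


def estimate_null_ratio(lyr_counts, hal_counts, error_rate: float = 0.0) -> float:
    """ML somatic ancestry ratio K_s under a constant-ratio binomial model.

    The per-site success probability is ``K_s (1-E) + (1-K_s) E``; the
    MLE is the error-corrected pooled lyrata-read fraction
    ``(f - E) / (1 - 2E)`` clamped into (0, 1).
    """
    lyr = np.asarray(lyr_counts, dtype=float)
    hal = np.asarray(hal_counts, dtype=float)
    if np.any(lyr < 0) or np.any(hal < 0):
        raise ValueError("allele counts must be non-negative")
    total = lyr.sum() + hal.sum()
    if total <= 0:
        raise ValueError("cannot estimate a null ratio from all-zero depth")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error rate must lie in [0, 0.5)")
    f = lyr.sum() / total
    k_s = (f - error_rate) / (1.0 - 2.0 * error_rate)
    return float(np.clip(k_s, _K_BOUNDS[0], _K_BOUNDS[1]))


# ---------------------------------------------------------------------------
# internal parameterisation: with q' = q(1-E) + (1-q)E and
# q = r + k(1-2r), the post-error ancestry probability is linear in k,
#   u(k) = alpha + beta k,  alpha = E + (1-2E) r,  beta = (1-2E)(1-2r),
# and with D = (b-1)u + 1 the read probability is pi = b u / D and
# 1 - pi = (1 - u)/D, so the site log-likelihood (coefficient-free) is
#   l = c_lyr [ln b + ln u] + c_hal ln(1-u) - n ln D.
# ---------------------------------------------------------------------------


def _site_params(r, error_rate):
    r = np.asarray(r, dtype=float)
    alpha = error_rate + (1.0 - 2.0 * error_rate) * r
    beta = (1.0 - 2.0 * error_rate) * (1.0 - 2.0 * r)
    return alpha, beta


def _loglik_rows(k, alpha, beta, wl, wh, wn, bias):
    """Coefficient-free log-likelihood for each grid row; k has shape (G,)."""
    u = alpha + beta * k[:, None]
    u = np.clip(u, _TINY, 1.0 - 1e-15)
    d = (bias - 1.0) * u + 1.0
    out = (wl * np.log(u)).sum(axis=1)
    out += (wh * np.log1p(-u)).sum(axis=1)
    if bias != 1.0:
        out += np.log(bias) * wl.sum() - (wn * np.log(d)).sum(axis=1)
    return out


def _grad_hess_rows(k, alpha, beta, wl, wh, wn, bm1, ws=None):
    """Score and curvature of the profile log-likelihood per grid row.

    ``ws`` is an optional reusable workspace of five (G, N) buffers;
    reusing it avoids large allocations in the scan's hot loop.
    """
    if ws is None:
        ws = [np.empty_like(alpha) for _ in range(5)]
    u, om, acc_g, acc_h, tmp = ws
    np.multiply(beta, k[:, None], out=u)
    u += alpha
    np.clip(u, 1e-12, 1.0 - 1e-12, out=u)
    np.subtract(1.0, u, out=om)
    np.divide(wl, u, out=acc_g)          # wl / u
    np.divide(acc_g, u, out=acc_h)       # wl / u^2
    np.divide(wh, om, out=tmp)           # wh / (1-u)
    acc_g -= tmp
    tmp /= om                            # wh / (1-u)^2
    acc_h += tmp
    if bm1 != 0.0:
        np.multiply(u, bm1, out=om)      # reuse om as D = bm1*u + 1
        om += 1.0
        np.divide(wn, om, out=tmp)
        tmp *= bm1                       # wn * bm1 / D
        acc_g -= tmp
        tmp *= bm1
        tmp /= om                        # wn * bm1^2 / D^2
        acc_h -= tmp
    acc_g *= beta
    g = acc_g.sum(axis=1)
    acc_h *= beta
    acc_h *= beta
    h = -acc_h.sum(axis=1)
    return g, h


def profile_kmax(
    alpha,
    beta,
    lyr,
    hal,
    bias: float = 1.0,
    weights=None,
    bounds=_K_BOUNDS,
    tol: float = 1e-8,
    max_iter: int = 100,
    init: float | None = None,
):
    """Maximise the germline log-likelihood in k for each grid row.

    ``alpha``/``beta`` have shape (G, N) — one row per candidate
    distorter position — and ``lyr``/``hal`` are per-site counts
    (optionally multiplied by bootstrap ``weights``).  Uses a
    bracketed, safeguarded Newton iteration on the score function.

    Returns ``(k_hat, loglik)`` arrays of shape (G,).
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    lyr = np.asarray(lyr, dtype=float)
    hal = np.asarray(hal, dtype=float)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        wl, wh = lyr * w, hal * w
    else:
        wl, wh = lyr, hal
    wn = wl + wh
    lo, hi = bounds
    n_grid = alpha.shape[0]
    bm1 = bias - 1.0

    klo = np.full(n_grid, lo)
    khi = np.full(n_grid, hi)
    if init is None:
        init = 0.5 * (lo + hi)
    k = np.full(n_grid, float(np.clip(init, lo + tol, hi - tol)))
    ws = [np.empty_like(alpha) for _ in range(5)]
    for _ in range(max_iter):
        g, h = _grad_hess_rows(k, alpha, beta, wl, wh, wn, bm1, ws=ws)
        np.copyto(klo, k, where=g > 0)
        np.copyto(khi, k, where=g < 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            k_new = k - g / h
        bad = ~np.isfinite(k_new) | (k_new <= klo) | (k_new >= khi) | (h >= 0)
        k_new = np.where(bad, 0.5 * (klo + khi), k_new)
        moved = np.max(np.abs(k_new - k))
        k = k_new
        if moved < tol:
            break
    ll = _loglik_rows(k, alpha, beta, wl, wh, wn, bias)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite log-likelihood in profile optimisation")
    return k, ll


def _prepare_sites(positions, lyr, hal, gmap: GeneticMap, chromosome: str):
    positions = np.asarray(positions)
    lyr = np.asarray(lyr, dtype=float)
    hal = np.asarray(hal, dtype=float)
    if not (positions.shape == lyr.shape == hal.shape):
        raise ValueError("positions and counts must have matching shapes")
    morgans = np.asarray(gmap.genetic_position(chromosome, positions), dtype=float)
    used = (lyr + hal) > 0
    return positions, lyr, hal, morgans, used


def loglik_germline(
    positions,
    lyr,
    hal,
    gmap: GeneticMap,
    chromosome: str,
    i: int,
    k: float,
    error_rate: float = 0.001,
    bias: float = 1.0,
) -> LikelihoodResult:
    """Chromosome-wide (coefficient-free) log-likelihood of germline counts.

    Sums over sites the binomial log-likelihood of the lyrata/halleri
    read counts with success probability
    ``read_prob(ancestry_prob(k, r_ip), E, b)`` where ``r_ip`` comes
    from Haldane's function applied to the fitted map.  Zero-depth
    sites are skipped and excluded from ``n_sites``.
    """
    if not 0.0 < k < 1.0:
        raise ValueError("k must lie in (0, 1)")
    positions, lyr, hal, morgans, used = _prepare_sites(positions, lyr, hal, gmap, chromosome)
    n_used = int(used.sum())
    if n_used == 0:
        return LikelihoodResult(0.0, k, 0)
    d = np.abs(morgans[used] - float(gmap.genetic_position(chromosome, i)))
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    alpha, beta = _site_params(r, error_rate)
    wl, wh = lyr[used], hal[used]
    ll = _loglik_rows(np.array([k]), alpha[None, :], beta[None, :], wl, wh, wl + wh, bias)
    return LikelihoodResult(float(ll[0]), k, n_used)


def optimize_k(
    positions,
    lyr,
    hal,
    gmap: GeneticMap,
    chromosome: str,
    i: int,
    error_rate: float = 0.001,
    bias: float = 1.0,
    bounds=_K_BOUNDS,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Bounded 1-D ML estimate of k at a fixed candidate position ``i``.

    Derivative-free bounded scalar search (Brent); returns
    ``(k_hat, max log-likelihood)``.  With no usable sites returns the
    Mendelian ratio 0.5 and log-likelihood 0.
    """
    lo, hi = bounds
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("k bounds must lie strictly inside (0, 1)")
    positions, lyr, hal, morgans, used = _prepare_sites(positions, lyr, hal, gmap, chromosome)
    if not used.any():
        return 0.5, 0.0
    d = np.abs(morgans[used] - float(gmap.genetic_position(chromosome, i)))
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    alpha, beta = _site_params(r, error_rate)
    wl, wh = lyr[used], hal[used]
    wn = wl + wh

    def neg(k: float) -> float:
        val = _loglik_rows(np.array([k]), alpha[None, :], beta[None, :], wl, wh, wn, bias)[0]
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite log-likelihood at k={k}")
        return -val

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": tol})
    k_hat, best = float(res.x), -float(res.fun)
    # ties (flat likelihood) break toward the Mendelian ratio
    if abs(-neg(0.5) - best) <= 1e-12 and abs(0.5 - k_hat) > tol:
        return 0.5, -neg(0.5)
    return k_hat, best
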