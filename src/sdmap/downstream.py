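"""Windowed raw ancestry ratios and viability / rate-of-evolution arithmetic.

The viability calculators convert a germline segregation ratio ``k``
into the relative viability ``X`` of gametes carrying the disfavored
allele (by solving ``1/(1+X) = k_major``), the proportional loss of
total viable gamete production at that locus, ``(1 - X)/2``, and the
combined loss across loci under either an independent (multiplicative)
model or a minimum model that uses only the maximally distorted locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WindowRatio",
    "ViabilityEstimate",
    "window_ratios",
    "relative_viability",
    "viability_decrease",
    "combined_decrease",
    "distorter_rate",
]


@dataclass(frozen=True)
class WindowRatio:
    chromosome: str
    window: int
    start: int
    end: int
    n_snps: int
    germ_fraction: float
    soma_fraction: float
    difference: float  # germline - somatic; positive = excess lyrata in germline


def window_ratios(counts: pd.DataFrame, snps_per_window: int = 1000) -> pd.DataFrame:
    """Raw lyrata-ancestry fractions in non-overlapping fixed-SNP windows.

    ``counts`` is a paired table in the 8-column dialect, sorted by
    (chrom, pos).  Every window holds exactly ``snps_per_window`` sites
    except the terminal window of each chromosome.  Windows with zero
    total depth in a library yield NaN fractions.
    """
    if snps_per_window < 1:
        raise ValueError("snps_per_window must be >= 1")
    for chrom, sub in counts.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) >= 0):
            raise ValueError(f"counts must be sorted by position within {chrom!r}")
    rows = []
    for chrom, sub in counts.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        for w, start in enumerate(range(0, len(sub), snps_per_window)):
            win = sub.iloc[start:start + snps_per_window]

            def _fraction(lib: str) -> float:
                lyr = win[f"{lib}_lyr"].sum()
                tot = lyr + win[f"{lib}_hal"].sum()
                return float(lyr / tot) if tot > 0 else float("nan")

            gf, sf = _fraction("germ"), _fraction("soma")
            rows.append({
                "chromosome": chrom,
                "window": w,
                "start": int(win["pos"].iloc[0]),
                "end": int(win["pos"].iloc[-1]),
                "n_snps": len(win),
                "germ_fraction": gf,
                "soma_fraction": sf,
                "difference": gf - sf,
            })
    return pd.DataFrame(rows)


def relative_viability(k: float) -> float:
    """Relative viability X of gametes carrying the disfavored allele.

    ``k`` is the segregation ratio toward either allele; the majority
    fraction ``k_major = max(k, 1-k)`` satisfies ``1/(1+X) = k_major``,
    hence ``X = (1 - k_major)/k_major <= 1``.
    """
    if not 0.0 < k < 1.0:
        raise ValueError("k must lie strictly inside (0, 1)")
    k_major = max(k, 1.0 - k)
    return (1.0 - k_major) / k_major


def viability_decrease(k: float) -> float:
    """Proportional decrease in total viable gamete production at one locus.

    Half the gametes carry the disfavored allele and survive at
    relative rate X, so production drops by ``(1 - X)/2``.
    """
    return (1.0 - relative_viability(k)) / 2.0


def combined_decrease(
    k_values: Sequence[float],
    model: Literal["independent", "minimum"] = "independent",
) -> float:
    """Combined production loss across loci.

    ``independent``: per-locus viable fractions multiply,
    ``1 - prod_l (1 - decrease_l)``; ``minimum``: the loss of the
    maximally distorted locus alone.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("need at least one k value")
    decreases = [viability_decrease(k) for k in k_values]
    if model == "independent":
        return 1.0 - float(np.prod([1.0 - d for d in decreases]))
    if model == "minimum":
        return max(decreases)
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class ViabilityEstimate:
    """Per-locus and combined viability impact of a set of distorters."""

    k_values: tuple[float, ...]
    relative_viabilities: tuple[float, ...]
    decreases: tuple[float, ...]
    independent_decrease: float
    minimum_decrease: float

    @classmethod
    def from_k(cls, k_values: Iterable[float]) -> "ViabilityEstimate":
        ks = tuple(float(k) for k in k_values)
        return cls(
            k_values=ks,
            relative_viabilities=tuple(relative_viability(k) for k in ks),
            decreases=tuple(viability_decrease(k) for k in ks),
            independent_decrease=combined_decrease(ks, "independent"),
            minimum_decrease=combined_decrease(ks, "minimum"),
        )


def distorter_rate(
    n_loci: int,
    divergence_years: float,
    lineages: int = 2,
) -> float:
    """Years per newly arising high-frequency distorter.

    Divides the total branch length separating the two lineages
    (``lineages * divergence_years``; set ``lineages=1`` for the
    single-lineage convention) by the number of distorters detected.
    """
    if n_loci < 1:
        raise ValueError("need at least one locus")
    if divergence_years <= 0:
        raise ValueError("divergence time must be positive")
    if lineages not in (1, 2):
        raise ValueError("lineages must be 1 or 2")
    return lineages * divergence_years / n_loci
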