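"""Genetic map interpolation and recombination probabilities.

A :class:`GeneticMap` is fitted from per-chromosome anchor points
``(physical bp, cumulative cM)`` by monotone piecewise-linear
interpolation.  Evaluation returns genetic positions in Morgans;
recombination probabilities between two positions on the same
chromosome follow Haldane's mapping function,

    r = (1 - exp(-2 d)) / 2,

with ``d`` the genetic distance in Morgans, so ``r`` lies in ``[0, 0.5)``
and increases monotonically with distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = ["MapAnchor", "GeneticMap", "fit_map", "recomb_fraction", "read_map"]

CM_PER_MORGAN = 100.0


@dataclass(frozen=True)
class MapAnchor:
    """One recombination-map anchor: physical bp vs cumulative cM."""

    chromosome: str
    position: int
    cm: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"anchor position must be >= 1, got {self.position}")
        if self.cm < 0:
            raise ValueError(f"anchor cM must be non-negative, got {self.cm}")


class GeneticMap:
    """Monotone piecewise-linear bp -> genetic-position map.

    Between anchors the map interpolates linearly on cumulative cM (and
    therefore reproduces every anchor exactly).  Beyond the terminal
    anchors the behaviour depends on ``extrapolation``:

    ``"slope"`` (default)
        continue with the terminal segment's slope (which is >= 0 by the
        monotonicity requirement); left-extrapolated values are clamped
        at 0 cM so genetic positions stay non-negative.
    ``"clamp"``
        hold the terminal anchor's cM constant.
    """

    def __init__(
        self,
        anchors: Mapping[str, tuple[np.ndarray, np.ndarray]],
        extrapolation: Literal["slope", "clamp"] = "slope",
    ) -> None:
        if extrapolation not in ("slope", "clamp"):
            raise ValueError(f"unknown extrapolation mode {extrapolation!r}")
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in anchors.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if pos.size < 2:
                raise ValueError(f"chromosome {chrom!r}: need >= 2 anchors, got {pos.size}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {chrom!r}: anchor positions must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom!r}: anchor cM must be non-decreasing")
            if np.any(cm < 0):
                raise ValueError(f"chromosome {chrom!r}: anchor cM must be non-negative")
            self._anchors[chrom] = (pos, cm)
        self.extrapolation = extrapolation

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def _require(self, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._anchors[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} not covered by the genetic map") from None

    def genetic_position(self, chromosome: str, position_bp) -> np.ndarray | float:
        """Genetic position(s) in Morgans at physical position(s) ``position_bp``."""
        xp, fp = self._require(chromosome)
        x = np.asarray(position_bp, dtype=float)
        cm = np.interp(x, xp, fp)
        if self.extrapolation == "slope":
            left = x < xp[0]
            if np.any(left):
                slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
                cm = np.where(left, np.maximum(fp[0] + slope * (x - xp[0]), 0.0), cm)
            right = x > xp[-1]
            if np.any(right):
                slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
                cm = np.where(right, fp[-1] + slope * (x - xp[-1]), cm)
        morgans = cm / CM_PER_MORGAN
        if np.isscalar(position_bp):
            return float(morgans)
        return morgans

    def recomb_fraction(self, chromosome: str, i_bp, p_bp) -> np.ndarray | float:
        """Haldane recombination probability between two bp positions."""
        d = np.abs(
            np.asarray(self.genetic_position(chromosome, i_bp))
            - np.asarray(self.genetic_position(chromosome, p_bp))
        )
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        if np.isscalar(i_bp) and np.isscalar(p_bp):
            return float(r)
        return r


def fit_map(
    anchors: Iterable[MapAnchor],
    extrapolation: Literal["slope", "clamp"] = "slope",
) -> GeneticMap:
    """Fit a :class:`GeneticMap` from a sequence of :class:`MapAnchor`.

    Anchors must be sorted by (chromosome, position); each chromosome
    needs at least two anchors with non-decreasing cM.
    """
    by_chrom: dict[str, list[MapAnchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chromosome, []).append(a)
    if not by_chrom:
        raise ValueError("no anchors supplied")
    data = {}
    for chrom, rows in by_chrom.items():
        pos = np.array([a.position for a in rows], dtype=float)
        cm = np.array([a.cm for a in rows], dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"chromosome {chrom!r}: anchors must be sorted by position")
        data[chrom] = (pos, cm)
    return GeneticMap(data, extrapolation=extrapolation)


def recomb_fraction(gmap: GeneticMap, chromosome: str, i_bp, p_bp):
    """Module-level convenience wrapper around :meth:`GeneticMap.recomb_fraction`."""
    return gmap.recomb_fraction(chromosome, i_bp, p_bp)


def read_map(path, zero_based: bool = False, extrapolation: Literal["slope", "clamp"] = "slope") -> GeneticMap:
    """Read a (chrom, pos_bp, cM) TSV with header into a :class:`GeneticMap`.

    ``zero_based=True`` treats input positions as 0-based (BED-like) and
    shifts them to the 1-based convention used throughout.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("map TSV needs at least 3 columns: chrom, pos_bp, cM")
    chrom_col, pos_col, cm_col = df.columns[:3]
    anchors = []
    for chrom, sub in df.groupby(chrom_col, sort=False):
        sub = sub.sort_values(pos_col)
        for _, row in sub.iterrows():
            pos = int(row[pos_col]) + (1 if zero_based else 0)
            anchors.append(MapAnchor(str(chrom), pos, float(row[cm_col])))
    return fit_map(anchors, extrapolation=extrapolation)
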