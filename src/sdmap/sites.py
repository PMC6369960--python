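"""Ancestry-informative site selection and per-library allele counting.

Sites are retained when they are differentially fixed between the two
parental lineages (every lyrata-side parent homozygous for one allele,
every halleri-side parent homozygous for the other) and heterozygous in
all F1 samples, with genotype quality at or above a cutoff.  Two
further filters mirror standard pool-seq practice: a depth-quantile
filter against structural-variant/collapsed-repeat artifacts, and a
minimum physical spacing so a single read can never be counted twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeRecord",
    "InformativeSite",
    "SiteCounts",
    "filter_informative",
    "filter_depth_quantiles",
    "enforce_spacing",
    "informative_sites_from_vcf",
    "build_counts_table",
    "load_roles",
]

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"

ROLE_KEYS = ("parent1", "parent2", "f1_soma", "f1_germ")


@dataclass(frozen=True)
class GenotypeRecord:
    """One multi-sample genotyped variant site."""

    chromosome: str
    position: int
    ref: str
    alt: str
    genotypes: Mapping[str, str]  # sample id -> one of HOM_REF/HOM_ALT/HET/MISSING
    quality: Mapping[str, float] = field(default_factory=dict)  # per-sample GQ
    depth: int = 0  # total read depth across all libraries

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be a 1-based coordinate >= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class InformativeSite:
    """A SNP fixed between the parental lineages and heterozygous in the F1."""

    chromosome: str
    position: int
    allele_lyr: str
    allele_hal: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be a 1-based coordinate >= 1")
        if self.allele_lyr == self.allele_hal:
            raise ValueError("lineage alleles must differ")


@dataclass(frozen=True)
class SiteCounts:
    """Reads supporting each lineage allele at one site in one library."""

    site: InformativeSite
    lyr: int
    hal: int

    def __post_init__(self) -> None:
        if self.lyr < 0 or self.hal < 0:
            raise ValueError("allele counts must be non-negative")


def _role_samples(roles: Mapping[str, Sequence[str]]) -> dict[str, list[str]]:
    out = {}
    for key in ROLE_KEYS:
        if key not in roles or not roles[key]:
            raise ValueError(f"sample-role configuration is missing {key!r}")
        val = roles[key]
        out[key] = [val] if isinstance(val, str) else list(val)
    return out


def filter_informative(
    records: Iterable[GenotypeRecord],
    roles: Mapping[str, Sequence[str]],
    min_gq: float = 30.0,
) -> list[InformativeSite]:
    """Keep sites fixed between the parental lineages and het in every F1 sample.

    ``roles`` maps ``parent1`` (lyrata lineage), ``parent2`` (halleri
    lineage), ``f1_soma`` and ``f1_germ`` to sample ids found in the
    records.  Sites with any missing genotype among those samples, or
    any genotype quality below ``min_gq``, are dropped.  Raises if a
    role's sample id is absent from a record.
    """
    role_map = _role_samples(roles)
    f1_samples = role_map["f1_soma"] + role_map["f1_germ"]
    involved = role_map["parent1"] + role_map["parent2"] + f1_samples
    kept: list[InformativeSite] = []
    for rec in records:
        try:
            gts = {s: rec.genotypes[s] for s in involved}
        except KeyError as exc:
            raise ValueError(
                f"sample {exc.args[0]!r} from the role configuration is absent at "
                f"{rec.chromosome}:{rec.position}"
            ) from None
        if any(g == MISSING for g in gts.values()):
            continue
        if any(rec.quality.get(s, np.inf) < min_gq for s in involved):
            continue
        p1 = {gts[s] for s in role_map["parent1"]}
        p2 = {gts[s] for s in role_map["parent2"]}
        if len(p1) != 1 or len(p2) != 1:
            continue
        g1, g2 = p1.pop(), p2.pop()
        if {g1, g2} != {HOM_REF, HOM_ALT}:
            continue  # a parent het, or both lineages share the allele
        if any(gts[s] != HET for s in f1_samples):
            continue
        lyr = rec.ref if g1 == HOM_REF else rec.alt
        hal = rec.alt if g1 == HOM_REF else rec.ref
        kept.append(InformativeSite(rec.chromosome, rec.position, lyr, hal))
    return kept


def filter_depth_quantiles(
    sites: Sequence,
    total_depths: Sequence[float],
    lower_q: float = 0.10,
    upper_q: float = 0.90,
) -> tuple[list, tuple[float, float]]:
    """Keep sites with total depth inside the closed empirical-quantile interval.

    Quantiles use the nearest-rank (type-1 / inverted-CDF) convention.
    Returns ``(kept_sites, (lower_cut, upper_cut))`` so the realized
    absolute cutoffs can be logged and reproduced.
    """
    if len(sites) == 0:
        raise ValueError("cannot compute depth quantiles for an empty site list")
    if len(sites) != len(total_depths):
        raise ValueError("need exactly one total depth per site")
    if not 0.0 <= lower_q < upper_q <= 1.0:
        raise ValueError("require 0 <= lower_q < upper_q <= 1")
    depths = np.asarray(total_depths, dtype=float)
    lo = float(np.quantile(depths, lower_q, method="inverted_cdf"))
    hi = float(np.quantile(depths, upper_q, method="inverted_cdf"))
    keep = (depths >= lo) & (depths <= hi)
    return [s for s, k in zip(sites, keep) if k], (lo, hi)


def _site_key(site):
    if isinstance(site, InformativeSite):
        return site.chromosome, site.position
    if isinstance(site, SiteCounts):
        return site.site.chromosome, site.site.position
    chrom, pos = site[0], site[1]  # (chrom, pos, ...) tuples accepted
    return chrom, pos


def enforce_spacing(sites: Sequence, min_gap_bp: int = 100) -> list:
    """Greedy left-to-right spacing filter.

    A site is kept iff its position exceeds the last kept position on
    the same chromosome by more than ``min_gap_bp`` (the leftmost of a
    close pair wins).  Input must be sorted by (chromosome, position).
    """
    kept = []
    last: dict[str, int] = {}
    prev_key = None
    for site in sites:
        chrom, pos = _site_key(site)
        if prev_key is not None and (chrom, pos) < prev_key:
            raise ValueError("sites must be sorted by (chromosome, position)")
        prev_key = (chrom, pos)
        if chrom not in last or pos - last[chrom] > min_gap_bp:
            kept.append(site)
            last[chrom] = pos
    return kept


# --------------------------------------------------------------------------
# VCF ingestion
# --------------------------------------------------------------------------


def load_roles(path) -> dict[str, list[str]]:
    """Load a YAML/JSON sample-role configuration file."""
    import yaml

    with open(path) as fh:
        roles = yaml.safe_load(fh)
    return _role_samples(roles)


def _gt_code(gt_type: int) -> str:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    return {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}.get(gt_type, MISSING)


def informative_sites_from_vcf(
    vcf_path,
    roles: Mapping[str, Sequence[str]],
    min_gq: float = 30.0,
) -> pd.DataFrame:
    """Extract candidate informative sites and per-library allele counts.

    Reads a multi-sample VCF (plain or compressed), applies the
    fixed-difference/heterozygote/GQ filter and returns a DataFrame in
    the 8-column counts dialect plus a ``total_depth`` column (summed
    across all samples) for downstream depth filtering.  Allele counts
    come from the AD FORMAT field, summed across the samples mapped to
    each F1 library role.
    """
    from cyvcf2 import VCF

    role_map = _role_samples(roles)
    vcf = VCF(str(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    for key, samples in role_map.items():
        for s in samples:
            if s not in sample_idx:
                raise ValueError(f"sample {s!r} (role {key}) not present in the VCF")

    rows = []
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] is None:
            continue  # biallelic SNPs only
        gt_types = var.gt_types
        gqs = var.gt_quals
        ad = var.format("AD")
        dp = var.format("DP")
        genotypes = {s: _gt_code(int(gt_types[i])) for s, i in sample_idx.items()}
        quality = {s: float(gqs[i]) for s, i in sample_idx.items()}
        if dp is not None:
            total_depth = int(np.nansum(np.where(dp < 0, 0, dp)))
        elif ad is not None:
            total_depth = int(np.nansum(np.where(ad < 0, 0, ad)))
        else:
            total_depth = 0
        rec = GenotypeRecord(
            chromosome=var.CHROM,
            position=var.POS,
            ref=var.REF,
            alt=var.ALT[0],
            genotypes=genotypes,
            quality=quality,
            depth=total_depth,
        )
        kept = filter_informative([rec], role_map, min_gq=min_gq)
        if not kept:
            continue
        site = kept[0]
        if ad is None:
            raise ValueError("VCF lacks the AD FORMAT field needed for allele counts")
        lyr_is_ref = site.allele_lyr == var.REF

        def _lib_counts(samples):
            ref_c = alt_c = 0
            for s in samples:
                pair = ad[sample_idx[s]]
                ref_c += max(int(pair[0]), 0)
                alt_c += max(int(pair[1]), 0)
            return (ref_c, alt_c) if lyr_is_ref else (alt_c, ref_c)

        soma_lyr, soma_hal = _lib_counts(role_map["f1_soma"])
        germ_lyr, germ_hal = _lib_counts(role_map["f1_germ"])
        rows.append(
            (site.chromosome, site.position, site.allele_lyr, site.allele_hal,
             soma_lyr, soma_hal, germ_lyr, germ_hal, total_depth)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "allele_lyr", "allele_hal",
                 "soma_lyr", "soma_hal", "germ_lyr", "germ_hal", "total_depth"],
    )


def build_counts_table(
    candidates: pd.DataFrame,
    lower_q: float = 0.10,
    upper_q: float = 0.90,
    min_gap_bp: int = 100,
    log_path=None,
) -> pd.DataFrame:
    """Apply depth-quantile and spacing filters to a candidate counts table.

    ``candidates`` is the dialect table from
    :func:`informative_sites_from_vcf` (a ``total_depth`` column is
    required for the depth filter unless ``lower_q == 0 and
    upper_q == 1``).  Optionally writes a JSON filter log with per-rule
    site tallies and the realized depth cutoffs.
    """
    df = candidates.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n_in = len(df)
    cutoffs = (float("-inf"), float("inf"))
    if (lower_q, upper_q) != (0.0, 1.0):
        if "total_depth" not in df.columns:
            raise ValueError("depth filtering requires a total_depth column")
        idx, cutoffs = filter_depth_quantiles(
            list(df.index), df["total_depth"].to_numpy(), lower_q, upper_q
        )
        df = df.loc[idx].reset_index(drop=True)
    n_depth = len(df)
    keys = list(zip(df["chrom"], df["pos"]))
    kept_keys = set(enforce_spacing(keys, min_gap_bp=min_gap_bp))
    df = df[[k in kept_keys for k in keys]].reset_index(drop=True)
    n_spacing = len(df)
    if log_path is not None:
        log = {
            "input_sites": n_in,
            "after_depth_filter": n_depth,
            "after_spacing_filter": n_spacing,
            "depth_cutoffs": list(cutoffs),
            "depth_quantiles": [lower_q, upper_q],
            "min_gap_bp": min_gap_bp,
        }
        with open(log_path, "w") as fh:
            json.dump(log, fh, indent=2)
    return df
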