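"""Tabular formats shared across the package.

The counts dialect is an 8-column TSV with header::

    chrom  pos  allele_lyr  allele_hal  soma_lyr  soma_hal  germ_lyr  germ_hal

(1-based positions; counts are reads supporting the lyrata-lineage and
halleri-lineage allele in the somatic and germline libraries).
"""

from __future__ import annotations

import pandas as pd

COUNT_COLUMNS = [
    "chrom", "pos", "allele_lyr", "allele_hal",
    "soma_lyr", "soma_hal", "germ_lyr", "germ_hal",
]

LIBRARIES = ("soma", "germ")


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV in the 8-column dialect (extra columns allowed)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table is missing columns: {missing}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def library_frame(df: pd.DataFrame, library: str) -> pd.DataFrame:
    """Project the paired counts table onto one library: (chrom, pos, lyr, hal)."""
    if library not in LIBRARIES:
        raise ValueError(f"library must be one of {LIBRARIES}, got {library!r}")
    out = df[["chrom", "pos", f"{library}_lyr", f"{library}_hal"]].copy()
    out.columns = ["chrom", "pos", "lyr", "hal"]
    return out
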