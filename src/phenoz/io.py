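"""Strict readers/writers for phenotype tables and result matrices.

Phenotype tables are tidy CSV with the columns ``assay_id, genotype,
allele_id, block_id, timepoint, arm, value, unit, replicate`` (``replicate``
is synthesized as a within-cell counter when absent).  Matrices are TSV with
lines as rows and assay-endpoints as columns, using the literal token ``NA``
for not-measured cells, UTF-8 and decimal points throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constants import NA_TOKEN

REQUIRED_COLUMNS = (
    "assay_id", "genotype", "allele_id", "block_id", "timepoint", "arm",
    "value", "unit",
)

KEY_COLUMNS = (
    "assay_id", "genotype", "allele_id", "block_id", "timepoint", "arm",
    "replicate",
)

__all__ = [
    "read_phenotype_csv",
    "write_phenotype_csv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "REQUIRED_COLUMNS",
]


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format phenotype CSV.

    Raises ``ValueError`` naming the offending CSV line numbers for
    non-finite values or duplicated measurement keys.  An empty
    ``timepoint`` column entry is accepted (endpoint assays).
    """
    table = pd.read_csv(path, dtype={"assay_id": str, "genotype": str,
                                     "allele_id": str, "block_id": str,
                                     "arm": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "replicate" not in table.columns:
        table["replicate"] = table.groupby(
            ["assay_id", "genotype", "block_id", "timepoint", "arm"], dropna=False
        ).cumcount() + 1
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = table.index[~np.isfinite(values)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-finite or non-numeric value at CSV line(s) {lines}")
    table["value"] = values
    table["timepoint"] = pd.to_numeric(table["timepoint"], errors="coerce")
    dup = table.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        offenders = table.loc[dup, list(KEY_COLUMNS)].head(10)
        lines = [int(i) + 2 for i in offenders.index]
        raise ValueError(
            f"{path}: duplicated measurement key at CSV line(s) {lines}:\n{offenders}"
        )
    return table


def write_phenotype_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table as tidy CSV (round-trip stable)."""
    cols = [c for c in (*REQUIRED_COLUMNS, "replicate") if c in table.columns]
    table[cols].to_csv(path, index=False, na_rep="")


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path,
                     index_label: str = "line") -> None:
    """Write a lines x assays matrix as TSV with explicit NA tokens."""
    matrix.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label=index_label)


def read_matrix_tsv(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False)
    if numeric:
        df = df.astype(float)
    return df
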