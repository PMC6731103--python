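"""Readers and writers for the plain-text interchange formats.

Counts travel as TSV (``gene_id`` + sample columns), viability as long-format
CSV (``line,agent,concentration_uM,replicate,viability_pct``), essentiality
as TSV (genes x lines) and perturbation reference signatures as GCT v1.2
text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_viability_csv",
    "write_viability_csv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gct",
    "write_gct",
]

VIABILITY_COLUMNS = ["line", "agent", "concentration_uM", "replicate", "viability_pct"]


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_viability_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VIABILITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"viability CSV missing columns: {sorted(missing)}")
    return df


def write_viability_csv(df: pd.DataFrame, path) -> None:
    df[VIABILITY_COLUMNS].to_csv(path, index=False)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "gene_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_gct(path) -> pd.DataFrame:
    """Read a GCT v1.2 text matrix into genes x perturbations."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        nrow, ncol = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != nrow or df.shape[1] - 2 != ncol:
        raise ValueError("GCT dimension header does not match body")
    return df.set_index(df.columns[0]).drop(columns=[df.columns[1]])


def write_gct(matrix: pd.DataFrame, path) -> None:
    """Write genes x perturbations as GCT v1.2."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        body = matrix.copy()
        body.insert(0, "Description", "na")
        body.index.name = "NAME"
        body.to_csv(fh, sep="\t")
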