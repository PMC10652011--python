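"""Readers and writers for the plain-text formats used across the pipeline.

Formats: GMT gene sets, AIRR rearrangement TSV, MatrixMarket (MTX) expression
triplets with sidecar gene/cell lists, and generic TSV tables with a header
comment naming the producing operation.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: Minimal AIRR rearrangement columns produced and consumed by this package.
AIRR_COLUMNS = [
    "cell_id", "locus", "junction", "junction_aa", "v_call", "j_call",
    "productive", "duplicate_count",
]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes]}`` (descriptions dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "crcisc") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV; booleans in ``productive`` are normalized."""
    df = pd.read_csv(path, sep="\t", dtype={"junction": str, "junction_aa": str})
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR table at {path} missing columns: {missing}")
    if df["productive"].dtype == object:
        df["productive"] = df["productive"].map(
            lambda v: str(v).strip().upper() in ("T", "TRUE", "1"))
    df["productive"] = df["productive"].astype(bool)
    return df


def write_airr(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in AIRR_COLUMNS if c in records.columns]
    extra = [c for c in records.columns if c not in cols]
    out = records[cols + extra].copy()
    out["productive"] = np.where(out["productive"], "T", "F")
    out.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, producer: str | None = None,
              index: bool = True) -> None:
    """Write a TSV with an optional ``#`` header comment naming the producer."""
    with open(path, "w") as fh:
        if producer:
            fh.write(f"# produced by crcisc: {producer}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression_mtx(expression: pd.DataFrame, out_dir: str | Path,
                         prefix: str = "matrix") -> None:
    """Write a cells x genes expression frame as MTX triplet + row/col lists.

    The matrix is stored genes x cells (the usual single-cell convention) with
    ``<prefix>.mtx``, ``<prefix>.genes.tsv`` and ``<prefix>.cells.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(expression.to_numpy().T)
    scipy.io.mmwrite(str(out / f"{prefix}.mtx"), mat)
    pd.Series(expression.columns).to_csv(out / f"{prefix}.genes.tsv",
                                         sep="\t", index=False, header=False)
    pd.Series(expression.index).to_csv(out / f"{prefix}.cells.tsv",
                                       sep="\t", index=False, header=False)


def read_expression_mtx(dir_path: str | Path, prefix: str = "matrix") -> pd.DataFrame:
    d = Path(dir_path)
    mat = scipy.io.mmread(str(d / f"{prefix}.mtx")).toarray().T
    genes = pd.read_csv(d / f"{prefix}.genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(d / f"{prefix}.cells.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(mat, index=cells, columns=genes)


def write_expression_tsv_gz(expression: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x cells gzipped TSV from a cells x genes frame."""
    with gzip.open(path, "wt") as fh:
        expression.T.to_csv(fh, sep="\t")


def read_expression_tsv_gz(path: str | Path) -> pd.DataFrame:
    with gzip.open(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0).T
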