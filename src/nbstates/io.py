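"""Readers and writers for the plain-text formats used across the pipeline.

Counts travel as TSV (first column = gene symbol, header = sample ids) or as
MatrixMarket coordinate files with ``.rows`` / ``.cols`` sidecars holding the
gene and sample names (1-based indices, per the MatrixMarket convention).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import CountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_condition_table",
    "read_signature_list",
    "read_ortholog_map",
    "read_cell_annotations",
]


def read_count_matrix(path, fmt: str = "tsv", condition: pd.Series | None = None) -> CountMatrix:
    """Read a gene x sample count matrix from ``tsv`` or ``mtx`` format."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx":
        df = _read_mtx(path)
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")
    return CountMatrix(df, condition)


def _read_mtx(path: Path) -> pd.DataFrame:
    base = path.with_suffix("") if path.suffix == ".mtx" else path
    rows = Path(f"{base}.rows").read_text().split()
    cols = Path(f"{base}.cols").read_text().split()
    _validate_mtx_indices(path)
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if mat.shape != (len(rows), len(cols)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(rows)} rows, {len(cols)} cols)"
        )
    return pd.DataFrame(mat, index=rows, columns=cols)


def _validate_mtx_indices(path: Path) -> None:
    # MatrixMarket coordinate entries are 1-based; reject 0-based files early.
    with open(path) as fh:
        header_seen = False
        coordinate = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                if line.startswith("%%MatrixMarket"):
                    coordinate = "coordinate" in line
                continue
            if not header_seen:
                header_seen = True  # dimensions line
                continue
            if not coordinate:
                return
            fields = line.split()
            if int(fields[0]) < 1 or int(fields[1]) < 1:
                raise ValueError(
                    f"{path}: MatrixMarket entries are 1-based; found index "
                    f"({fields[0]}, {fields[1]})"
                )


def write_count_matrix(cm: CountMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        out = cm.counts.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
    elif fmt == "mtx":
        base = path.with_suffix("") if path.suffix == ".mtx" else path
        scipy.io.mmwrite(
            str(path), scipy.sparse.coo_matrix(cm.counts.to_numpy()), field="integer"
        )
        Path(f"{base}.rows").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{base}.cols").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")


def read_condition_table(path) -> pd.Series:
    """TSV with columns (sample, group) -> Series sample -> group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (sample, group)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def read_signature_list(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    genes: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym and sym not in seen:
            genes.append(sym)
            seen.add(sym)
    return genes


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV (reference symbol, target symbol) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ref_symbol, target_symbol)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_cell_annotations(path) -> pd.DataFrame:
    """TSV with columns cell_id, cell_type, dev_order -> indexed DataFrame."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "cell_type", "dev_order"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df.set_index("cell_id")


def atomic_write_text(path, text: str) -> None:
    """Write a file atomically (temp file + rename)."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
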