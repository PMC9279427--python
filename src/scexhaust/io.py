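"""Readers and writers for the formats the pipeline touches.

10x-style MTX triplets (MatrixMarket coordinate integer matrix +
features.tsv + barcodes.tsv), annotation and panel CSVs, and TSV result
tables.  Reads are gzip-transparent (a ``.gz`` suffix is handled for every
text input).  The on-disk MTX may be either genes x cells (the 10x
convention) or cells x genes; orientation is inferred from the barcode and
feature list lengths and the in-memory result is always cells x genes.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import AnalytePanel, CountMatrix, validate_annotation

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_panel_csv",
    "write_panel_csv",
    "write_results_tsv",
    "mito_mask_from_symbols",
]

MITO_PREFIXES = ("MT-", "mt-")


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _maybe_gz(directory: Path, stem: str) -> Path:
    """Return ``stem`` or ``stem.gz`` inside directory, whichever exists."""
    plain = directory / stem
    if plain.exists():
        return plain
    gz = directory / (stem + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(f"neither {plain} nor {gz} exists")


def mito_mask_from_symbols(genes, prefixes=MITO_PREFIXES) -> np.ndarray:
    """Boolean mask of mitochondrial genes by symbol prefix ("MT-"/"mt-")."""
    return np.array([g.startswith(tuple(prefixes)) for g in genes], dtype=bool)


def _dedupe(symbols: list[str]) -> list[str]:
    """Disambiguate repeated gene symbols by suffixing .1, .2 in file order."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def _read_tsv_column(path, col: int, n_cols_min: int) -> list[str]:
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < n_cols_min:
                raise ValueError(f"{path}: line {ln}: expected >= {n_cols_min} tab-separated fields")
            rows.append(parts[col])
    return rows


def read_10x_mtx(
    directory,
    matrix_name: str = "matrix.mtx",
    features_name: str = "features.tsv",
    barcodes_name: str = "barcodes.tsv",
    mito_prefixes=MITO_PREFIXES,
) -> CountMatrix:
    """Read a 10x-style MTX triplet into a cells x genes :class:`CountMatrix`.

    The features file may have one column (symbol) or the 10x dialect
    (id, symbol[, type]); the second column is used as symbol when present.
    Duplicate symbols are disambiguated with ``.1``, ``.2`` suffixes in file
    order; the mitochondrial mask is set from the symbol prefix rule.
    """
    directory = Path(directory)
    mtx_path = _maybe_gz(directory, matrix_name)
    feat_path = _maybe_gz(directory, features_name)
    bc_path = _maybe_gz(directory, barcodes_name)

    with _open_text(feat_path) as fh:
        first = fh.readline()
    n_feat_cols = len(first.rstrip("\n").split("\t")) if first else 1
    symbol_col = 1 if n_feat_cols >= 2 else 0
    symbols = _read_tsv_column(feat_path, symbol_col, symbol_col + 1)
    barcodes = _read_tsv_column(bc_path, 0, 1)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError(f"{bc_path}: duplicate barcodes")

    with _open_text(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"{mtx_path}: failed to parse MatrixMarket file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{mtx_path}: non-integer entries in count matrix")

    n_rows, n_cols = mat.shape
    if (n_rows, n_cols) == (len(symbols), len(barcodes)):
        mat = mat.T  # genes x cells on disk (10x convention)
    elif (n_rows, n_cols) == (len(barcodes), len(symbols)):
        pass  # already cells x genes
    else:
        raise ValueError(
            f"{mtx_path}: matrix shape {mat.shape} matches neither "
            f"(genes={len(symbols)}, cells={len(barcodes)}) nor its transpose"
        )

    genes = _dedupe(symbols)
    return CountMatrix(
        barcodes=barcodes,
        genes=genes,
        values=sp.csr_matrix(mat),
        mito_mask=mito_mask_from_symbols(genes, mito_prefixes),
    )


def write_10x_mtx(matrix: CountMatrix, directory) -> dict[str, Path]:
    """Write a :class:`CountMatrix` as a 10x-style triplet (genes x cells on
    disk, deterministic column-major entry order).  Returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "features": directory / "features.tsv",
        "barcodes": directory / "barcodes.tsv",
    }
    gxc = sp.csc_matrix(matrix.values.T)  # genes x cells, column-major = per cell
    scipy.io.mmwrite(os.fspath(paths["matrix"]), gxc, field="integer")
    with open(paths["features"], "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(b + "\n" for b in matrix.barcodes)
    return paths


def read_annotation_csv(path) -> pd.DataFrame:
    """Read and schema-validate a per-cell annotation CSV."""
    with _open_text(path) as fh:
        ann = pd.read_csv(fh)
    validate_annotation(ann)
    for col in ("true_exhausted", "true_malignant", "high_exhaustion"):
        if col in ann.columns and ann[col].dtype == object:
            ann[col] = ann[col].map({"True": True, "False": False}).astype("boolean")
    return ann


def write_annotation_csv(ann: pd.DataFrame, path) -> None:
    validate_annotation(ann)
    ann.to_csv(path, index=False)


def read_panel_csv(path, group_column: str = "group", floor_row: str = "__floor__") -> AnalytePanel:
    """Read a samples x analytes panel CSV.

    Layout: one row per sample indexed by the first column, analyte columns,
    plus a group-label column.  An optional ``__floor__`` row carries the
    per-analyte detection floor (default 0 when absent).
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, index_col=0)
    if group_column not in df.columns:
        raise ValueError(f"{path}: panel CSV must contain a {group_column!r} column")
    if floor_row in df.index:
        floors = df.loc[floor_row].drop(group_column).astype(float)
        df = df.drop(index=floor_row)
    else:
        floors = pd.Series(0.0, index=[c for c in df.columns if c != group_column])
    group = df[group_column].astype(str)
    values = df.drop(columns=[group_column]).astype(float)
    for obj in (values, group, floors):
        obj.index.name = None
    return AnalytePanel(values=values, group=group, detection_floor=floors)


def write_panel_csv(panel: AnalytePanel, path, group_column: str = "group", floor_row: str = "__floor__") -> None:
    df = panel.values.copy()
    df.insert(0, group_column, panel.group)
    floor = panel.detection_floor.to_frame().T
    floor.index = [floor_row]
    floor.insert(0, group_column, "")
    pd.concat([df, floor]).to_csv(path, index_label="sample")


def write_results_tsv(tables: dict[str, pd.DataFrame], directory) -> dict[str, Path]:
    """Write named result tables as TSV files ``<name>.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, table in tables.items():
        p = directory / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        out[name] = p
    return out
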