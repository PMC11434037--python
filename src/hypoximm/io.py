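"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: MatrixMarket sparse triplets with companion features /
barcodes files (the 10x convention, uncompressed), dense TSV matrices
(first column gene ids, header row sample ids), GMT gene-set files, and
tissue-position CSV tables in both the headered and headerless 10x dialects.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ExpressionMatrix, FormatError, SignatureSet

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _read_lines(path: PathLike, what: str) -> list[str]:
    p = Path(path)
    if not p.exists():
        raise FormatError(f"{what} file not found: {p}")
    with open(p) as fh:
        return [ln.rstrip("\n").split("\t")[0] for ln in fh if ln.strip()]


def read_mtx(
    matrix_path: PathLike, features_path: PathLike, barcodes_path: PathLike
) -> ExpressionMatrix:
    """Read a 10x-style MTX triplet into a raw-counts matrix.

    Gene and sample order follow the features / barcodes files; the MTX body
    order is irrelevant.  Dimension mismatches between the header and the
    companion files raise :class:`FormatError` naming the offending file.
    """
    genes = _read_lines(features_path, "features")
    barcodes = _read_lines(barcodes_path, "barcodes")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # malformed header/body
        raise FormatError(f"cannot parse MTX file {matrix_path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"MTX declares {mat.shape[0]} rows but features file "
            f"{features_path} has {len(genes)} entries"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX declares {mat.shape[1]} columns but barcodes file "
            f"{barcodes_path} has {len(barcodes)} entries"
        )
    dense = np.asarray(mat.todense(), dtype=float)
    return ExpressionMatrix(genes, barcodes, dense, "raw_counts")


def write_mtx(
    expr: ExpressionMatrix,
    matrix_path: PathLike,
    features_path: PathLike,
    barcodes_path: PathLike,
) -> None:
    sparse = scipy.sparse.coo_matrix(expr.values)
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer"
                     if expr.value_kind == "raw_counts" else "real")
    Path(features_path).write_text("".join(f"{g}\n" for g in expr.gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in expr.sample_ids))


def read_dense_tsv(path: PathLike, value_kind: str = "raw_counts") -> ExpressionMatrix:
    """Read a dense gene x sample TSV.

    Duplicate gene ids collapse by sum (raw_counts) or mean (lognorm), with a
    logged warning; any non-numeric cell raises with its row/column location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        row = mask.any(axis=1).idxmax()
        col = mask.loc[row].idxmax()
        raise FormatError(
            f"non-numeric cell at gene {row!r}, sample {col!r} in {path}"
        )
    if numeric.index.duplicated().any():
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        how = "sum" if value_kind == "raw_counts" else "mean"
        logger.warning(
            "collapsing %d duplicated gene ids by %s: %s",
            len(dups), how, dups[:5],
        )
        grouped = numeric.groupby(level=0, sort=False)
        numeric = grouped.sum() if value_kind == "raw_counts" else grouped.mean()
    return ExpressionMatrix(
        list(numeric.index.astype(str)),
        list(numeric.columns.astype(str)),
        numeric.to_numpy(float),
        value_kind,
    )


def write_dense_tsv(expr: ExpressionMatrix, path: PathLike) -> None:
    df = expr.to_frame()
    if expr.value_kind == "raw_counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene")


_POSITION_COLS = ["barcode", "in_tissue", "array_row", "array_col", "px_x", "px_y"]


def read_positions(path: PathLike) -> pd.DataFrame:
    """Read a tissue-positions CSV (headered or headerless; auto-detected).

    Returns a barcode-indexed frame with array_row, array_col, px_x, px_y for
    in-tissue spots only.
    """
    with open(path) as fh:
        first = fh.readline()
    # the headered dialect starts with a "barcode" column name
    has_header = "barcode" in first.lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise FormatError(
            f"positions file {path} has {df.shape[1]} columns, expected 6"
        )
    df.columns = _POSITION_COLS
    df = df[df["in_tissue"].astype(int) == 1].copy()
    df["barcode"] = df["barcode"].astype(str)
    df = df.set_index("barcode")
    return df[["array_row", "array_col", "px_x", "px_y"]].astype(float)


def write_positions(
    barcodes: list[str],
    array_row: np.ndarray,
    array_col: np.ndarray,
    px_x: np.ndarray,
    px_y: np.ndarray,
    path: PathLike,
) -> None:
    pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": 1,
            "array_row": np.asarray(array_row, dtype=int),
            "array_col": np.asarray(array_col, dtype=int),
            "px_x": px_x,
            "px_y": px_y,
        }
    ).to_csv(path, index=False)


def join_positions(expr: ExpressionMatrix, positions: pd.DataFrame):
    """Align a positions table to expression columns by barcode.

    Raises :class:`FormatError` listing the expression barcodes missing from
    the positions table.
    """
    missing = [b for b in expr.sample_ids if b not in positions.index]
    if missing:
        raise FormatError(
            f"{len(missing)} barcodes present in expression but absent from "
            f"positions: {missing[:10]}"
        )
    return positions.loc[expr.sample_ids]


def read_gmt(path: PathLike) -> SignatureSet:
    """Read a GMT file into ordered, de-duplicated gene lists."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} in {path} has {len(fields)} fields; "
                    "expected name, description, and at least one gene"
                )
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "duplicate gene %s in signature %s (line %d); keeping first",
                        g, name, lineno,
                    )
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    return SignatureSet(sets=sets)


def write_gmt(signatures: SignatureSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def report_missing_genes(expr: ExpressionMatrix, signatures: SignatureSet) -> dict:
    """Log and return signature genes absent from the matrix (exact match)."""
    present = set(expr.gene_ids)
    missing = {
        name: [g for g in genes if g not in present]
        for name, genes in signatures.items()
    }
    for name, genes in missing.items():
        if genes:
            logger.info(
                "signature %s: %d/%d genes absent from matrix: %s",
                name, len(genes), len(signatures[name]), genes[:10],
            )
    return missing
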