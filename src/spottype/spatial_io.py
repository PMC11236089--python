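"""Readers and writers for the standard spatial expression formats.

Supported: Matrix Market bundles (``matrix.mtx[.gz]`` + ``features.tsv[.gz]``
+ ``barcodes.tsv[.gz]``), Visium-style ``tissue_positions.csv`` (with or
without header), dense CSV matrices for small data, annotation TSVs and
two-column taxonomy TSVs.  Micron coordinates follow the image convention
(origin top-left, y increasing downward, 0-based), matching full-resolution
pixel coordinates of Visium position files.
"""

from __future__ import annotations

import gzip
import logging
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import GeneSpotMatrix, SpotGeometry, canonical_gene
from .errors import FormatError
from .scoring import AnnotationResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_tissue_positions",
    "write_tissue_positions",
    "read_dense_matrix",
    "write_dense_matrix",
    "write_annotations",
    "read_annotations",
]

_POSITION_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


def _find(dir_path: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        p = os.path.join(dir_path, name)
        if os.path.exists(p):
            return p
    raise FormatError(f"{stem}[.gz] not found in {dir_path}")


def _open_text(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_mtx_bundle(dir_path: str) -> GeneSpotMatrix:
    """Read a genes x spots count matrix from an MTX three-file bundle.

    ``features.tsv`` carries gene id and gene symbol columns (symbol is the
    second column when two or more are present, otherwise the only one);
    symbols are canonicalized and duplicate symbols are resolved by summing
    their rows (logged).
    """
    mtx_path = _find(dir_path, "matrix.mtx")
    feat_path = _find(dir_path, "features.tsv")
    bc_path = _find(dir_path, "barcodes.tsv")

    opener = gzip.open if mtx_path.endswith(".gz") else open
    with opener(mtx_path, "rb") as fh:
        mat = sp.csr_matrix(scipy.io.mmread(fh))

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()
    symbols = feats[1] if feats.shape[1] >= 2 else feats[0]
    symbols = [canonical_gene(s) for s in symbols.tolist()]

    if mat.shape != (len(symbols), len(barcodes)):
        raise FormatError(
            f"matrix.mtx is {mat.shape} but features/barcodes give "
            f"{len(symbols)} x {len(barcodes)}"
        )

    if len(set(symbols)) != len(symbols):
        order: list[str] = []
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(symbols):
            if s not in groups:
                groups[s] = []
                order.append(s)
            groups[s].append(i)
        dupes = [s for s in order if len(groups[s]) > 1]
        logger.warning("summing rows of %d duplicated gene symbol(s): %s",
                       len(dupes), dupes[:10])
        rows = [np.asarray(mat[groups[s], :].sum(axis=0)).ravel() for s in order]
        mat = sp.csr_matrix(np.vstack(rows))
        symbols = order

    return GeneSpotMatrix(values=mat, gene_ids=symbols,
                          spot_ids=barcodes, layer="counts")


def write_mtx_bundle(expr: GeneSpotMatrix, dir_path: str, gzipped: bool = False) -> None:
    """Write a :class:`GeneSpotMatrix` as an MTX three-file bundle."""
    os.makedirs(dir_path, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    mtx_path = os.path.join(dir_path, "matrix.mtx" + suffix)
    opener = gzip.open if gzipped else open
    with opener(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(expr.values))

    def _write_lines(name: str, lines: list[str]) -> None:
        with opener(os.path.join(dir_path, name + suffix), "wb") as fh:
            fh.write(("\n".join(lines) + "\n").encode())

    _write_lines("features.tsv", [f"{g}\t{g}" for g in expr.gene_ids])
    _write_lines("barcodes.tsv", list(expr.spot_ids))


def read_tissue_positions(
    path: str, diameter_um: float, px_to_um: float = 1.0
) -> SpotGeometry:
    """Read a Visium-style tissue positions CSV into micron-space geometry.

    Both the headered and headerless 6-column dialects are accepted; micron
    coordinates are pixel coordinates scaled by ``px_to_um``
    (x from ``pxl_col_in_fullres``, y from ``pxl_row_in_fullres``).
    """
    first = pd.read_csv(path, nrows=1, header=None, dtype=str)
    has_header = "barcode" in first.iloc[0].tolist()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise FormatError(
            f"tissue positions file has {df.shape[1]} columns, expected 6"
        )
    df = df.iloc[:, :6]
    df.columns = _POSITION_COLUMNS
    table = pd.DataFrame(
        {
            "barcode": df["barcode"].astype(str),
            "in_tissue": df["in_tissue"].astype(int),
            "array_row": df["array_row"].astype(int),
            "array_col": df["array_col"].astype(int),
            "x_um": df["pxl_col_in_fullres"].astype(float) * px_to_um,
            "y_um": df["pxl_row_in_fullres"].astype(float) * px_to_um,
        }
    )
    return SpotGeometry(table=table, spot_diameter_um=diameter_um)


def write_tissue_positions(
    geom: SpotGeometry, path: str, header: bool = True, px_to_um: float = 1.0
) -> None:
    """Write geometry back to the Visium CSV dialect (pixel coordinates)."""
    out = pd.DataFrame(
        {
            "barcode": geom.table["barcode"],
            "in_tissue": geom.table["in_tissue"],
            "array_row": geom.table["array_row"],
            "array_col": geom.table["array_col"],
            "pxl_row_in_fullres": geom.table["y_um"] / px_to_um,
            "pxl_col_in_fullres": geom.table["x_um"] / px_to_um,
        }
    )
    out.to_csv(path, index=False, header=header)


def read_dense_matrix(path: str, layer: str = "counts") -> GeneSpotMatrix:
    """Read a dense genes x spots CSV/TSV (gene ids in the first column)."""
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return GeneSpotMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[canonical_gene(g) for g in df.index],
        spot_ids=[str(c) for c in df.columns],
        layer=layer,
    )


def write_dense_matrix(expr: GeneSpotMatrix, path: str) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr.to_frame().to_csv(path, sep=sep)


_ANNOT_COLUMNS = ["id", "assigned_label", "top_score", "runner_up", "margin"]


def write_annotations(result: AnnotationResult, path: str) -> None:
    """Write an annotation table as TSV in input row order."""
    out = result.table.reset_index()
    out.columns = _ANNOT_COLUMNS
    out.to_csv(path, sep="\t", index=False)


def read_annotations(path: str, mode: str = "spot") -> AnnotationResult:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "runner_up": str},
                     keep_default_na=False)
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation TSV missing column(s): {missing}")
    df["top_score"] = df["top_score"].astype(float)
    df["margin"] = df["margin"].astype(float)
    table = df.set_index("id")
    spot_labels = dict(zip(df["id"], df["assigned_label"]))
    return AnnotationResult(table=table, mode=mode, spot_labels=spot_labels)
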