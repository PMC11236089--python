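"""In-memory containers for spot expression data and spot geometry.

Everything downstream operates on a genes x spots matrix
(:class:`GeneSpotMatrix`) with unique identifiers on both axes, plus a
:class:`SpotGeometry` table describing where each capture spot sits on the
slide in micron coordinates (image convention: origin top-left, y grows
downward, 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

__all__ = ["GeneSpotMatrix", "SpotGeometry", "canonical_gene"]


def canonical_gene(symbol: str) -> str:
    """Canonicalize a gene symbol: strip whitespace and uppercase."""
    return symbol.strip().upper()


@dataclass
class GeneSpotMatrix:
    """A genes x spots numeric matrix with identifiers on both axes.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, shape ``(n_genes, n_spots)``.
    gene_ids, spot_ids
        Ordered unique identifiers for rows and columns.
    layer
        One of ``counts`` (non-negative raw counts), ``normalized`` or
        ``zscored`` (each retained gene row has mean 0, sd 1 across spots).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    spot_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.spot_ids = list(self.spot_ids)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene identifiers are not unique")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValidationError("spot identifiers are not unique")
        if self.layer not in ("counts", "normalized", "zscored"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.layer == "counts":
            vmin = self.values.min() if self.values.size else 0.0
            if vmin < 0:
                raise ValidationError("counts layer contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def dense(self) -> np.ndarray:
        """Return values as a dense float ndarray."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "GeneSpotMatrix":
        """Row-subset to ``genes`` (which must all be present), in the given order."""
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        vals = self.values[rows, :]
        return replace(self, values=vals, gene_ids=list(genes))

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view, genes as index, spots as columns."""
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.spot_ids)


@dataclass
class SpotGeometry:
    """Per-spot slide geometry.

    ``table`` holds one row per spot with columns ``barcode``, ``in_tissue``
    (0/1), ``array_row``, ``array_col``, ``x_um``, ``y_um``; all spots share
    a single capture diameter ``spot_diameter_um``.
    """

    table: pd.DataFrame
    spot_diameter_um: float
    _required: tuple = field(
        default=("barcode", "in_tissue", "array_row", "array_col", "x_um", "y_um"),
        repr=False,
    )

    def __post_init__(self) -> None:
        missing = [c for c in self._required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"SpotGeometry table missing columns: {missing}")
        if self.spot_diameter_um <= 0:
            raise ValidationError("spot_diameter_um must be > 0")
        if self.table["barcode"].duplicated().any():
            raise ValidationError("spot barcodes are not unique")
        coords = self.table[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("spot coordinates must be finite")
        self.table = self.table.reset_index(drop=True)

    @property
    def barcodes(self) -> list[str]:
        return self.table["barcode"].tolist()

    def coords(self) -> np.ndarray:
        """(n_spots, 2) array of (x_um, y_um)."""
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)
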