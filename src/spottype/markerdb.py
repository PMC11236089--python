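"""Marker database handling: parsing, validation, specificity weights,

panel-coverage diagnostics and marker derivation from reference profiles.

A marker database assigns to every (tissue, cell type) pair a set of
positive marker genes (expected high in that cell type) and an optional set
of negative markers (expected low).  The on-disk dialect is a UTF-8 TSV
with columns ``tissueType``, ``cellName``, ``geneSymbolmore1`` (positive
markers, comma-separated) and ``geneSymbolmore2`` (negative markers,
comma-separated, may be empty) — the layout used by public marker
collections such as scTypeDB.

Specificity weights up-weight genes that mark few cell types of a tissue
and down-weight promiscuous markers: with ``N`` cell types in the tissue
and a gene appearing in the marker lists of ``n_g`` of them,

    w_g = 1 - (n_g - 1) / (N - 1)        (w_g = 1 when N == 1)

so a gene marking exactly one cell type gets weight 1 and a gene marking
all of them gets weight 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSpotMatrix, canonical_gene
from .errors import FormatError, TissueLookupError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerEntry",
    "MarkerDatabase",
    "SpecificityWeights",
    "CoverageReport",
    "load_marker_db",
    "compute_specificity_weights",
    "marker_coverage_report",
    "derive_markers_from_reference",
]

_COLUMNS = ("tissueType", "cellName", "geneSymbolmore1", "geneSymbolmore2")


@dataclass(frozen=True)
class MarkerEntry:
    tissue: str
    cell_type: str
    positive_genes: frozenset[str]
    negative_genes: frozenset[str]


@dataclass
class MarkerDatabase:
    """Validated collection of marker entries keyed by (tissue, cell type)."""

    entries: list[MarkerEntry]
    allow_empty_positive: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.tissue, e.cell_type)
            if key in seen:
                raise ValidationError(
                    f"duplicate (tissue, cell type) entry: {e.tissue!r}/{e.cell_type!r}"
                )
            seen.add(key)
            both = e.positive_genes & e.negative_genes
            if both:
                raise ValidationError(
                    f"gene(s) {sorted(both)} listed as both positive and negative "
                    f"markers of {e.tissue!r}/{e.cell_type!r}"
                )
            if not e.positive_genes and not self.allow_empty_positive:
                raise ValidationError(
                    f"entry {e.tissue!r}/{e.cell_type!r} has no positive markers"
                )

    def tissues(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.tissue not in out:
                out.append(e.tissue)
        return out

    def entries_for(self, tissue: str) -> list[MarkerEntry]:
        found = [e for e in self.entries if e.tissue == tissue]
        if not found:
            raise TissueLookupError(
                f"tissue {tissue!r} not found in marker database "
                f"(available: {self.tissues()})"
            )
        return found

    def cell_types(self, tissue: str) -> list[str]:
        return [e.cell_type for e in self.entries_for(tissue)]

    def all_genes(self, tissue: str) -> set[str]:
        genes: set[str] = set()
        for e in self.entries_for(tissue):
            genes |= e.positive_genes | e.negative_genes
        return genes

    def to_tsv(self, path) -> None:
        rows = [
            {
                "tissueType": e.tissue,
                "cellName": e.cell_type,
                "geneSymbolmore1": ",".join(sorted(e.positive_genes)),
                "geneSymbolmore2": ",".join(sorted(e.negative_genes)),
            }
            for e in self.entries
        ]
        pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, sep="\t", index=False)


@dataclass
class SpecificityWeights:
    """Per-gene specificity weights for one tissue's marker panel."""

    weights: dict[str, float]
    tissue: str
    n_cell_types: int

    def __post_init__(self) -> None:
        for g, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"weight for {g} out of [0, 1]: {w}")

    def __getitem__(self, gene: str) -> float:
        return self.weights[gene]


@dataclass
class CoverageReport:
    """Marker-panel coverage of a gene universe, one row per cell type.

    Columns: cell_type, n_positive_in_db, n_positive_detected,
    n_negative_in_db, n_negative_detected, fraction_detected.
    """

    per_cell_type: pd.DataFrame
    genes_in_universe: int
    db_genes_detected: int

    def to_tsv(self, path) -> None:
        self.per_cell_type.to_csv(path, sep="\t", index=False)


def _split_genes(cell: str) -> frozenset[str]:
    if not isinstance(cell, str):
        return frozenset()
    return frozenset(
        canonical_gene(g) for g in cell.split(",") if canonical_gene(g)
    )


def load_marker_db(path, tissue_filter: str | None = None) -> MarkerDatabase:
    """Parse a marker-database TSV, optionally restricted to one tissue.

    Gene symbols are whitespace-trimmed, uppercased and deduplicated within
    each list.  Raises :class:`FormatError` on missing columns and
    :class:`ValidationError` on duplicate (tissue, cellName) rows or a gene
    appearing in both lists of one cell type.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"marker DB is missing required column(s): {missing}")
    entries = []
    for _, row in df.iterrows():
        tissue = row["tissueType"].strip()
        cell_type = row["cellName"].strip()
        if tissue_filter is not None and tissue != tissue_filter:
            continue
        entries.append(
            MarkerEntry(
                tissue=tissue,
                cell_type=cell_type,
                positive_genes=_split_genes(row["geneSymbolmore1"]),
                negative_genes=_split_genes(row["geneSymbolmore2"]),
            )
        )
    if tissue_filter is not None and not entries:
        raise TissueLookupError(f"tissue {tissue_filter!r} not found in {path}")
    return MarkerDatabase(entries)


def compute_specificity_weights(db: MarkerDatabase, tissue: str) -> SpecificityWeights:
    """Linear specificity weights over the tissue's marker-gene union.

    A cell type counts once toward ``n_g`` whether the gene sits in its
    positive or negative list (or both); cross-tissue occurrences are
    ignored because scoring is always tissue-scoped.
    """
    entries = db.entries_for(tissue)
    n_types = len(entries)
    counts: dict[str, int] = {}
    for e in entries:
        for g in e.positive_genes | e.negative_genes:
            counts[g] = counts.get(g, 0) + 1
    if n_types == 1:
        weights = {g: 1.0 for g in counts}
    else:
        weights = {g: 1.0 - (n - 1) / (n_types - 1) for g, n in counts.items()}
    return SpecificityWeights(weights=weights, tissue=tissue, n_cell_types=n_types)


def marker_coverage_report(
    db: MarkerDatabase, tissue: str, gene_universe: set[str]
) -> CoverageReport:
    """Count how many of each cell type's markers are present in a gene universe.

    ``gene_universe`` is the set of genes the assay profiles (e.g. a 313-gene
    targeted panel).  Rows are ordered lexicographically by cell type.
    """
    if not gene_universe:
        raise ValidationError("gene_universe must be non-empty")
    universe = {canonical_gene(g) for g in gene_universe}
    rows = []
    db_genes: set[str] = set()
    for e in sorted(db.entries_for(tissue), key=lambda e: e.cell_type):
        db_genes |= e.positive_genes | e.negative_genes
        n_pos = len(e.positive_genes)
        n_neg = len(e.negative_genes)
        n_pos_det = len(e.positive_genes & universe)
        n_neg_det = len(e.negative_genes & universe)
        rows.append(
            {
                "cell_type": e.cell_type,
                "n_positive_in_db": n_pos,
                "n_positive_detected": n_pos_det,
                "n_negative_in_db": n_neg,
                "n_negative_detected": n_neg_det,
                "fraction_detected": (n_pos_det + n_neg_det) / (n_pos + n_neg),
            }
        )
    return CoverageReport(
        per_cell_type=pd.DataFrame(rows),
        genes_in_universe=len(universe),
        db_genes_detected=len(db_genes & universe),
    )


def derive_markers_from_reference(
    expr: GeneSpotMatrix,
    labels: dict[str, str],
    top_n: int,
    tissue: str,
) -> MarkerDatabase:
    """Derive positive marker sets from labeled reference profiles.

    For each label ``k`` and gene ``g`` the score is the log1p-mean
    expression of ``g`` in ``k`` minus the maximum log1p-mean over all other
    labels; the top ``top_n`` genes with strictly positive score become
    ``k``'s positive markers (ties broken by lexicographic gene symbol).
    Negative marker sets are left empty — a deterministic mean-difference
    rule rather than a formal differential-expression test.
    """
    missing = [s for s in expr.spot_ids if s not in labels]
    if missing:
        raise ValidationError(f"profiles without a label: {missing[:5]}")
    lab = np.array([labels[s] for s in expr.spot_ids])
    classes = sorted(set(lab))
    if len(classes) < 2:
        raise ValidationError("need at least 2 distinct labels to derive markers")

    logx = np.log1p(expr.dense())
    means = np.stack([logx[:, lab == k].mean(axis=1) for k in classes])  # K x G

    entries = []
    genes = np.array([canonical_gene(g) for g in expr.gene_ids])
    for ki, k in enumerate(classes):
        others = np.delete(means, ki, axis=0)
        score = means[ki] - others.max(axis=0)
        ok = np.flatnonzero(score > 0)
        order = sorted(ok, key=lambda i: (-score[i], genes[i]))
        if len(order) < top_n:
            logger.warning(
                "label %r: only %d genes with positive specificity score "
                "(top_n=%d requested)", k, len(order), top_n,
            )
        chosen = frozenset(genes[i] for i in order[:top_n])
        entries.append(
            MarkerEntry(
                tissue=tissue,
                cell_type=k,
                positive_genes=chosen,
                negative_genes=frozenset(),
            )
        )
    return MarkerDatabase(entries, allow_empty_positive=True)
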