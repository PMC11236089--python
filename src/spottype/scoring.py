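"""Marker-set enrichment scoring and label assignment for spots or clusters.

The pipeline is: restrict the expression matrix to marker genes, log1p and
z-score each gene across spots (:func:`zscore_normalize`), then for every
cell type ``k`` with detected positive markers ``P_k`` and negative markers
``N_k`` compute at each spot ``s``

    ES(k, s) = ( sum_{g in P_k} w_g z_{g,s} - sum_{g in N_k} w_g z_{g,s} )
               / sqrt(|P_k| + |N_k|)

where ``w_g`` is the gene's specificity weight.  The square-root
marker-count normalizer makes scores comparable between cell types with
different marker-set sizes.  The per-spot label is the maximum-scoring cell
type; cluster mode sums scores over member spots first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import GeneSpotMatrix, canonical_gene
from .errors import NoMarkerGenesError, ValidationError
from .markerdb import MarkerDatabase, SpecificityWeights

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentMatrix",
    "AnnotationResult",
    "zscore_normalize",
    "sctype_score",
    "assign_spots",
    "assign_clusters",
]

UNKNOWN = "Unknown"


@dataclass
class EnrichmentMatrix:
    """Cell types x spots score matrix.

    Cell types with zero usable markers are excluded from the rows but
    recorded in ``markers_used`` with (0, 0).
    """

    scores: np.ndarray
    cell_types: list[str]
    spot_ids: list[str]
    markers_used: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.cell_types), len(self.spot_ids)):
            raise ValidationError("enrichment matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("enrichment scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_types, columns=self.spot_ids)


@dataclass
class AnnotationResult:
    """Label assignment per spot or per cluster.

    ``table`` has one row per unit (spot or cluster) with columns
    ``assigned_label``, ``top_score``, ``runner_up``, ``margin``; the index
    is the unit id in input order.  ``spot_labels`` always maps every spot
    to its final label (cluster members inherit the cluster label).
    """

    table: pd.DataFrame
    mode: str
    spot_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.mode not in ("spot", "cluster"):
            raise ValidationError(f"unknown annotation mode {self.mode!r}")
        if (self.table["margin"] < 0).any():
            raise ValidationError("negative margin in annotation result")


def zscore_normalize(expr: GeneSpotMatrix, gene_subset: set[str]) -> GeneSpotMatrix:
    """Restrict to marker genes, log1p-transform and z-score each gene row.

    Standardization uses the n-1 (sample) denominator across spots; rows
    with zero variance are dropped and logged.  Raises
    :class:`NoMarkerGenesError` when no gene of ``gene_subset`` is present
    in the matrix — the failure mode of targeted panels whose probes do not
    overlap the marker database.
    """
    if expr.layer not in ("counts", "normalized"):
        raise ValidationError("zscore_normalize expects a counts or normalized layer")
    if not gene_subset:
        raise ValidationError("gene_subset must be non-empty")
    subset = {canonical_gene(g) for g in gene_subset}
    keep = [g for g in expr.gene_ids if canonical_gene(g) in subset]
    if not keep:
        raise NoMarkerGenesError("no marker genes detected in data")
    sub = expr.subset_genes(keep)
    x = np.log1p(sub.dense())
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True) if x.shape[1] > 1 else np.zeros_like(mu)
    nonzero = sd[:, 0] > 0
    dropped = [g for g, ok in zip(sub.gene_ids, nonzero) if not ok]
    if dropped:
        logger.info("dropping %d zero-variance gene row(s): %s",
                    len(dropped), dropped[:10])
    z = (x[nonzero] - mu[nonzero]) / sd[nonzero]
    return GeneSpotMatrix(
        values=z,
        gene_ids=[g for g, ok in zip(sub.gene_ids, nonzero) if ok],
        spot_ids=sub.spot_ids,
        layer="zscored",
    )


def sctype_score(
    z: GeneSpotMatrix,
    db: MarkerDatabase,
    tissue: str,
    w: SpecificityWeights,
) -> EnrichmentMatrix:
    """Weighted positive/negative marker-set enrichment per cell type and spot."""
    if z.layer != "zscored":
        raise ValidationError("sctype_score expects a zscored matrix")
    if w.tissue != tissue:
        raise ValidationError(
            f"weights computed for tissue {w.tissue!r}, scoring {tissue!r}"
        )
    entries = db.entries_for(tissue)
    zmat = z.dense()
    gidx = z.gene_index()

    rows: list[np.ndarray] = []
    kept_types: list[str] = []
    markers_used: dict[str, tuple[int, int]] = {}
    for e in entries:
        pos = sorted(g for g in e.positive_genes if g in gidx)
        neg = sorted(g for g in e.negative_genes if g in gidx)
        markers_used[e.cell_type] = (len(pos), len(neg))
        n_markers = len(pos) + len(neg)
        if n_markers == 0:
            logger.warning(
                "cell type %r has no markers detected in the data; excluded",
                e.cell_type,
            )
            continue
        signal = np.zeros(zmat.shape[1])
        for g in pos:
            signal += w[g] * zmat[gidx[g]]
        for g in neg:
            signal -= w[g] * zmat[gidx[g]]
        rows.append(signal / np.sqrt(n_markers))
        kept_types.append(e.cell_type)
    scores = np.vstack(rows) if rows else np.empty((0, zmat.shape[1]))
    return EnrichmentMatrix(
        scores=scores,
        cell_types=kept_types,
        spot_ids=list(z.spot_ids),
        markers_used=markers_used,
    )


def _argmax_lexi(scores: np.ndarray, labels: list[str]) -> tuple[int, int | None]:
    """Index of the max score and of the runner-up; exact score ties go to

    the lexicographically smallest label."""
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], labels[i]))
    best = order[0]
    runner = order[1] if len(order) > 1 else None
    return best, runner


def assign_spots(
    em: EnrichmentMatrix, unknown_if_nonpositive: bool = False
) -> AnnotationResult:
    """Assign each spot the maximum-scoring cell type.

    With ``unknown_if_nonpositive`` a spot whose top score is <= 0 is
    labeled ``Unknown`` (its score columns are still reported).
    """
    if not em.cell_types:
        raise ValidationError("enrichment matrix has no cell-type rows")
    records = []
    spot_labels: dict[str, str] = {}
    for j, spot in enumerate(em.spot_ids):
        col = em.scores[:, j]
        best, runner = _argmax_lexi(col, em.cell_types)
        top = float(col[best])
        label = em.cell_types[best]
        if unknown_if_nonpositive and top <= 0:
            label = UNKNOWN
        runner_label = em.cell_types[runner] if runner is not None else ""
        margin = top - float(col[runner]) if runner is not None else 0.0
        records.append(
            {
                "id": spot,
                "assigned_label": label,
                "top_score": top,
                "runner_up": runner_label,
                "margin": margin,
            }
        )
        spot_labels[spot] = label
    table = pd.DataFrame(records).set_index("id")
    return AnnotationResult(table=table, mode="spot", spot_labels=spot_labels)


def assign_clusters(
    em: EnrichmentMatrix,
    cluster_of: dict[str, str],
    min_score_fraction: float = 0.25,
) -> AnnotationResult:
    """Assign each cluster the cell type with the largest summed score.

    Scores are summed over member spots; a cluster whose top summed score
    falls below ``min_score_fraction`` x (cluster size) is labeled
    ``Unknown``.  Every member spot inherits its cluster's label.
    """
    if not em.cell_types:
        raise ValidationError("enrichment matrix has no cell-type rows")
    missing = [s for s in em.spot_ids if s not in cluster_of]
    if missing:
        raise ValidationError(f"spot(s) missing from cluster map: {missing[:5]}")

    clusters: list[str] = []
    for s in em.spot_ids:  # first-appearance order
        c = str(cluster_of[s])
        if c not in clusters:
            clusters.append(c)
    members = {c: [j for j, s in enumerate(em.spot_ids)
                   if str(cluster_of[s]) == c] for c in clusters}

    records = []
    spot_labels: dict[str, str] = {}
    for c in clusters:
        cols = members[c]
        summed = em.scores[:, cols].sum(axis=1)
        best, runner = _argmax_lexi(summed, em.cell_types)
        top = float(summed[best])
        label = em.cell_types[best]
        if top < min_score_fraction * len(cols):
            label = UNKNOWN
        runner_label = em.cell_types[runner] if runner is not None else ""
        margin = top - float(summed[runner]) if runner is not None else 0.0
        records.append(
            {
                "id": c,
                "assigned_label": label,
                "top_score": top,
                "runner_up": runner_label,
                "margin": margin,
            }
        )
        for j in cols:
            spot_labels[em.spot_ids[j]] = label
    table = pd.DataFrame(records).set_index("id")
    return AnnotationResult(table=table, mode="cluster", spot_labels=spot_labels)
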