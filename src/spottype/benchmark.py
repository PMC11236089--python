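"""Taxonomy-aware benchmarking of annotation outputs against ground truth.

A prediction counts as correct when it equals the true label or is a
descendant of it in the cell-type taxonomy ("same or deeper level"): with
truth "Immune cell", predictions "T cell", "Dendritic cell" or "B cell" are
all correct while "Stromal" is not.  Before computing per-class metrics,
predictions are unified to the truth label set by mapping each to its
nearest ancestor present in that set; one-vs-rest TP/FP/FN then yield
precision, recall and F1 per truth class, summarized by the median F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["Taxonomy", "BenchmarkReport", "is_correct", "unify_labels", "evaluate"]

OTHER = "Other"
UNKNOWN = "Unknown"
EMPTY = "Empty"
MAX_DEPTH = 100


@dataclass
class Taxonomy:
    """Rooted forest of cell-type labels; ``parent`` omits the roots."""

    parent: dict[str, str]
    _warned: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        for label in self.parent:
            seen = {label}
            node = label
            for _ in range(MAX_DEPTH):
                node = self.parent.get(node)
                if node is None:
                    break
                if node in seen:
                    raise ValidationError(f"taxonomy cycle through {node!r}")
                seen.add(node)
            else:
                raise ValidationError(
                    f"label {label!r} deeper than {MAX_DEPTH} levels (cycle?)"
                )

    @property
    def labels(self) -> set[str]:
        return set(self.parent) | set(self.parent.values())

    def ancestors(self, label: str) -> list[str]:
        """Proper ancestors of ``label``, nearest first."""
        out: list[str] = []
        node = self.parent.get(label)
        while node is not None:
            out.append(node)
            node = self.parent.get(node)
        return out

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValidationError("taxonomy TSV needs two columns (child, parent)")
        if list(df.iloc[0]) == ["child", "parent"]:
            df = df.iloc[1:]
        return cls(parent=dict(zip(df[0], df[1])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.parent.items())).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class BenchmarkReport:
    """Per-class confusion counts and metrics plus the median F1 summary."""

    per_class: pd.DataFrame  # class, TP, FP, FN, precision, recall, f1
    median_f1: float

    def to_tsv(self, path) -> None:
        out = self.per_class.copy()
        summary = {c: "" for c in out.columns}
        summary.update({"class": "__median__", "f1": self.median_f1})
        out = pd.concat([out, pd.DataFrame([summary])], ignore_index=True)
        out.to_csv(path, sep="\t", index=False)


def is_correct(pred: str, truth: str, tax: Taxonomy) -> bool:
    """True iff the prediction equals the truth or the truth is one of the

    prediction's (proper) ancestors.  Predictions absent from the taxonomy
    are incorrect (logged once per unseen label)."""
    if pred == truth:
        return True
    if pred not in tax.labels:
        if pred not in tax._warned:
            tax._warned.add(pred)
            logger.warning("prediction %r is not a taxonomy label", pred)
        return False
    return truth in tax.ancestors(pred)


def unify_labels(
    preds: dict[str, str], tax: Taxonomy, truth_level_labels: set[str]
) -> dict[str, str]:
    """Map each prediction to its nearest ancestor (or itself) inside the

    truth label set; predictions with no such ancestor map to "Other"."""
    out: dict[str, str] = {}
    for spot, pred in preds.items():
        if pred == UNKNOWN:
            out[spot] = OTHER
            continue
        for candidate in [pred] + tax.ancestors(pred):
            if candidate in truth_level_labels:
                out[spot] = candidate
                break
        else:
            out[spot] = OTHER
    return out


def evaluate(
    preds: dict[str, str], truths: dict[str, str], tax: Taxonomy
) -> BenchmarkReport:
    """Unify predictions to the truth label set and compute per-class

    precision/recall/F1 and the median F1.

    Spots are inner-joined on their keys (mismatches logged); spots whose
    truth is "Empty" or "Unknown" are excluded from evaluation.  Classes
    are ordered lexicographically; the median over an even number of
    classes is the mean of the two central F1 values.
    """
    common = [s for s in truths if s in preds]
    n_dropped = (len(truths) - len(common)) + (len(preds) - len(common))
    if n_dropped:
        logger.info("dropping %d spot(s) absent from preds or truths", n_dropped)
    if not common:
        raise ValidationError("no overlapping spots between preds and truths")
    common = [s for s in common if truths[s] not in (EMPTY, UNKNOWN)]
    if not common:
        raise ValidationError("no evaluable spots (all truths Empty/Unknown)")

    classes = sorted({truths[s] for s in common})
    unified = unify_labels({s: preds[s] for s in common}, tax, set(classes))

    rows = []
    f1s = []
    for k in classes:
        tp = sum(1 for s in common if truths[s] == k and unified[s] == k)
        fp = sum(1 for s in common if truths[s] != k and unified[s] == k)
        fn = sum(1 for s in common if truths[s] == k and unified[s] != k)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall)
            else 0.0
        )
        f1s.append(f1)
        rows.append(
            {
                "class": k, "TP": tp, "FP": fp, "FN": fn,
                "precision": precision, "recall": recall, "f1": f1,
            }
        )
    return BenchmarkReport(
        per_class=pd.DataFrame(rows), median_f1=float(np.median(f1s))
    )
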