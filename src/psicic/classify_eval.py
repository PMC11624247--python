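"""Phenotype calls from colony annotations, and evaluation metrics.

A corrected annotation with ``a`` red and ``b`` white regions maps to a
phenotype: no red regions and at least one white region is [PSI+]; at least
one red region and no white regions is [psi-]; at least one of each is
sectored, with the sector count equal to the red-region count (red and white
regions alternate on a closed boundary, so a == b) and a secondary label
S1, S2, ... in reporting.

Evaluation compares predicted calls against ground-truth labels per colony:
one-vs-rest TP/FP/FN per class, precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 their harmonic mean, overall accuracy with and without the
sector-count refinement, and a confusion matrix (row-normalizable for
reporting). Sector-count classes above S3 are binned to "S3+" in summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sectorannot import ColonyAnnotation

__all__ = [
    "PSI_PLUS",
    "PSI_MINUS",
    "SECTORED",
    "ColonyCall",
    "EvalReport",
    "assign_class",
    "coarse_label",
    "summary_label",
    "precision_recall_f1",
    "f1_score",
    "evaluate",
]

PSI_PLUS = "PSI+"
PSI_MINUS = "psi-"
SECTORED = "sectored"

SUMMARY_SECTOR_BIN = 3  # S4, S5, ... reported as "S3+" in summary tables


@dataclass(frozen=True)
class ColonyCall:
    """Predicted phenotype of one colony."""

    phenotype: str  # PSI_PLUS, PSI_MINUS or SECTORED
    sector_count: int = 0  # >= 1 iff SECTORED
    weighted_purity: float = 0.0

    @property
    def secondary_label(self) -> str | None:
        return f"S{self.sector_count}" if self.phenotype == SECTORED else None

    @property
    def label(self) -> str:
        """Refined label: "PSI+", "psi-", or "S{k}"."""
        return self.secondary_label or self.phenotype


def assign_class(annotation: ColonyAnnotation) -> ColonyCall:
    """Map region counts (a red, b white) to a phenotype call."""
    if not annotation.ok:
        raise ValueError(f"cannot classify unquantifiable colony ({annotation.reason})")
    a, b = annotation.a, annotation.b
    if a == 0 and b == 0:
        raise ValueError("annotation has no regions; should be unquantifiable upstream")
    if a == 0:
        return ColonyCall(PSI_PLUS, 0, annotation.weighted_purity)
    if b == 0:
        return ColonyCall(PSI_MINUS, 0, annotation.weighted_purity)
    return ColonyCall(SECTORED, a, annotation.weighted_purity)


def coarse_label(label: str) -> str:
    """Collapse refined labels to {PSI+, psi-, sectored}."""
    return SECTORED if label.startswith("S") and label != PSI_MINUS else label


def summary_label(label: str) -> str:
    """Bin high sector counts for summary tables: S4, S5, ... -> "S3+"."""
    if label.startswith("S") and label != PSI_MINUS:
        k = int(label[1:].rstrip("+"))
        if k >= SUMMARY_SECTOR_BIN:
            return f"S{SUMMARY_SECTOR_BIN}+"
    return label


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, f1_score(precision, recall)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Classification metrics against ground truth."""

    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    accuracy: float = 0.0  # refined labels (sector counts matter)
    accuracy_coarse: float = 0.0  # phenotype only
    confusion: pd.DataFrame | None = None  # rows = truth, cols = prediction
    n_colonies: int = 0

    def confusion_row_normalized(self) -> pd.DataFrame:
        c = self.confusion.astype(float)
        sums = c.sum(axis=1).replace(0, np.nan)
        return c.div(sums, axis=0).fillna(0.0)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "accuracy_coarse": self.accuracy_coarse,
            "n_colonies": self.n_colonies,
            "confusion": (
                {str(k): v for k, v in self.confusion.to_dict(orient="index").items()}
                if self.confusion is not None
                else None
            ),
        }


def evaluate(calls: dict, truths: dict[str, str] | dict[int, str]) -> EvalReport:
    """Score predicted calls against ground-truth labels.

    ``calls`` maps colony id to a `ColonyCall` (or a refined label string);
    ``truths`` maps the same ids to refined labels ("PSI+", "psi-", "S1",
    ...). The two key sets must match exactly.
    """
    missing = sorted(set(truths) - set(calls))
    extra = sorted(set(calls) - set(truths))
    if missing or extra:
        raise ValueError(
            f"colony id mismatch: missing predictions for {missing[:10]}, "
            f"unmatched predictions {extra[:10]}"
        )
    ids = sorted(calls, key=str)
    pred = [c.label if isinstance(c, ColonyCall) else str(c) for c in (calls[i] for i in ids)]
    true = [str(truths[i]) for i in ids]
    n = len(ids)

    pred_s = [summary_label(p) for p in pred]
    true_s = [summary_label(t) for t in true]

    report = EvalReport(n_colonies=n)
    if n == 0:
        return report
    report.accuracy = float(np.mean([p == t for p, t in zip(pred, true)]))
    report.accuracy_coarse = float(
        np.mean([coarse_label(p) == coarse_label(t) for p, t in zip(pred, true)])
    )

    # per-class one-vs-rest over phenotypes and binned sector counts
    classes = [PSI_PLUS, PSI_MINUS, SECTORED] + sorted(
        {c for c in pred_s + true_s if c.startswith("S") and c != PSI_MINUS}
    )
    pred_c = [coarse_label(p) for p in pred]
    true_c = [coarse_label(t) for t in true]
    for cls in classes:
        if cls in (PSI_PLUS, PSI_MINUS, SECTORED):
            p_vec, t_vec = pred_c, true_c
        else:
            p_vec, t_vec = pred_s, true_s
        tp = sum(1 for p, t in zip(p_vec, t_vec) if p == cls and t == cls)
        fp = sum(1 for p, t in zip(p_vec, t_vec) if p == cls and t != cls)
        fn = sum(1 for p, t in zip(p_vec, t_vec) if p != cls and t == cls)
        precision, recall, f1 = precision_recall_f1(tp, fp, fn)
        report.per_class[cls] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }

    labels = sorted(set(pred_s) | set(true_s))
    report.confusion = pd.crosstab(
        pd.Series(true_s, name="truth"), pd.Series(pred_s, name="prediction")
    ).reindex(index=labels, columns=labels, fill_value=0)
    return report
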