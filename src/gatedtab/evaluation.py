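"""Imbalanced-classification metrics: confusion matrix, P/R/F1, ROC, PR.

With a rare outcome class, accuracy alone is uninformative; this module
reports the quantities that matter for minority-class detection:

* the confusion matrix at a probability threshold (positive call iff
  ``prob >= threshold``);
* precision ``TP/(TP+FP)``, recall ``TP/(TP+FN)`` and their harmonic mean
  F1 — degenerate denominators return 0 with a warning rather than
  aborting a batch evaluation;
* the ROC curve with trapezoidal AUC, which equals the probability that a
  random positive outranks a random negative (ties credited 1/2);
* the precision-recall curve with step-wise average precision
  ``AP = sum_k (R_k - R_{k-1}) * P_k``.

Curves and areas are computed with scikit-learn, whose conventions match
those definitions exactly; the test suite checks them against independent
brute-force rank and enumeration oracles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from .model import GatedTabTransformer
from .preprocess import EncodedDataset

__all__ = ["ConfusionMatrix", "CurveReport", "MetricsReport", "confusion",
           "precision_recall_f1", "roc_auc", "pr_ap", "evaluate_events"]


class DegenerateMetricWarning(UserWarning):
    """A metric denominator was zero; the metric is reported as 0."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_csv(self, path: str | Path) -> None:
        Path(path).write_text(
            "metric,count\n"
            f"tp,{self.tp}\nfp,{self.fp}\nfn,{self.fn}\ntn,{self.tn}\n",
            encoding="utf-8")


@dataclass
class CurveReport:
    """An ordered curve (ROC or PR) plus its scalar area."""

    x: np.ndarray            # FPR for ROC, recall for PR
    y: np.ndarray            # TPR for ROC, precision for PR
    thresholds: np.ndarray
    area: float
    kind: str                # "roc" | "pr"

    def to_tsv(self, path: str | Path) -> None:
        header = {"roc": "fpr\ttpr", "pr": "recall\tprecision"}[self.kind]
        lines = [header] + [f"{a:.10g}\t{b:.10g}" for a, b in zip(self.x, self.y)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def confusion(y_true: np.ndarray, y_prob: np.ndarray,
              threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion counts at a threshold; positive call iff prob >= threshold."""
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    if y_true.shape != y_prob.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_prob.shape}")
    calls = y_prob >= threshold
    pos = y_true == 1
    return ConfusionMatrix(
        tp=int((calls & pos).sum()),
        fp=int((calls & ~pos).sum()),
        fn=int((~calls & pos).sum()),
        tn=int((~calls & ~pos).sum()),
    )


def precision_recall_f1(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Precision, recall and F1 from counts; zero denominators yield 0."""

    def ratio(num: int, denom: int, name: str) -> float:
        if denom == 0:
            warnings.warn(f"{name} denominator is zero; reporting 0",
                          DegenerateMetricWarning, stacklevel=3)
            return 0.0
        return num / denom

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    if precision + recall == 0.0:
        warnings.warn("F1 denominator is zero; reporting 0",
                      DegenerateMetricWarning, stacklevel=2)
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def roc_auc(y_true: np.ndarray, y_prob: np.ndarray) -> CurveReport:
    """ROC curve over all distinct score thresholds with trapezoidal AUC."""
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(y_true, y_prob)
    return CurveReport(x=fpr, y=tpr, thresholds=thresholds,
                       area=float(roc_auc_score(y_true, y_prob)), kind="roc")


def pr_ap(y_true: np.ndarray, y_prob: np.ndarray) -> CurveReport:
    """Precision-recall curve with step-wise average precision."""
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.sum() == 0:
        raise ValueError("PR analysis requires at least one positive sample")
    precision, recall, thresholds = precision_recall_curve(y_true, y_prob)
    # sklearn returns the curve from high to low threshold; store by recall
    return CurveReport(x=recall[::-1], y=precision[::-1],
                       thresholds=thresholds[::-1],
                       area=float(average_precision_score(y_true, y_prob)),
                       kind="pr")


@dataclass
class EventMetrics:
    confusion: ConfusionMatrix
    precision: float
    recall: float
    f1: float
    auc: float
    ap: float
    roc: CurveReport
    pr: CurveReport

    def scalars(self) -> dict:
        return {
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "fn": self.confusion.fn, "tn": self.confusion.tn},
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "auc": self.auc, "ap": self.ap,
        }


@dataclass
class MetricsReport:
    """Per-event metric blocks for one evaluation run."""

    events: dict[str, EventMetrics]
    threshold: float

    def to_json(self, path: str | Path) -> None:
        payload = {"threshold": self.threshold,
                   "events": {e: m.scalars() for e, m in self.events.items()}}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                              encoding="utf-8")

    def export_curves(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for event, m in self.events.items():
            m.roc.to_tsv(d / f"{event}_roc.tsv")
            m.pr.to_tsv(d / f"{event}_pr.tsv")
            m.confusion.to_csv(d / f"{event}_confusion.csv")


def evaluate_event(y_true: np.ndarray, y_prob: np.ndarray,
                   threshold: float = 0.5) -> EventMetrics:
    cm = confusion(y_true, y_prob, threshold)
    precision, recall, f1 = precision_recall_f1(cm)
    roc = roc_auc(y_true, y_prob)
    pr = pr_ap(y_true, y_prob)
    return EventMetrics(confusion=cm, precision=precision, recall=recall,
                        f1=f1, auc=roc.area, ap=pr.area, roc=roc, pr=pr)


def evaluate_events(models: dict[str, GatedTabTransformer],
                    test_set: EncodedDataset,
                    events: list[str] | None = None,
                    threshold: float = 0.5) -> MetricsReport:
    """Score one fitted model per adverse event on a held-out split."""
    events = events or list(models)
    blocks: dict[str, EventMetrics] = {}
    for event in events:
        if event not in test_set.event_names:
            raise ValueError(
                f"event {event!r} absent from dataset outcomes "
                f"{test_set.event_names}")
        if event not in models:
            raise ValueError(f"no trained model supplied for event {event!r}")
        model = models[event]
        probs = model.predict_proba(test_set.cat_codes, test_set.cont_values)
        col = 0 if model.n_events == 1 else test_set.event_names.index(event)
        blocks[event] = evaluate_event(test_set.event_labels(event),
                                       probs[:, col], threshold)
    return MetricsReport(events=blocks, threshold=threshold)
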