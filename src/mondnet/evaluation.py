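"""Confusion-matrix accounting and screening metrics.

Accuracy is reported in percent; precision, recall, specificity and F1
as fractions by default (a ``percent`` toggle rescales them).  The
positive class is "abnormal" throughout — the screening posture — and a
per-class report is obtained by swapping the positive class.

Zero-denominator conventions: a metric whose denominator is zero is
reported as 0 with a logged warning; F1 is 0 when precision + recall = 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .synthetic import ABNORMAL, NORMAL

logger = logging.getLogger(__name__)


class EvaluationContractError(ValueError):
    """Raised when evaluation inputs violate an operation contract."""


@dataclass(frozen=True)
class ConfusionCounts:
    """The 2x2 tally: true/false positives/negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationContractError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive and negative classes exchanged."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class MetricReport:
    """Accuracy in percent; the other metrics as fractions unless ``percent``."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    percent: bool = False


def tally(
    predictions: Sequence[str],
    truth: Sequence[str],
    positive_class: str = ABNORMAL,
) -> ConfusionCounts:
    """Standard 2x2 tally of aligned prediction/truth label sequences."""
    if len(predictions) != len(truth):
        raise EvaluationContractError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    tp = tn = fp = fn = 0
    for pred, true in zip(predictions, truth):
        if true == positive_class:
            if pred == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, percent: bool = False) -> MetricReport:
    """Accuracy (percent), precision, recall, specificity and F1 from a tally."""
    if c.total == 0:
        raise EvaluationContractError("cannot compute metrics from all-zero counts")
    accuracy = (c.tp + c.tn) / c.total * 100.0
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    specificity = _safe_div(c.tn, c.tn + c.fp, "specificity")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "f1")
    scale = 100.0 if percent else 1.0
    return MetricReport(
        accuracy=accuracy,
        precision=precision * scale,
        recall=recall * scale,
        specificity=specificity * scale,
        f1=f1 * scale,
        percent=percent,
    )


def per_class_report(
    predictions: Sequence[str], truth: Sequence[str], percent: bool = False
) -> pd.DataFrame:
    """Metric table with one row per class, each as the positive class."""
    rows = []
    for cls in (NORMAL, ABNORMAL):
        counts = tally(predictions, truth, positive_class=cls)
        rep = compute_metrics(counts, percent=percent)
        rows.append(
            {
                "class": cls,
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "specificity": rep.specificity,
                "f1": rep.f1,
            }
        )
    return pd.DataFrame(rows)


def write_metrics(
    report: MetricReport, counts: ConfusionCounts, path: str | Path
) -> None:
    """Serialize a metric report plus its confusion counts as JSON."""
    payload = {"metrics": asdict(report), "confusion": asdict(counts)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
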