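"""Binary-classification evaluation: the eight-criterion report.

Threshold metrics (accuracy, sensitivity, specificity, F1, MCC, precision)
are computed from a confusion matrix built at a fixed score threshold
(score >= threshold counts as a predicted binder).  Ranking metrics are
the ROC AUC (Mann-Whitney rank formula, ties credited 1/2) and the area
under the precision-recall curve (descending-score step sweep, tie groups
processed atomically).

Any metric whose denominator vanishes is reported as ``None`` (NA) rather
than coerced to 0 — e.g. F1 is NA whenever precision + sensitivity is
zero, and AUC/AUPR are NA when a class is absent.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

DEFAULT_THRESHOLD = 0.5


@dataclasses.dataclass(frozen=True)
class ScoredLabels:
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if s.shape != y.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("scores and labels must be equal-length, non-empty 1-D")
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclasses.dataclass
class MetricsReport:
    """All eight criteria; ``None`` marks an undefined (NA) value."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    mcc: float | None = None
    precision: float | None = None
    auc: float | None = None
    aupr: float | None = None
    n_positive: int = 0
    n_negative: int = 0
    threshold: float = DEFAULT_THRESHOLD

    FIELDS = ("accuracy", "sensitivity", "specificity", "f1", "mcc",
              "precision", "auc", "aupr")

    def rounded(self, ndigits: int = 3) -> dict:
        """Presentation form: half-up rounding to ``ndigits`` decimals."""
        out = {}
        q = 10 ** ndigits
        for f in self.FIELDS:
            v = getattr(self, f)
            out[f] = None if v is None else math.floor(abs(v) * q + 0.5) / q * (1 if v >= 0 else -1)
        out["n_positive"] = self.n_positive
        out["n_negative"] = self.n_negative
        return out

    def to_json(self, path: str | Path) -> None:
        d = {f: getattr(self, f) for f in self.FIELDS}
        d.update(n_positive=self.n_positive, n_negative=self.n_negative,
                 threshold=self.threshold)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    def to_row(self) -> str:
        def fmt(v):
            return "NA" if v is None else f"{v:.3f}"
        return "\t".join(fmt(getattr(self, f)) for f in self.FIELDS) + \
            f"\t{self.n_positive}\t{self.n_negative}"


def confusion_from_scores(data: ScoredLabels, threshold: float = DEFAULT_THRESHOLD) -> ConfusionMatrix:
    """Dichotomize scores at ``threshold`` (>= is positive) and count."""
    pred = data.scores >= threshold
    pos = data.labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def basic_metrics(cm: ConfusionMatrix, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """The six threshold criteria from TP/TN/FP/FN counts.

    accuracy    = (TP+TN) / (TP+TN+FP+FN)
    sensitivity = TP / (TP+FN)
    specificity = TN / (TN+FP)
    precision   = TP / (TP+FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    if prec is None or sens is None or prec + sens == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    mcc_den = math.sqrt(float(tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    return MetricsReport(
        accuracy=(tp + tn) / cm.n,
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        mcc=mcc,
        precision=prec,
        n_positive=cm.n_positive,
        n_negative=cm.n_negative,
        threshold=threshold,
    )


def auc(data: ScoredLabels) -> float | None:
    """ROC AUC via the Mann-Whitney rank statistic; ties credit 1/2.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half.  NA when either class is absent.
    """
    pos = data.labels == 1
    P, N = int(pos.sum()), int((~pos).sum())
    if P == 0 or N == 0:
        return None
    ranks = rankdata(data.scores)  # midranks
    return float((ranks[pos].sum() - P * (P + 1) / 2) / (P * N))


def aupr(data: ScoredLabels) -> float | None:
    """Area under the precision-recall step curve (descending-score sweep).

    Tie groups enter atomically, so a constant score vector yields a
    single PR point whose area is the positive prevalence.  NA with no
    positives.
    """
    pos = (data.labels == 1).astype(float)
    P = pos.sum()
    if P == 0:
        return None
    order = np.argsort(-data.scores, kind="stable")
    s = data.scores[order]
    y = pos[order]
    # indices where a tie group ends
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundary, len(s) - 1)
    tp_cum = np.cumsum(y)[ends]
    n_cum = (ends + 1).astype(float)
    precision = tp_cum / n_cum
    recall = tp_cum / P
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def metrics_report(
    data: ScoredLabels, threshold: float = DEFAULT_THRESHOLD
) -> MetricsReport:
    """All eight criteria for one scored dataset."""
    report = basic_metrics(confusion_from_scores(data, threshold), threshold)
    report.auc = auc(data)
    report.aupr = aupr(data)
    return report


def scored(scores: Sequence[float], labels: Sequence[int]) -> ScoredLabels:
    """Convenience constructor."""
    return ScoredLabels(np.asarray(scores, float), np.asarray(labels, int))
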