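"""Confusion matrices, one-vs-rest metric tables, and ROC/AUC.

The five scalar metrics are the standard ones::

    TP rate = TP / (TP + FN)          FP rate = FP / (FP + TN)
    Precision = TP / (TP + FP)        Recall = TP rate
    F1 = 2 * Precision * Recall / (Precision + Recall)

Reports follow the classic one-vs-rest layout: each class is treated as
positive in turn, and a support-weighted summary row aggregates the two.
Full precision is kept internally; the table renderer rounds half-up to three
decimals and — deliberately — computes the weighted row from the *rounded*
per-class cells so the printed summary is self-consistent with the printed
per-class rows.

ROC curves are built by sweeping a decision threshold over the distinct score
values (equal scores collapse into a single step); AUC is the trapezoidal
area, which equals the Mann–Whitney pair statistic with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "weighted_metrics",
    "metrics_report",
    "roc_points",
    "auc",
    "round_half_up",
]

METRIC_NAMES = ("tp_rate", "fp_rate", "precision", "recall", "f1")


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (0.0005 -> 0.001), as used in printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for a designated positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.total == 0:
            raise InputError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def support(self) -> int:
        """Number of truly-positive samples."""
        return self.tp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions with the other class designated positive."""
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


def confusion(
    true_labels: Sequence,
    predicted_labels: Sequence,
    positive_class,
) -> ConfusionMatrix:
    """Count tp/fn/fp/tn with ``positive_class`` designated positive."""
    t = np.asarray([str(v) for v in true_labels], dtype=object)
    p = np.asarray([str(v) for v in predicted_labels], dtype=object)
    if len(t) != len(p) or len(t) == 0:
        raise InputError("label vectors must be same-length and non-empty")
    seen = set(t) | set(p)
    if str(positive_class) not in set(t):
        raise InputError(f"positive class {positive_class!r} absent from true labels")
    unknown = seen - set(t)
    if unknown:
        raise InputError(f"predicted label(s) never seen in truth: {sorted(unknown)}")
    tpos = t == str(positive_class)
    ppos = p == str(positive_class)
    return ConfusionMatrix(
        tp=int(np.sum(tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The five metrics for one positive class, at full precision.

    When no sample is predicted positive, precision is reported as 0.0 and
    the ``precision_defined`` entry is False.
    """
    if cm.tp + cm.fn == 0:
        raise InputError("empty positive class")
    if cm.fp + cm.tn == 0:
        raise InputError("empty negative class")
    tp_rate = cm.tp / (cm.tp + cm.fn)
    fp_rate = cm.fp / (cm.fp + cm.tn)
    defined = cm.tp + cm.fp > 0
    precision = cm.tp / (cm.tp + cm.fp) if defined else 0.0
    f1 = (
        2.0 * precision * tp_rate / (precision + tp_rate)
        if precision + tp_rate > 0
        else 0.0
    )
    return {
        "tp_rate": tp_rate,
        "fp_rate": fp_rate,
        "precision": precision,
        "recall": tp_rate,
        "f1": f1,
        "precision_defined": float(defined),
    }


def weighted_metrics(
    per_class: Mapping[str, Mapping[str, float]],
    supports: Mapping[str, int],
) -> dict[str, float]:
    """Support-weighted mean of per-class metric values.

    Pure arithmetic on whatever values are supplied — full-precision metrics
    for internal use, or rounded ones when reproducing a printed table.
    """
    total = sum(supports.values())
    if total <= 0 or any(s <= 0 for s in supports.values()):
        raise InputError("supports must be positive")
    out: dict[str, float] = {}
    for m in METRIC_NAMES:
        out[m] = sum(per_class[c][m] * supports[c] for c in per_class) / total
    return out


@dataclass
class MetricsReport:
    """One-vs-rest metric table for a two-class prediction."""

    per_class: dict[str, dict[str, float]]
    weighted: dict[str, float]
    supports: dict[str, int]
    confusions: dict[str, ConfusionMatrix]

    def rounded(self, ndigits: int = 3) -> pd.DataFrame:
        """Presentation table: per-class rows rounded half-up, weighted row
        aggregated from the *rounded* per-class values."""
        rows = {}
        rounded_pc = {
            c: {m: round_half_up(v[m], ndigits) for m in METRIC_NAMES}
            for c, v in self.per_class.items()
        }
        for c in sorted(rounded_pc):
            rows[f"{c}: positive"] = rounded_pc[c]
        w = weighted_metrics(rounded_pc, self.supports)
        rows["Weighted average"] = {m: round_half_up(w[m], ndigits) for m in METRIC_NAMES}
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]

    def to_tsv(self, path, ndigits: int = 3) -> None:
        frame = self.rounded(ndigits)
        frame.index.name = "class"
        frame.to_csv(path, sep="\t", float_format=f"%.{ndigits}f")


def metrics_report(true_labels: Sequence, predicted_labels: Sequence) -> MetricsReport:
    """Both classes one-vs-rest plus the support-weighted summary."""
    classes = sorted({str(v) for v in true_labels})
    if len(classes) != 2:
        raise InputError(f"expected two classes in truth, got {classes}")
    confusions = {c: confusion(true_labels, predicted_labels, c) for c in classes}
    per_class = {c: per_class_metrics(cm) for c, cm in confusions.items()}
    supports = {c: cm.support for c, cm in confusions.items()}
    weighted = weighted_metrics(per_class, supports)
    return MetricsReport(
        per_class=per_class,
        weighted=weighted,
        supports=supports,
        confusions=confusions,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_points(
    scores: Sequence[float],
    true_labels: Sequence,
    positive_class,
) -> np.ndarray:
    """Ordered (fp_rate, tp_rate) pairs, one per distinct score threshold,
    anchored at (0,0) and (1,1); both coordinates non-decreasing."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray([str(v) == str(positive_class) for v in true_labels])
    if len(s) != len(t) or len(s) == 0:
        raise InputError("scores and labels must be same-length and non-empty")
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tps = np.cumsum(t_sorted)
    fps = np.cumsum(~t_sorted)
    # keep only the last index of each tied-score run (ties share a threshold)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # unreachable; cumulative sums end at totals
        fpr = np.r_[fpr, 1.0]
        tpr = np.r_[tpr, 1.0]
    return np.column_stack([fpr, tpr])


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under a :func:`roc_points` curve; in [0, 1]."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InputError("expected an (n, 2) array of (fp_rate, tp_rate) points")
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
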