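"""Binary-classifier evaluation: confusion-matrix scalars, ROC and AUC.

AUC is the Mann-Whitney concordance probability (ties get half credit);
the ROC curve is a threshold sweep over unique scores, and its trapezoidal
area equals the rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "EvalReport", "scalar_metrics", "roc_auc", "round_half_up"]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding, matching printed-table presentation."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0 or int(v) != v:
                raise ValueError("confusion counts must be non-negative integers")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    counts: ConfusionCounts | None = None
    sen: float | None = None
    spe: float | None = None
    pre: float | None = None
    f1: float | None = None
    acc: float | None = None
    mcc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        out = {}
        for k in ("sen", "spe", "pre", "f1", "acc", "mcc", "auc"):
            v = getattr(self, k)
            out[k] = None if v is None else round_half_up(v, ndigits)
        return out

    def to_dict(self) -> dict:
        d = self.rounded()
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            }
        if self.roc_points:
            d["roc_points"] = [list(p) for p in self.roc_points]
        return d


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def scalar_metrics(c: ConfusionCounts) -> EvalReport:
    """Sensitivity, specificity, precision, F1, accuracy and MCC.

    Zero-denominator metrics come back as None; MCC is 0 when any marginal
    is zero.
    """
    sen = _safe_div(c.tp, c.tp + c.fn)
    spe = _safe_div(c.tn, c.tn + c.fp)
    pre = _safe_div(c.tp, c.tp + c.fp)
    acc = _safe_div(c.tp + c.tn, c.total)
    if sen is None or pre is None or (sen + pre) == 0:
        f1 = None
    else:
        f1 = 2.0 * sen * pre / (sen + pre)
    marginals = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if marginals == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(marginals))
    return EvalReport(counts=c, sen=sen, spe=spe, pre=pre, f1=f1, acc=acc, mcc=float(mcc))


def roc_auc(scores, labels) -> EvalReport:
    """ROC points and AUC from scores and 0/1 labels.

    Raises ``ValueError`` when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    npos = int(labels.sum())
    nneg = len(labels) - npos
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")

    ranks = rankdata(scores)  # average ranks -> half credit for ties
    auc = (ranks[labels == 1].sum() - npos * (npos + 1) / 2.0) / (npos * nneg)

    # threshold sweep over unique scores, descending; includes (0,0), (1,1)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(l_sorted[j] == 1)
            fp += int(l_sorted[j] == 0)
            j += 1
        points.append((fp / nneg, tp / npos))
        i = j
    return EvalReport(roc_points=points, auc=float(auc))


def trapezoid_auc(points) -> float:
    """Trapezoidal area under an ROC polyline (cross-check for the rank AUC)."""
    pts = sorted(points)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


def plot_roc(report: EvalReport, path) -> None:
    """Write an ROC curve figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p[0] for p in report.roc_points]
    ys = [p[1] for p in report.roc_points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(xs, ys, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if report.auc is not None:
        ax.set_title(f"AUC = {report.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_predictions(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full report: threshold the scores for the confusion matrix and add ROC/AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    c = ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
    )
    report = scalar_metrics(c)
    try:
        roc = roc_auc(scores, labels)
        report.roc_points = roc.roc_points
        report.auc = roc.auc
    except ValueError:
        pass
    return report
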