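"""Segmentation evaluation: confusion counts, threshold metrics, curves.

All counting is restricted to pixels inside the field-of-view mask (the
camera border is trivially non-vessel and would inflate specificity).
Metrics are accuracy, sensitivity (= recall), specificity, precision,
F1 and the Matthews correlation coefficient; ranked evaluation produces
ROC and precision-recall curves with trapezoidal AUC. Ratios with a zero
denominator are reported as NaN with an ``undefined`` flag, never
silently as 0. The default binarisation threshold is 0.49, applied with
a strict ``>`` on floating-point probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_THRESHOLD = 0.49


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    mcc: float
    roc_auc: float = float("nan")
    pr_auc: float = float("nan")
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "threshold": self.threshold,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "mcc": self.mcc,
            "roc_auc": self.roc_auc, "pr_auc": self.pr_auc,
            "undefined": list(self.undefined),
        }


@dataclass
class Curve:
    points: np.ndarray   # (n, 2) with x non-decreasing
    auc: float


def binarize(prob: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Vessel mask: pixel is 1 iff probability strictly exceeds threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    prob = np.asarray(prob, dtype=np.float64)
    return (prob > threshold).astype(np.uint8)


def confusion(pred: np.ndarray, truth: np.ndarray,
              fov: np.ndarray | None = None) -> ConfusionCounts:
    """Count TP/FP/TN/FN over FOV pixels (whole image if ``fov`` is None)."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if fov is None:
        fov = np.ones(pred.shape, dtype=bool)
    else:
        fov = np.asarray(fov).astype(bool)
        if fov.shape != pred.shape:
            raise ValueError("fov shape differs")
    p, t = pred[fov], truth[fov]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation: (TP*TN - FP*FN) / sqrt of the marginal product.

    NaN when any marginal sum is zero (the correlation is undefined).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return float("nan")
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def metrics(counts: ConfusionCounts, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Threshold metrics from confusion counts."""
    if counts.total == 0:
        raise ValueError("no evaluated pixels")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: list = []
    acc = (tp + tn) / counts.total
    se = _ratio(tp, tp + fn, "sensitivity", undefined)
    sp = _ratio(tn, tn + fp, "specificity", undefined)
    prec = _ratio(tp, tp + fp, "precision", undefined)
    if np.isnan(prec) or np.isnan(se) or (prec + se) == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * prec * se / (prec + se)
    m = mcc(counts)
    if np.isnan(m):
        undefined.append("mcc")
    return MetricsReport(counts=counts, threshold=threshold, accuracy=acc,
                         sensitivity=se, specificity=sp, precision=prec,
                         recall=se, f1=f1, mcc=m, undefined=tuple(undefined))


def roc_pr_curves(prob: np.ndarray, truth: np.ndarray,
                  fov: np.ndarray | None = None):
    """ROC and PR curves swept over the distinct probability values.

    AUC by the trapezoid rule. Requires both classes inside the FOV.
    Returns ``(Curve_roc, Curve_pr)``.
    """
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if fov is not None:
        sel = np.asarray(fov).astype(bool)
        prob, truth = prob[sel], truth[sel]
    prob, truth = prob.ravel(), truth.ravel()
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ranked evaluation")

    order = np.argsort(-prob, kind="stable")
    sorted_truth = truth[order]
    sorted_prob = prob[order]
    tp_cum = np.cumsum(sorted_truth)
    fp_cum = np.cumsum(~sorted_truth)
    # keep only the last index of each distinct threshold value
    distinct = np.nonzero(np.diff(sorted_prob))[0]
    idx = np.concatenate([distinct, [truth.size - 1]])

    tpr = np.concatenate([[0.0], tp_cum[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[idx] / n_neg])
    roc_auc = float(np.trapezoid(tpr, fpr))
    roc = Curve(points=np.column_stack([fpr, tpr]), auc=roc_auc)

    recall = tp_cum[idx] / n_pos
    precision = tp_cum[idx] / (tp_cum[idx] + fp_cum[idx])
    # anchor at recall 0 with the precision of the strictest cut
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    pr_auc = float(np.trapezoid(precision, recall))
    pr = Curve(points=np.column_stack([recall, precision]), auc=pr_auc)
    return roc, pr


def evaluate_probability_map(prob: np.ndarray, truth: np.ndarray,
                             fov: np.ndarray | None = None,
                             threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Full per-image report: threshold metrics plus ROC/PR AUC."""
    pred = binarize(prob, threshold)
    report = metrics(confusion(pred, truth, fov), threshold)
    truth_b = np.asarray(truth).astype(bool)
    sel = truth_b[np.asarray(fov).astype(bool)] if fov is not None else truth_b
    if 0 < int(sel.sum()) < sel.size:
        roc, pr = roc_pr_curves(prob, truth, fov)
        report.roc_auc = roc.auc
        report.pr_auc = pr.auc
    else:
        report.undefined = report.undefined + ("roc_auc", "pr_auc")
    return report


def aggregate_reports(reports, threshold: float = DEFAULT_THRESHOLD) -> dict:
    """Micro-average (summed counts) headline metrics plus the per-image
    macro mean/std the benchmark tables report."""
    total = ConfusionCounts(0, 0, 0, 0)
    for r in reports:
        total = total + r.counts
    micro = metrics(total, threshold)

    def _ms(vals):
        vals = np.asarray([v for v in vals], dtype=np.float64)
        ok = np.isfinite(vals)
        if not ok.any():
            return {"mean": float("nan"), "std": float("nan")}
        return {"mean": float(vals[ok].mean()), "std": float(vals[ok].std())}

    names = ("accuracy", "sensitivity", "specificity", "precision", "f1",
             "mcc", "roc_auc", "pr_auc")
    macro = {n: _ms([getattr(r, n) for r in reports]) for n in names}
    return {"micro": micro.to_dict(), "macro": macro,
            "per_image": [r.to_dict() for r in reports]}
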