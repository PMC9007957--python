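"""Strict FOV-masked evaluation: pooled AUC, Dice-optimal threshold calibration,
and confusion-matrix metrics at native resolution.

The protocol is deliberately pooled, not per-image: probabilities and labels of
every field-of-view pixel are accumulated across the whole split, the ROC/AUC
analysis and the metric computation run once on that pool, and the binarization
threshold is the one calibrated on the *training* split (never re-tuned on test
or cross-dataset targets).  Pixels outside the FOV mask are excluded from every
metric, since they are trivially non-vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

#: pools larger than this switch from the exact rank AUC to a histogram ROC
AUC_EXACT_MAX_PIXELS = 5_000_000
#: number of bins of the approximate histogram ROC
AUC_HIST_BINS = 1024
#: binarization grid: 8-bit levels {0, 1/255, ..., 1}
THRESHOLD_GRID = np.arange(256) / 255.0


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN over FOV pixels only."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalReport:
    auc: float
    dice: float
    mcc: float
    acc: float
    gmean: float
    kappa: float
    fdr: float
    threshold: float
    counts: ConfusionCounts


def _pool(probs, labels, fovs):
    """Flatten FOV pixels of a list of (prob, label, fov) image triples."""
    ps, ys = [], []
    for p, y, f in zip(probs, labels, fovs):
        p = np.asarray(p, dtype=np.float64).squeeze()
        y = np.asarray(y).squeeze()
        f = np.asarray(f).squeeze().astype(bool)
        if not (p.shape == y.shape == f.shape):
            raise ValueError(
                f"shape mismatch: prob {p.shape}, label {y.shape}, fov {f.shape}")
        ps.append(p[f])
        ys.append(y[f].astype(np.int8))
    if not ps:
        raise ValueError("empty pool")
    return np.concatenate(ps), np.concatenate(ys)


def pooled_auc(probs, labels, fovs, method: str = "auto",
               sample_weight=None) -> float:
    """Area under the ROC curve over all FOV pixels pooled across images.

    ``method``: "exact" (rank/trapezoid, ties counted half), "hist"
    (1024-bin histogram ROC, for very large pools) or "auto".
    """
    p, y = _pool(probs, labels, fovs)
    return _auc_flat(p, y, method=method, sample_weight=sample_weight)


def _auc_flat(p, y, method="auto", sample_weight=None):
    if y.min() == y.max():
        raise ValueError("AUC undefined: pool contains a single class")
    if method == "auto":
        method = "exact" if p.size <= AUC_EXACT_MAX_PIXELS else "hist"
    if method == "exact":
        return float(roc_auc_score(y, p, sample_weight=sample_weight))
    if method != "hist":
        raise ValueError(f"unknown AUC method {method!r}")
    bins = np.clip((p * AUC_HIST_BINS).astype(np.int64), 0, AUC_HIST_BINS - 1)
    w_pos = sample_weight * (y == 1) if sample_weight is not None else (y == 1)
    w_neg = sample_weight * (y == 0) if sample_weight is not None else (y == 0)
    hp = np.bincount(bins, weights=w_pos, minlength=AUC_HIST_BINS)
    hn = np.bincount(bins, weights=w_neg, minlength=AUC_HIST_BINS)
    # rank AUC with ties counted half, computed bin-wise
    npos, nneg = hp.sum(), hn.sum()
    cneg_below = np.concatenate([[0.0], np.cumsum(hn)[:-1]])
    pairs = (hp * (cneg_below + 0.5 * hn)).sum()
    return float(pairs / (npos * nneg))


def calibrate_threshold(probs, labels, fovs) -> float:
    """Training-set Dice-optimal binarization threshold on the 8-bit grid.

    Returns the smallest grid value maximizing pooled Dice of (prob >= t);
    this same threshold is then applied to the test set and to any
    cross-dataset target.
    """
    p, y = _pool(probs, labels, fovs)
    level = np.clip(np.floor(p * 255.0).astype(np.int64), 0, 255)
    pos = np.bincount(level[y == 1], minlength=256)
    neg = np.bincount(level[y == 0], minlength=256)
    # prob >= i/255  <=>  level >= i ; suffix sums give TP and FP per threshold
    tp = np.cumsum(pos[::-1])[::-1].astype(np.float64)
    fp = np.cumsum(neg[::-1])[::-1].astype(np.float64)
    fn = pos.sum() - tp
    denom = 2 * tp + fp + fn
    dice = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 1.0)
    return float(THRESHOLD_GRID[int(np.argmax(dice))])


def confusion_counts(prob, label, fov, threshold: float) -> ConfusionCounts:
    """FOV-restricted confusion counts of (prob >= threshold) vs label."""
    p = np.asarray(prob).squeeze()
    y = np.asarray(label).squeeze().astype(bool)
    f = np.asarray(fov).squeeze().astype(bool)
    pred = p >= threshold
    tp = int(np.count_nonzero(pred & y & f))
    fp = int(np.count_nonzero(pred & ~y & f))
    fn = int(np.count_nonzero(~pred & y & f))
    tn = int(np.count_nonzero(~pred & ~y & f))
    return ConfusionCounts(tp, fp, fn, tn)


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Dice, MCC, ACC, G-mean, Kappa and FDR from confusion counts.

    Zero-denominator conventions (documented, never NaN): Dice = 1 when
    TP = FP = FN = 0; MCC = 0 when any marginal is empty; FDR = 0 when no pixel
    is predicted vessel; a sensitivity/specificity with an empty class is 0
    (G-mean inherits it); Kappa is 1 for perfect agreement with degenerate
    marginals and 0 otherwise.
    """
    tp, fp, fn, tn = (float(c.tp), float(c.fp), float(c.fn), float(c.tn))
    n = tp + fp + fn + tn
    dice = 1.0 if (tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    m1, m2, m3, m4 = tp + fp, tp + fn, tn + fp, tn + fn
    if min(m1, m2, m3, m4) == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(m1 * m2 * m3 * m4)
    acc = (tp + tn) / n if n else 1.0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    gmean = float(np.sqrt(sens * spec))
    if n:
        p_o = (tp + tn) / n
        p_e = (m1 * m2 + m3 * m4) / (n * n)
        kappa = (p_o - p_e) / (1 - p_e) if p_e < 1.0 else (1.0 if p_o == 1.0 else 0.0)
    else:
        kappa = 1.0
    fdr = fp / (fp + tp) if (fp + tp) else 0.0
    return {"dice": float(dice), "mcc": float(mcc), "acc": float(acc),
            "gmean": gmean, "kappa": float(kappa), "fdr": float(fdr)}


def report_from_pool(probs, labels, fovs, threshold: float,
                     auc_method: str = "auto") -> EvalReport:
    """Pooled metrics of a split given pre-computed probability maps."""
    counts = ConfusionCounts(0, 0, 0, 0)
    for p, y, f in zip(probs, labels, fovs):
        counts = counts + confusion_counts(p, y, f, threshold)
    auc = pooled_auc(probs, labels, fovs, method=auc_method)
    m = metrics_from_counts(counts)
    return EvalReport(auc=auc, threshold=float(threshold), counts=counts, **m)


def evaluate_split(model, samples, threshold: float, tta: bool = True,
                   auc_method: str = "auto") -> EvalReport:
    """Predict every sample (TTA, restored to native resolution), binarize at
    the calibrated ``threshold`` and report pooled FOV metrics."""
    from .inference import predict_tta, restore_native

    probs, labels, fovs = [], [], []
    for s in samples:
        prob = predict_tta(model, s.image_float(), tta=tta)
        prob = restore_native(prob, s.native_size)
        probs.append(prob)
        labels.append(s.label)
        fovs.append(s.fov)
    return report_from_pool(probs, labels, fovs, threshold)
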