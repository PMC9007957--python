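"""Stratified pixel bootstrap for comparing two segmentation models.

The test pool (all FOV pixels across the test set) is resampled with
replacement 100 times; each resample preserves the vessel and background
stratum sizes exactly, so every bootstrap replicate has the same class balance
as the original pool.  Per round, AUC and Dice (each model binarized at its own
pre-calibrated threshold, held fixed) are computed for both models; the
difference is oriented better-model-minus-other, with "better" fixed a priori
by full-pool AUC.  The p-value is the fraction of rounds whose difference is
negative or zero; significance is declared at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import _auc_flat, _pool

ALPHA = 0.05
N_ROUNDS = 100


@dataclass(frozen=True)
class BootstrapResult:
    metric: str
    better: str                 # "A" or "B"
    differences: np.ndarray     # length n_rounds, better minus other
    p_value: float
    significant: bool


def stratified_resample(labels: np.ndarray, fov: np.ndarray | None,
                        rng: np.random.Generator) -> np.ndarray:
    """Indices (into the FOV-pooled pixel vector) of one stratified resample.

    Vessel and background pixels are drawn with replacement separately within
    their stratum, preserving both stratum sizes exactly.
    """
    y = np.asarray(labels).ravel()
    if fov is not None:
        y = y[np.asarray(fov).ravel().astype(bool)]
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both vessel and background strata must be non-empty")
    take_pos = pos[rng.integers(0, pos.size, size=pos.size)]
    take_neg = neg[rng.integers(0, neg.size, size=neg.size)]
    return np.concatenate([take_pos, take_neg])


def _dice_weighted(p, y, thr, w):
    pred = p >= thr
    tp = float(np.sum(w * (pred & (y == 1))))
    fp = float(np.sum(w * (pred & (y == 0))))
    fn = float(np.sum(w * (~pred & (y == 1))))
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def compare_models(probs_a, probs_b, labels, fovs, threshold_a: float,
                   threshold_b: float, n_rounds: int = N_ROUNDS,
                   seed: int = 0) -> dict[str, BootstrapResult]:
    """Bootstrap comparison of two probability pools on the same pixels.

    ``probs_a``/``probs_b`` are lists of per-image probability maps aligned to
    the same ``labels``/``fovs``.  Returns one :class:`BootstrapResult` per
    metric ("auc", "dice").
    """
    pa, ya = _pool(probs_a, labels, fovs)
    pb, yb = _pool(probs_b, labels, fovs)
    if pa.shape != pb.shape or not np.array_equal(ya, yb):
        raise ValueError("the two probability pools are not aligned")
    y = ya
    rng = np.random.default_rng(seed)

    better_is_a = _auc_flat(pa, y) >= _auc_flat(pb, y)
    better = "A" if better_is_a else "B"
    p_hi, p_lo = (pa, pb) if better_is_a else (pb, pa)
    thr_hi, thr_lo = ((threshold_a, threshold_b) if better_is_a
                      else (threshold_b, threshold_a))

    diffs = {"auc": np.empty(n_rounds), "dice": np.empty(n_rounds)}
    for r in range(n_rounds):
        idx = stratified_resample(y, None, rng)
        w = np.bincount(idx, minlength=y.size).astype(np.float64)
        diffs["auc"][r] = (_auc_flat(p_hi, y, sample_weight=w)
                           - _auc_flat(p_lo, y, sample_weight=w))
        diffs["dice"][r] = (_dice_weighted(p_hi, y, thr_hi, w)
                            - _dice_weighted(p_lo, y, thr_lo, w))

    out = {}
    for metric, d in diffs.items():
        p_value = float(np.mean(d <= 0.0))
        out[metric] = BootstrapResult(metric=metric, better=better,
                                      differences=d, p_value=p_value,
                                      significant=p_value < ALPHA)
    return out
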