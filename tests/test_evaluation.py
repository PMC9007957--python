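import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lwvessel as lw
from lwvessel.evaluation import ConfusionCounts, _auc_flat, report_from_pool


def brute_force_auc(p, y):
    """Pair-counting oracle: fraction of positive-negative pairs ranked
    correctly, ties counted half."""
    pos, neg = p[y == 1], p[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_threshold(p, y):
    """Exhaustive Dice-optimal threshold over all unique probability values."""
    best_t, best_d = None, -1.0
    for t in np.unique(np.concatenate([[0.0], p])):
        pred = p >= t
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        fn = np.sum(~pred & (y == 1))
        d = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
        if d > best_d:
            best_t, best_d = t, d
    return best_t, best_d


def _pool_dice(p, y, t):
    pred = p >= t
    tp = np.sum(pred & (y == 1))
    fp = np.sum(pred & (y == 0))
    fn = np.sum(~pred & (y == 1))
    return 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)


class TestPooledAUC:
    def test_four_pixel_example(self):
        p = np.array([[0.9, 0.8, 0.7, 0.1]])
        y = np.array([[1, 0, 1, 0]])
        f = np.ones_like(y)
        assert lw.pooled_auc([p], [y], [f]) == pytest.approx(0.75)

    def test_perfect_and_constant(self):
        y = np.array([[1, 0, 1, 0, 0]])
        f = np.ones_like(y)
        assert lw.pooled_auc([y.astype(float)], [y], [f]) == 1.0
        assert lw.pooled_auc([np.full_like(y, 0.3, dtype=float)], [y], [f]) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.random(2000), 2)  # rounding forces ties
        y = (rng.random(2000) < 0.2).astype(int)
        got = _auc_flat(p, y, method="exact")
        assert got == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_histogram_method_close_to_exact(self):
        rng = np.random.default_rng(3)
        y = (rng.random(50_000) < 0.1).astype(int)
        p = np.clip(rng.normal(0.3 + 0.4 * y, 0.2), 0, 1)
        exact = _auc_flat(p, y, method="exact")
        hist = _auc_flat(p, y, method="hist")
        assert hist == pytest.approx(exact, abs=2e-3)

    def test_single_class_pool_raises(self):
        y = np.ones((1, 4), int)
        with pytest.raises(ValueError, match="single class"):
            lw.pooled_auc([y.astype(float)], [y], [np.ones_like(y)])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        p = rng.random((1, 300))
        y = (rng.random((1, 300)) < 0.3).astype(int)
        f = np.ones_like(y)
        a1 = lw.pooled_auc([p], [y], [f])
        a2 = lw.pooled_auc([np.tanh(3 * p) ** 3], [y], [f])
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_pooled_not_per_image_mean(self):
        # one easy and one hard image: pooling is not averaging
        p1, y1 = np.array([[0.9, 0.9, 0.1]]), np.array([[1, 1, 0]])
        p2, y2 = np.array([[0.2, 0.8, 0.8]]), np.array([[1, 0, 0]])
        f = np.ones_like(y1)
        pooled = lw.pooled_auc([p1, p2], [y1, y2], [f, f])
        mean = 0.5 * (brute_force_auc(p1[0], y1[0]) + brute_force_auc(p2[0], y2[0]))
        assert pooled != pytest.approx(mean)


class TestThresholdCalibration:
    def test_separated_pool_returns_smallest_maximizing_level(self):
        p = np.array([[0.85, 0.9, 0.15, 0.2, 0.1]])
        y = np.array([[1, 1, 0, 0, 0]])
        t = lw.calibrate_threshold([p], [y], [np.ones_like(y)])
        # any grid value in (0.2, 0.85] gives Dice 1; the smallest grid level
        # strictly above the best-scored negative (0.2 = 51/255) is 52/255
        assert t == pytest.approx(52 / 255)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(800) < 0.25).astype(int)
        p = np.round(np.clip(rng.normal(0.25 + 0.35 * y, 0.25), 0, 1), 3)
        t_grid = lw.calibrate_threshold([p[None]], [y[None]], [np.ones(800, int)[None]])
        _, d_exh = brute_force_threshold(p, y)
        d_grid = _pool_dice(p, y, t_grid)
        # the 8-bit grid may lose at most one grid step of Dice
        neighbours = [d_grid]
        i = int(round(t_grid * 255))
        for j in (i - 1, i + 1):
            if 0 <= j <= 255:
                neighbours.append(_pool_dice(p, y, j / 255))
        assert max(neighbours) >= d_exh - 1e-9 or d_exh - d_grid < 0.01

    def test_constant_pool_predicts_everything_vessel(self):
        p = np.full((1, 10), 0.4)
        y = np.array([[1, 1, 0, 0, 0, 0, 0, 0, 0, 1]])
        t = lw.calibrate_threshold([p], [y], [np.ones_like(y)])
        assert t <= 0.4

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            lw.calibrate_threshold([], [], [])


class TestMetrics:
    def test_fixed_confusion_table(self):
        m = lw.metrics_from_counts(ConfusionCounts(tp=4, fp=1, fn=1, tn=94))
        assert m["dice"] == pytest.approx(0.8000)
        assert m["mcc"] == pytest.approx(375 / 475)
        assert m["acc"] == pytest.approx(0.98)
        assert m["fdr"] == pytest.approx(0.2)

    def test_perfect_prediction(self):
        m = lw.metrics_from_counts(ConfusionCounts(tp=10, fp=0, fn=0, tn=90))
        assert m["dice"] == m["acc"] == 1.0
        assert m["mcc"] == pytest.approx(1.0)
        assert m["gmean"] == pytest.approx(1.0)
        assert m["kappa"] == pytest.approx(1.0)
        assert m["fdr"] == 0.0

    def test_zero_denominator_conventions(self):
        assert lw.metrics_from_counts(ConfusionCounts(0, 0, 0, 50))["dice"] == 1.0
        assert lw.metrics_from_counts(ConfusionCounts(0, 0, 0, 50))["mcc"] == 0.0
        assert lw.metrics_from_counts(ConfusionCounts(0, 0, 5, 45))["fdr"] == 0.0

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500), tn=st.integers(0, 500))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_ranges_and_finiteness(self, tp, fp, fn, tn):
        m = lw.metrics_from_counts(ConfusionCounts(tp, fp, fn, tn))
        assert 0 <= m["dice"] <= 1 and 0 <= m["acc"] <= 1
        assert 0 <= m["gmean"] <= 1 and 0 <= m["fdr"] <= 1
        assert -1 <= m["mcc"] <= 1 and -1 <= m["kappa"] <= 1
        assert all(np.isfinite(v) for v in m.values())

    def test_pooled_dice_differs_from_per_image_mean(self):
        easy = ConfusionCounts(90, 10, 10, 890)
        hard = ConfusionCounts(10, 50, 90, 850)
        pooled = lw.metrics_from_counts(easy + hard)["dice"]
        mean = 0.5 * (lw.metrics_from_counts(easy)["dice"]
                      + lw.metrics_from_counts(hard)["dice"])
        assert pooled != pytest.approx(mean)


class TestFovMasking:
    def test_outside_fov_perturbation_changes_nothing(self):
        rng = np.random.default_rng(5)
        p = rng.random((2, 20, 20))
        y = (rng.random((2, 20, 20)) < 0.3).astype(int)
        f = np.zeros((2, 20, 20), int)
        f[:, 4:16, 4:16] = 1
        base = report_from_pool(list(p), list(y), list(f), threshold=0.5)
        p2, y2 = p.copy(), y.copy()
        outside = f == 0
        p2[outside] = rng.random(outside.sum())
        y2[outside] = 1 - y2[outside]
        pert = report_from_pool(list(p2), list(y2), list(f), threshold=0.5)
        for attr in ("auc", "dice", "mcc", "acc", "gmean", "kappa", "fdr"):
            assert getattr(base, attr) == getattr(pert, attr)

    def test_counts_sum_to_fov_size(self):
        rng = np.random.default_rng(6)
        p = rng.random((10, 10))
        y = (rng.random((10, 10)) < 0.5).astype(int)
        f = (rng.random((10, 10)) < 0.7).astype(int)
        c = lw.confusion_counts(p, y, f, 0.5)
        assert c.total == f.sum()


class TestReportFromPool:
    def test_perfect_single_image(self):
        y = np.array([[1, 1, 0, 0]])
        f = np.ones_like(y)
        rep = report_from_pool([y.astype(float)], [y], [f], threshold=0.5)
        assert rep.dice == rep.acc == rep.auc == 1.0 and rep.fdr == 0.0

    def test_duplicating_images_leaves_pooled_metrics_unchanged(self):
        rng = np.random.default_rng(7)
        p = rng.random((15, 15))
        y = (rng.random((15, 15)) < 0.3).astype(int)
        f = np.ones_like(y)
        single = report_from_pool([p], [y], [f], threshold=0.4)
        doubled = report_from_pool([p, p], [y, y], [f, f], threshold=0.4)
        for attr in ("auc", "dice", "mcc", "acc", "gmean", "kappa", "fdr"):
            assert getattr(single, attr) == pytest.approx(getattr(doubled, attr))
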