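"""Metric correctness against brute-force oracles and hand-computed cases."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ventriseg.detection import Detection
from ventriseg.evaluation import (average_precision, box_iou, detection_scores,
                                  dice, hausdorff95, jaccard,
                                  match_detections, score_masks,
                                  surface_voxels)
from tests.conftest import random_blob


# ---------------------------------------------------------------------------
# independent oracles

def brute_dice(a, b):
    inter = np.logical_and(a, b).sum()
    return 1.0 if a.sum() + b.sum() == 0 else 2.0 * inter / (a.sum() + b.sum())


def brute_jaccard(a, b):
    union = np.logical_or(a, b).sum()
    return 1.0 if union == 0 else np.logical_and(a, b).sum() / union


def brute_hd95(a, b, spacing=1.0):
    """All-pairs O(n^2) surface distances, pooled percentile."""
    pa = surface_voxels(a) * spacing
    pb = surface_voxels(b) * spacing
    d = cdist(pa, pb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


def brute_ap(tp_flags, n_gt, n_steps=100000):
    """Riemann integration of the precision envelope over a fine recall grid."""
    flags = np.asarray(tp_flags, dtype=float)
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(1 - flags)
    rec = tp / n_gt
    prec = tp / (tp + fp)
    grid = np.linspace(0, rec[-1], n_steps, endpoint=False) + rec[-1] / n_steps / 2
    vals = np.zeros_like(grid)
    for i, r in enumerate(grid):
        ok = rec >= r
        vals[i] = prec[ok].max() if ok.any() else 0.0
    return float(vals.mean() * rec[-1])


def _det(cid, cx, cy, w, h, conf=1.0, z=0):
    return Detection(class_id=cid, z_index=z, cx=cx, cy=cy, w=w, h=h,
                     confidence=conf)


# ---------------------------------------------------------------------------
# mask metrics

class TestMaskMetrics:
    def test_hand_computed_pair(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a.flat[:4] = True          # |A| = 4
        b.flat[:8] = True          # |B| = 8, overlap 4
        assert dice(a, b) == pytest.approx(2 * 4 / 12)
        assert jaccard(a, b) == pytest.approx(4 / 8)

    def test_identical_and_disjoint(self):
        a = np.zeros((5, 5), bool)
        a[1:3, 1:3] = True
        b = np.zeros((5, 5), bool)
        b[3:5, 3:5] = True
        assert dice(a, a) == 1.0 and jaccard(a, a) == 1.0
        assert dice(a, b) == 0.0 and jaccard(a, b) == 0.0

    def test_both_empty_convention(self):
        empty = np.zeros((3, 3), bool)
        assert dice(empty, empty) == 1.0
        assert jaccard(empty, empty) == 1.0
        assert hausdorff95(empty, empty) is None

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_jaccard_dice_identity_500_pairs(self, rng):
        for _ in range(500):
            a = rng.random((8, 8, 8)) > 0.6
            b = rng.random((8, 8, 8)) > 0.6
            d, j = dice(a, b), jaccard(a, b)
            assert abs(j - d / (2 - d)) < 1e-12

    def test_metrics_match_brute_force_on_50_blob_pairs(self, rng):
        for _ in range(50):
            a = random_blob(rng, shape=(10, 10, 10), n_seeds=2, radius=4)
            b = random_blob(rng, shape=(10, 10, 10), n_seeds=2, radius=4)
            if not (a.any() and b.any()):
                continue
            assert abs(dice(a, b) - brute_dice(a, b)) < 1e-9
            assert abs(jaccard(a, b) - brute_jaccard(a, b)) < 1e-9
            assert abs(hausdorff95(a, b) - brute_hd95(a, b)) < 1e-9

    def test_hd95_two_voxels_3mm_apart(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[2, 2, 2] = True
        b[2, 2, 5] = True
        assert hausdorff95(a, b, spacing=1.0) == pytest.approx(3.0)
        # anisotropic spacing scales the same gap
        assert hausdorff95(a, b, spacing=(1.0, 1.0, 2.0)) == pytest.approx(6.0)

    def test_hd95_symmetry_and_self_zero(self, rng):
        a = random_blob(rng)
        b = random_blob(rng)
        assert hausdorff95(a, b) == pytest.approx(hausdorff95(b, a))
        assert hausdorff95(a, a) == 0.0

    def test_empty_mask_gives_missing_hd95(self):
        a = np.zeros((5, 5), bool)
        b = np.ones((5, 5), bool)
        s = score_masks(a, b)
        assert s.hd95 is None and s.dice == 0.0


# ---------------------------------------------------------------------------
# detection metrics

class TestDetectionMetrics:
    def test_single_match_above_threshold(self):
        gt = [_det(0, 0.5, 0.5, 0.2, 0.2)]
        pred = [_det(0, 0.52, 0.5, 0.2, 0.2, conf=0.9)]
        assert box_iou((0.5, 0.5, 0.2, 0.2), (0.52, 0.5, 0.2, 0.2)) > 0.5
        matches, n_gt = match_detections(gt, pred, 0.5)
        assert n_gt == 1 and matches[0][1] is True

    def test_greedy_duplicate_assignment(self):
        gt = [_det(0, 0.5, 0.5, 0.2, 0.2)]
        pred = [_det(0, 0.5, 0.5, 0.2, 0.2, conf=0.7),
                _det(0, 0.51, 0.5, 0.2, 0.2, conf=0.9)]
        matches, _ = match_detections(gt, pred, 0.5)
        # higher-confidence prediction is visited first and takes the GT
        by_conf = {m[0].confidence: m[1] for m in matches}
        assert by_conf[0.9] is True and by_conf[0.7] is False

    def test_matching_equals_exhaustive_oracle_small_sets(self, rng):
        """Greedy confidence-ordered matching on <= 5 boxes reproduces the
        TP count of explicit enumeration of the greedy order."""
        for _ in range(50):
            n_gt, n_pred = rng.integers(1, 4), rng.integers(0, 6)
            gt = [_det(0, *rng.uniform(0.3, 0.7, 2), 0.2, 0.2) for _ in range(n_gt)]
            pred = [_det(0, *rng.uniform(0.3, 0.7, 2), 0.2, 0.2,
                         conf=float(rng.uniform(0.1, 1.0))) for _ in range(n_pred)]
            matches, _ = match_detections(gt, pred, 0.5)
            # oracle: explicit greedy over confidence-sorted predictions
            order = sorted(pred, key=lambda d: -d.confidence)
            used = set()
            expected_tp = 0
            for p in order:
                cands = [(box_iou((p.cx, p.cy, p.w, p.h),
                                  (g.cx, g.cy, g.w, g.h)), i)
                         for i, g in enumerate(gt) if i not in used]
                cands = [(v, i) for v, i in cands if v >= 0.5]
                if cands:
                    used.add(max(cands)[1])
                    expected_tp += 1
            assert sum(tp for _, tp in matches) == expected_tp

    def test_ap_hand_enumerated_three_box_case(self):
        # confidences 0.9 TP, 0.8 FP, 0.7 TP with n_gt = 2:
        # PR points (0.5, 1.0), (0.5, 0.5), (1.0, 2/3) -> envelope area
        flags = [True, False, True]
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        assert average_precision(flags, 2) == pytest.approx(expected)
        assert average_precision(flags, 2) == pytest.approx(
            brute_ap(flags, 2), abs=1e-4)

    def test_ap_matches_brute_force_random_flag_sequences(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 6))
            flags = list(rng.random(n) > 0.4)
            n_gt = max(1, int(sum(flags) + rng.integers(0, 3)))
            assert average_precision(flags, n_gt) == pytest.approx(
                brute_ap(flags, n_gt), abs=1e-4)

    def test_ap_degenerate_cases(self):
        assert average_precision([], 3) == 0.0
        assert average_precision([True], 1) == 1.0
        with pytest.raises(ValueError):
            average_precision([True], 0)

    def test_perfect_predictions_score_one_everywhere(self):
        gt = [_det(c, 0.3 + 0.1 * c, 0.5, 0.1, 0.1) for c in range(3)]
        pred = [_det(c, 0.3 + 0.1 * c, 0.5, 0.1, 0.1, conf=0.99)
                for c in range(3)]
        s = detection_scores(gt, pred)
        assert s.precision == s.recall == s.ap50 == s.ap50_95 == 1.0

    def test_no_predictions_scores_zero(self):
        gt = [_det(0, 0.5, 0.5, 0.2, 0.2)]
        s = detection_scores(gt, [])
        assert s.ap50 == 0.0 and s.recall == 0.0

    def test_classes_without_gt_excluded_from_aggregate(self):
        gt = [_det(0, 0.5, 0.5, 0.2, 0.2)]
        pred = [_det(0, 0.5, 0.5, 0.2, 0.2, conf=0.9),
                _det(5, 0.5, 0.5, 0.2, 0.2, conf=0.9)]  # spurious class
        s = detection_scores(gt, pred)
        assert 5 not in s.per_class
        assert s.ap50 == 1.0  # the mean is over class 0 only


# ---------------------------------------------------------------------------
# property-based invariants

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.2, 0.8))
def test_jaccard_dice_identity_and_symmetry_property(seed, density):
    """J = D/(2-D) and argument symmetry hold for arbitrary mask pairs."""
    r = np.random.default_rng(seed)
    a = r.random((6, 6, 6)) > density
    b = r.random((6, 6, 6)) > density
    d, j = dice(a, b), jaccard(a, b)
    assert abs(j - d / (2 - d)) < 1e-12
    assert dice(b, a) == d and jaccard(b, a) == j
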