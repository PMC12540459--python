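"""Overlap metrics, HD95, cluster statistics, post-processing, detection."""

from collections import deque

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lemunet.metrics import (
    cluster_stats,
    connected_components26,
    detection_rates,
    hd95,
    largest_component_postprocess,
    overlap_metrics,
    slice_dice_scores,
)


def hd95_bruteforce(G, P, spacing):
    """All-pairs distance matrix + linear-interpolation percentile."""
    a = np.argwhere(G) * np.asarray(spacing)
    b = np.argwhere(P) * np.asarray(spacing)
    d = cdist(a, b)
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


def flood_fill_components(mask):
    """BFS flood fill with 26-neighbourhood."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and not labels[n]:
                    labels[n] = nxt
                    q.append(n)
    return labels, nxt


class TestOverlapMetrics:
    def test_identical_nonempty_masks(self, rng):
        g = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        m = overlap_metrics(g, g)
        assert (m.dc, m.precision, m.recall, m.iou) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_nonempty_masks(self):
        g = np.zeros((4, 4, 4), np.uint8)
        p = np.zeros((4, 4, 4), np.uint8)
        g[0, 0, 0] = 1
        p[3, 3, 3] = 1
        m = overlap_metrics(g, p)
        assert (m.dc, m.precision, m.recall, m.iou) == (0.0, 0.0, 0.0, 0.0)

    def test_counted_example(self):
        # |G| = 4, |P| = 2, |overlap| = 2
        g = np.zeros((4, 4, 4), np.uint8)
        p = np.zeros((4, 4, 4), np.uint8)
        g[0, 0, :4] = 1
        p[0, 0, :2] = 1
        m = overlap_metrics(g, p)
        assert m.dc == pytest.approx(2 * 2 / 6)
        assert m.precision == 1.0
        assert m.recall == 0.5
        assert m.iou == 0.5

    def test_empty_mask_conventions(self):
        empty = np.zeros((3, 3, 3), np.uint8)
        one = empty.copy()
        one[1, 1, 1] = 1
        both = overlap_metrics(empty, empty)
        assert both.dc == 1.0 and both.iou == 1.0
        assert both.precision == 0.0 and both.recall == 0.0
        assert overlap_metrics(one, empty).dc == 0.0
        assert overlap_metrics(empty, one).precision == 0.0

    def test_dc_iou_identity_on_random_masks(self, rng):
        for _ in range(50):
            g = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
            p = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
            m = overlap_metrics(g, p)
            assert m.dc == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-12)

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(np.full((2, 2, 2), 2), np.zeros((2, 2, 2)))


class TestHD95:
    def test_identical_masks_zero(self, rng):
        g = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        assert hd95(g, g) == 0.0

    def test_single_voxel_pair_distance(self):
        g = np.zeros((8, 8, 8), np.uint8)
        p = np.zeros((8, 8, 8), np.uint8)
        g[1, 1, 1] = 1
        p[1, 1, 4] = 1
        assert hd95(g, p, (1.0, 1.0, 1.0)) == pytest.approx(3.0)
        assert hd95(g, p, (1.0, 1.0, 2.0)) == pytest.approx(6.0)

    def test_empty_mask_undefined(self):
        g = np.zeros((4, 4, 4), np.uint8)
        p = g.copy()
        p[0, 0, 0] = 1
        assert hd95(g, p) is None
        assert hd95(p, g) is None

    def test_matches_bruteforce_on_random_masks(self, rng):
        spacing = (1.0, 0.7, 1.3)
        for _ in range(25):
            g = (rng.random((12, 12, 12)) < 0.08).astype(np.uint8)
            p = (rng.random((12, 12, 12)) < 0.08).astype(np.uint8)
            if not (g.any() and p.any()):
                continue
            assert hd95(g, p, spacing) == pytest.approx(hd95_bruteforce(g, p, spacing))

    def test_monotone_under_nested_growth_toward_gt(self, rng):
        g = np.zeros((10, 10, 10), np.uint8)
        g[2:8, 2:8, 2:8] = 1
        prev = np.inf
        for r in (1, 2, 3):
            p = np.zeros_like(g)
            p[5 - r : 5 + r, 5 - r : 5 + r, 5 - r : 5 + r] = 1
            d = hd95(g, p)
            assert d <= prev
            prev = d


class TestConnectedComponents:
    def test_corner_touching_voxels_are_one_component(self):
        m = np.zeros((4, 4, 4), np.uint8)
        m[0, 0, 0] = m[1, 1, 1] = 1
        _, n = connected_components26(m)
        assert n == 1

    def test_gap_separates_components(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[0, 0, 0] = m[0, 0, 2] = 1
        _, n = connected_components26(m)
        assert n == 2

    def test_matches_flood_fill_oracle_up_to_relabeling(self, rng):
        for _ in range(20):
            m = (rng.random((10, 10, 10)) < 0.08).astype(np.uint8)
            got_lab, got_n = connected_components26(m)
            exp_lab, exp_n = flood_fill_components(m)
            assert got_n == exp_n
            # same partition: label pairs must be in bijection
            pairs = set(zip(got_lab[m > 0].ravel(), exp_lab[m > 0].ravel()))
            assert len(pairs) == got_n


class TestClusterStats:
    def _two_blob_gt(self):
        g = np.zeros((10, 10, 10), np.uint8)
        g[1:3, 1:3, 1:3] = 1
        g[7:9, 7:9, 7:9] = 1
        return g

    def test_perfect_prediction(self):
        g = self._two_blob_gt()
        s = cluster_stats(g, g)
        assert (s.tp_lesions, s.fp_lesions, s.fn_lesions, s.gt_lesions) == (2, 0, 0, 2)

    def test_empty_prediction(self):
        g = self._two_blob_gt()
        s = cluster_stats(g, np.zeros_like(g))
        assert (s.tp_lesions, s.fp_lesions, s.fn_lesions, s.gt_lesions) == (0, 0, 2, 2)
        assert s.tp_lesions + s.fn_lesions == s.gt_lesions

    def test_partial_overlap_plus_isolated_blob(self):
        g = self._two_blob_gt()
        p = np.zeros_like(g)
        p[1:3, 1:3, 1:3] = 1       # hits GT blob 1
        p[4:6, 4:6, 4:6] = 1       # isolated false positive
        s = cluster_stats(g, p)
        assert (s.tp_lesions, s.fp_lesions, s.fn_lesions, s.gt_lesions) == (1, 1, 1, 2)


class TestPostprocess:
    def test_single_component_unchanged(self, rng):
        p = np.zeros((8, 8, 8), np.uint8)
        p[2:5, 2:5, 2:5] = 1
        g = (rng.random((8, 8, 8)) < 0.2).astype(np.uint8)
        np.testing.assert_array_equal(largest_component_postprocess(p, g), p)

    def test_removes_harmful_blob(self):
        g = np.zeros((12, 12, 12), np.uint8)
        g[2:6, 2:6, 2:6] = 1
        p = g.copy()
        p[9:11, 9:11, 9:11] = 1  # small disjoint FP blob
        out = largest_component_postprocess(p, g)
        # removal strictly increases DC, so the blob must be gone
        assert overlap_metrics(g, out).dc > overlap_metrics(g, p).dc
        assert out[9:11, 9:11, 9:11].sum() == 0

    def test_preserves_prediction_when_largest_component_is_fp(self):
        g = np.zeros((12, 12, 12), np.uint8)
        g[1:3, 1:3, 1:3] = 1                  # small lesion
        p = np.zeros_like(g)
        p[1:3, 1:3, 1:3] = 1                  # correct hit (8 voxels)
        p[6:11, 6:11, 6:11] = 1               # big FP blob (125 voxels) = largest
        out = largest_component_postprocess(p, g)
        np.testing.assert_array_equal(out, p)  # keeping only the blob would hurt

    def test_never_decreases_dice_on_random_cohort(self, rng):
        for _ in range(50):
            g = (rng.random((10, 10, 10)) < 0.1).astype(np.uint8)
            p = (rng.random((10, 10, 10)) < 0.1).astype(np.uint8)
            out = largest_component_postprocess(p, g)
            assert overlap_metrics(g, out).dc >= overlap_metrics(g, p).dc

    def test_empty_prediction_returned_unchanged(self):
        p = np.zeros((4, 4, 4), np.uint8)
        g = np.ones((4, 4, 4), np.uint8)
        np.testing.assert_array_equal(largest_component_postprocess(p, g), p)


class TestDetectionRates:
    def test_all_detected_above_both_thresholds(self):
        r = detection_rates([0.5, 0.9, 0.23])
        assert r.individual[0.0] == 100.0
        assert r.individual[0.22] == 100.0

    def test_strict_inequality_at_zero(self):
        r = detection_rates([0.5, 0.0])
        assert r.individual[0.0] == 50.0

    def test_scripted_cohort_matches_hand_count(self):
        dcs = [0.0, 0.05, 0.10, 0.22, 0.25, 0.30, 0.50, 0.80, 0.15, 0.21]
        r = detection_rates(dcs)
        # hand count: 9 of 10 exceed 0.0; 4 of 10 exceed 0.22 (0.22 itself excluded)
        assert r.individual[0.0] == 90.0
        assert r.individual[0.22] == 40.0
        assert r.individual[0.22] <= r.individual[0.0]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            detection_rates([])

    def test_slice_rates_from_scripted_masks(self):
        g = np.zeros((4, 4, 4), np.uint8)
        g[0, 0, 0] = 1  # GT in slice 0 of every axis
        p = np.zeros_like(g)
        p[0, 0, 0] = 1
        scores = slice_dice_scores(g, p)
        assert all(scores[ax] == [1.0] for ax in range(3))
        r = detection_rates([1.0], [scores])
        assert r.slice_rates[0.0] == 100.0

    def test_slice_denominator_counts_only_gt_bearing_slices(self):
        g = np.zeros((4, 4, 4), np.uint8)
        g[0] = 1
        g[2] = 1
        p = np.zeros_like(g)
        p[0] = 1  # detects one of the two GT-bearing axial slices
        scores = slice_dice_scores(g, p)
        assert len(scores[0]) == 2
        r = detection_rates([0.5], [scores])
        # axis 0: 1/2 detected; axes 1 and 2: each GT-bearing slice half covered -> 4/4
        assert r.slice_rates[0.0] == pytest.approx((50.0 + 100.0 + 100.0) / 3)
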