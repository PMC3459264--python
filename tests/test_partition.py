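"""Discriminant thresholding and offset-optimized quadtree partitioning."""

import itertools

import numpy as np
import pytest

from fracvq import (
    classify,
    discriminant_thresholds,
    division_image,
    quadtree_divide,
    select_initial_position,
    ssim_global,
)
from fracvq.exceptions import ConfigurationError, DegenerateInputError
from fracvq.partition import partition_bits, partition_from_bits


def brute_force_thresholds(values, n_classes, bins=64):
    """Naive exhaustive maximization of between-class variance on the
    binned distribution (direct sums, no cumulative shortcuts)."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    mu = float((p * centers).sum())
    best, best_combo = -1.0, None
    for combo in itertools.combinations(range(bins - 1), n_classes - 1):
        bounds = (-1,) + combo + (bins - 1,)
        score, ok = 0.0, True
        for c in range(n_classes):
            sel = slice(bounds[c] + 1, bounds[c + 1] + 1)
            w = float(p[sel].sum())
            if w <= 0:
                ok = False
                break
            m = float((p[sel] * centers[sel]).sum()) / w
            score += w * (m - mu) ** 2
        if ok and score > best:
            best, best_combo = score, combo
    return np.array([edges[i + 1] for i in best_combo])


class TestDiscriminantThresholds:
    def test_symmetric_bimodal(self):
        values = np.array([2.1] * 50 + [2.9] * 50)
        (t,) = discriminant_thresholds(values, n_classes=2)
        assert 2.1 < t < 2.9
        labels = classify(values, [t]).labels
        assert (labels == 0).sum() == 50 and (labels == 1).sum() == 50

    def test_three_separable_spikes(self):
        values = np.array([2.1] * 30 + [2.5] * 30 + [2.9] * 30)
        t1, t2 = discriminant_thresholds(values, n_classes=3)
        assert 2.1 < t1 < 2.5 < t2 < 2.9

    def test_matches_brute_force_oracle(self, rng):
        values = rng.uniform(2.0, 3.0, size=200)
        mine = discriminant_thresholds(values, n_classes=3)
        oracle = brute_force_thresholds(values, n_classes=3)
        assert np.allclose(mine, oracle)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            discriminant_thresholds(np.full(10, 2.5), n_classes=3)


class TestClassify:
    def test_all_below_first_threshold(self):
        cm = classify(np.full((4, 4), 2.0), [2.5, 2.8])
        assert np.all(cm.labels == 0)

    def test_threshold_value_goes_to_lower_class(self):
        cm = classify(np.array([2.5, 2.50000001, 2.8, 2.9]), [2.5, 2.8])
        assert cm.labels.tolist() == [0, 1, 1, 2]

    def test_label_histogram_matches_pointwise_oracle(self, rng):
        values = rng.uniform(2, 3, size=(20, 20))
        thresholds = [2.3, 2.7]
        labels = classify(values, thresholds).labels
        oracle = np.empty_like(labels)
        for i in range(20):
            for j in range(20):
                v = values[i, j]
                oracle[i, j] = 0 if v <= 2.3 else (1 if v <= 2.7 else 2)
        assert np.array_equal(labels, oracle)


class TestQuadtree:
    def test_homogeneous_smooth_map(self):
        p = quadtree_divide(np.zeros((16, 16), dtype=int), (0, 0), l0=8)
        assert sorted(p.blocks) == [(0, 0, 8), (0, 8, 8), (8, 0, 8), (8, 8, 8)]

    def test_single_complex_pixel_splits_one_quadrant(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[0, 0] = 2
        p = quadtree_divide(labels, (0, 0), l0=8)
        sizes = sorted(s for _, _, s in p.blocks)
        assert sizes == [2, 2, 2, 2, 4, 4, 4]
        div = division_image(p)
        oracle = np.ones((8, 8), dtype=int)
        oracle[:4, :4] = 2
        assert np.array_equal(div, oracle)

    def test_all_label_one_gives_quarter_blocks(self):
        p = quadtree_divide(np.ones((16, 16), dtype=int), (0, 0), l0=8)
        assert all(s == 4 for _, _, s in p.blocks)
        assert len(p.blocks) == 16

    def test_tiling_exactness_and_nesting(self, rng):
        for _ in range(10):
            labels = rng.integers(0, 3, size=(rng.integers(9, 40), rng.integers(9, 40)))
            offset = (int(rng.integers(0, 8)), int(rng.integers(0, 8)))
            p = quadtree_divide(labels, offset, l0=8)
            rows, cols = p.extended_size
            assert sum(s * s for _, _, s in p.blocks) == rows * cols
            covered = np.zeros(p.extended_size, dtype=int)
            for r, c, s in p.blocks:
                covered[r : r + s, c : c + s] += 1
                assert r // 8 == (r + s - 1) // 8 and c // 8 == (c + s - 1) // 8
            assert np.all(covered == 1)

    def test_division_image_idempotent(self, rng):
        # unpadded configuration: the division image is an exact fixed point
        # (with replication padding the pad region is re-derived from the
        # cropped map, so only the interior is stable)
        labels = rng.integers(0, 3, size=(24, 24))
        p = quadtree_divide(labels, (0, 0), l0=8)
        p2 = quadtree_divide(division_image(p), (0, 0), l0=8)
        assert p2.blocks == p.blocks

    def test_offset_out_of_range(self):
        with pytest.raises(ConfigurationError):
            quadtree_divide(np.zeros((16, 16), dtype=int), (8, 0), l0=8)

    def test_bitstring_round_trip(self, rng):
        labels = rng.integers(0, 3, size=(30, 21))
        p = quadtree_divide(labels, (2, 0), l0=8)
        payload, nbits = partition_bits(p)
        p2 = partition_from_bits(payload, nbits, p.offset, p.source_shape, p.l0)
        assert p2.blocks == p.blocks and p2.extended_size == p.extended_size


def brute_force_best_offset(labels, l0=8):
    """Independent enumeration of all 2*l0-1 shifts via the block-list route."""
    candidates = [(r, 0) for r in range(l0)] + [(0, c) for c in range(1, l0)]
    best, best_off = -np.inf, None
    for off in candidates:
        p = quadtree_divide(labels, off, l0)
        n2 = sum(1 for _, _, s in p.blocks if s == l0 // 4)
        div = division_image(p)
        score = n2 + 1e5 * ssim_global(
            np.rint(labels * 127.5), np.rint(div * 127.5), peak=255
        )
        if score > best:
            best, best_off = score, off
    return best_off


class TestSelectInitialPosition:
    def test_constant_map_ties_to_origin(self):
        offset, p, sums = select_initial_position(np.zeros((32, 32), dtype=int), l0=8)
        assert offset == (0, 0)
        assert len(sums) == 15
        assert np.allclose(sums, sums[0])
        assert all(s == 8 for _, _, s in p.blocks)

    def test_stripe_matches_brute_force(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[5:7, :] = 2
        offset, _, _ = select_initial_position(labels, l0=8)
        assert offset == brute_force_best_offset(labels)

    def test_agrees_with_exhaustive_search_on_random_maps(self, rng):
        for _ in range(15):
            labels = rng.integers(0, 3, size=(32, 32))
            offset, _, _ = select_initial_position(labels, l0=8)
            assert offset == brute_force_best_offset(labels)

    def test_extra_complex_pixel_never_decreases_smallest_count(self, rng):
        labels = rng.integers(0, 2, size=(32, 32))
        p1 = quadtree_divide(labels, (4, 0), l0=8)
        labels2 = labels.copy()
        labels2[13, 21] = 2
        p2 = quadtree_divide(labels2, (4, 0), l0=8)
        count = lambda p: sum(1 for _, _, s in p.blocks if s == 2)
        assert count(p2) >= count(p1)
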