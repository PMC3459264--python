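"""Energy-initialized K-means codebooks and block encode/decode."""

import numpy as np
import pytest

from fracvq import (
    BlockSet,
    block_energy,
    energy_init,
    extract_blocks,
    kmeans_train,
    quadtree_divide,
    random_init,
    vq_decode,
    vq_encode,
)
from fracvq.exceptions import ContainerError, InfeasibleCodebookError


def bs(vectors, size=2):
    return BlockSet(vectors=np.asarray(vectors, dtype=float), block_size=size)


class TestBlockEnergy:
    def test_examples(self):
        assert block_energy([1, 2, 2, 0]) == 9
        assert block_energy(np.zeros(16)) == 0

    def test_matches_naive_loop(self, rng):
        v = rng.normal(size=16)
        assert block_energy(v) == pytest.approx(sum(x * x for x in v), rel=1e-12)


class TestEnergyInit:
    def test_equal_interval_positions(self):
        blocks = bs([[1, 0, 0, 0], [0, 0, 2, 0], [3, 0, 0, 0], [0, 2, 0, 0]])
        # energies 1, 4, 9, 4 -> sorted order [1, 4, 4, 9]; k=2 picks pos 1, 3
        init = energy_init(blocks, 2)
        assert block_energy(init[0]) == 4  # stable sort keeps earlier index first
        assert block_energy(init[1]) == 9

    def test_four_distinct_energies(self):
        vecs = [[1, 0, 0, 0], [0, np.sqrt(2), 0, 0], [0, 0, np.sqrt(3), 0], [2, 0, 0, 0]]
        init = energy_init(bs(vecs), 2)
        assert [round(block_energy(v)) for v in init] == [2, 4]

    def test_k_equals_n_selects_every_block(self):
        vecs = np.eye(4) * np.arange(1, 5)[:, None]
        init = energy_init(bs(vecs), 4)
        assert np.array_equal(init, vecs)  # already energy-sorted

    def test_k_one_gives_median_energy_block(self):
        vecs = np.zeros((5, 4))
        vecs[:, 0] = [5, 1, 3, 2, 4]
        init = energy_init(bs(vecs), 1)
        assert block_energy(init[0]) == 9  # position floor(N/2) of energies {1,4,9,16,25}

    def test_infeasible(self):
        with pytest.raises(InfeasibleCodebookError):
            energy_init(bs(np.zeros((3, 4))), 4)


class TestRandomInit:
    def test_deterministic_under_seed(self, rng):
        blocks = bs(rng.normal(size=(20, 4)))
        assert np.array_equal(random_init(blocks, 5, seed=7), random_init(blocks, 5, seed=7))

    def test_k_equals_n_is_a_permutation(self, rng):
        vecs = rng.normal(size=(6, 4))
        sel = random_init(bs(vecs), 6, seed=0)
        assert np.array_equal(np.sort(sel, axis=0), np.sort(vecs, axis=0))

    def test_selection_is_uniform(self):
        vecs = np.arange(5, dtype=float)[:, None] * np.ones(4)
        blocks = bs(vecs)
        counts = np.zeros(5)
        for seed in range(10000):
            v = random_init(blocks, 1, seed=seed)[0, 0]
            counts[int(v)] += 1
        assert np.all(np.abs(counts / 10000 - 0.2) < 0.02)


class TestKmeans:
    def test_two_tight_clusters_recover_means(self, rng):
        a = rng.normal(0, 0.01, size=(30, 4))
        b = rng.normal(100, 0.01, size=(30, 4))
        blocks = bs(np.vstack([a, b]))
        cb = kmeans_train(blocks, 2, energy_init(blocks, 2), max_iter=50, tol=1e-8)
        got = cb.codewords[np.argsort(cb.codewords[:, 0])]
        assert np.allclose(got[0], a.mean(axis=0), atol=1e-9)
        assert np.allclose(got[1], b.mean(axis=0), atol=1e-9)

    def test_k_equals_distinct_gives_zero_distortion(self, rng):
        vecs = rng.normal(size=(8, 4))
        blocks = bs(vecs)
        cb = kmeans_train(blocks, 8, energy_init(blocks, 8))
        assert cb.final_distortion < 1e-9

    def test_distortion_history_non_increasing(self, rng):
        blocks = bs(rng.normal(size=(200, 4)))
        cb = kmeans_train(blocks, 8, random_init(blocks, 8, seed=3), max_iter=30, tol=0.0)
        h = np.array(cb.distortion_history)
        assert np.all(np.diff(h) <= 1e-9 * h[0])

    def test_empty_cluster_is_reseeded(self, rng):
        vecs = rng.normal(size=(40, 4))
        blocks = bs(vecs)
        # duplicate seeds force empty clusters at the first assignment
        init = np.repeat(vecs[:1], 4, axis=0)
        cb = kmeans_train(blocks, 4, init, max_iter=20, tol=0.0)
        idx = vq_encode(blocks, cb)
        assert np.unique(idx).size == 4


class TestEncodeDecode:
    def test_codeword_blocks_encode_to_identity(self, rng):
        vecs = rng.normal(size=(6, 4))
        cb = kmeans_train(bs(vecs), 6, vecs.copy())
        assert np.array_equal(vq_encode(bs(vecs), cb), np.arange(6))

    def test_single_codeword_maps_all_to_zero(self, rng):
        blocks = bs(rng.normal(size=(10, 4)))
        cb = kmeans_train(blocks, 1, energy_init(blocks, 1))
        assert np.all(vq_encode(blocks, cb) == 0)

    def test_matches_brute_force_nearest_neighbor(self, rng):
        blocks = bs(rng.normal(size=(50, 4)))
        cb = kmeans_train(blocks, 7, energy_init(blocks, 7))
        idx = vq_encode(blocks, cb)
        for i, v in enumerate(blocks.vectors):
            d = [np.sum((v - c) ** 2) for c in cb.codewords]
            assert d[idx[i]] == pytest.approx(min(d), abs=1e-9)

    def test_dimension_mismatch(self, rng):
        blocks = bs(rng.normal(size=(5, 4)))
        cb = kmeans_train(bs(rng.normal(size=(5, 16)), size=4), 2,
                          energy_init(bs(rng.normal(size=(5, 16)), size=4), 2))
        with pytest.raises(ContainerError):
            vq_encode(blocks, cb)

    def test_lossless_limit_round_trip(self, rng):
        """K = N per size reconstructs the band's block contents exactly."""
        labels = rng.integers(0, 3, size=(16, 16))
        p = quadtree_divide(labels, (0, 0), l0=8)
        band = rng.normal(size=p.extended_size)
        blocksets = extract_blocks(band, p)
        codebooks, indices = {}, {}
        for s, blocks in blocksets.items():
            cb = kmeans_train(blocks, blocks.n, blocks.vectors.copy())
            codebooks[s] = cb
            indices[s] = vq_encode(blocks, cb)
        rec = vq_decode(indices, codebooks, p, band.shape)
        assert np.array_equal(rec, band)

    def test_distortion_bookkeeping_identity(self, rng):
        """Decoding the training blocks reproduces the training distortion."""
        labels = np.zeros((16, 16), dtype=int)
        p = quadtree_divide(labels, (0, 0), l0=8)  # four 8x8 blocks
        band = rng.normal(size=(16, 16))
        blocks = extract_blocks(band, p)[8]
        cb = kmeans_train(blocks, 2, energy_init(blocks, 2))
        idx = vq_encode(blocks, cb)
        train_d = float(sum(np.sum((blocks.vectors[i] - cb.codewords[idx[i]]) ** 2)
                            for i in range(blocks.n)))
        rec = vq_decode(idx, cb, p, band.shape)
        assert np.sum((rec - band) ** 2) == pytest.approx(train_d, rel=1e-12)

    def test_out_of_range_index(self, rng):
        labels = np.zeros((8, 8), dtype=int)
        p = quadtree_divide(labels, (0, 0), l0=8)
        blocks = extract_blocks(rng.normal(size=(8, 8)), p)[8]
        cb = kmeans_train(blocks, 1, energy_init(blocks, 1))
        with pytest.raises(ContainerError):
            vq_decode([5], cb, p, (8, 8))
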