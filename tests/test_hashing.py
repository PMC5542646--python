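"""Kernelized LSH: kernel, model fitting, hashing and Hamming distance."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from salret.hashing import (
    HashKey,
    fit_klsh,
    hamming,
    hash_descriptor,
    hash_many,
    median_gamma,
    rbf_kernel,
)


def clustered_descriptors(n_clusters=8, per_cluster=40, dim=16, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.2, 0.8, (n_clusters, dim))
    X = np.concatenate(
        [np.clip(c + rng.normal(0, 0.06, (per_cluster, dim)), 0, 1) for c in centers]
    )
    return X


class TestRBFKernel:
    def test_self_similarity_is_one(self):
        x = np.array([0.3, 0.7])
        assert rbf_kernel(x, x, 2.0) == 1.0

    def test_symmetry(self):
        x, y = np.array([0.1, 0.2]), np.array([0.9, 0.4])
        assert rbf_kernel(x, y, 1.3) == rbf_kernel(y, x, 1.3)

    def test_unit_distance_at_inverse_gamma(self):
        x = np.zeros(4)
        y = np.array([0.5, 0.5, 0.5, 0.5])  # squared norm 1.0
        assert rbf_kernel(x, y, 1.0) == pytest.approx(np.exp(-1))

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.zeros(2), 0.0)


class TestFit:
    def test_determinism_and_shapes(self):
        X = clustered_descriptors()
        m1 = fit_klsh(X, rho=50, t=10, b=32, seed=9)
        m2 = fit_klsh(X, rho=50, t=10, b=32, seed=9)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.anchors, m2.anchors)
        assert m1.W.shape == (32, 50)

    def test_invalid_sizes(self):
        X = clustered_descriptors(per_cluster=5)
        with pytest.raises(ValueError):
            fit_klsh(X, rho=10_000, t=10, b=8)
        with pytest.raises(ValueError):
            fit_klsh(X, rho=10, t=20, b=8)

    def test_inverse_sqrt_oracle_on_toy_anchors(self):
        """K^{-1/2} K K^{-1/2} acts as identity on the retained eigenspace."""
        from salret.hashing import _center_kernel, _inv_sqrt
        from scipy.spatial.distance import cdist

        anchors = np.array(
            [[0.1, 0.2], [0.8, 0.3], [0.4, 0.9], [0.6, 0.6]]
        )
        K = np.exp(-1.5 * cdist(anchors, anchors, "sqeuclidean"))
        Kc = _center_kernel(K)
        Kinv = _inv_sqrt(Kc, 1e-12)
        vals, vecs = np.linalg.eigh(Kc)
        keep = vals > 1e-12
        projector = (vecs[:, keep]) @ vecs[:, keep].T
        np.testing.assert_allclose(Kinv @ Kc @ Kinv, projector, atol=1e-8)

    def test_near_duplicate_anchors_still_finite(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 1, 12)
        X = np.stack([base + rng.normal(0, 1e-9, 12) for _ in range(20)])
        model = fit_klsh(X, rho=10, t=3, b=16, seed=1, gamma=1.0)
        assert np.all(np.isfinite(model.W))
        key = hash_descriptor(model, X[0])
        assert key.b == 16

    def test_median_gamma_positive(self):
        X = clustered_descriptors(per_cluster=4)
        g = median_gamma(X)
        assert g > 0


class TestHash:
    def test_repeat_hash_identical(self):
        X = clustered_descriptors()
        model = fit_klsh(X, rho=40, t=8, b=24, seed=2)
        k1 = hash_descriptor(model, X[3])
        k2 = hash_descriptor(model, X[3])
        assert k1 == k2
        assert k1.b == 24

    def test_anchor_hashes_cleanly(self):
        X = clustered_descriptors()
        model = fit_klsh(X, rho=40, t=8, b=24, seed=2)
        key = hash_descriptor(model, model.anchors[0])
        assert set(np.unique(key.bits)).issubset({0, 1})

    def test_hash_many_matches_single(self):
        X = clustered_descriptors(per_cluster=6)
        model = fit_klsh(X, rho=30, t=6, b=16, seed=3)
        batch = hash_many(model, X[:10])
        for i in range(10):
            np.testing.assert_array_equal(
                batch[i], hash_descriptor(model, X[i]).bits
            )

    def test_length_mismatch(self):
        X = clustered_descriptors()
        model = fit_klsh(X, rho=40, t=8, b=24, seed=2)
        with pytest.raises(ValueError):
            hash_descriptor(model, np.zeros(5))

    def test_bits_not_constant_across_inputs(self):
        """Centered-kernel hashing must produce informative (varying) bits."""
        X = clustered_descriptors(seed=5)
        model = fit_klsh(X, rho=60, t=12, b=32, seed=5)
        keys = hash_many(model, X)
        per_bit_mean = keys.mean(axis=0)
        assert np.any((per_bit_mean > 0.05) & (per_bit_mean < 0.95))

    def test_locality_quick(self):
        """Key agreement correlates with kernel similarity on clustered data."""
        X = clustered_descriptors(seed=6)
        model = fit_klsh(X, rho=80, t=15, b=64, seed=6)
        rng = np.random.default_rng(7)
        sims, agrees = [], []
        keys = hash_many(model, X)
        for _ in range(400):
            i, j = rng.integers(0, len(X), 2)
            sims.append(rbf_kernel(X[i], X[j], model.gamma))
            agrees.append(1.0 - np.count_nonzero(keys[i] != keys[j]) / model.b)
        rho_s, p = spearmanr(sims, agrees)
        assert rho_s > 0 and p < 0.01


class TestHamming:
    def test_identical_and_complementary(self):
        k1 = HashKey.from_bits(np.array([0, 1, 1, 0, 1]))
        k2 = HashKey.from_bits(np.array([1, 0, 0, 1, 0]))
        assert hamming(k1, k1) == 0
        assert hamming(k1, k2) == 5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming(HashKey.from_bits(np.zeros(4)), HashKey.from_bits(np.zeros(8)))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            a, b, c = (HashKey.from_bits(rng.integers(0, 2, 16)) for _ in range(3))
            assert hamming(a, b) == hamming(b, a)
            assert hamming(a, c) <= hamming(a, b) + hamming(b, c)

    def test_packing_roundtrip(self):
        bits = np.random.default_rng(9).integers(0, 2, 37).astype(np.uint8)
        np.testing.assert_array_equal(HashKey.from_bits(bits).bits, bits)
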