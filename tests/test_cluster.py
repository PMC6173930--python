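"""Dendrograms, k-means profiles, multiscale bootstrap and the AU curve fit."""
import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from _oracles import complete_linkage_brute
from conftest import make_matrix
from xdevo.cluster import (
    DEFAULT_SCALES,
    au_from_bp_curve,
    bootstrap_feature_indices,
    correlation_distance,
    hierarchical_cluster,
    kmeans_profiles,
    multiscale_bootstrap_support,
)
from xdevo.errors import ConfigError, DataError


class TestCorrelationDistance:
    def test_identical_antipodal_orthogonal(self):
        x = np.array([1.0, 0.0, -1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert correlation_distance(x, x) == pytest.approx(0.0)
        assert correlation_distance(x, -x) == pytest.approx(2.0)
        assert correlation_distance(x, y) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError, match="constant"):
            correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHierarchical:
    def test_identical_pair_merges_first_at_height_zero(self):
        x = np.array([[1.0, 2.0, 3.0, 1.0], [2.0, 1.0, 0.0, 5.0], [1.0, 2.0, 3.0, 1.0]]).T
        tree = hierarchical_cluster(make_matrix(x), axis="samples")
        first = tree.merges[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first[0]), int(first[1])} == {0, 2}

    def test_zero_variance_item_rejected_with_offender(self):
        x = np.ones((5, 3))
        x[:, 0] = [1, 2, 3, 4, 5.0]
        with pytest.raises(DataError, match="s1"):
            hierarchical_cluster(make_matrix(x), axis="samples")

    def test_complete_heights_dominate_single_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(0, 1, (30, 8)))
        tree = hierarchical_cluster(m, axis="samples")
        d = 1 - np.corrcoef(m.values.to_numpy().T)
        np.fill_diagonal(d, 0)
        single = linkage(squareform(d, checks=False), method="single")
        assert np.all(np.sort(tree.merges[:, 2]) >= np.sort(single[:, 2]) - 1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_merge_sequence_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(3, 9))
        m = make_matrix(rng.normal(0, 1, (12, n_leaves)))
        tree = hierarchical_cluster(m, axis="samples")
        d = 1 - np.corrcoef(m.values.to_numpy().T)
        np.fill_diagonal(d, 0)
        d = np.clip((d + d.T) / 2, 0, 2)
        ref = complete_linkage_brute(d)
        impl = sorted(
            (h, frozenset(int(lab[1:]) for lab in cs))
            for (k, cs), h in zip(tree.clades(include_root=True).items(), [tree.heights()[k] for k in tree.clades(include_root=True)])
        )
        ref_sorted = sorted((h, frozenset(s)) for s, h in ref)
        assert len(impl) == len(ref_sorted)
        for (h1, s1), (h2, s2) in zip(impl, ref_sorted):
            assert s1 == s2
            assert h1 == pytest.approx(h2, abs=1e-9)


class TestKMeans:
    def test_k1_centroid_is_mean_profile(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(0, 1, (40, 5)))
        res = kmeans_profiles(m, k=1, seed=0)
        x = m.values.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        assert np.allclose(res.centroids.iloc[0].to_numpy(), z.mean(axis=0), atol=1e-9)

    def test_planted_templates_recovered_exactly(self):
        rng = np.random.default_rng(0)
        cents = np.array(
            [[2, 0, -2, 0, 0], [0, 2, 0, -2, 0], [-2, 0, 2, 0, 0], [0, -2, 0, 2, 0]], float
        )
        lab = rng.integers(0, 4, 200)
        x = cents[lab] + rng.normal(0, 0.05, (200, 5))
        res = kmeans_profiles(make_matrix(x), k=4, seed=1)
        assert adjusted_rand_score(lab, res.labels.to_numpy()) == 1.0
        # centroids equal member means in z-space
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        for c in range(1, 5):
            members = res.labels.to_numpy() == c
            assert np.allclose(res.centroids.loc[c], z[members].mean(axis=0), atol=1e-9)

    def test_same_seed_reproducible_and_k_bounds(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(0, 1, (50, 6)))
        r1 = kmeans_profiles(m, k=3, seed=7)
        r2 = kmeans_profiles(m, k=3, seed=7)
        assert (r1.labels == r2.labels).all()
        with pytest.raises(ConfigError):
            kmeans_profiles(m, k=51, seed=0)


class TestAUCurve:
    def test_exact_curve_recovers_parameters(self):
        v, c = 0.5, 0.2
        bp = {
            float(r): float(1 - norm.cdf(v * np.sqrt(r) + c / np.sqrt(r)))
            for r in DEFAULT_SCALES
        }
        fit = au_from_bp_curve(bp, n_boot=1000)
        assert fit.v == pytest.approx(v, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.au == pytest.approx(1 - norm.cdf(0.3), abs=1e-6)

    def test_zero_curvature_makes_au_equal_model_bp(self):
        bp = {float(r): float(1 - norm.cdf(0.7 * np.sqrt(r))) for r in DEFAULT_SCALES}
        fit = au_from_bp_curve(bp, n_boot=1000)
        assert fit.au == pytest.approx(fit.bp, abs=1e-9)

    def test_saturated_and_absent_clades_clip(self):
        ones = {float(r): 1.0 for r in DEFAULT_SCALES}
        zeros = {float(r): 0.0 for r in DEFAULT_SCALES}
        assert au_from_bp_curve(ones, n_boot=100).au == 1.0
        assert au_from_bp_curve(zeros, n_boot=100).au == 0.0
        assert au_from_bp_curve(ones, n_boot=100).degenerate

    def test_single_scale_falls_back_to_bp(self):
        fit = au_from_bp_curve({1.0: 0.8}, n_boot=100)
        assert fit.degenerate
        assert fit.au == pytest.approx(0.8)

    def test_au_dominates_model_bp_for_positive_curvature(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(-1, 1)
            c = rng.uniform(0.05, 0.5)
            bp = {
                float(r): float(1 - norm.cdf(v * np.sqrt(r) + c / np.sqrt(r)))
                for r in DEFAULT_SCALES
            }
            fit = au_from_bp_curve(bp, n_boot=1000)
            assert fit.au >= fit.bp


class TestBootstrap:
    def test_scales_must_include_one(self, block_matrix):
        with pytest.raises(ConfigError, match="1.0"):
            multiscale_bootstrap_support(block_matrix, scales=[0.5, 0.8], n_boot=100, seed=0)

    def test_bp_at_scale_one_matches_naive_bootstrap(self, block_matrix):
        """At r=1 the reported BP equals a from-scratch bootstrap replaying
        the same index stream with independently coded clustering."""
        tree = multiscale_bootstrap_support(
            block_matrix, scales=[0.5, 1.0], n_boot=100, seed=11
        )
        data = block_matrix.values.to_numpy().T
        labels = block_matrix.sample_ids
        nf = data.shape[1]
        counts = {k: 0 for k in tree.clades()}
        for b in range(100):
            idx = bootstrap_feature_indices(11, 1, b, nf, nf)  # scale index 1 is r=1.0
            sub = data[:, idx]
            d = 1 - np.corrcoef(sub)
            np.fill_diagonal(d, 0)
            merges = complete_linkage_brute(np.clip((d + d.T) / 2, 0, 2))
            rep = {frozenset(labels[i] for i in s) for s, _ in merges}
            for k, cs in tree.clades().items():
                if cs in rep:
                    counts[k] += 1
        for k in counts:
            assert tree.support[k].bp == pytest.approx(counts[k] / 100)

    def test_separated_blocks_get_full_support(self, block_matrix):
        tree = multiscale_bootstrap_support(block_matrix, n_boot=100, seed=3)
        b1 = frozenset(f"s{i}" for i in range(5))
        b2 = frozenset(f"s{i}" for i in range(5, 10))
        found = 0
        for k, cs in tree.clades().items():
            if cs in (b1, b2):
                found += 1
                assert tree.support[k].bp == 1.0
                assert tree.support[k].au >= 0.99
        assert found == 2
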