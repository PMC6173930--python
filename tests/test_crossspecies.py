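"""Ortholog joining, PCA conventions, phase maps and the conservation screen."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from xdevo import crossspecies as cs
from xdevo.errors import ConfigError, DataError
from xdevo.matrix import OrthologMap


def _centered_pair(n_genes=5, seed=0):
    rng = np.random.default_rng(seed)
    xa = rng.normal(0, 1, (n_genes, 4))
    xb = rng.normal(0, 1, (n_genes, 4))
    xa -= xa.mean(axis=1, keepdims=True)
    xb -= xb.mean(axis=1, keepdims=True)
    a = make_matrix(xa, samples=[f"a{i}" for i in range(4)], species=["A"] * 4, scale="log_centered")
    b = make_matrix(xb, samples=[f"b{i}" for i in range(4)], species=["B"] * 4, scale="log_centered")
    b.values.index = [f"H{i}" for i in range(n_genes)]
    return a, b


class TestCombine:
    def test_joins_pairs_present_in_both(self):
        a, b = _centered_pair()
        omap = OrthologMap([("G0", "H0"), ("G1", "H1"), ("G2", "H2")])
        comb = cs.combine_by_orthologs(a, b, omap)
        assert comb.n_genes == 3
        assert comb.n_samples == 8
        assert list(comb.values.index) == ["G0|H0", "G1|H1", "G2|H2"]
        assert comb.species_tag == "combined"

    def test_missing_gene_drops_pair(self):
        a, b = _centered_pair()
        omap = OrthologMap([("G0", "H0"), ("G1", "HX")])
        comb = cs.combine_by_orthologs(a, b, omap)
        assert comb.n_genes == 1

    def test_per_species_row_means_stay_zero(self):
        a, b = _centered_pair(n_genes=20, seed=3)
        omap = OrthologMap([(f"G{i}", f"H{i}") for i in range(20)])
        comb = cs.combine_by_orthologs(a, b, omap)
        x = comb.values.to_numpy()
        assert np.allclose(x[:, :4].mean(axis=1), 0, atol=1e-9)
        assert np.allclose(x[:, 4:].mean(axis=1), 0, atol=1e-9)

    def test_uncentered_or_empty_rejected(self):
        a, b = _centered_pair()
        raw = make_matrix(np.ones((2, 2)), scale="log")
        with pytest.raises(DataError):
            cs.combine_by_orthologs(raw, b, OrthologMap([("G0", "H0")]))
        with pytest.raises(DataError, match="no ortholog"):
            cs.combine_by_orthologs(a, b, OrthologMap([("GX", "HX")]))


class TestPCA:
    def test_two_samples_give_one_component_with_all_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (30, 2))
        x -= x.mean(axis=1, keepdims=True)
        res = cs.pca(make_matrix(x, scale="log_centered"))
        assert res.variance_explained.shape == (1,)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_variance_explained_sums_to_one_and_is_sorted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (40, 6))
        x -= x.mean(axis=1, keepdims=True)
        res = cs.pca(make_matrix(x, scale="log_centered"))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (25, 5))
        x -= x.mean(axis=1, keepdims=True)
        res = cs.pca(make_matrix(x, scale="log_centered"))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        for j in range(L.shape[1]):
            assert L[np.abs(L[:, j]).argmax(), j] > 0


class TestLoadingRetrieval:
    def test_unreachable_threshold_gives_empty_set(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (20, 4))
        x -= x.mean(axis=1, keepdims=True)
        res = cs.pca(make_matrix(x, scale="log_centered"))
        assert cs.retrieve_pc_loading_genes(res, component=1, threshold=1.1) == []

    def test_sign_flip_leaves_retrieved_set_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (20, 4))
        x -= x.mean(axis=1, keepdims=True)
        res = cs.pca(make_matrix(x, scale="log_centered"))
        got = cs.retrieve_pc_loading_genes(res, component=2, threshold=0.2)
        res.loadings.iloc[:, 1] *= -1
        assert cs.retrieve_pc_loading_genes(res, component=2, threshold=0.2) == got

    def test_bad_component_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (10, 3))
        x -= x.mean(axis=1, keepdims=True)
        res = cs.pca(make_matrix(x, scale="log_centered"))
        with pytest.raises(ConfigError):
            cs.retrieve_pc_loading_genes(res, component=9)


def _two_species_matrix():
    m = make_matrix(
        np.arange(26.0).reshape(2, 13),
        species=["A"] * 6 + ["B"] * 7,
        ages=[1, 1, 2, 2, 3, 3] + [1, 2, 3, 4, 5, 6, 7],
        scale="log_centered",
    )
    return m


class TestPhases:
    def test_explicit_mapping_assigns_and_validates(self):
        m = _two_species_matrix()
        mapping = {
            "A": {"t1": "early", "t2": "intermediate", "t3": "late"},
            "B": {f"t{i}": p for i, p in zip(range(1, 8), ["early"] * 3 + ["intermediate"] * 2 + ["late"] * 2)},
        }
        phases = cs.assign_phases(m, mapping)
        assert phases["s0"] == "early"
        assert phases["s12"] == "late"

    def test_default_phase_config_is_valid_and_covers_phases(self):
        m = make_matrix(
            np.arange(24.0).reshape(2, 12),
            species=["monodelphis"] * 7 + ["mouse"] * 5,
            ages=list(range(1, 8)) + list(range(1, 6)),
            scale="log_centered",
        )
        labels = ["D3", "D8", "D14", "D29", "D35", "D63", "ADULT", "E16", "E18", "P2", "P10", "P30"]
        m.meta["age_label"] = labels
        phases = cs.assign_phases(m, cs.DEFAULT_PHASE_CONFIG)
        assert phases["s0"] == "early"
        assert phases["s11"] == "late"

    def test_missing_sample_in_mapping_errors_with_name(self):
        m = _two_species_matrix()
        with pytest.raises(ConfigError, match="s0"):
            cs.assign_phases(m, {"A": {}, "B": {}})

    def test_rank_thirds_cover_every_phase_per_species(self):
        m = _two_species_matrix()
        phases = cs.phases_by_rank(m)
        for sp in ("A", "B"):
            sids = [s for s in m.sample_ids if m.meta.loc[s, "species"] == sp]
            assert {phases[s] for s in sids} == {"early", "intermediate", "late"}

    def test_phase_average_means_and_shape(self):
        m = _two_species_matrix()
        phases = cs.phases_by_rank(m)
        avgs = cs.phase_average(m, phases)
        assert set(avgs) == {"A", "B"}
        assert list(avgs["A"].columns) == ["early", "intermediate", "late"]
        assert avgs["A"].loc["G0", "early"] == pytest.approx((0 + 1) / 2)


class TestConservationTable:
    def _table(self, rows_a, rows_b):
        idx = [f"P{i}" for i in range(len(rows_a))]
        a = pd.DataFrame(rows_a, index=idx, columns=["early", "intermediate", "late"])
        b = pd.DataFrame(rows_b, index=idx, columns=["early", "intermediate", "late"])
        return cs.ortholog_profile_correlation(a, b)

    def test_identical_opposite_and_flat_profiles(self):
        t = self._table(
            [[1, 2, 3], [1, 2, 3], [1, 2, 3]],
            [[1, 2, 3], [3, 2, 1], [2, 2, 2]],
        )
        assert t.loc["P0", "class"] == "conserved_strict"
        assert t.loc["P0", "cor"] == pytest.approx(1.0)
        assert t.loc["P1", "class"] == "not_conserved"
        assert t.loc["P1", "cor"] == pytest.approx(-1.0)
        assert t.loc["P2", "class"] == "undefined"
        assert not t.loc["P2", "conserved"]

    def test_strict_subset_of_conserved(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.normal(0, 1, (50, 3)), rng.normal(0, 1, (50, 3)))
        assert set(t.index[t["conserved_strict"]]) <= set(t.index[t["conserved"]])

    def test_row_mismatch_rejected(self):
        a = pd.DataFrame([[1, 2, 3]], index=["P0"], columns=["early", "intermediate", "late"])
        b = pd.DataFrame([[1, 2, 3]], index=["P1"], columns=["early", "intermediate", "late"])
        with pytest.raises(DataError):
            cs.ortholog_profile_correlation(a, b)
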