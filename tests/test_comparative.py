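"""Tests of cross-condition/cross-species comparison operations."""

import numpy as np
import pandas as pd
import pytest

from toxmod.comparative import (
    cluster_separation_check,
    common_genes,
    correlate_scores,
    overlap_matrix,
    pca_embed,
    rank_by_mean_fc,
)
from toxmod.datatypes import Condition, DegSet, InvalidInputError
from toxmod.io import load_reference_module_scores

from conftest import make_profile


def deg(label: str, genes) -> DegSet:
    return DegSet(Condition.from_label(label), frozenset(genes), 0.1)


class TestOverlapMatrix:
    def test_diagonal_equals_own_sizes(self):
        d = deg("v_LD_9h", {"a", "b", "c"})
        m = overlap_matrix([d])
        assert m.counts.iloc[0, 0] == 3

    def test_disjoint_sets_zero_offdiagonal(self):
        m = overlap_matrix([deg("v_LD_9h", {"a"}), deg("v_HD_9h", {"b"})])
        assert m.counts.iloc[0, 1] == 0

    def test_matches_bruteforce_counts(self, rng):
        universe = [f"g{i}" for i in range(100)]
        sets = [
            deg(f"v_d{i}_t", set(rng.choice(universe, 30, replace=False)))
            for i in range(4)
        ]
        m = overlap_matrix(sets)
        for i in range(4):
            for j in range(4):
                assert m.counts.iloc[i, j] == len(sets[i].gene_ids & sets[j].gene_ids)
        assert (m.counts.to_numpy() == m.counts.to_numpy().T).all()

    def test_duplicate_condition_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            overlap_matrix([deg("v_LD_9h", {"a"}), deg("v_LD_9h", {"b"})])


class TestCommonGenes:
    def test_identical_sets(self):
        genes = {"a", "b", "c"}
        sets = [deg(f"v_d{i}_t", genes) for i in range(3)]
        assert common_genes(sets) == frozenset(genes)

    def test_bounded_by_smallest_set(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sets = [deg(f"v_d{i}_t", set(rng.choice(universe, 10 + 5 * i, replace=False)))
                for i in range(3)]
        assert len(common_genes(sets)) <= min(len(s) for s in sets)

    def test_planted_core_recovered_exactly(self, rng):
        # eight DEG sets sharing an 87-gene core plus per-set noise genes
        core = {f"core{i}" for i in range(87)}
        noise_pool = [f"noise{i}" for i in range(400)]
        sets = []
        for i in range(8):
            noise = set(rng.choice(noise_pool, 40, replace=False))
            sets.append(deg(f"v_d{i}_t", core | noise))
        assert common_genes(sets) == frozenset(core)

    def test_empty_intersection_is_valid(self):
        assert common_genes([deg("v_a_t", {"x"}), deg("v_b_t", {"y"})]) == frozenset()

    def test_order_independent_and_idempotent(self, rng):
        universe = [f"g{i}" for i in range(30)]
        sets = [deg(f"v_d{i}_t", set(rng.choice(universe, 15, replace=False)))
                for i in range(4)]
        inter = common_genes(sets)
        assert common_genes(sets[::-1]) == inter
        again = common_genes(sets + [deg("v_self_t", inter)])
        assert again == common_genes(sets + [deg("v_self_t", inter)])
        if inter:
            assert common_genes([deg("v_x_t", inter), deg("v_y_t", inter)]) == inter


class TestRankByMeanFc:
    def test_arithmetic_mean_across_conditions(self):
        p1 = make_profile({"a": 2.0, "b": 0.0}, Condition("v", "LD", "9h"))
        p2 = make_profile({"a": 4.0, "b": 1.0}, Condition("v", "HD", "9h"))
        table = rank_by_mean_fc(["a", "b"], [p1, p2])
        assert table.loc[0, "gene_id"] == "a"
        assert table.loc[0, "mean_log2_fc"] == pytest.approx(3.0)
        assert list(table["rank"]) == [1, 2]

    def test_identical_profiles_preserve_single_profile_order(self, rng):
        fc = dict(zip([f"g{i}" for i in range(20)], rng.normal(0, 2, 20)))
        profs = [make_profile(fc, Condition("v", f"d{i}", "t")) for i in range(3)]
        table = rank_by_mean_fc(list(fc), profs)
        expected = sorted(fc, key=fc.get, reverse=True)
        assert list(table["gene_id"]) == expected

    def test_top_k_keeps_extremes(self, rng):
        fc = dict(zip([f"g{i}" for i in range(30)], np.linspace(5, -5, 30)))
        table = rank_by_mean_fc(list(fc), [make_profile(fc)], top_k=10)
        assert len(table) == 20
        assert table["mean_log2_fc"].iloc[0] == pytest.approx(5.0)
        assert table["mean_log2_fc"].iloc[-1] == pytest.approx(-5.0)

    def test_gene_missing_from_profile_dropped(self):
        p1 = make_profile({"a": 1.0, "b": 2.0})
        p2 = make_profile({"a": 1.0}, Condition("v", "HD", "9h"))
        table = rank_by_mean_fc(["a", "b"], [p1, p2])
        assert list(table["gene_id"]) == ["a"]


class TestCorrelateScores:
    def test_published_cross_platform_correlation(self):
        # in vivo 33h high-dose vs in vitro 24h high-dose module z-scores
        ref = load_reference_module_scores()
        r, r2 = correlate_scores(ref["invivo_33h_HD"], ref["invitro_24h_HD"])
        assert round(r2, 2) == 0.31

    def test_perfect_linear_relation(self, rng):
        v = rng.normal(0, 1, 10)
        _, r2 = correlate_scores(v, 2 * v + 1)
        assert r2 == pytest.approx(1.0)

    def test_matches_bruteforce_pearson(self, rng):
        a = rng.normal(0, 1, 25)
        b = a[rng.permutation(25)]
        r, r2 = correlate_scores(a, b)
        am, bm = a - a.mean(), b - b.mean()
        expected = float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))
        assert r == pytest.approx(expected, abs=1e-12)
        assert r2 == pytest.approx(expected**2, abs=1e-12)

    def test_affine_invariance_positive_slope(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        _, r2 = correlate_scores(a, b)
        _, r2b = correlate_scores(3.2 * a + 7, b)
        assert r2b == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            correlate_scores([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vectors_rejected(self):
        with pytest.raises(InvalidInputError):
            correlate_scores([1.0, 2.0], [3.0, 4.0])


class TestPcaEmbed:
    def test_two_mirror_items(self):
        x = np.array([3.0, 4.0, 0.0])
        table = pd.DataFrame([x, -x], index=["a", "b"])
        emb = pca_embed(table, n_components=2)
        pc1 = emb.points["PC1"].to_numpy()
        assert sorted(np.abs(pc1)) == pytest.approx([5.0, 5.0])
        assert emb.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_valid(self, rng):
        emb = pca_embed(pd.DataFrame(rng.normal(0, 1, (6, 10))))
        frac = emb.explained_variance_fraction
        assert (np.diff(frac) <= 1e-9).all()
        assert frac.sum() <= 1 + 1e-9

    def test_full_reconstruction_roundtrip(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (6, 10)))
        emb = pca_embed(X)
        recon = emb.points.to_numpy() @ emb.components.to_numpy() + emb.mean.to_numpy()
        assert np.allclose(recon, X.to_numpy(), atol=1e-9)

    def test_deterministic_sign_convention(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (8, 5)))
        e1, e2 = pca_embed(X, 2), pca_embed(X.copy(), 2)
        assert np.allclose(e1.points.to_numpy(), e2.points.to_numpy())
        for j in range(2):
            row = e1.components.iloc[j].to_numpy()
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_table_rejected(self):
        with pytest.raises(InvalidInputError):
            pca_embed(pd.DataFrame(np.ones((4, 4))))


class TestClusterSeparation:
    def embed(self, coords, items):
        table = pd.DataFrame(coords, index=items, columns=["f1", "f2"])
        return pca_embed(table, n_components=2)

    def test_well_separated_groups_high_score(self):
        emb = self.embed([[0, 0], [0, 1], [10, 10], [10, 11]], list("abcd"))
        score, flag = cluster_separation_check(
            emb, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        )
        assert score > 0.9 and not flag

    def test_random_grouping_near_zero(self, rng):
        scores = []
        for _ in range(100):
            pts = rng.normal(0, 1, (40, 2))
            emb = self.embed(pts, [f"i{j}" for j in range(40)])
            labels = {f"i{j}": rng.choice(["g1", "g2"]) for j in range(40)}
            if len(set(labels.values())) < 2:
                continue
            s, _ = cluster_separation_check(emb, labels)
            scores.append(s)
        assert -0.2 <= np.mean(scores) <= 0.2

    def test_all_singleton_groups_convention(self):
        emb = self.embed([[0, 0], [5, 5], [9, 1]], list("abc"))
        score, flag = cluster_separation_check(emb, {"a": "x", "b": "y", "c": "z"})
        assert score == 0.0 and flag

    def test_single_group_rejected(self):
        emb = self.embed([[0, 0], [1, 1]], list("ab"))
        with pytest.raises(InvalidInputError):
            cluster_separation_check(emb, {"a": "g", "b": "g"})
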