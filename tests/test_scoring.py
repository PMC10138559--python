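"""Tests of AAFC/AFC module scoring and the permutation null."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxmod.datatypes import Condition, GeneSet, GeneSetCollection, InvalidInputError
from toxmod.io import load_reference_module_scores
from toxmod.scoring import (
    AAFC,
    AFC,
    NullConfig,
    aafc_score,
    afc_score,
    match_genes,
    permutation_null,
    score_all_modules,
    score_module,
)

from conftest import make_profile, random_profile


def gene_set(*genes: str, name="mod") -> GeneSet:
    return GeneSet(name=name, description="", gene_ids=tuple(genes))


class TestMatchGenes:
    def test_case_insensitive_intersection(self):
        prof = make_profile({"gsta2": 1.0, "mt2a": 2.0, "cbr1": -1.0})
        assert match_genes(gene_set("GSTA2", "MT2A"), prof) == ["gsta2", "mt2a"]

    def test_disjoint_sets_match_nothing(self):
        prof = make_profile({"a": 1.0})
        assert match_genes(gene_set("b", "c"), prof) == []

    def test_matches_bruteforce_casefold_intersection(self, rng):
        pool = [f"Gene{i}" for i in range(200)]
        for _ in range(200):
            prof_genes = rng.choice(pool, 50, replace=False)
            set_genes = [g.upper() for g in rng.choice(pool, 30, replace=False)]
            prof = make_profile({g: 0.0 for g in prof_genes})
            got = match_genes(set_genes, prof)
            want = {g.casefold() for g in set_genes} & {g.casefold() for g in prof_genes}
            assert {g.casefold() for g in got} == want


class TestScores:
    def test_aafc_ignores_direction(self):
        prof = make_profile({"a": 1.0, "b": -1.0})
        assert aafc_score(prof, ["a", "b"]) == pytest.approx(1.0)

    def test_aafc_zero_profile(self):
        prof = make_profile({"a": 0.0, "b": 0.0, "c": 0.0})
        assert aafc_score(prof, ["a", "b", "c"]) == 0.0

    def test_afc_signed_cancellation(self):
        prof = make_profile({"a": 1.0, "b": -1.0})
        assert afc_score(prof, ["a", "b"]) == pytest.approx(0.0)

    def test_afc_net_upregulation(self):
        prof = make_profile({"a": 2.0, "b": 2.0})
        assert afc_score(prof, ["a", "b"]) == pytest.approx(2.0)

    def test_scores_match_bruteforce_means(self, rng):
        prof = random_profile(30, rng)
        genes = list(prof.gene_ids[:17])
        fc = prof.table.loc[genes, "log2_fc"].to_numpy()
        assert abs(aafc_score(prof, genes) - np.abs(fc).mean()) < 1e-12
        assert abs(afc_score(prof, genes) - fc.mean()) < 1e-12

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=200)
    def test_afc_magnitude_bounded_by_aafc(self, fcs):
        genes = [f"g{i}" for i in range(len(fcs))]
        prof = make_profile(dict(zip(genes, fcs)))
        assert abs(afc_score(prof, genes)) <= aafc_score(prof, genes) + 1e-12

    def test_empty_gene_list_rejected(self, small_profile):
        with pytest.raises(InvalidInputError):
            aafc_score(small_profile, [])


class TestPermutationNull:
    def test_exhaustive_enumeration_small_universe(self, small_profile):
        null = permutation_null(small_profile, 2, AAFC)
        assert null.exhaustive
        assert sorted(null.scores) == pytest.approx([1.5, 2.0, 2.5, 2.5, 3.0, 3.5])
        assert null.mean == pytest.approx(2.5)
        assert null.sd == pytest.approx(math.sqrt(2.5 / 6))

    def test_constant_profile_degenerate_null(self):
        prof = make_profile({f"g{i}": -3.0 for i in range(6)})
        null = permutation_null(prof, 2, AAFC)
        assert null.sd == 0.0
        assert np.allclose(null.scores, 3.0)

    def test_monte_carlo_agrees_with_enumeration(self, rng):
        prof = random_profile(12, rng)
        exact = permutation_null(prof, 4, AAFC)
        mc = permutation_null(
            prof, 4, AAFC,
            NullConfig(n_resamples=10_000, seed=3, exhaustive_limit=0),
        )
        assert not mc.exhaustive
        assert abs(mc.mean - exact.mean) < 3 * exact.sd / math.sqrt(10_000)

    def test_set_size_bounds_enforced(self, small_profile):
        with pytest.raises(InvalidInputError):
            permutation_null(small_profile, 5, AAFC)
        with pytest.raises(InvalidInputError):
            permutation_null(small_profile, 0, AAFC)


class TestScoreModule:
    def test_exhaustive_example_z_and_p(self, small_profile):
        res = score_module(small_profile, gene_set("g3", "g4"), AAFC)
        assert res.score == pytest.approx(3.5)
        assert res.null_mean == pytest.approx(2.5)
        assert res.null_sd == pytest.approx(math.sqrt(2.5 / 6))
        assert res.z_score == pytest.approx(1.0 / math.sqrt(2.5 / 6), abs=1e-3)
        assert res.z_score == pytest.approx(1.549, abs=1e-3)
        assert not res.activated
        assert res.p_empirical == pytest.approx(1 / 6)  # only {g3,g4} scores >= 3.5

    def test_z_consistent_with_null_moments(self, rng):
        prof = random_profile(300, rng)
        genes = tuple(prof.gene_ids[:20])
        res = score_module(prof, gene_set(*genes), AAFC,
                           NullConfig(n_resamples=2000, seed=1))
        assert res.z_score == pytest.approx(
            (res.score - res.null_mean) / res.null_sd, abs=1e-9
        )

    def test_activation_threshold_rule_on_reference_scores(self):
        # the bundled published z-score table: >2 means activated
        ref = load_reference_module_scores()
        assert ref.loc["Dilatation", "invivo_33h_HD"] == pytest.approx(10.45)
        assert ref.loc["Dilatation", "invivo_33h_HD"] > 2.0  # activated
        assert ref.loc["Hypertrophy", "invivo_33h_HD"] == pytest.approx(1.50)
        assert not ref.loc["Hypertrophy", "invivo_33h_HD"] > 2.0

    def test_module_equal_to_universe_degenerate(self, small_profile):
        res = score_module(small_profile, gene_set("g1", "g2", "g3", "g4"), AAFC)
        assert res.null_sd == 0.0
        assert np.isnan(res.z_score) and not res.activated

    def test_no_matched_genes_refused(self, small_profile):
        with pytest.raises(InvalidInputError):
            score_module(small_profile, gene_set("absent"), AAFC)

    def test_afc_two_sided_p_symmetric(self, rng):
        # a strongly down module is as significant as a strongly up one
        fc = {f"g{i}": 0.0 for i in range(50)}
        fc.update({"u1": 5.0, "u2": 5.0, "d1": -5.0, "d2": -5.0})
        prof = make_profile(fc)
        cfg = NullConfig(n_resamples=2000, seed=9)
        up = score_module(prof, gene_set("u1", "u2"), AFC, cfg)
        down = score_module(prof, gene_set("d1", "d2"), AFC, cfg)
        assert up.p_empirical < 0.05 and down.p_empirical < 0.05
        assert down.z_score < 0 < up.z_score


class TestInvariances:
    def test_global_scaling_leaves_z_unchanged(self, rng):
        prof = random_profile(10, rng)
        scaled = make_profile(dict(zip(prof.gene_ids, 3.7 * prof.log2_fc)))
        genes = gene_set(*prof.gene_ids[:3])
        a = score_module(prof, genes, AAFC)
        b = score_module(scaled, genes, AAFC)
        assert b.z_score == pytest.approx(a.z_score, abs=1e-12)

    def test_constant_shift_moves_score_and_null_equally(self, rng):
        fc = np.abs(rng.normal(0, 1, 10)) + 0.1  # all positive
        genes = [f"g{i}" for i in range(10)]
        prof = make_profile(dict(zip(genes, fc)))
        shifted = make_profile(dict(zip(genes, fc + 5.0)))
        gs = gene_set(*genes[:4])
        a = score_module(prof, gs, AAFC)
        b = score_module(shifted, gs, AAFC)
        assert b.score - a.score == pytest.approx(5.0, abs=1e-9)
        assert b.null_mean - a.null_mean == pytest.approx(5.0, abs=1e-9)
        assert b.z_score == pytest.approx(a.z_score, abs=1e-9)


class TestScoreAllModules:
    def make_inputs(self, rng, n_cond=3, n_mod=4):
        profiles = [
            random_profile(120, rng)
            for _ in range(n_cond)
        ]
        for i, p in enumerate(profiles):
            p.condition = Condition("in_vivo", f"d{i}", "short")
        sets = [
            GeneSet(f"mod{j}", "", tuple(rng.choice(profiles[0].gene_ids, 10, replace=False)))
            for j in range(n_mod)
        ]
        return profiles, GeneSetCollection(sets=sets)

    def test_table_shape_and_determinism(self, rng):
        profiles, coll = self.make_inputs(rng)
        cfg = NullConfig(n_resamples=500, seed=4)
        t1, r1 = score_all_modules(profiles, coll, AAFC, cfg)
        t2, _ = score_all_modules(profiles, coll, AAFC, cfg)
        assert t1.shape == (4, 3)
        assert t1.equals(t2)

    def test_cells_independent_of_evaluation_order(self, rng):
        profiles, coll = self.make_inputs(rng)
        cfg = NullConfig(n_resamples=500, seed=4)
        t1, _ = score_all_modules(profiles, coll, AAFC, cfg)
        t2, _ = score_all_modules(profiles[::-1], coll, AAFC, cfg)
        assert np.allclose(t1.to_numpy(), t2[t1.columns].to_numpy())

    def test_empty_collection_gives_empty_table(self, rng):
        profiles, _ = self.make_inputs(rng, n_mod=4)
        table, results = score_all_modules(
            profiles, GeneSetCollection(sets=[]), AAFC, NullConfig(n_resamples=100, seed=0)
        )
        assert table.empty or table.shape[0] == 0
        assert results == []

    def test_unmatched_module_becomes_nan_cell(self, rng):
        profiles, coll = self.make_inputs(rng, n_mod=2)
        coll.sets.append(GeneSet("orphan", "", ("NOT_IN_PROFILE",)))
        table, _ = score_all_modules(profiles, coll, AAFC,
                                     NullConfig(n_resamples=100, seed=0))
        assert table.loc["orphan"].isna().all()
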