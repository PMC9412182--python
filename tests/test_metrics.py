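import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pandas as pd
import phylohotspots as ph
from conftest import make_counties, make_occ, make_taxa, random_instance
from _oracles import pd_bruteforce, pe_bruteforce, richness_recount, we_bruteforce


class TestSpeciesRichness:
    def test_counts_and_empty_subset(self):
        occ = make_occ([("s1", "c1"), ("s2", "c1"), ("s3", "c1"), ("s1", "c2")])
        rich = ph.species_richness(occ)
        assert rich.values["c1"] == 3
        assert rich.values["c2"] == 1
        thr = ph.species_richness(occ, ph.STANDARD_SUBSETS["threatened"])
        assert (thr.values == 0).all()

    def test_matches_independent_recount(self):
        rng = np.random.default_rng(0)
        _, occ = random_instance(rng, max_tips=20, max_counties=50)
        rich = ph.species_richness(occ)
        expect = richness_recount(occ)
        for c, v in expect.items():
            assert rich.values[c] == v


class TestFaithPD:
    def test_empty_set_is_zero(self):
        phylo = ph.simulate_phylogeny(5, seed=0)
        assert ph.faith_pd(phylo, set()) == 0.0

    def test_all_tips_give_total_length(self):
        phylo = ph.simulate_phylogeny(8, seed=1)
        assert ph.faith_pd(phylo, set(phylo.tip_labels)) == pytest.approx(
            phylo.total_length, abs=1e-9)

    def test_unknown_tip_rejected(self):
        phylo = ph.simulate_phylogeny(5, seed=0)
        with pytest.raises(ValueError):
            ph.faith_pd(phylo, {"nope"})

    def test_matches_edge_union_enumeration(self):
        phylo = ph.simulate_phylogeny(12, seed=2)
        tips = sorted(phylo.tip_labels)
        rng = np.random.default_rng(3)
        for _ in range(200):
            k = int(rng.integers(0, len(tips) + 1))
            subset = set(rng.choice(tips, size=k, replace=False))
            assert ph.faith_pd(phylo, subset) == pytest.approx(
                pd_bruteforce(phylo, subset), abs=1e-9)

    def test_monotone_under_inclusion(self):
        phylo = ph.simulate_phylogeny(15, seed=4)
        tips = sorted(phylo.tip_labels)
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = set(rng.choice(tips, size=int(rng.integers(1, 10)),
                               replace=False))
            b = a | set(rng.choice(tips, size=3, replace=False))
            assert ph.faith_pd(phylo, a) <= ph.faith_pd(phylo, b) + 1e-12

    def test_single_tip_without_root_path_is_zero(self):
        phylo = ph.simulate_phylogeny(6, seed=6)
        t = phylo.tip_labels[0]
        assert ph.faith_pd(phylo, {t}, include_root=False) == 0.0
        assert ph.faith_pd(phylo, {t}, include_root=True) > 0.0


class TestPDPattern:
    def test_county_with_all_tips_has_total_length(self):
        phylo = ph.simulate_phylogeny(6, seed=0)
        pairs = [(t, "c1") for t in phylo.tip_labels] + \
                [(phylo.tip_labels[0], "c2")]
        occ = make_occ(pairs)
        pat = ph.pd_pattern(phylo, occ)
        assert pat.values["c1"] == pytest.approx(phylo.total_length, abs=1e-9)

    def test_off_tree_only_county_is_zero(self):
        phylo = ph.simulate_phylogeny(4, seed=1)
        tips = phylo.tip_labels
        taxa = make_taxa(sorted(tips) + ["off1"],
                         on_tree=[True] * 4 + [False])
        occ = make_occ([(tips[0], "c1"), ("off1", "c2")], taxa=taxa,
                       counties=make_counties(["c1", "c2"]))
        pat = ph.pd_pattern(phylo, occ)
        assert pat.values["c2"] == 0.0

    def test_monotone_when_taxon_sets_nested(self):
        phylo = ph.simulate_phylogeny(10, seed=2)
        tips = sorted(phylo.tip_labels)
        pairs = [(t, "big") for t in tips] + [(t, "small") for t in tips[:4]]
        occ = make_occ(pairs)
        pat = ph.pd_pattern(phylo, occ)
        assert pat.values["small"] <= pat.values["big"]


class TestPhylogeneticEndemism:
    def test_single_county_pe_equals_pd(self):
        phylo = ph.simulate_phylogeny(7, seed=0)
        occ = make_occ([(t, "c1") for t in phylo.tip_labels])
        pe = ph.phylogenetic_endemism(phylo, occ)
        pdv = ph.pd_pattern(phylo, occ)
        assert pe.values["c1"] == pytest.approx(pdv.values["c1"], abs=1e-9)

    def test_two_identical_counties_split_pd(self):
        phylo = ph.simulate_phylogeny(7, seed=1)
        pairs = [(t, c) for t in phylo.tip_labels for c in ("c1", "c2")]
        occ = make_occ(pairs)
        pe = ph.phylogenetic_endemism(phylo, occ)
        pdv = ph.pd_pattern(phylo, occ)
        for c in ("c1", "c2"):
            assert pe.values[c] == pytest.approx(pdv.values[c] / 2, abs=1e-9)

    def test_matches_branch_county_double_loop(self):
        rng = np.random.default_rng(7)
        phylo = ph.simulate_phylogeny(10, seed=8)
        tips = sorted(phylo.tip_labels)
        county_ids = [f"c{i}" for i in range(6)]
        pairs = []
        for t in tips:
            k = int(rng.integers(1, 7))
            pairs += [(t, str(c)) for c in
                      rng.choice(county_ids, size=k, replace=False)]
        occ = make_occ(pairs, counties=make_counties(county_ids))
        pe = ph.phylogenetic_endemism(phylo, occ)
        expect = pe_bruteforce(phylo, occ)
        for c, v in expect.items():
            assert pe.values[c] == pytest.approx(v, abs=1e-9)

    def test_pe_bounded_by_pd_and_sums_to_total(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            phylo, occ = random_instance(rng, max_tips=25, max_counties=15)
            pe = ph.phylogenetic_endemism(phylo, occ)
            pdv = ph.pd_pattern(phylo, occ)
            assert ((pe.values <= pdv.values + 1e-9) &
                    (pe.values >= -1e-12)).all()
            on_tree = {t for t in occ.recorded_taxa
                       if occ.taxa.loc[t, "on_tree"]}
            assert pe.values.sum() == pytest.approx(
                ph.faith_pd(phylo, on_tree), abs=1e-9)


class TestWeightedEndemism:
    def test_single_county_endemic_contributes_one(self):
        occ = make_occ([("s1", "c1"), ("s2", "c1"), ("s2", "c2")])
        we = ph.weighted_endemism(occ)
        assert we.values["c1"] == pytest.approx(1.5)
        assert we.values["c2"] == pytest.approx(0.5)

    def test_identical_composition_halves(self):
        pairs = [(f"s{i}", c) for i in range(4) for c in ("c1", "c2")]
        we = ph.weighted_endemism(make_occ(pairs))
        assert we.values["c1"] == pytest.approx(2.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(11)
        _, occ = random_instance(rng, max_tips=30, max_counties=15)
        we = ph.weighted_endemism(occ)
        expect = we_bruteforce(occ)
        for c, v in expect.items():
            assert we.values[c] == pytest.approx(v, abs=1e-12)

    def test_sums_to_recorded_taxon_count(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            _, occ = random_instance(rng, max_tips=20, max_counties=12)
            we = ph.weighted_endemism(occ)
            assert we.values.sum() == pytest.approx(len(occ.recorded_taxa),
                                                    abs=1e-9)


class TestStandardize:
    def test_ratio_to_max(self):
        pat = ph.PatternVector("x", pd.Series([2.0, 4.0, 8.0],
                                              index=["a", "b", "c"]))
        std = ph.standardize(pat)
        assert list(std.standardized) == [0.25, 0.5, 1.0]

    def test_all_zero_stays_zero(self):
        pat = ph.PatternVector("x", pd.Series([0.0, 0.0], index=["a", "b"]))
        std = ph.standardize(pat)
        assert (std.standardized == 0).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                    min_size=1, max_size=30))
    def test_idempotent_with_unit_max(self, vals):
        pat = ph.PatternVector("x", pd.Series(
            vals, index=[f"c{i}" for i in range(len(vals))]))
        once = ph.standardize(pat)
        twice = ph.standardize(ph.PatternVector("x", once.standardized))
        assert np.allclose(once.standardized, twice.standardized)
        if max(vals) > 0:
            assert once.standardized.max() == pytest.approx(1.0)


class TestCombinedScore:
    def _stds(self, seed=0):
        phylo, occ = random_instance(np.random.default_rng(seed),
                                     max_tips=15, max_counties=10)
        return (ph.standardize(ph.pd_pattern(phylo, occ)),
                ph.standardize(ph.phylogenetic_endemism(phylo, occ)),
                ph.standardize(ph.weighted_endemism(occ)))

    def test_range_and_argmax_stability(self):
        pdv, pe, we = self._stds()
        comb = ph.phylo_combined_score(pdv, pe, we)
        assert ((comb.values >= 0) & (comb.values <= 3 + 1e-12)).all()
        std = ph.standardize(comb)
        assert std.standardized.idxmax() == comb.values.idxmax()
        assert std.standardized.max() == pytest.approx(1.0)

    def test_requires_standardized_and_matching_counties(self):
        pdv, pe, we = self._stds(1)
        raw = ph.PatternVector("PD", pdv.values)
        with pytest.raises(ValueError):
            ph.phylo_combined_score(raw, pe, we)
        shrunk = ph.PatternVector("WE", we.values.iloc[:-1],
                                  we.standardized.iloc[:-1])
        with pytest.raises(ValueError):
            ph.phylo_combined_score(pdv, pe, shrunk)
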