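"""Guest-tree simulator closed forms, rate estimation, synthetic fixtures."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from wgdkit.core_io import write_newick
from wgdkit.dup_age import filter_duplicate_pairs, single_linkage_families
from wgdkit.errors import InsufficientDataError
from wgdkit.maps_core import OccupancyRule, map_duplications, maps_profile
from wgdkit.simulate import (BirthDeathRates, WgdEvent, bd_transition_probs,
                             build_null_set, build_positive_set, family_counts,
                             estimate_rates, ladder_species_tree,
                             simulate_guest_tree, synth_hit_table,
                             synth_ks_sample)


@pytest.fixture(scope="module")
def ladder6():
    return ladder_species_tree(list("ABCDEF"), branch_length=50.0)


def copy_numbers(tree):
    return Counter(tree.taxon_of(l) for l in tree.root.leaf_labels())


class TestClosedForms:
    def test_no_events_gives_species_tree_copy(self, ladder6):
        tree = simulate_guest_tree(ladder6, BirthDeathRates(0, 0), seed=0)
        assert copy_numbers(tree) == {t: 1 for t in "ABCDEF"}
        # topology congruent with the species tree: same nested clades
        clades = {frozenset(t.split("_")[0] for t in n.leaf_labels())
                  for n in tree.root.postorder() if not n.is_leaf}
        expected = {frozenset(n.leaf_labels())
                    for n in ladder6.root.postorder() if not n.is_leaf}
        assert clades == expected

    def test_root_wgd_full_retention_doubles_every_taxon(self, ladder6):
        tree = simulate_guest_tree(
            ladder6, BirthDeathRates(0, 0),
            wgd_events=[WgdEvent(node="N5", retention=1.0)], seed=1)
        assert copy_numbers(tree) == {t: 2 for t in "ABCDEF"}
        events = map_duplications(tree, ladder6)
        assert [e.mapped_node for e in events] == ["N5"]

    def test_mid_ladder_wgd_full_retention(self, ladder6):
        tree = simulate_guest_tree(
            ladder6, BirthDeathRates(0, 0),
            wgd_events=[WgdEvent(node="N3", retention=1.0)], seed=2)
        assert copy_numbers(tree) == {"A": 2, "B": 2, "C": 2, "D": 2,
                                      "E": 1, "F": 1}
        (event,) = map_duplications(tree, ladder6)
        assert event.mapped_node == "N3"

    def test_critical_process_mean_copy_number_is_one(self, ladder6):
        rates = BirthDeathRates(0.002, 0.002)
        rng = np.random.default_rng(7)
        taxa = sorted(ladder6.taxa())
        counts = np.zeros((2000, len(taxa)))
        for i in range(2000):
            tree = simulate_guest_tree(ladder6, rates, seed=rng,
                                       condition=False)
            if tree is not None:
                c = copy_numbers(tree)
                counts[i] = [c.get(t, 0) for t in taxa]
        mean = counts.mean(axis=0)
        se = counts.std(axis=0) / math.sqrt(counts.shape[0])
        assert np.all(np.abs(mean - 1.0) <= 3 * se)

    def test_pure_birth_mean_matches_yule_expectation(self):
        # mu=0: expected copies per taxon e^{lambda * root-to-tip path}
        sp = ladder_species_tree(["A", "B", "C"], branch_length=100.0)
        lam = 0.004
        rng = np.random.default_rng(8)
        total = 0
        n = 1500
        for _ in range(n):
            tree = simulate_guest_tree(sp, BirthDeathRates(lam, 0.0),
                                       seed=rng, condition=False)
            total += copy_numbers(tree).get("C", 0)
        depth = 200.0  # C's root-to-tip path
        expected = math.exp(lam * depth)
        se = math.sqrt(expected * (expected - 1) * 2) / math.sqrt(n)
        assert abs(total / n - expected) <= 4 * max(se, 0.05)


class TestSimulatorInvariants:
    def test_leaves_are_species_tips_and_tree_binary(self, ladder6):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tree = simulate_guest_tree(ladder6, BirthDeathRates(0.003, 0.003),
                                       seed=rng)
            for node in tree.root.postorder():
                assert len(node.children) in (0, 2)
                if node.is_leaf:
                    assert tree.taxon_of(node.label) in set("ABCDEF")

    def test_conditioned_trees_cover_all_taxa(self, ladder6):
        rng = np.random.default_rng(10)
        for _ in range(20):
            tree = simulate_guest_tree(ladder6, BirthDeathRates(0.004, 0.004),
                                       seed=rng)
            assert tree.leaf_taxa() == set("ABCDEF")


class TestSimulationSets:
    def test_null_set_reproducible_and_plan_shapes(self, ladder6):
        rates = BirthDeathRates(0.002, 0.002)
        s1 = build_null_set(ladder6, rates, n=40, subset=20, n_resamples=5,
                            seed=3)
        s2 = build_null_set(ladder6, rates, n=40, subset=20, n_resamples=5,
                            seed=3)
        assert len(s1.trees) == 40 and len(s1.resample_indices) == 5
        assert all(len(i) == 20 for i in s1.resample_indices)
        assert [write_newick(a.root) for a in s1.trees] == \
            [write_newick(b.root) for b in s2.trees]
        assert all(np.array_equal(a, b) for a, b in
                   zip(s1.resample_indices, s2.resample_indices))

    def test_subset_larger_than_pool_rejected(self, ladder6):
        with pytest.raises(ValueError, match="subset"):
            build_null_set(ladder6, BirthDeathRates(0.002, 0.002),
                           n=10, subset=20, n_resamples=2, seed=0)

    def test_zero_retention_positive_matches_null(self, ladder6):
        # a WGD that retains nothing is statistically a null set
        rates = BirthDeathRates(0.002, 0.002)
        rule = OccupancyRule(0.45)
        pct_null, pct_r0 = [], []
        for i in range(12):
            null = build_null_set(ladder6, rates, n=120, subset=1,
                                  n_resamples=0, seed=100 + i)
            r0 = build_positive_set(ladder6, rates, wgd_node="N3",
                                    retention=0.0, n=120, subset=1,
                                    n_resamples=0, seed=300 + i)
            pct_null.append(maps_profile(null.trees, ladder6, rule).pct_dup("N3"))
            pct_r0.append(maps_profile(r0.trees, ladder6, rule).pct_dup("N3"))
        assert stats.ks_2samp(pct_null, pct_r0).pvalue > 0.01

    def test_partial_retention_enriches_target_node(self, ladder6):
        rates = BirthDeathRates(0.002, 0.002)
        rule = OccupancyRule(0.45)
        wins = 0
        for i in range(10):
            null = build_null_set(ladder6, rates, n=100, subset=1,
                                  n_resamples=0, seed=500 + i)
            pos = build_positive_set(ladder6, rates, wgd_node="N3",
                                     retention=0.2, n=100, subset=1,
                                     n_resamples=0, seed=700 + i)
            base = maps_profile(null.trees, ladder6, rule).pct_dup("N3")
            lifted = maps_profile(pos.trees, ladder6, rule).pct_dup("N3")
            wins += lifted > base
        assert wins >= 9


class TestRateEstimation:
    def test_all_single_copy_families_give_zero_rates(self, ladder6):
        counts = [{t: 1 for t in "ABCDEF"}] * 60
        rates = estimate_rates(counts, ladder6)
        assert rates.birth == 0.0 and rates.death == 0.0

    def test_too_few_families_error(self, ladder6):
        with pytest.raises(InsufficientDataError):
            estimate_rates([{t: 1 for t in "ABCDEF"}] * 10, ladder6)

    def test_transition_probabilities_are_distributions(self):
        for birth, death in [(0.002, 0.002), (0.004, 0.001), (0.0, 0.003)]:
            P = bd_transition_probs(birth, death, 50.0, 20)
            assert np.all(P >= 0)
            # rows sum to <=1 (mass beyond the truncation is dropped)
            assert np.all(P.sum(axis=1) <= 1 + 1e-12)
            assert P[1].sum() > 0.999

    def test_likelihood_higher_at_true_rates_than_doubled(self, ladder6):
        from wgdkit.simulate import _count_patterns, _loglik_counts
        rng = np.random.default_rng(11)
        rates = BirthDeathRates(0.002, 0.002)
        trees = [simulate_guest_tree(ladder6, rates, seed=rng)
                 for _ in range(400)]
        counts = family_counts(trees)
        taxa = sorted(ladder6.taxa())
        patterns, mult = _count_patterns(counts, taxa)
        ll_true = _loglik_counts(0.002, 0.002, ladder6.root, patterns, mult,
                                 taxa, 20)
        ll_double = _loglik_counts(0.004, 0.004, ladder6.root, patterns, mult,
                                   taxa, 20)
        assert ll_true > ll_double

    def test_recovery_smoke(self, ladder6):
        rng = np.random.default_rng(12)
        rates = BirthDeathRates(0.002, 0.002)
        trees = [simulate_guest_tree(ladder6, rates, seed=rng)
                 for _ in range(300)]
        est = estimate_rates(family_counts(trees), ladder6)
        assert 0.001 <= est.birth <= 0.004
        assert 0.001 <= est.death <= 0.004


class TestSyntheticFixtures:
    def test_empty_peaks_pure_null_and_zero_n(self):
        ages = synth_ks_sample(1.5, peaks=[], n=500, seed=0)
        assert len(ages.records) == 500
        assert all(0.01 < r.ks <= 2.0 for r in ages.records)
        assert synth_ks_sample(1.5, n=0, seed=0).records == []

    def test_hit_table_round_trips_requested_families(self):
        fams = [{"a", "b", "c"}, {"d", "e"}]
        hits = synth_hit_table(fams, seed=1)
        pairs = filter_duplicate_pairs(hits)
        got = [set(f.members) for f in single_linkage_families(pairs)]
        assert sorted(got, key=min) == sorted(fams, key=min)
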