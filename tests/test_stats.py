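"""Permutation machinery, parsimony, BH correction, candidate-locus tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from beclone import (CandidatePlacement, bh_correct, classify_upper_lower,
                     clustering_test, dispersion_test, expansion_test,
                     ordering_test, parsimony_changes, permutation_pvalue,
                     subclonality_tests)
from beclone.model import Clade, PhylogenyForest

from conftest import make_forest


# ---------------------------------------------------------------------------
# permutation p values
# ---------------------------------------------------------------------------

class TestPermutationP:
    def test_all_resamples_less_extreme(self):
        rng = np.random.default_rng(0)
        p, repr_ = permutation_pvalue(1, np.full(10_000, 5.0), "one", rng,
                                      direction="less")
        assert p == 1 / 10_000
        assert repr_.startswith("<")

    def test_all_ties_near_half(self):
        rng = np.random.default_rng(1)
        ps = [permutation_pvalue(3.0, np.full(1000, 3.0), "one", rng,
                                 direction="less")[0] for _ in range(200)]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_two_tailed_median_observation(self):
        rng = np.random.default_rng(2)
        res = rng.normal(size=10_001)
        p, _ = permutation_pvalue(float(np.median(res)), res, "two", rng)
        assert p > 0.9

    def test_two_tailed_doubles_smaller_tail(self):
        rng = np.random.default_rng(3)
        res = np.arange(1000, dtype=float)
        p, _ = permutation_pvalue(100.0, res, "two", rng)
        assert p == pytest.approx(0.2, abs=0.01)


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------

class TestBH:
    def test_single_p_unchanged(self):
        assert bh_correct([0.07]) == pytest.approx([0.07])

    def test_hand_stepup(self):
        # q_(i) = min_{j>=i} p_(j) * m / j  ->  all 0.03 here
        assert bh_correct([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        q = bh_correct(p)
        perm = rng.permutation(20)
        assert bh_correct(p[perm]) == pytest.approx(q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty(self):
        assert len(bh_correct([])) == 0


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _brute_force_min(tree: Clade, states: dict, cost_fn) -> float:
    """Exhaustive minimum over all internal-node state assignments."""
    internal = [n for n in tree.walk() if not n.is_tip]
    tip_vals = sorted({states[t.tip.biopsy_id] for t in tree.tips()})
    best = np.inf
    for combo in itertools.product(tip_vals, repeat=len(internal)):
        val = dict(zip(map(id, internal), combo))

        def state(n):
            return states[n.tip.biopsy_id] if n.is_tip else val[id(n)]

        cost = sum(cost_fn(state(n.parent), state(n))
                   for n in tree.walk() if n.parent is not None)
        best = min(best, cost)
    return best


class TestParsimony:
    def test_clustered_tree_single_change(self):
        forest = make_forest("P", (0, [(0, [("A-1", 0, 1), ("B-1", 0, 1)]),
                                       (0, [("C-1", 0, 1), ("D-1", 0, 1)])]))
        states = {"A": "L", "B": "L", "C": "U", "D": "U"}
        assert parsimony_changes(forest, states) == 1

    def test_interleaved_tree_two_changes(self):
        forest = make_forest("P", (0, [(0, [("A-1", 0, 1), ("B-1", 0, 1)]),
                                       (0, [("C-1", 0, 1), ("D-1", 0, 1)])]))
        states = {"A": "L", "B": "U", "C": "L", "D": "U"}
        assert parsimony_changes(forest, states) == 2

    def test_ordered_three_tips_any_topology(self):
        # total linear-cost change for values 2, 5, 10 is the range, 8
        forest = make_forest("P", (0, [("A-1", 0, 1),
                                       (0, [("B-1", 0, 1), ("C-1", 0, 1)])]))
        states = {"A": 2.0, "B": 5.0, "C": 10.0}
        assert parsimony_changes(forest, states, mode="ordered") == 8
        star = make_forest("P", (0, [("A-1", 0, 1), ("B-1", 0, 1),
                                     ("C-1", 0, 1)]))
        assert parsimony_changes(star, states, mode="ordered") == 8

    def test_disjoint_trees_score_no_changes(self):
        forest = make_forest("P", (0, [("A-1", 0, 1), ("B-1", 0, 1)]),
                             (0, [("C-1", 0, 1), ("D-1", 0, 1)]))
        states = {"A": "L", "B": "L", "C": "U", "D": "U"}
        assert parsimony_changes(forest, states) == 0

    def test_matches_brute_force_on_random_trees(self):
        from test_acceptance import random_forest_tree
        rng = np.random.default_rng(5)
        for _ in range(30):
            tree, biopsies = random_forest_tree(rng, n_tips=int(rng.integers(4, 9)))
            forest = PhylogenyForest("P", [tree])
            labels = {b: rng.choice(["U", "L"]) for b in biopsies}
            got = parsimony_changes(forest, labels)
            want = _brute_force_min(tree, labels, lambda a, b: a != b)
            assert got == want
            vals = {b: float(rng.integers(0, 3)) for b in biopsies}
            got_o = parsimony_changes(forest, vals, mode="ordered")
            want_o = _brute_force_min(tree, vals, lambda a, b: abs(a - b))
            assert got_o == want_o

    def test_unlabeled_tip_errors(self):
        forest = make_forest("P", (0, [("A-1", 0, 1), ("B-1", 0, 1)]))
        with pytest.raises(ValueError, match="unlabeled"):
            parsimony_changes(forest, {"A": "L"})


class TestUpperLower:
    def test_basic_split(self):
        labels = classify_upper_lower({"A": 1, "B": 2, "C": 5})
        assert labels == {"A": "L", "B": "L", "C": "U"}

    def test_equidistant_tie_goes_upper(self):
        labels = classify_upper_lower({"A": 1, "B": 3, "C": 5})
        assert labels == {"A": "L", "B": "U", "C": "U"}

    def test_equidistant_joins_minority(self):
        labels = classify_upper_lower({"A": 1, "B": 2, "C": 3, "D": 5})
        # L={A,B}, U={D}; C equidistant joins the smaller group U
        assert labels["C"] == "U"

    def test_all_same_distance_excluded(self):
        assert classify_upper_lower({"A": 4, "B": 4, "C": 4}) is None


# ---------------------------------------------------------------------------
# clustering / subclonality tests on constructed cohorts
# ---------------------------------------------------------------------------

def _meta(rows):
    return pd.DataFrame(rows, columns=["patient", "biopsy", "sample",
                                       "time_point", "gej_cm", "outcome",
                                       "ploidy_class", "gd_corroborated"])


def _clustered_forest(pid):
    return make_forest(pid, (50, [(40, [("A-1", 0, .8), ("B-1", 0, .7)]),
                                  (40, [("C-1", 0, .9), ("D-1", 0, .6)])]))


def _patient_meta(pid, cms, outcome="CO"):
    return [(pid, b, f"{pid}_{b}", "TP1" if i < 2 else "TP2", cm, outcome,
             "near_diploid", False)
            for i, (b, cm) in enumerate(zip("ABCD", cms))]


class TestClusteringTest:
    def test_perfectly_clustered_small_p(self):
        forests = {f"P{i}": _clustered_forest(f"P{i}") for i in range(6)}
        meta = _meta(sum((_patient_meta(f"P{i}", [1, 2, 7, 8])
                          for i in range(6)), []))
        res = clustering_test(forests, meta, "upper_lower",
                              n_resamples=2000, seed=0)
        assert res.observed == 6  # one change per patient
        assert res.p_value < 0.05

    def test_identical_labels_tie_half(self):
        # every biopsy from the same time point: observed changes = 0 and
        # every permutation ties, so p hovers at 1/2 by the tie rule
        forests = {"P0": _clustered_forest("P0")}
        rows = [("P0", b, f"P0_{b}", "TP1", cm, "NCO", "near_diploid", False)
                for b, cm in zip("ABCD", [1, 2, 7, 8])]
        meta = _meta(rows)
        ps = [clustering_test(forests, meta, "time_point",
                              n_resamples=500, seed=s).p_value
              for s in range(40)]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.15)

    def test_gej_cm_ordered_variant_runs(self):
        forests = {f"P{i}": _clustered_forest(f"P{i}") for i in range(4)}
        meta = _meta(sum((_patient_meta(f"P{i}", [1, 2, 7, 8])
                          for i in range(4)), []))
        res = clustering_test(forests, meta, "gej_cm", n_resamples=1000, seed=1)
        assert res.p_value < 0.1
        assert res.observed <= res.null_mean


class TestSubclonality:
    def test_no_subclonal_samples_p_near_one(self):
        forests = {f"P{i}": _clustered_forest(f"P{i}") for i in range(4)}
        meta = _meta(sum((_patient_meta(f"P{i}", [1, 2, 7, 8],
                                        outcome="CO" if i % 2 else "NCO")
                          for i in range(4)), []))
        results = subclonality_tests(forests, meta, n_resamples=500, seed=0)
        assert len(results) == 4
        for r in results:
            assert r.p_value > 0.9  # statistic is permutation-invariant

    def test_concentrated_subclonality_detected(self):
        # P0 has all four biopsies subclonal; 7 other patients none
        sub = make_forest("P0", (50, [
            (40, [("A-1", 0, .5), ("A-2", 0, .3), ("B-1", 0, .6),
                  ("B-2", 0, .2)]),
            (40, [("C-1", 0, .5), ("C-2", 0, .3), ("D-1", 0, .6),
                  ("D-2", 0, .2)])]))
        forests = {"P0": sub}
        for i in range(1, 8):
            forests[f"P{i}"] = _clustered_forest(f"P{i}")
        meta = _meta(sum((_patient_meta(f"P{i}", [1, 2, 7, 8],
                                        outcome="CO" if i % 2 else "NCO")
                          for i in range(8)), []))
        results = subclonality_tests(forests, meta, n_resamples=2000, seed=0)
        clustering = results[0]
        assert clustering.observed == 1  # one patient holds all 4
        assert clustering.p_value < 0.05


# ---------------------------------------------------------------------------
# candidate-locus tests on toy forests
# ---------------------------------------------------------------------------

def _toy_forest():
    # root(100) -> [tipA(0), inner(50) -> tipB, tipC]
    return make_forest("P0", (100, [("A-1", 0, 0.5),
                                    (50, [("B-1", 0, 0.6), ("C-1", 0, 0.7)])]))


def _inner_label(forest):
    return [n.label for n in forest.branches()
            if not n.is_tip and n.parent is not None][0]


class TestExpansion:
    def test_root_mutation_covers_all_tips(self):
        forests = {"P0": _toy_forest()}
        placements = {"P0": [CandidatePlacement("TP53", 0, "T0.0",
                                                "heterozygous")]}
        leaves, cf = expansion_test(forests, placements, "TP53",
                                    n_resamples=200, seed=0)
        assert leaves.observed == 3
        assert cf.observed == pytest.approx(1.8)

    def test_null_mean_matches_enumeration(self):
        """Re-placement is branch-length-weighted, so the null mean equals
        the exhaustive weighted average over branches."""
        forests = {"P0": _toy_forest()}
        inner = _inner_label(forests["P0"])
        placements = {"P0": [CandidatePlacement("TP53", 0, inner,
                                                "heterozygous")]}
        leaves, cf = expansion_test(forests, placements, "TP53",
                                    n_resamples=20_000, seed=1)
        # branches: root len 100 (3 leaves), inner len 50 (2 leaves),
        # tips len 0 each
        exact = (100 * 3 + 50 * 2) / 150
        assert leaves.null_mean == pytest.approx(exact, rel=0.02)
        exact_cf = (100 * 1.8 + 50 * 1.3) / 150
        assert cf.null_mean == pytest.approx(exact_cf, rel=0.02)

    def test_hom_filter_counts_secondary_subtree(self):
        forests = {"P0": _toy_forest()}
        placements = {"P0": [CandidatePlacement(
            "CDKN2A", 0, "T0.0", "heterozygous", secondary_events=["B-1"])]}
        leaves_all, _ = expansion_test(forests, placements, "CDKN2A", "all",
                                       n_resamples=100, seed=2)
        leaves_hom, _ = expansion_test(forests, placements, "CDKN2A", "hom",
                                       n_resamples=100, seed=2)
        leaves_het, _ = expansion_test(forests, placements, "CDKN2A", "het",
                                       n_resamples=100, seed=2)
        assert leaves_all.observed == 3
        assert leaves_hom.observed == 1
        assert leaves_het.observed == 2


class TestDispersionAndOrdering:
    def test_single_mutation_p_near_one(self):
        forests = {"P0": _toy_forest(), "P1": _toy_forest()}
        forests["P1"].patient_id = "P1"
        placements = {"P0": [CandidatePlacement("TTN", 0, "T0.0",
                                                "heterozygous")]}
        ps = [dispersion_test(forests, placements, "TTN", n_resamples=500,
                              seed=s).p_value for s in range(20)]
        assert np.mean(ps) > 0.6  # observed == every resample; tie rule

    def test_ordering_configurations(self):
        forests = {"P0": _toy_forest()}
        inner = _inner_label(forests["P0"])

        def run(b1, b2):
            placements = {"P0": [
                CandidatePlacement("TP53", 0, b1, "heterozygous"),
                CandidatePlacement("CDKN2A", 1, b2, "heterozygous")]}
            return ordering_test(forests, placements, "TP53", "CDKN2A",
                                 n_resamples=100, seed=0)

        res = run("T0.0", inner)  # root ancestral to inner
        assert res.extra["observed_counts"] == [0, 1, 0, 0]  # A_first
        res = run(inner, inner)
        assert res.extra["observed_counts"] == [1, 0, 0, 0]  # same branch
        res = run("A-1", "B-1")
        assert res.extra["observed_counts"] == [0, 0, 0, 1]  # skew

    def test_ordering_skew_across_disjoint_trees(self):
        forest = make_forest("P0", (10, [("A-1", 0, .5), ("B-1", 0, .5)]),
                             (10, [("C-1", 0, .5), ("D-1", 0, .5)]))
        placements = {"P0": [
            CandidatePlacement("TP53", 0, "T0.0", "heterozygous"),
            CandidatePlacement("CDKN2A", 1, "T1.0", "heterozygous")]}
        res = ordering_test({"P0": forest}, placements, "TP53", "CDKN2A",
                            n_resamples=100, seed=0)
        assert res.extra["observed_counts"] == [0, 0, 0, 1]
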