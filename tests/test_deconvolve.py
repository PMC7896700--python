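"""Peak interpretation, partition ordering, and forest assembly."""

import numpy as np
import pytest

from beclone import (DeconvConfig, SampleContext, UnresolvableError,
                     deconvolute_patient, interpret_multi_peaks,
                     order_partitions, vaf_peak_to_cf)
from beclone.deconvolve import (ChainUnit, LineageLevel, assemble_forest,
                                count_origins, estimate_tip_cfs)
from beclone.partition import CNGroup, SNVPartition, VAFPeak


class TestPeakToCF:
    @pytest.mark.parametrize("vaf,mut,total,cf", [
        (0.25, 1, 2, 0.50),   # diploid heterozygous
        (0.40, 2, 2, 0.40),   # homozygous: VAF equals CF
        (0.10, 1, 4, 0.40),   # tetraploid, post-doubling single copy
        (0.80, 1, 2, 1.00),   # capped at 1
    ])
    def test_arithmetic(self, vaf, mut, total, cf):
        assert vaf_peak_to_cf(vaf, mut, total) == pytest.approx(cf)

    def test_zero_mut_copies_rejected(self):
        with pytest.raises(ValueError):
            vaf_peak_to_cf(0.2, 0, 2)


class TestOrdering:
    def _part(self, samples, n):
        return SNVPartition("P", frozenset(samples), np.arange(n))

    def test_two_sample_first_more_snvs_break_ties(self):
        ab = self._part("AB", 500)
        ac = self._part("AC", 700)
        abc = self._part("ABC", 900)
        assert order_partitions([ab, ac, abc]) == [ac, ab, abc]

    def test_full_tie_lexicographic(self):
        ab = self._part("AB", 500)
        ac = self._part("AC", 500)
        assert order_partitions([ac, ab]) == [ab, ac]

    def test_singleton(self):
        ab = self._part("AB", 10)
        assert order_partitions([ab]) == [ab]


def _group(peaks_by_sample, signature):
    g = CNGroup(signature=signature, snv_idx=np.arange(500))
    g.peaks = {s: [VAFPeak(s, loc, w) for loc, w in pk]
               for s, pk in peaks_by_sample.items()}
    return g


class TestInterpretMultiPeaks:
    def _ctx(self, samples, gd=False):
        cls = "near_tetraploid" if gd else "near_diploid"
        return {s: SampleContext(s, cls, gd) for s in samples}

    def test_unbalanced_cn_one_lineage(self):
        # 2+1 region: haplotype peaks at CF/3 and 2 CF/3
        g = _group({"A": [(0.17, 170), (0.33, 330)]}, (("A", 2, 1),))
        hyp, levels = interpret_multi_peaks(g, self._ctx("A"))
        assert hyp == "unbalanced_cn"
        assert len(levels) == 1
        assert levels[0].cf["A"] == pytest.approx(0.5, abs=0.02)

    def test_genome_doubling_needs_corroboration(self):
        peaks = {"A": [(0.15, 250), (0.30, 250)]}
        sig = (("A", 2, 2),)
        hyp, levels = interpret_multi_peaks(
            _group(peaks, sig), self._ctx("A", gd=True))
        assert hyp == "genome_doubling"
        assert levels[0].gd is True
        assert levels[0].cf["A"] == pytest.approx(0.6)

        # same pattern without external corroboration: never genome doubling
        sig2 = (("A", 1, 1),)
        hyp2, levels2 = interpret_multi_peaks(
            _group({"A": [(0.15, 250), (0.30, 250)]}, sig2), self._ctx("A"))
        assert hyp2 == "split_lineages"
        assert not any(l.gd for l in levels2)

    def test_split_lineages_orders_depths(self):
        g = _group({"A": [(0.20, 200), (0.50, 300)],
                    "B": [(0.18, 200), (0.45, 300)]},
                   (("A", 1, 1), ("B", 1, 1)))
        hyp, levels = interpret_multi_peaks(g, self._ctx("AB"))
        assert hyp == "split_lineages"
        assert len(levels) == 2
        # ancestral level = higher CF
        assert levels[0].cf["A"] == pytest.approx(1.0)   # 0.5 * 2 capped
        assert levels[1].cf["A"] == pytest.approx(0.4)
        assert levels[0].n_snvs == pytest.approx(300)

    def test_too_many_levels_unresolvable(self):
        g = _group({"A": [(0.1, 150), (0.2, 150), (0.35, 150), (0.5, 150)]},
                   (("A", 1, 1),))
        with pytest.raises(UnresolvableError):
            interpret_multi_peaks(g, self._ctx("A"))


class _FakePData:
    """Minimal PatientData stand-in for assembly unit tests (synthetic)."""

    def __init__(self, biopsies):
        self.patient_id = "P"
        self.samples = [f"P_{b}" for b in biopsies]
        self.biopsy_of = {f"P_{b}": b for b in biopsies}
        self.context = {s: SampleContext(s) for s in self.samples}
        self.dropped_biopsies = []


def _chain(pid, cfs, n, gd=False):
    sset = frozenset(f"P_{b}" for b in cfs)
    lev = LineageLevel(cf={f"P_{b}": v for b, v in cfs.items()},
                       n_snvs=n, gd=gd)
    return ChainUnit(partition_id=pid, sample_set=sset, levels=[lev])


class TestAssembly:
    def test_superset_nesting(self):
        pdata = _FakePData("ABC")
        chains = [_chain(0, {"A": 0.6, "B": 0.8}, 500),
                  _chain(1, {"A": 0.6, "B": 0.8, "C": 0.7}, 400)]
        forest = assemble_forest(chains, pdata)
        assert len(forest.trees) == 1
        root = forest.trees[0]
        assert root.biopsies() == {"A", "B", "C"}
        inner = [c for c in root.children if not c.is_tip]
        assert len(inner) == 1 and inner[0].biopsies() == {"A", "B"}

    def test_polytomy_without_pairwise_support(self):
        pdata = _FakePData("ABC")
        forest = assemble_forest(
            [_chain(0, {"A": 0.9, "B": 0.8, "C": 0.7}, 1000)], pdata)
        root = forest.trees[0]
        assert len(root.children) == 3
        assert all(c.is_tip for c in root.children)

    def test_disjoint_trees_stay_disjoint(self):
        pdata = _FakePData("ABCD")
        chains = [_chain(0, {"A": 0.9, "B": 0.8}, 800),
                  _chain(1, {"C": 0.7, "D": 0.6}, 700)]
        forest = assemble_forest(chains, pdata)
        assert len(forest.trees) == 2

    def test_subclonal_split_on_overlap(self):
        # {A,B} at CF_A 0.6 and {A,C} at CF_A 0.3 fit within A's budget:
        # A splits into two lineages rather than conflicting
        pdata = _FakePData("ABC")
        chains = [_chain(0, {"A": 0.6, "B": 0.8}, 600),
                  _chain(1, {"A": 0.3, "C": 0.7}, 300)]
        forest = assemble_forest(chains, pdata)
        a_tips = [t for t in forest.tips() if t.tip.biopsy_id == "A"]
        assert len(a_tips) == 2
        assert sorted(round(t.tip.cell_fraction, 2) for t in a_tips) == [0.3, 0.6]

    def test_budget_conflict_reclassified_as_dropout(self):
        # {A,C} cannot fit A's CF budget next to {A,B}; its SNVs fold into
        # the compatible superset branch {A,B,C} as allelic dropout of B
        pdata = _FakePData("ABC")
        chains = [_chain(0, {"A": 0.9, "B": 0.8}, 900),
                  _chain(1, {"A": 0.8, "C": 0.3}, 100),
                  _chain(2, {"A": 0.9, "B": 0.8, "C": 0.3}, 400)]
        forest = assemble_forest(chains, pdata)
        assert forest.status == "resolved"
        assert len(forest.tips()) == 3
        assert any("dropout" in line for line in forest.assembly_log)
        # reclassified SNVs land on the superset branch
        assert forest.trees[0].n_snvs == 500

    def test_split_chain_creates_residual_tip(self):
        sset = frozenset({"P_A", "P_B"})
        chain = ChainUnit(partition_id=0, sample_set=sset, levels=[
            LineageLevel(cf={"P_A": 0.85, "P_B": 0.8}, n_snvs=400),
            LineageLevel(cf={"P_A": 0.25, "P_B": 0.8}, n_snvs=200),
        ])
        forest = assemble_forest([chain], _FakePData("AB"))
        a_tips = sorted((t.tip.cell_fraction for t in forest.tips()
                         if t.tip.biopsy_id == "A"))
        b_tips = [t for t in forest.tips() if t.tip.biopsy_id == "B"]
        assert a_tips == pytest.approx([0.25, 0.60])  # derived + residual
        assert len(b_tips) == 1                        # no residual in B


class TestTipCFs:
    def test_weighted_average_over_supporting_partitions(self):
        pdata = _FakePData("AB")
        chains = [_chain(0, {"A": 0.40, "B": 0.9}, 600),
                  _chain(1, {"A": 0.50, "B": 0.9}, 200)]
        # same sample set twice: forms a chain; tip CF averages over both
        forest = assemble_forest(chains, pdata)
        a_tip = next(t for t in forest.tips() if t.tip.biopsy_id == "A")
        assert a_tip.tip.cell_fraction == pytest.approx(0.425)

    def test_single_partition_cf(self):
        forest = assemble_forest([_chain(0, {"A": 0.44, "B": 0.8}, 100)],
                                 _FakePData("AB"))
        a_tip = next(t for t in forest.tips() if t.tip.biopsy_id == "A")
        assert a_tip.tip.cell_fraction == pytest.approx(0.44)


class TestRecoveryAndOrigins:
    def test_origin_count_excludes_thin_only_trees(self, small_sim):
        cohort, truths = small_sim
        for pid in cohort.patients:
            forest, parts, pdata = deconvolute_patient(cohort, pid)
            assert forest.status == "resolved"
            assert forest.origin_count == truths[pid].origin_count

    def test_gd_flag_only_with_corroboration(self, small_sim):
        cohort, truths = small_sim
        for pid in cohort.patients:
            forest, _parts, pdata = deconvolute_patient(cohort, pid)
            corroborated = {pdata.biopsy_of[s]
                            for s in pdata.samples
                            if pdata.context[s].gd_corroborated}
            for node in forest.branches():
                if node.gd:
                    assert node.biopsies() <= corroborated

    def test_per_biopsy_cf_sum_bounded(self, small_sim):
        cohort, _ = small_sim
        for pid in cohort.patients:
            forest, _p, _d = deconvolute_patient(cohort, pid)
            sums = {}
            for t in forest.tips():
                sums.setdefault(t.tip.biopsy_id, 0.0)
                sums[t.tip.biopsy_id] += t.tip.cell_fraction or 0.0
            assert all(v <= 1.05 + 1e-9 for v in sums.values())

    def test_topology_and_cf_recovery(self, small_sim):
        cohort, truths = small_sim
        for pid in cohort.patients:
            forest, _p, _d = deconvolute_patient(cohort, pid)
            assert forest.rf_distance(truths[pid].forest) == 0
            inferred = {t.tip.label: t.tip.cell_fraction
                        for t in forest.tips()}
            for label, cf in truths[pid].tip_cf.items():
                assert inferred[label] == pytest.approx(cf, abs=0.06)
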