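"""SNV partitioning, filters, and VAF peak detection."""

import numpy as np
import pandas as pd
import pytest

from beclone import Cohort, PartitionConfig, detect_peaks, fit_peak_weights
from beclone.partition import (PatientData, apply_loh_exclusion,
                               build_partitions, drop_thin_biopsies,
                               partition_snvs)
from sklearn.mixture import GaussianMixture


def _cohort_from_matrix(alt, meta_over=None, cn_rows=None, tot=60):
    """Cohort with one patient and explicit alt-read matrix (n_snvs x 3)."""
    alt = np.asarray(alt)
    samples = ["P1_A", "P1_B", "P1_C"]
    meta = pd.DataFrame({
        "patient": "P1", "biopsy": ["A", "B", "C"], "sample": samples,
        "time_point": ["TP1", "TP1", "TP2"], "gej_cm": [1.0, 2.0, 5.0],
        "outcome": "NCO", "ploidy_class": "near_diploid",
        "gd_corroborated": False,
    })
    if meta_over:
        for k, v in meta_over.items():
            meta[k] = v
    n = len(alt)
    snvs = pd.DataFrame({
        "patient": "P1", "chrom": "1", "pos": np.arange(1, n + 1) * 100,
        "ref": "A", "alt": "T", "severity": "MODIFIER", "locus": "",
    })
    for j, s in enumerate(samples):
        snvs[f"{s}_alt"] = alt[:, j]
        snvs[f"{s}_tot"] = tot
    if cn_rows is None:
        cn_rows = [{"sample": s, "chrom": "1", "start": 1, "end": 10_000_000,
                    "major": 1, "minor": 1} for s in samples]
    return Cohort(meta=meta, snvs=snvs, cn=pd.DataFrame(cn_rows))


class TestPartitioning:
    def test_detected_subset_keys_partition(self):
        alt = np.array([[20, 18, 0], [22, 25, 1], [15, 0, 30]])
        pdata = PatientData(_cohort_from_matrix(alt), "P1")
        parts = partition_snvs(pdata)
        keys = {tuple(sorted(b[-1] for b in p.sample_set)) for p in parts}
        assert keys == {("A", "B"), ("A", "C")}

    def test_all_private_flagged(self):
        alt = np.array([[20, 0, 0], [0, 25, 0], [0, 0, 30]])
        pdata = PatientData(_cohort_from_matrix(alt), "P1")
        parts = partition_snvs(pdata)
        assert all(p.private for p in parts)

    def test_partition_sizes_conserve_snvs(self):
        rng = np.random.default_rng(0)
        alt = rng.integers(0, 30, size=(200, 3))
        pdata = PatientData(_cohort_from_matrix(alt), "P1")
        parts = partition_snvs(pdata)
        detected_any = (alt >= 3).any(axis=1).sum()
        assert sum(p.size for p in parts) == detected_any


class TestLOHExclusion:
    def _pdata(self, c_minor):
        alt = np.array([[20, 18, 0]] * 5)  # detected in {A, B}, absent in C
        cn_rows = [{"sample": s, "chrom": "1", "start": 1, "end": 10_000_000,
                    "major": 1, "minor": 1} for s in ["P1_A", "P1_B"]]
        cn_rows.append({"sample": "P1_C", "chrom": "1", "start": 1,
                        "end": 10_000_000, "major": 2, "minor": c_minor})
        return PatientData(_cohort_from_matrix(alt, cn_rows=cn_rows), "P1")

    def test_absent_sample_with_loh_excludes(self):
        pdata = self._pdata(c_minor=0)  # 2+0: one haplotype lost
        (part,) = partition_snvs(pdata)
        kept, removed = apply_loh_exclusion(part, pdata)
        assert kept.size == 0 and len(removed) == 5

    def test_absent_sample_balanced_retains(self):
        pdata = self._pdata(c_minor=2)
        (part,) = partition_snvs(pdata)
        kept, removed = apply_loh_exclusion(part, pdata)
        assert kept.size == 5 and len(removed) == 0

    def test_present_everywhere_never_excluded(self):
        alt = np.array([[20, 18, 25]] * 5)
        cn_rows = [{"sample": s, "chrom": "1", "start": 1, "end": 10_000_000,
                    "major": 2, "minor": 0} for s in ["P1_A", "P1_B", "P1_C"]]
        pdata = PatientData(_cohort_from_matrix(alt, cn_rows=cn_rows), "P1")
        (part,) = partition_snvs(pdata)
        kept, removed = apply_loh_exclusion(part, pdata)
        assert kept.size == 5 and len(removed) == 0


class TestThinBiopsies:
    @pytest.mark.parametrize("n_c,expect_dropped", [(99, True), (100, False)])
    def test_boundary_at_100(self, n_c, expect_dropped):
        # A and B share 150 SNVs; C has n_c private SNVs only
        rows = [[20, 20, 0]] * 150 + [[0, 0, 20]] * n_c
        pdata = PatientData(_cohort_from_matrix(np.array(rows)), "P1")
        parts = partition_snvs(pdata)
        kept, dropped = drop_thin_biopsies(pdata, parts)
        assert (["P1_C"] == dropped) is expect_dropped

    def test_rich_biopsies_untouched(self):
        rows = [[20, 20, 20]] * 150
        pdata = PatientData(_cohort_from_matrix(np.array(rows)), "P1")
        parts = partition_snvs(pdata)
        kept, dropped = drop_thin_biopsies(pdata, parts)
        assert dropped == [] and kept[0].size == 150


class TestDetectPeaks:
    def test_unimodal_recovery(self):
        rng = np.random.default_rng(1)
        x = np.clip(rng.normal(0.25, 0.03, size=1000), 0, 1)
        peaks = detect_peaks(x)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(0.25, abs=0.02)

    def test_two_separated_clusters_vs_mixture_oracle(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.binomial(60, 0.15, 500) / 60,
                  rng.binomial(60, 0.45, 500) / 60]
        peaks = detect_peaks(x)
        assert len(peaks) == 2
        gm = GaussianMixture(2, random_state=0).fit(x.reshape(-1, 1))
        oracle = sorted(gm.means_.ravel())
        assert peaks[0] == pytest.approx(oracle[0], abs=0.02)
        assert peaks[1] == pytest.approx(oracle[1], abs=0.02)

    def test_constant_input_single_peak(self):
        assert detect_peaks([0.3] * 50) == [0.3]

    def test_binomial_noise_not_split(self):
        # a single 60x read-sampling cluster must yield one peak
        rng = np.random.default_rng(3)
        for vaf in (0.1, 0.25, 0.4):
            x = rng.binomial(60, vaf, size=400) / 60
            locs = detect_peaks(x)
            peaks = fit_peak_weights(x, locs)
            assert len(peaks) == 1, f"vaf={vaf} split into {locs}"


class TestPeakWeights:
    def test_weights_match_hard_assignment_oracle(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.binomial(60, 0.25, 800) / 60,
                  rng.binomial(60, 0.50, 300) / 60]
        peaks = fit_peak_weights(x, detect_peaks(x))
        assert len(peaks) == 2
        # oracle: hard assignment to the nearer center
        hard = np.array([np.abs(x - 0.25) <= np.abs(x - 0.50)]).sum()
        assert peaks[0].weight == pytest.approx(hard, rel=0.10)
        assert peaks[1].weight == pytest.approx(len(x) - hard, rel=0.10)

    def test_small_peak_discarded_at_100(self):
        rng = np.random.default_rng(5)
        x = np.r_[rng.binomial(60, 0.25, 950) / 60,
                  rng.binomial(60, 0.50, 50) / 60]
        peaks = fit_peak_weights(x, detect_peaks(x))
        assert len(peaks) == 1
        assert peaks[0].location == pytest.approx(0.25, abs=0.03)

    def test_single_cluster_weight_is_n(self):
        rng = np.random.default_rng(6)
        x = rng.binomial(60, 0.3, 500) / 60
        peaks = fit_peak_weights(x, detect_peaks(x))
        assert len(peaks) == 1 and peaks[0].weight == 500

    def test_weights_sum_to_group_size(self):
        rng = np.random.default_rng(7)
        x = np.r_[rng.binomial(60, 0.15, 400) / 60,
                  rng.binomial(60, 0.45, 600) / 60]
        peaks = fit_peak_weights(x, detect_peaks(x))
        assert sum(p.weight for p in peaks) == pytest.approx(1000, abs=1)


def test_build_partitions_log_reconciles(small_sim):
    cohort, _ = small_sim
    for pid in cohort.patients:
        pdata = PatientData(cohort, pid)
        parts, log = build_partitions(pdata)
        assert (sum(p.size for p in parts) + log["n_undetected"]
                + log["n_loh_excluded"] == log["n_snvs"])
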