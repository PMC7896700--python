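"""Partition SNVs by sample presence, subdivide by copy number, find VAF peaks.

The unit of phylogenetic evidence is the *partition*: the subset of a
patient's samples in which a group of SNVs is detected. Partitions are
subdivided into copy-number groups (same allele-specific call in every
member sample), each group's per-sample VAF histogram is scanned for peaks
with a Gaussian kernel smoother, and a Gaussian mixture assigns SNV counts
to peaks. Peaks below ``min_peak_snvs`` (default 100) are discarded, as are
groups left without a qualifying peak; SNVs whose absent samples show loss
of one haplotype (deletion or copy-neutral LOH) are excluded because their
ancestral presence cannot be determined; biopsies with no partition of 100+
SNVs are dropped from phylogenetic analysis entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Cohort


@dataclass
class PartitionConfig:
    min_peak_snvs: int = 100
    min_group_snvs: int = 100
    # floor chosen as ~1/3 of the binomial VAF noise scale at 60x depth;
    # a smaller floor lets read noise split single clusters into spurious maxima
    bandwidth_scale: float = 0.5
    bandwidth_floor: float = 0.02
    # mixture component spread is bounded by read-sampling noise at ~60x
    # (max binomial sd ~0.065); without the upper clamp a component can
    # stretch to absorb a neighboring small peak
    peak_sd_min: float = 0.01
    peak_sd_max: float = 0.09
    # fitted peaks closer than this are one read-noise cluster, not two
    # lineage signals (every true mechanism here separates peaks by more)
    peak_min_sep: float = 0.06
    merge_tol: float = 0.03
    detection_min_alt: int = 3
    min_partition_snvs: int = 100   # biopsy-retention / origin thresholds
    uncovered_cn_policy: str = "keep"  # SNV with no CN segment: keep | drop


@dataclass
class VAFPeak:
    sample_id: str
    location: float
    weight: float


@dataclass
class CNGroup:
    signature: tuple              # ((sample, major, minor), ...) partition samples
    snv_idx: np.ndarray
    peaks: dict = field(default_factory=dict)  # sample -> [VAFPeak], ascending
    retained: bool = True

    @property
    def size(self) -> int:
        return len(self.snv_idx)


@dataclass
class SNVPartition:
    patient_id: str
    sample_set: frozenset
    snv_idx: np.ndarray
    private: bool = False
    cn_groups: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.snv_idx)


class PatientData:
    """Per-patient matrices derived from the cohort tables.

    Rows follow the patient's SNV table; columns follow ``samples``.
    ``det`` is the boolean detection matrix, ``vaf`` the observed VAFs, and
    ``major``/``minor`` the local allele-specific copy number per SNV.
    """

    def __init__(self, cohort: Cohort, patient_id: str,
                 config: PartitionConfig | None = None):
        self.config = config or PartitionConfig()
        self.patient_id = patient_id
        self.snvs = cohort.patient_snvs(patient_id)
        self.samples = cohort.samples_of(patient_id)
        meta = cohort.meta.set_index("sample")
        self.biopsy_of = {s: meta.loc[s, "biopsy"] for s in self.samples}
        self.context = {s: cohort.context_of(s) for s in self.samples}

        n, m = len(self.snvs), len(self.samples)
        alt = np.zeros((n, m)); tot = np.zeros((n, m))
        det_cols_present = all(f"{s}_det" in self.snvs.columns for s in self.samples)
        det = np.zeros((n, m), dtype=bool)
        for j, s in enumerate(self.samples):
            alt[:, j] = self.snvs[f"{s}_alt"].to_numpy(dtype=float)
            tot[:, j] = self.snvs[f"{s}_tot"].to_numpy(dtype=float)
            if det_cols_present:
                det[:, j] = self.snvs[f"{s}_det"].to_numpy(dtype=bool)
        self.det_from_threshold = not det_cols_present
        if not det_cols_present:
            det = alt >= self.config.detection_min_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
        self.alt, self.tot, self.det, self.vaf = alt, tot, det, vaf
        self.major, self.minor, self.cn_covered = self._cn_lookup(cohort)
        self.dropped_biopsies: list[str] = []
        self.log: dict = {"n_snvs": n}

    def _cn_lookup(self, cohort: Cohort):
        n, m = len(self.snvs), len(self.samples)
        major = np.ones((n, m), dtype=int)
        minor = np.ones((n, m), dtype=int)
        covered = np.zeros((n, m), dtype=bool)
        chrom = self.snvs["chrom"].to_numpy(dtype=str)
        pos = self.snvs["pos"].to_numpy(dtype=np.int64)
        for j, s in enumerate(self.samples):
            seg = cohort.cn_of(s)
            for c, sub in seg.groupby("chrom"):
                rows = np.flatnonzero(chrom == str(c))
                if len(rows) == 0:
                    continue
                sub = sub.sort_values("start")
                starts = sub["start"].to_numpy(dtype=np.int64)
                ends = sub["end"].to_numpy(dtype=np.int64)
                k = np.searchsorted(starts, pos[rows], side="right") - 1
                ok = (k >= 0) & (pos[rows] <= ends[np.clip(k, 0, None)])
                rr = rows[ok]
                kk = k[ok]
                major[rr, j] = sub["major"].to_numpy()[kk]
                minor[rr, j] = sub["minor"].to_numpy()[kk]
                covered[rr, j] = True
        return major, minor, covered


# ---------------------------------------------------------------------------
# partitioning and filters
# ---------------------------------------------------------------------------

def partition_snvs(pdata: PatientData, snv_idx: np.ndarray | None = None
                   ) -> list[SNVPartition]:
    """Group SNVs by the exact subset of samples in which they are detected.

    Single-sample (private) partitions are kept but flagged; they are never
    deconvoluted. SNVs detected nowhere are omitted.
    """
    idx = np.arange(len(pdata.snvs)) if snv_idx is None else snv_idx
    det = pdata.det[idx]
    # encode each detection pattern as an integer key
    codes = det @ (1 << np.arange(det.shape[1], dtype=np.int64))
    parts = []
    for code in np.unique(codes):
        if code == 0:
            continue
        members = idx[codes == code]
        sset = frozenset(s for j, s in enumerate(pdata.samples)
                         if code >> j & 1)
        parts.append(SNVPartition(pdata.patient_id, sset, members,
                                  private=len(sset) == 1))
    parts.sort(key=lambda p: sorted(p.sample_set))
    return parts


def apply_loh_exclusion(partition: SNVPartition, pdata: PatientData
                        ) -> tuple[SNVPartition, np.ndarray]:
    """Drop SNVs for which a sample *lacking* the SNV lost a haplotype there.

    With one parental copy gone (deletion or copy-neutral LOH) in an absent
    sample, the SNV's ancestral presence or absence in that sample cannot be
    recovered, so the SNV carries no reliable phylogenetic signal.
    """
    absent = [j for j, s in enumerate(pdata.samples)
              if s not in partition.sample_set]
    if not absent:
        return partition, np.array([], dtype=int)
    minor = pdata.minor[partition.snv_idx][:, absent]
    covered = pdata.cn_covered[partition.snv_idx][:, absent]
    bad = ((minor == 0) & covered).any(axis=1)
    if pdata.config.uncovered_cn_policy == "drop":
        bad |= ~covered.all(axis=1)
    removed = partition.snv_idx[bad]
    kept = SNVPartition(partition.patient_id, partition.sample_set,
                        partition.snv_idx[~bad], private=partition.private)
    return kept, removed


def drop_thin_biopsies(pdata: PatientData, partitions: list[SNVPartition]
                       ) -> tuple[list[SNVPartition], list[str]]:
    """Remove biopsies whose every partition (private included) is < 100 SNVs."""
    threshold = pdata.config.min_partition_snvs
    best: dict[str, int] = {s: 0 for s in pdata.samples}
    for p in partitions:
        for s in p.sample_set:
            best[s] = max(best[s], p.size)
    dropped = sorted(s for s, n in best.items() if n < threshold)
    if not dropped:
        return partitions, []
    keep_cols = [j for j, s in enumerate(pdata.samples) if s not in dropped]
    keep_samples = [pdata.samples[j] for j in keep_cols]
    merged: dict[frozenset, list] = {}
    for p in partitions:
        sset = frozenset(p.sample_set) - set(dropped)
        if not sset:
            continue
        merged.setdefault(sset, []).append(p.snv_idx)
    out = [SNVPartition(pdata.patient_id, sset, np.sort(np.concatenate(idx)),
                        private=len(sset) == 1)
           for sset, idx in merged.items()]
    out.sort(key=lambda p: sorted(p.sample_set))
    pdata.dropped_biopsies.extend(dropped)
    return out, dropped


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _silverman(x: np.ndarray) -> float:
    n = len(x)
    std = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(std, iqr / 1.34) if iqr > 0 else std
    if spread <= 0:
        return 0.0
    return 0.9 * spread * n ** (-0.2)


def _peaks_with_heights(x: np.ndarray, bandwidth: float | None,
                        cfg: PartitionConfig):
    if np.ptp(x) == 0:
        return [float(x[0])], [float(len(x))]
    h = bandwidth if bandwidth is not None else max(
        cfg.bandwidth_scale * _silverman(x), cfg.bandwidth_floor)
    grid = np.linspace(0.0, 1.0, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    left = np.r_[-np.inf, dens[:-1]]
    right = np.r_[dens[1:], -np.inf]
    is_max = (dens > left) & (dens >= right)
    locs = grid[is_max]
    heights = dens[is_max]
    # merge near-coincident maxima, keeping the higher
    order = np.argsort(-heights)
    kept, kept_h = [], []
    for i in order:
        if all(abs(locs[i] - k) > cfg.merge_tol for k in kept):
            kept.append(float(locs[i]))
            kept_h.append(float(heights[i]))
    return kept, kept_h


def detect_peaks(vafs, bandwidth: float | None = None,
                 config: PartitionConfig | None = None) -> list[float]:
    """Locations of local maxima of the kernel-smoothed VAF density on [0,1].

    Bandwidth defaults to Silverman's rule scaled by ``bandwidth_scale``
    with a floor of ``bandwidth_floor``; maxima closer than ``merge_tol``
    are merged into the higher one.
    """
    cfg = config or PartitionConfig()
    x = np.asarray(vafs, dtype=float)
    if len(x) == 0:
        return []
    locs, _h = _peaks_with_heights(x, bandwidth, cfg)
    return sorted(locs)


def _em_gmm_1d(x: np.ndarray, means_init, cfg: PartitionConfig,
               max_iter: int = 300, tol: float = 1e-7):
    """1-D Gaussian mixture EM with component sd clamped to a noise band.

    Returns (means, weights, loglik) or None if the fit degenerates.
    """
    n, k = len(x), len(means_init)
    means = np.asarray(means_init, dtype=float).copy()
    var = np.full(k, (2 * cfg.peak_sd_min + cfg.peak_sd_max) ** 2 / 9)
    w = np.full(k, 1.0 / k)
    var_lo, var_hi = cfg.peak_sd_min ** 2, cfg.peak_sd_max ** 2
    loglik = -np.inf
    for _ in range(max_iter):
        logp = (-0.5 * (x[:, None] - means) ** 2 / var
                - 0.5 * np.log(2 * np.pi * var) + np.log(w))
        m = logp.max(axis=1, keepdims=True)
        r = np.exp(logp - m)
        s = r.sum(axis=1, keepdims=True)
        new_loglik = float((m.ravel() + np.log(s.ravel())).sum())
        r /= s
        nk = r.sum(axis=0)
        if np.any(nk < 1e-9):
            return None
        means = (r * x[:, None]).sum(axis=0) / nk
        var = np.clip((r * (x[:, None] - means) ** 2).sum(axis=0) / nk,
                      var_lo, var_hi)
        w = nk / n
        if abs(new_loglik - loglik) < tol * max(1.0, abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    return means, w, loglik


def fit_peak_weights(vafs, peak_locations: list[float], sample_id: str = "",
                     config: PartitionConfig | None = None) -> list[VAFPeak]:
    """Assign SNV counts to peaks with a Gaussian mixture.

    The detected peak locations cap the number of components; the mixture
    order is chosen by BIC, which protects against the kernel smoother
    splitting a single binomial read-sampling cluster into spurious
    maxima. Component sd is clamped to the read-noise band so one
    component cannot stretch to absorb a neighboring peak. Component
    weight times n estimates the number of SNVs under each peak; peaks
    holding fewer than ``min_peak_snvs`` SNVs are discarded.
    """
    cfg = config or PartitionConfig()
    x = np.asarray(vafs, dtype=float)
    n = len(x)
    if n == 0 or not peak_locations:
        return []
    locations = sorted(peak_locations)
    k_max = len(locations)
    if k_max == 1 or np.ptp(x) == 0:
        return [p for p in [VAFPeak(sample_id, float(np.mean(x)), float(n))]
                if p.weight >= cfg.min_peak_snvs]

    # rank candidate locations by KDE height so k < k_max keeps the majors
    _locs, _h = _peaks_with_heights(x, None, cfg)
    by_height = sorted(range(len(_locs)), key=lambda i: -_h[i])
    best, best_bic = None, np.inf
    for k in range(1, k_max + 1):
        init = sorted(_locs[i] for i in by_height[:k]) if len(_locs) >= k \
            else list(np.quantile(x, (np.arange(k) + 0.5) / k))
        fit = _em_gmm_1d(x, init, cfg)
        if fit is None:
            continue
        means, w, loglik = fit
        if k > 1 and np.min(np.diff(np.sort(means))) < cfg.peak_min_sep:
            continue
        bic = -2.0 * loglik + (3 * k - 1) * np.log(n)
        if bic < best_bic:
            best, best_bic = (means, w), bic
    if best is None:
        warnings.warn("mixture fit failed; falling back to hard assignment")
        locs = np.asarray(locations)
        nearest = np.argmin(np.abs(x[:, None] - locs[None, :]), axis=1)
        peaks = [VAFPeak(sample_id, float(x[nearest == i].mean()),
                         float((nearest == i).sum()))
                 for i in range(len(locs)) if (nearest == i).any()]
    else:
        means, w = best
        peaks = [VAFPeak(sample_id, float(m), float(wi * n))
                 for m, wi in zip(means, w)]
    peaks = [p for p in peaks if p.weight >= cfg.min_peak_snvs]
    peaks.sort(key=lambda p: p.location)
    return peaks


def detection_debias(location: float, depth: float, min_alt: int) -> float:
    """Correct a VAF peak location for detection truncation.

    Detection requires ``min_alt`` alternate reads, so low-VAF peaks are
    biased upward: the observed mean is E[X/d | X >= min_alt] for
    X ~ Binomial(d, v). Returns the v whose truncated mean matches the
    observed location (bisection); locations at or below the truncation
    floor min_alt/d are returned unchanged.
    """
    from scipy import stats as sps

    if min_alt <= 0:
        return location
    d = max(int(round(depth)), 1)
    floor = min_alt / d
    if location <= floor + 1e-9:
        return location
    ks = np.arange(0, min_alt)

    def cond_mean(v: float) -> float:
        p_ge = float(sps.binom.sf(min_alt - 1, d, v))
        if p_ge < 1e-12:
            return floor
        trunc = float((sps.binom.pmf(ks, d, v) * ks).sum())
        return (d * v - trunc) / (d * p_ge)

    lo, hi = 1e-9, location
    if cond_mean(hi) <= location:   # bias negligible at this VAF
        return location
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if cond_mean(mid) < location:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_cn_groups(partition: SNVPartition, pdata: PatientData) -> None:
    """Split a partition into same-copy-number groups and fit their peaks."""
    cfg = pdata.config
    cols = [j for j, s in enumerate(pdata.samples) if s in partition.sample_set]
    samples = [pdata.samples[j] for j in cols]
    maj = pdata.major[partition.snv_idx][:, cols]
    mino = pdata.minor[partition.snv_idx][:, cols]
    sig = np.stack([maj, mino], axis=2).reshape(len(partition.snv_idx), -1)
    groups = []
    uniq, inverse = np.unique(sig, axis=0, return_inverse=True)
    for g in range(len(uniq)):
        members = partition.snv_idx[inverse == g]
        pairs = uniq[g].reshape(-1, 2)
        signature = tuple((s, int(a), int(b))
                          for s, (a, b) in zip(samples, pairs))
        group = CNGroup(signature=signature, snv_idx=members)
        if len(members) < cfg.min_group_snvs:
            group.retained = False
        else:
            for j, s in zip(cols, samples):
                v = pdata.vaf[members, j]
                locs = detect_peaks(v, config=cfg)
                peaks = fit_peak_weights(v, locs, sample_id=s, config=cfg)
                if pdata.det_from_threshold:
                    depth = float(np.median(pdata.tot[members, j]))
                    for p in peaks:
                        p.location = detection_debias(
                            p.location, depth, cfg.detection_min_alt)
                group.peaks[s] = peaks
            if any(len(group.peaks[s]) == 0 for s in samples):
                group.retained = False
        groups.append(group)
    partition.cn_groups = groups


def build_partitions(pdata: PatientData) -> tuple[list[SNVPartition], dict]:
    """Full partition stage: partition, LOH filter, thin-biopsy drop, peaks.

    Returns the partition list (with fitted CN groups) and a log of exact
    removal counts, so that partition sizes always reconcile with the SNV
    total.
    """
    parts = partition_snvs(pdata)
    log = {"n_snvs": len(pdata.snvs),
           "n_undetected": len(pdata.snvs) - sum(p.size for p in parts)}
    filtered, n_loh = [], 0
    for p in parts:
        kept, removed = apply_loh_exclusion(p, pdata)
        n_loh += len(removed)
        if kept.size:
            filtered.append(kept)
    log["n_loh_excluded"] = n_loh
    filtered, dropped = drop_thin_biopsies(pdata, filtered)
    log["dropped_biopsies"] = dropped
    for p in filtered:
        if not p.private:
            build_cn_groups(p, pdata)
    log["n_partitions"] = len(filtered)
    pdata.log.update(log)
    return filtered, log
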