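"""Assign SNVs to forest branches, compute placed fractions, place candidates.

Branch lengths are SNV counts: an SNV detected in several samples belongs
on the branch whose descendant tips cover exactly those biopsies. When
multiple branches lead to the same biopsy set (nested lineages), the
branch whose expected VAF is closest to the observed VAF wins; SNVs
matching no branch are discordant with the phylogeny and dropped.
Functional mutations in candidate loci are placed the same way but with a
preference for branches on which the mutation can be heterozygous, and a
mutation homozygous in some lineages but heterozygous in others is scored
as an ancestral heterozygous event with tipward loss-of-wild-type
transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Clade, PhylogenyForest
from .partition import PatientData

DISCORDANT = "DISCORDANT"


@dataclass
class BranchAssignment:
    patient_id: str
    snv_idx: int
    branch_label: str     # node label / tip label, or DISCORDANT


@dataclass
class CandidatePlacement:
    locus: str
    snv_idx: int
    branch_label: str
    zygosity: str                      # heterozygous | homozygous
    secondary_events: list = field(default_factory=list)  # tipward hom branches


def _branch_label(node: Clade) -> str:
    return node.tip.label if node.is_tip else node.label


def _expected_vaf(node: Clade, sample: str, pdata: PatientData,
                  hom: bool = False) -> float:
    """Expected VAF of an SNV on this branch in one sample."""
    b = pdata.biopsy_of[sample]
    cf = sum(t.tip.cell_fraction or 0.0 for t in node.tips()
             if t.tip.biopsy_id == b)
    ctx = pdata.context[sample]
    total = ctx.total_copies
    if hom:
        return min(1.0, cf)
    below_gd = node.gd or any(a.gd for a in node.ancestors())
    mut = 1 if (ctx.gd_corroborated and below_gd) else max(1, total // 2)
    return min(1.0, cf * mut / total)


def assign_snvs_to_branches(forest: PhylogenyForest, pdata: PatientData,
                            usable_idx: np.ndarray | None = None
                            ) -> tuple[list[BranchAssignment], dict]:
    """Assign every usable multi-sample SNV to a branch; set branch lengths.

    Returns (assignments, summary). Branch ``n_snvs`` is reset to the
    number of SNVs assigned to it.
    """
    forest.relabel()
    if usable_idx is None:
        usable_idx = usable_snv_indices(pdata)

    by_biopsies: dict[frozenset, list[Clade]] = {}
    for node in forest.branches():
        bset = node.biopsies()
        if len(bset) >= 2 or (node.is_tip and node.parent is None):
            by_biopsies.setdefault(bset, []).append(node)

    keep_cols = np.array([j for j, s in enumerate(pdata.samples)
                          if s not in pdata.dropped_biopsies])
    det = pdata.det[np.ix_(usable_idx, keep_cols)]
    codes = det @ (1 << np.arange(det.shape[1], dtype=np.int64))
    assignments: list[BranchAssignment] = []
    counts: dict[str, int] = {}
    n_discordant = 0

    for code in np.unique(codes):
        members = usable_idx[codes == code]
        cols = [int(keep_cols[j]) for j in range(det.shape[1]) if code >> j & 1]
        sset = frozenset(pdata.biopsy_of[pdata.samples[j]] for j in cols)
        candidates = by_biopsies.get(sset, [])
        if not candidates:
            n_discordant += len(members)
            assignments.extend(BranchAssignment(pdata.patient_id, int(i), DISCORDANT)
                               for i in members)
            continue
        if len(candidates) == 1:
            label = _branch_label(candidates[0])
            counts[label] = counts.get(label, 0) + len(members)
            assignments.extend(BranchAssignment(pdata.patient_id, int(i), label)
                               for i in members)
            continue
        # several branches lead to the same biopsies: nearest expected VAF
        exp = np.array([[_expected_vaf(c, pdata.samples[j], pdata)
                         for j in cols] for c in candidates])
        obs = pdata.vaf[np.ix_(members, cols)]
        dev = np.abs(obs[:, None, :] - exp[None, :, :]).mean(axis=2)
        pick = np.argmin(dev, axis=1)
        for i, k in zip(members, pick):
            label = _branch_label(candidates[k])
            counts[label] = counts.get(label, 0) + 1
            assignments.append(BranchAssignment(pdata.patient_id, int(i), label))

    for node in forest.branches():
        label = _branch_label(node)
        node.n_snvs = counts.get(label, 0)

    # private SNVs support the pendant branch of a biopsy's sole lineage
    # (they are excluded from usable/placed bookkeeping, but they weight
    # the branch in resampling); with several lineages in a biopsy the
    # private SNVs cannot be apportioned and the tips keep zero support
    det_all = pdata.det[:, keep_cols]
    single = det_all.sum(axis=1) == 1
    for j, col in enumerate(keep_cols):
        b = pdata.biopsy_of[pdata.samples[col]]
        tips_b = forest.tips_in(b)
        if len(tips_b) == 1:
            tips_b[0].private_snvs = int((single & det_all[:, j]).sum())

    summary = {"n_usable": len(usable_idx), "n_placed": len(usable_idx) - n_discordant,
               "n_discordant": n_discordant}
    return assignments, summary


def usable_snv_indices(pdata: PatientData) -> np.ndarray:
    """SNVs informative for phylogeny: detected in 2+ samples and not in a
    region deleted in any sample carrying them."""
    det = pdata.det
    multi = det.sum(axis=1) >= 2
    total_cn = pdata.major + pdata.minor
    deleted = ((total_cn == 0) & det).any(axis=1)
    keep = multi & ~deleted
    # biopsies dropped from phylogenetic analysis do not count as samples
    if pdata.dropped_biopsies:
        cols = [j for j, s in enumerate(pdata.samples)
                if s not in pdata.dropped_biopsies]
        multi = det[:, cols].sum(axis=1) >= 2
        keep = multi & ~deleted
    return np.flatnonzero(keep)


def placed_fraction(summary: dict) -> float:
    """Proportion of usable SNVs placed on the phylogeny."""
    if summary["n_usable"] == 0:
        raise ValueError("no usable SNVs")
    return summary["n_placed"] / summary["n_usable"]


def cohort_placed_fractions(per_patient: dict) -> dict:
    vals = np.array(sorted(per_patient.values()))
    return {"mean": float(vals.mean()), "median": float(np.median(vals)),
            "min": float(vals.min()), "per_patient": per_patient}


# ---------------------------------------------------------------------------
# zygosity and candidate placement
# ---------------------------------------------------------------------------

def assign_zygosity(observed_vaf: float, cell_fraction: float,
                    total_copies: int = 2, het_copies: int = 1) -> str:
    """Heterozygous vs homozygous by the numerically closer expected VAF.

    Heterozygous means at least one wild-type copy remains (expected VAF =
    CF * het_copies / total); homozygous means none (expected VAF = CF).
    Exact ties go to heterozygous.
    """
    exp_het = cell_fraction * het_copies / total_copies
    exp_hom = cell_fraction
    if abs(observed_vaf - exp_het) <= abs(observed_vaf - exp_hom):
        return "heterozygous"
    return "homozygous"


def _tip_zygosity(node: Clade, tip: Clade, sample: str, vaf: float,
                  pdata: PatientData) -> str:
    ctx = pdata.context[sample]
    total = ctx.total_copies
    below_gd = node.gd or any(a.gd for a in node.ancestors())
    het_copies = 1 if (not ctx.gd_corroborated or below_gd) else 2
    cf = sum(t.tip.cell_fraction or 0.0 for t in node.tips()
             if t.tip.biopsy_id == tip.tip.biopsy_id)
    return assign_zygosity(vaf, cf, total, het_copies)


def place_candidate_mutations(forest: PhylogenyForest, pdata: PatientData,
                              candidate_loci: list[str] | None = None
                              ) -> list[CandidatePlacement]:
    """Place functional candidate-locus SNVs on branches with zygosity.

    Functional means severity MODERATE or HIGH. Among branches matching the
    SNV's biopsy set, branches on which the mutation can be heterozygous
    are preferred; within the preferred class the nearest expected VAF
    wins. Mixed heterozygous/homozygous calls across a branch's biopsies
    become an ancestral heterozygous placement with secondary
    loss-of-wild-type events on the tipward pendant branches.
    """
    forest.relabel()
    snvs = pdata.snvs
    functional = snvs["severity"].isin(["MODERATE", "HIGH"])
    has_locus = snvs["locus"].astype(str) != ""
    if candidate_loci is not None:
        has_locus &= snvs["locus"].isin(candidate_loci)
    cand_idx = np.flatnonzero(functional & has_locus)

    by_biopsies: dict[frozenset, list[Clade]] = {}
    for node in forest.branches():
        bset = node.biopsies()
        if bset:
            by_biopsies.setdefault(bset, []).append(node)

    placements: list[CandidatePlacement] = []
    for i in cand_idx:
        det_cols = np.flatnonzero(pdata.det[i])
        if len(det_cols) == 0:
            continue
        sset = frozenset(pdata.biopsy_of[pdata.samples[j]] for j in det_cols)
        candidates = by_biopsies.get(sset, [])
        if not candidates:
            continue  # discordant candidate: logged by caller, excluded

        scored = []
        for node in candidates:
            calls, devs = [], []
            for j in det_cols:
                s = pdata.samples[j]
                vaf = pdata.vaf[i, j]
                tips_b = [t for t in node.tips()
                          if t.tip.biopsy_id == pdata.biopsy_of[s]]
                zyg = _tip_zygosity(node, tips_b[0], s, vaf, pdata)
                exp = _expected_vaf(node, s, pdata, hom=(zyg == "homozygous"))
                calls.append(zyg)
                devs.append(abs(vaf - exp))
            all_het = all(c == "heterozygous" for c in calls)
            scored.append((node, calls, float(np.mean(devs)), all_het))

        het_ok = [e for e in scored if e[3]]
        pool = het_ok if het_ok else scored
        node, calls, _dev, _ = min(pool, key=lambda e: e[2])

        hets = [c == "heterozygous" for c in calls]
        if all(hets):
            zygosity, secondary = "heterozygous", []
        elif not any(hets):
            zygosity, secondary = "homozygous", []
        else:
            # ancestral heterozygous, homozygosity acquired tipward
            zygosity = "heterozygous"
            secondary = []
            for j, c in zip(det_cols, calls):
                if c == "homozygous":
                    b = pdata.biopsy_of[pdata.samples[j]]
                    for t in node.tips():
                        if t.tip.biopsy_id == b:
                            secondary.append(t.tip.label)
                            break
        placements.append(CandidatePlacement(
            locus=str(snvs["locus"].iloc[i]), snv_idx=int(i),
            branch_label=_branch_label(node), zygosity=zygosity,
            secondary_events=sorted(set(secondary))))
    return placements


def placements_table(placements: list[CandidatePlacement],
                     patient_id: str) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient": patient_id, "locus": p.locus, "snv": p.snv_idx,
        "branch": p.branch_label, "zygosity": p.zygosity,
        "secondary_events": ";".join(p.secondary_events),
    } for p in placements])
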