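"""Assemble a patient's phylogenetic forest from filtered SNV partitions.

Partitions are processed from two-sample sets toward the root (larger sets
later; among equal sizes, more SNVs first). Each partition's VAF peaks are
interpreted as cell fractions (CF): a peak at VAF v for a mutation on
``mut`` of ``total`` local copies implies CF = v * total / mut. Partitions
with several peaks are explained, in order of preference, by (1) an
unbalanced copy-number call, (2) a corroborated genome doubling (peak pairs
a factor of two apart), or (3) a split into nested lineages relating the
same samples at different time depths. Assembly nests a partition over
existing clades whose samples it contains and whose CFs it can cover,
splits a sample into multiple lineages when overlapping partitions fit
within the sample's CF budget, and otherwise reclassifies the smaller
conflicting partition as allelic dropout of a compatible larger one.
Sample groups sharing fewer than 100 SNVs are never connected, so a
patient's phylogeny may be a forest of disjoint trees (candidate
independent origins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Clade, PhylogenyForest, new_tip
from .partition import CNGroup, PatientData, SNVPartition


@dataclass
class DeconvConfig:
    cf_tol: float = 0.10          # parent/child CF slack
    ratio_tol: float = 0.25       # relative tolerance on peak ratios
    residual_min_cf: float = 0.15  # smallest reportable residual lineage
    budget_tol: float = 0.05      # per-biopsy CF sum may reach 1 + this
    max_reclassifications: int = 5
    max_levels: int = 3           # >3 stacked peaks: partition unresolvable
    min_partition_snvs: int = 100


class UnresolvableError(RuntimeError):
    """The partition set admits no tree under the assembly rules."""


@dataclass
class LineageLevel:
    """One lineage inferred from a partition (a chain level), with its CFs."""
    cf: dict
    n_snvs: float
    gd: bool = False


@dataclass
class ChainUnit:
    """A partition interpreted as 1-3 nested lineages (ancestral first)."""
    partition_id: int
    sample_set: frozenset
    levels: list
    hypothesis: str = "single"

    @property
    def n_snvs(self) -> float:
        return sum(l.n_snvs for l in self.levels)


def vaf_peak_to_cf(vaf: float, mut_copies: int, total_copies: int) -> float:
    """Cell fraction implied by a VAF peak given the local copy context."""
    if mut_copies < 1:
        raise ValueError("mut_copies must be >= 1")
    if mut_copies > total_copies:
        raise ValueError("mut_copies cannot exceed total_copies")
    return min(1.0, vaf * total_copies / mut_copies)


# ---------------------------------------------------------------------------
# peak interpretation
# ---------------------------------------------------------------------------

def _close(a: float, b: float, rel: float) -> bool:
    return abs(a - b) <= rel * max(abs(a), abs(b), 1e-12)


def interpret_multi_peaks(group: CNGroup, contexts: dict,
                          config: DeconvConfig | None = None):
    """Explain a copy-number group's peaks; returns (hypothesis, levels).

    Hypotheses, tried in order: ``unbalanced_cn`` (only when the CN call is
    unbalanced and the peak ratio matches the haplotype copy counts),
    ``genome_doubling`` (all samples externally corroborated as doubled and
    peaks a factor of two apart), ``split_lineages`` (nested lineages at
    different depths). Raises :class:`UnresolvableError` when more than
    ``max_levels`` stacked peaks remain.
    """
    cfg = config or DeconvConfig()
    sig = dict((s, (maj, mino)) for s, maj, mino in group.signature)
    samples = sorted(sig)

    resolved: dict[str, list] = {}   # sample -> [(cf, weight)] descending CF
    hypothesis = "single"
    for s in samples:
        maj, mino = sig[s]
        peaks = sorted(group.peaks[s], key=lambda p: -p.location)
        total = maj + mino
        ctx = contexts[s]
        if len(peaks) == 2 and maj != mino and mino > 0 and \
                _close(peaks[0].location / max(peaks[1].location, 1e-9),
                       maj / mino, cfg.ratio_tol):
            # one lineage; the two peaks are the two haplotypes
            cf_hi = vaf_peak_to_cf(peaks[0].location, maj, total)
            cf_lo = vaf_peak_to_cf(peaks[1].location, mino, total)
            w = peaks[0].weight + peaks[1].weight
            cf = (cf_hi * peaks[0].weight + cf_lo * peaks[1].weight) / w
            resolved[s] = [(cf, w)]
            hypothesis = "unbalanced_cn"
        else:
            # mutations sit on one haplotype; in corroborated tetraploid
            # samples a lone peak is read as post-doubling (1 of 4 copies)
            if ctx.gd_corroborated:
                mut = 1 if len(peaks) == 1 else None
            else:
                mut = max(mino, 1) if maj == mino else maj
            if len(peaks) == 1:
                m = mut if mut is not None else 1
                resolved[s] = [(vaf_peak_to_cf(peaks[0].location, m, total), peaks[0].weight)]
            else:
                resolved[s] = None  # defer to group-level hypothesis
                resolved[s] = [(p.location, p.weight) for p in peaks]  # raw

    multi = {s for s in samples if len(resolved[s]) > 1}
    if not multi:
        levels = [LineageLevel(cf={s: resolved[s][0][0] for s in samples},
                               n_snvs=float(np.mean([resolved[s][0][1] for s in samples])))]
        return hypothesis, levels

    # genome doubling: factor-of-two peak pairs in corroborated samples only
    def _has_factor_two(entries) -> bool:
        return any(_close(hi / max(lo, 1e-9), 2.0, cfg.ratio_tol)
                   for (hi, _), (lo, _) in
                   ((entries[i], entries[j])
                    for i in range(len(entries))
                    for j in range(i + 1, len(entries))))

    all_gd = all(contexts[s].gd_corroborated for s in samples)
    if all_gd and all(_has_factor_two(resolved[s]) for s in multi):
        cf = {}
        for s in samples:
            maj, mino = sig[s]
            total = maj + mino
            if len(resolved[s]) > 1:
                hi = resolved[s][0][0]  # highest peak = ancestral 2-of-4 copies
                cf[s] = vaf_peak_to_cf(hi, 2, total)
            else:
                cf[s] = resolved[s][0][0]
        n = float(np.mean([sum(w for _, w in resolved[s]) for s in samples]))
        return "genome_doubling", [LineageLevel(cf=cf, n_snvs=n, gd=True)]

    # split lineages: same samples at different time depths
    kmax = max(len(resolved[s]) for s in samples)
    if kmax > cfg.max_levels:
        raise UnresolvableError(
            f"{kmax} stacked VAF peaks cannot be interpreted")
    levels = []
    full = [s for s in samples if len(resolved[s]) == kmax]
    for i in range(kmax):
        cf = {}
        for s in samples:
            vals = resolved[s]
            v, _w = vals[min(i, len(vals) - 1)]
            maj, mino = sig[s]
            if contexts[s].gd_corroborated:
                mut = 1
            else:
                mut = max(mino, 1) if maj == mino else maj
            # raw multi-peak entries are VAFs; singles are already CFs
            cf[s] = vaf_peak_to_cf(v, mut, maj + mino) if len(vals) > 1 else v
        n = float(np.mean([resolved[s][i][1] for s in full]))
        levels.append(LineageLevel(cf=cf, n_snvs=n))
    return "split_lineages", levels


def partition_to_chain(partition: SNVPartition, pdata: PatientData,
                       pid: int, config: DeconvConfig | None = None
                       ) -> ChainUnit | None:
    """Interpret a partition's retained CN groups as one chain of lineages.

    The largest retained group sets the level structure; other groups merge
    into it by CF similarity, weighting CF estimates by SNV count.
    """
    cfg = config or DeconvConfig()
    contexts = pdata.context
    groups = [g for g in partition.cn_groups if g.retained]
    if not groups:
        return None
    interpreted = [interpret_multi_peaks(g, contexts, cfg) for g in groups]
    order = np.argsort([-g.size for g in groups])
    hyp, template = interpreted[order[0]]
    template = [LineageLevel(cf=dict(l.cf), n_snvs=l.n_snvs, gd=l.gd)
                for l in template]
    weights = [[l.n_snvs for l in template]]
    for gi in order[1:]:
        _h, levels = interpreted[gi]
        for lev in levels:
            # merge into the template level with the closest CF profile
            dists = [np.mean([abs(lev.cf[s] - t.cf[s]) for s in lev.cf])
                     for t in template]
            j = int(np.argmin(dists))
            t = template[j]
            wt, wl = t.n_snvs, lev.n_snvs
            for s in t.cf:
                t.cf[s] = (t.cf[s] * wt + lev.cf[s] * wl) / (wt + wl)
            t.n_snvs = wt + wl
            t.gd = t.gd or lev.gd
    return ChainUnit(partition_id=pid, sample_set=partition.sample_set,
                     levels=template, hypothesis=hyp)


# ---------------------------------------------------------------------------
# ordering and assembly
# ---------------------------------------------------------------------------

def order_partitions(partitions: list) -> list:
    """Two-sample partitions first, then toward the root; ties by SNV count
    (descending) then lexicographic sample set."""
    def key(p):
        return (len(p.sample_set), -_size_of(p), tuple(sorted(p.sample_set)))

    return sorted(partitions, key=key)


def _size_of(p) -> float:
    return p.n_snvs if isinstance(p, ChainUnit) else p.size


class _Assembler:
    def __init__(self, pdata: PatientData, config: DeconvConfig):
        self.pdata = pdata
        self.cfg = config
        self.roots: list[Clade] = []
        self.node_units: dict[int, LineageLevel] = {}
        self.tip_claims: dict[str, float] = {}   # sample -> claimed CF sum
        self.n_reclassified = 0
        self.log: list[str] = []

    # -- helpers ---------------------------------------------------------

    def _sample_of_tip(self, tip: Clade) -> str:
        for s, b in self.pdata.biopsy_of.items():
            if b == tip.tip.biopsy_id:
                return s
        raise KeyError(tip.tip.biopsy_id)

    def _tips_below(self, node: Clade, sample: str | None = None) -> list[Clade]:
        biopsy = self.pdata.biopsy_of.get(sample) if sample else None
        return [t for t in node.tips()
                if biopsy is None or t.tip.biopsy_id == biopsy]

    def _samples_below(self, node: Clade) -> set:
        biopsies = {t.tip.biopsy_id for t in node.tips()}
        return {s for s, b in self.pdata.biopsy_of.items() if b in biopsies}

    def _tip_cf_sum(self, node: Clade, sample: str) -> float:
        return sum(t.tip.cell_fraction or 0.0
                   for t in self._tips_below(node, sample))

    def _make_tip(self, sample: str, cf: float) -> Clade:
        tip = new_tip(self.pdata.biopsy_of[sample], 0, cf)
        self.tip_claims[sample] = self.tip_claims.get(sample, 0.0) + cf
        return tip

    # -- chain placement -------------------------------------------------

    def add_chain(self, chain: ChainUnit, defer: bool = True) -> bool:
        """Place one chain; returns False if it conflicts and was deferred
        (or, with ``defer=False``, reclassified as allelic dropout)."""
        cfg = self.cfg
        samples = set(chain.sample_set)

        # candidate subtrees this chain could be ancestral to
        adoptable = []
        for r in self.roots:
            rs = self._samples_below(r)
            if rs and rs <= samples:
                adoptable.append((r, rs))
        adoptable.sort(key=lambda e: (-sum(n.n_snvs for n in e[0].walk()),
                                      tuple(sorted(e[1]))))

        # choose, for each adopted root, the most derived level that covers it
        adopted: list[tuple[Clade, int]] = []
        used = {s: 0.0 for s in samples}
        for r, rs in adoptable:
            level = None
            for li in range(len(chain.levels) - 1, -1, -1):
                ok = all(chain.levels[li].cf.get(s, 0.0) + cfg.cf_tol >=
                         self._tip_cf_sum(r, s) + (used[s] if li == 0 else 0.0)
                         for s in rs)
                if ok:
                    level = li
                    break
            if level is None:
                continue
            adopted.append((r, level))
            for s in rs:
                used[s] += self._tip_cf_sum(r, s)

        covered = set()
        for r, _li in adopted:
            covered |= self._samples_below(r)
        new_samples = sorted(samples - covered)

        derived = chain.levels[-1]
        for s in new_samples:
            claim = self.tip_claims.get(s, 0.0)
            if claim + derived.cf.get(s, 0.0) > 1.0 + cfg.budget_tol:
                if not defer:
                    self._reclassify(chain)
                return False

        # build the chain of nodes, ancestral level on top
        nodes = []
        for li, lev in enumerate(chain.levels):
            node = Clade(n_snvs=int(round(lev.n_snvs)),
                         partition_ids=(chain.partition_id,), gd=lev.gd)
            self.node_units[id(node)] = lev
            if nodes:
                nodes[-1].add_child(node)
            nodes.append(node)
        bottom = nodes[-1]

        for r, li in adopted:
            self.roots.remove(r)
            nodes[li].add_child(r)
        for s in new_samples:
            bottom.add_child(self._make_tip(s, derived.cf.get(s, 0.0)))

        # residual lineages: ancestral CF not accounted for by tips below
        for li in range(len(nodes) - 1, -1, -1):
            lev = chain.levels[li]
            for s in sorted(samples):
                residual = lev.cf.get(s, 0.0) - self._tip_cf_sum(nodes[li], s)
                if residual >= cfg.residual_min_cf:
                    nodes[li].add_child(self._make_tip(s, residual))

        self.roots.append(nodes[0])
        return True

    def _reclassify(self, chain: ChainUnit) -> None:
        """Treat the chain's partition as allelic dropout of a superset."""
        self.n_reclassified += 1
        if self.n_reclassified > self.cfg.max_reclassifications:
            raise UnresolvableError("too many dropout reclassifications")
        best, best_key = None, None
        for r in self.roots:
            for node in r.walk():
                if node.is_tip:
                    continue
                ns = self._samples_below(node)
                if chain.sample_set <= ns:
                    key = (len(ns - chain.sample_set), -node.n_snvs)
                    if best_key is None or key < best_key:
                        best, best_key = node, key
        if best is None:
            raise UnresolvableError(
                f"partition {sorted(chain.sample_set)} fits no superset branch")
        best.n_snvs += int(round(chain.n_snvs))
        self.log.append(
            f"reclassified partition {sorted(chain.sample_set)} as dropout")


def assemble_forest(chains: list, pdata: PatientData,
                    partitions: list | None = None,
                    config: DeconvConfig | None = None) -> PhylogenyForest:
    """Incrementally assemble the forest from ordered chain units.

    ``partitions`` (the full filtered list, private included) is used to
    add singleton trees for samples supported only by a large private
    partition. Returns a forest with status ``unresolvable`` if assembly
    fails.
    """
    cfg = config or DeconvConfig()
    asm = _Assembler(pdata, cfg)
    try:
        deferred = []
        for chain in order_partitions(chains):
            if not asm.add_chain(chain, defer=True):
                deferred.append(chain)
        # conflicting partitions retry once the full forest exists, then
        # fall back to allelic-dropout reclassification (smallest first)
        for chain in sorted(deferred, key=_size_of):
            asm.add_chain(chain, defer=False)
    except UnresolvableError as err:
        forest = PhylogenyForest(pdata.patient_id, [], status="unresolvable")
        forest.failure_reason = str(err)
        return forest

    # samples seen in no multi-sample partition but with a big private
    # partition stand as their own single-tip trees
    placed = set()
    for r in asm.roots:
        placed |= asm._samples_below(r)
    if partitions is not None:
        for p in partitions:
            if p.private and p.size >= cfg.min_partition_snvs:
                (s,) = tuple(p.sample_set)
                if s in placed or s in pdata.dropped_biopsies:
                    continue
                col = pdata.samples.index(s)
                v = float(np.median(pdata.vaf[p.snv_idx, col]))
                total = pdata.context[s].total_copies
                mut = 1 if pdata.context[s].gd_corroborated else max(1, total // 2)
                cf = vaf_peak_to_cf(v, mut, total)
                tip = new_tip(pdata.biopsy_of[s], 0, cf)
                tip.n_snvs = p.size
                asm.roots.append(tip)
                placed.add(s)

    forest = PhylogenyForest(pdata.patient_id, sorted(
        asm.roots, key=lambda r: tuple(sorted(r.biopsies()))))
    forest.node_units = asm.node_units
    forest.assembly_log = asm.log
    estimate_tip_cfs(forest, pdata)
    assign_lineage_indices(forest)
    return forest


def estimate_tip_cfs(forest: PhylogenyForest, pdata: PatientData) -> None:
    """Tip CF = SNV-weighted mean over partitions private to that lineage.

    A partition on the path to a tip contributes only if the tip is the
    sole lineage of its biopsy below that branch — the CF the lineage
    possessed when diverging from the rest of the phylogeny. Residual
    lineages keep the CF inferred at their creation.
    """
    units = getattr(forest, "node_units", {})
    sample_of = {b: s for s, b in pdata.biopsy_of.items()}
    for tip in forest.tips():
        b = tip.tip.biopsy_id
        s = sample_of.get(b)
        num = den = 0.0
        node = tip
        while node is not None:
            lev = units.get(id(node))
            if lev is not None and s in lev.cf:
                same_b = [t for t in node.tips() if t.tip.biopsy_id == b]
                if same_b == [tip]:
                    num += lev.cf[s] * lev.n_snvs
                    den += lev.n_snvs
            node = node.parent
        if den > 0:
            tip.tip.cell_fraction = num / den


def assign_lineage_indices(forest: PhylogenyForest) -> None:
    """Number lineages within each biopsy by descending cell fraction."""
    by_biopsy: dict[str, list] = {}
    for t in forest.tips():
        by_biopsy.setdefault(t.tip.biopsy_id, []).append(t)
    for b, tips in by_biopsy.items():
        tips.sort(key=lambda t: (-(t.tip.cell_fraction or 0.0), id(t)))
        for i, t in enumerate(tips, start=1):
            t.tip.lineage_index = i
    forest.relabel()


def count_origins(forest: PhylogenyForest, pdata: PatientData,
                  partitions: list, config: DeconvConfig | None = None) -> int:
    """Number of disjoint trees, ignoring biopsies with no partition >100 SNVs."""
    cfg = config or DeconvConfig()
    best: dict[str, int] = {s: 0 for s in pdata.samples}
    for p in partitions:
        for s in p.sample_set:
            best[s] = max(best[s], p.size)
    informative = {pdata.biopsy_of[s] for s, n in best.items()
                   if n > cfg.min_partition_snvs}
    count = 0
    for tree in forest.trees:
        if tree.biopsies() & informative:
            count += 1
    return count


def deconvolute_patient(cohort, patient_id: str,
                        part_config=None, config: DeconvConfig | None = None):
    """Run the partition + deconvolution stages for one patient.

    Returns (forest, partitions, pdata). The forest carries
    ``origin_count`` as an attribute.
    """
    from .partition import PartitionConfig, build_partitions

    cfg = config or DeconvConfig()
    pdata = PatientData(cohort, patient_id, part_config or PartitionConfig())
    partitions, _log = build_partitions(pdata)
    chains = []
    unresolved = None
    for pid, p in enumerate(partitions):
        if p.private:
            continue
        try:
            chain = partition_to_chain(p, pdata, pid, cfg)
        except UnresolvableError as err:
            unresolved = str(err)
            break
        if chain is not None:
            chains.append(chain)
    if unresolved is not None:
        forest = PhylogenyForest(patient_id, [], status="unresolvable")
        forest.failure_reason = unresolved
    else:
        forest = assemble_forest(chains, pdata, partitions, cfg)
    forest.origin_count = (count_origins(forest, pdata, partitions, cfg)
                           if forest.status == "resolved" else 0)
    return forest, partitions, pdata
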