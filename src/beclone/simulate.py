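"""Synthetic multi-region Barrett's cohort generator with known ground truth.

Real cohorts of this kind (4–6 biopsies per patient over 2–3 endoscopies,
~60x whole-genome sequencing) are access-controlled, so every downstream
stage is exercised against simulated patients with a known clone forest.

The generative model, per patient:

1. Draw the number of independent origins; partition the patient's biopsies
   among origins (spatially contiguous blocks along the cm-from-GEJ axis
   with probability ``spatial_autocorr``, otherwise at random — the knob
   that makes spatial phylogenetic clustering a tunable truth while time
   point never correlates with clone structure).
2. Grow a random bifurcating clone tree per origin; each branch (including
   the trunk) accumulates a uniform number of neutral SNVs.
3. Each biopsy carries its own primary clone and, with probability
   ``p_extra_lineage``, a minority lineage borrowed from another clone of
   the same origin, giving within-biopsy subclonal mixtures.
4. Whole-genome doubling may occur on an origin trunk: trunk SNVs arising
   before the doubling sit on 2 of 4 copies, later SNVs on 1 of 4, so the
   doubling leaves the characteristic factor-of-two split between VAF
   peaks in all descendant samples.
5. Read counts are Poisson-depth/Binomial-alt; an SNV is detected in a
   sample when it has at least ``detection_min_alt`` alternate reads,
   which produces realistic allelic dropout of low-cell-fraction lineages.

The defaults encode the cohort the analysis is designed for: 40/40
cancer/noncancer outcome patients, 60x depth, origin-count frequencies
43:29:5:1, and a ~15% detectability floor on clone cell fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Clade, Cohort, LineageTip, PhylogenyForest, new_tip
from . import io as _io

CHROMS = [str(c) for c in range(1, 23)]
CHROM_LEN = 100_000_000

#: candidate loci (gene symbols) with fixed synthetic genomic intervals;
#: the 14 loci carrying 25+ functional mutations in cohorts of this kind.
CANDIDATE_LOCI = [
    "ARID1A", "CDKN2A", "CSMD1", "CSMD3", "FAT3", "LAMA1", "LRP1B",
    "MUC16", "MUC19", "PCLO", "SMARCA4", "SYNE1", "TP53", "TTN",
]


def locus_interval(locus: str) -> tuple[str, int, int]:
    """Fixed synthetic 100-kb interval for a candidate locus (chrom 1..14)."""
    i = CANDIDATE_LOCI.index(locus)
    start = 10_000_001 + i * 1_000_000
    return CHROMS[i], start, start + 100_000


class SimulationError(RuntimeError):
    """No feasible clone/biopsy configuration after bounded retries."""


@dataclass
class LocusParams:
    p_mut: float = 0.35          # per-patient probability of one functional SNV
    p_hom: float = 0.4           # probability the mutation is homozygous
    p_secondary_hom: float = 0.1  # het mutation gains a tipward hom transition
    expansion_bias: float = 0.0  # >0 biases placement toward high-CF branches


def default_loci() -> dict:
    loci = {name: LocusParams() for name in CANDIDATE_LOCI}
    # expansion of null-allele clones is the real-data signature of these two
    loci["TP53"] = LocusParams(expansion_bias=1.0)
    loci["CDKN2A"] = LocusParams(expansion_bias=1.0)
    return loci


@dataclass
class SimParams:
    """Generator knobs; defaults are the cohort conditions described above."""

    n_patients: int = 80
    depth_mean: float = 60.0
    n_origins_distribution: dict = field(
        default_factory=lambda: {1: 43 / 78, 2: 29 / 78, 3: 5 / 78, 4: 1 / 78})
    snvs_per_branch_range: tuple = (150, 700)
    gd_trunk_snv_range: tuple = (400, 700)
    min_clone_cf: float = 0.15
    p_extra_lineage: float = 0.35
    spatial_autocorr: float = 1.0
    p_genome_doubling: float = 0.12   # per origin trunk
    p_unbalanced_cn: float = 0.05     # per chromosome (chroms 15-22 only)
    p_tp3: float = 0.25               # NCO patients with a third time point
    candidate_loci: dict = field(default_factory=default_loci)
    detection_min_alt: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in [self.p_extra_lineage, self.spatial_autocorr,
                  self.p_genome_doubling, self.p_unbalanced_cn, self.p_tp3]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.min_clone_cf < 1.0:
            raise ValueError("min_clone_cf must lie in (0, 1)")
        if self.snvs_per_branch_range[0] <= 0:
            raise ValueError("snvs_per_branch_range must be positive")
        total = sum(self.n_origins_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("n_origins_distribution must sum to 1")


@dataclass
class TruePatient:
    """Ground truth for one simulated patient."""

    patient_id: str
    forest: PhylogenyForest                 # observable truth (tips = biopsy-lineage)
    tip_cf: dict                            # tip label -> true divergence CF
    gd_branches: list                       # labels of branches carrying GD
    placements: list                        # candidate-locus truth records
    origin_count: int


def sample_reads(true_vaf, depth_mean: float, rng: np.random.Generator,
                 size=None) -> tuple[np.ndarray, np.ndarray]:
    """Poisson total depth (min 1) and binomial alternate reads."""
    vaf = np.asarray(true_vaf, dtype=float)
    if size is None:
        size = vaf.shape
    tot = np.maximum(rng.poisson(depth_mean, size=size), 1)
    alt = rng.binomial(tot, np.broadcast_to(vaf, tot.shape))
    return alt, tot


# ---------------------------------------------------------------------------
# internal clone-tree machinery
# ---------------------------------------------------------------------------

class _CloneNode:
    __slots__ = ("children", "parent", "n_snvs", "leaf_id")

    def __init__(self, leaf_id=None):
        self.children = []
        self.parent = None
        self.n_snvs = 0
        self.leaf_id = leaf_id

    def leaves(self):
        if self.leaf_id is not None:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def _random_clone_tree(n_leaves: int, rng) -> _CloneNode:
    nodes = [_CloneNode(leaf_id=i) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _CloneNode()
        for k in (i, j):
            parent.children.append(nodes[k])
            nodes[k].parent = parent
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def _ladder_order(root: _CloneNode) -> list[int]:
    return [n.leaf_id for n in root.leaves()]


def simulate_patient(params: SimParams, rng: np.random.Generator,
                     patient_id: str, outcome: str):
    """Simulate one patient; returns (TruePatient, meta rows, snv table, cn rows)."""
    n_tp = 3 if (outcome == "NCO" and rng.random() < params.p_tp3) else 2
    n_biopsies = 2 * n_tp
    letters = [chr(ord("A") + i) for i in range(n_biopsies)]

    # biopsy positions (cm above the GEJ), distinct, spread over the segment
    seg_top = rng.uniform(4.0, 12.0)
    pos = np.sort(rng.uniform(0.5, seg_top, size=n_biopsies))
    pos = np.round(pos, 1) + np.arange(n_biopsies) * 0.01  # enforce distinctness
    order = rng.permutation(n_biopsies)  # position is independent of time point
    time_points = [f"TP{1 + order[i] // 2}" for i in range(n_biopsies)]

    # origins and biopsy->origin assignment
    ks = sorted(params.n_origins_distribution)
    probs = np.array([params.n_origins_distribution[k] for k in ks])
    n_origins = int(rng.choice(ks, p=probs / probs.sum()))
    n_origins = min(n_origins, n_biopsies)
    spatial = rng.random() < params.spatial_autocorr
    by_pos = np.argsort(pos)
    if spatial:
        cuts = np.sort(rng.choice(np.arange(1, n_biopsies), size=n_origins - 1,
                                  replace=False)) if n_origins > 1 else np.array([], int)
        blocks = np.split(by_pos, cuts)
    else:
        perm = rng.permutation(n_biopsies)
        cuts = np.sort(rng.choice(np.arange(1, n_biopsies), size=n_origins - 1,
                                  replace=False)) if n_origins > 1 else np.array([], int)
        blocks = np.split(perm, cuts)

    gd_origin = [rng.random() < params.p_genome_doubling for _ in range(n_origins)]
    patient_gd = any(gd_origin)

    # unbalanced chromosomes (kept away from candidate loci and GD patients)
    unbalanced = set()
    if not patient_gd:
        for c in CHROMS[14:]:
            if rng.random() < params.p_unbalanced_cn:
                unbalanced.add(c)

    origins = []
    for oi, block in enumerate(blocks):
        bset = [letters[i] for i in block]
        if spatial:
            bset = [letters[i] for i in sorted(block, key=lambda i: pos[i])]
        origins.append(_simulate_origin(params, rng, bset, gd_origin[oi]))

    # candidate-locus functional mutations
    placements = []
    for locus, lp in sorted(params.candidate_loci.items()):
        if rng.random() < lp.p_mut:
            placements.append(_place_candidate(rng, origins, locus, lp, patient_gd))
    placements = [p for p in placements if p is not None]

    # ---- observable truth forest -------------------------------------
    trees, tip_cf, gd_branches = [], {}, []
    for org in origins:
        tree, mapping = _truth_tree(org)
        org["tree_root"] = tree
        org["edge_map"] = mapping
        trees.append(tree)
    forest = PhylogenyForest(patient_id, trees)
    _assign_lineage_indices(forest)
    for org in origins:
        if org["gd"]:
            gd_branches.append(_clade_label(org["tree_root"]))
    for t in forest.tips():
        tip_cf[t.tip.label] = t.tip.cell_fraction

    # ---- tables ------------------------------------------------------
    snv_samples = [f"{patient_id}_{b}" for b in letters]
    snv_df = _emit_snvs(params, rng, patient_id, letters, snv_samples, origins,
                        placements, unbalanced)
    for pl in placements:
        pl["branch_label"] = _edge_label(pl.pop("origin"), pl.pop("edge"))

    truth = TruePatient(patient_id=patient_id, forest=forest, tip_cf=tip_cf,
                        gd_branches=gd_branches, placements=placements,
                        origin_count=len(trees))

    samples = snv_samples
    meta_rows = []
    for i, b in enumerate(letters):
        org = next(o for o in origins if b in o["biopsies"])
        tetra = org["gd"]
        meta_rows.append({
            "patient": patient_id, "biopsy": b, "sample": samples[i],
            "time_point": time_points[i], "gej_cm": float(pos[i]),
            "outcome": outcome,
            "ploidy_class": "near_tetraploid" if tetra else "near_diploid",
            "gd_corroborated": bool(tetra),
        })

    cn_rows = []
    for i, b in enumerate(letters):
        org = next(o for o in origins if b in o["biopsies"])
        base = (2, 2) if org["gd"] else (1, 1)
        for c in CHROMS:
            maj, mino = base
            if c in unbalanced:
                maj, mino = 2, 1
            cn_rows.append({"sample": samples[i], "chrom": c, "start": 1,
                            "end": CHROM_LEN, "major": maj, "minor": mino})

    return truth, meta_rows, snv_df, cn_rows


def _simulate_origin(params: SimParams, rng, biopsies: list, gd: bool) -> dict:
    m = len(biopsies)
    root = _random_clone_tree(m, rng)
    leaf_order = _ladder_order(root)
    # primary clone of biopsy i (spatial rank) = leaf at ladder rank i
    primary_of = {}
    for rank, leaf in enumerate(leaf_order):
        primary_of[leaf] = biopsies[rank]

    # composition: biopsy -> {leaf_id: cf}
    comp = {b: {} for b in biopsies}
    secondary = {}
    leaves = {n.leaf_id: n for n in root.leaves()}
    for leaf, b in primary_of.items():
        has_extra = (m >= 3) and (rng.random() < params.p_extra_lineage)
        if has_extra:
            # borrow a non-sibling clone as a minority lineage; a leaf's
            # sibling clone would make two branches carry the same sample set
            candidates = [l for l in leaves if l != leaf and
                          not (leaves[l].parent is leaves[leaf].parent)]
            if candidates:
                other = int(rng.choice(sorted(candidates)))
                p_cf = rng.uniform(0.5, 0.7)
                s_cf = rng.uniform(max(0.2, params.min_clone_cf + 0.05),
                                   min(0.4, 0.95 - p_cf))
                comp[b][leaf] = p_cf
                comp[b][other] = s_cf
                secondary[b] = other
                continue
        comp[b][leaf] = rng.uniform(0.6, 0.95)

    _fix_degenerate(root, comp, primary_of, secondary)

    # branch SNV counts
    lo, hi = params.snvs_per_branch_range
    for node in root.walk():
        node.n_snvs = int(rng.integers(lo, hi + 1))
    if gd:
        glo, ghi = params.gd_trunk_snv_range
        root.n_snvs = int(rng.integers(glo, ghi + 1))
        f_pre = rng.uniform(0.35, 0.65)
    else:
        f_pre = 1.0

    return {"root": root, "biopsies": biopsies, "comp": comp, "gd": gd,
            "f_pre": f_pre, "primary_of": primary_of}


def _edge_biopsy_sets(root: _CloneNode, comp: dict) -> dict:
    """Map clone node -> set of biopsies containing any clone below its edge."""
    out = {}

    def rec(node):
        if node.leaf_id is not None:
            s = {b for b, mix in comp.items() if node.leaf_id in mix}
        else:
            s = set()
            for c in node.children:
                s |= rec(c)
        out[id(node)] = s
        return s

    rec(root)
    return out


def _fix_degenerate(root, comp, primary_of, secondary, max_rounds: int = 20):
    """Drop secondary lineages that make branch sample-sets non-identifiable.

    Two branches with identical multi-biopsy sample sets (outside a
    parent-child chain the deconvolution can resolve by VAF) cannot be told
    apart, so the truth would be unrecoverable by construction, not by
    failure of the method.
    """
    for _ in range(max_rounds):
        sets = _edge_biopsy_sets(root, comp)
        seen, conflict_biopsy = {}, None
        for node in root.walk():
            s = frozenset(sets[id(node)])
            if len(s) < 2:
                continue
            parent = node.parent
            if parent is not None and frozenset(sets[id(parent)]) == s:
                conflict_biopsy = _some_secondary(s, secondary)
                break
            if s in seen:
                conflict_biopsy = _some_secondary(s, secondary)
                break
            seen[s] = node
        if conflict_biopsy is None:
            return
        other = secondary.pop(conflict_biopsy)
        comp[conflict_biopsy].pop(other, None)
    raise SimulationError("could not reach an identifiable clone configuration")


def _some_secondary(sample_set, secondary):
    for b in sorted(sample_set):
        if b in secondary:
            return b
    if secondary:
        return sorted(secondary)[0]
    raise SimulationError("degenerate clone tree without secondary lineages")


def _truth_tree(org: dict) -> tuple[Clade, dict]:
    """Observable truth tree plus a clone-edge -> truth-clade mapping."""
    comp = org["comp"]
    mapping: dict[int, Clade] = {}

    def rec(node: _CloneNode) -> Clade:
        if node.leaf_id is not None:
            holders = sorted(b for b, mix in comp.items() if node.leaf_id in mix)
            tips = [new_tip(b, 0, comp[b][node.leaf_id]) for b in holders]
            if len(tips) == 1:
                tip = tips[0]
                tip.n_snvs = node.n_snvs
                mapping[id(node)] = tip
                return tip
            parent = Clade(n_snvs=node.n_snvs)
            for t in tips:
                parent.add_child(t)
            mapping[id(node)] = parent
            return parent
        clade = Clade(n_snvs=node.n_snvs)
        for c in node.children:
            clade.add_child(rec(c))
        mapping[id(node)] = clade
        return clade

    root = rec(org["root"])
    root.gd = org["gd"]
    return root, mapping


def _assign_lineage_indices(forest: PhylogenyForest) -> None:
    """Number lineages within each biopsy by descending cell fraction."""
    by_biopsy: dict[str, list] = {}
    for t in forest.tips():
        by_biopsy.setdefault(t.tip.biopsy_id, []).append(t)
    for b, tips in by_biopsy.items():
        tips.sort(key=lambda t: (-(t.tip.cell_fraction or 0.0), id(t)))
        for i, t in enumerate(tips, start=1):
            t.tip.lineage_index = i
    forest.relabel()


def _clade_label(node: Clade) -> str:
    return node.tip.label if node.is_tip else node.label


def _edge_label(org: dict, edge: _CloneNode) -> str:
    """Label of the truth-forest branch matching a clone-tree edge."""
    return _clade_label(org["edge_map"][id(edge)])


def _place_candidate(rng, origins, locus, lp: LocusParams, patient_gd: bool):
    edges, weights = [], []
    for oi, org in enumerate(origins):
        sets = _edge_biopsy_sets(org["root"], org["comp"])
        for node in org["root"].walk():
            cf_total = sum(org["comp"][b].get(l, 0.0)
                           for b in org["biopsies"]
                           for l in _leaves_below(node))
            w = node.n_snvs * (1.0 + cf_total) ** lp.expansion_bias \
                if lp.expansion_bias > 0 else node.n_snvs
            edges.append((oi, node))
            weights.append(w)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        return None
    oi, edge = edges[int(rng.choice(len(edges), p=weights / weights.sum()))]
    hom = rng.random() < lp.p_hom
    secondary_edge = None
    if not hom and rng.random() < lp.p_secondary_hom:
        below = [n for n in edge.walk() if n is not edge]
        if below:
            secondary_edge = below[int(rng.integers(len(below)))]
    return {"locus": locus, "origin": origins[oi], "edge": edge,
            "zygosity": "homozygous" if hom else "heterozygous",
            "secondary_edge": secondary_edge}


def _leaves_below(node: _CloneNode):
    return [n.leaf_id for n in node.walk() if n.leaf_id is not None]


def _emit_snvs(params, rng, patient_id, letters, samples, origins,
               placements, unbalanced) -> pd.DataFrame:
    rows_alt, rows_tot, fixed = [], [], []
    n_samples = len(letters)
    biopsy_idx = {b: i for i, b in enumerate(letters)}
    bg_chroms = [c for c in CHROMS if c not in {locus_interval(l)[0]
                                                for l in CANDIDATE_LOCI}]

    def cf_vector(org, edge) -> np.ndarray:
        leaves = _leaves_below(edge)
        cf = np.zeros(n_samples)
        for b in org["biopsies"]:
            cf[biopsy_idx[b]] = sum(org["comp"][b].get(l, 0.0) for l in leaves)
        return cf

    for org in origins:
        tetra = org["gd"]
        for node in org["root"].walk():
            n = node.n_snvs
            cf = cf_vector(org, node)
            is_trunk = node.parent is None
            n_pre = int(round(org["f_pre"] * n)) if (tetra and is_trunk) else (
                n if not tetra else 0)
            # copy fraction per SNV batch: (mut_copies, total_copies)
            batches = []
            if tetra:
                if n_pre:
                    batches.append((n_pre, 2, 4))
                if n - n_pre:
                    batches.append((n - n_pre, 1, 4))
            else:
                batches.append((n, 1, 2))
            for n_b, mut, tot_cp in batches:
                chroms = rng.choice(bg_chroms, size=n_b)
                positions = rng.integers(1, CHROM_LEN, size=n_b)
                mutc = np.full(n_b, mut, dtype=float)
                totc = np.full(n_b, tot_cp, dtype=float)
                if not tetra and unbalanced:
                    in_unb = np.isin(chroms, list(unbalanced))
                    on_major = rng.random(n_b) < (2.0 / 3.0)
                    mutc[in_unb & on_major] = 2
                    totc[in_unb] = 3
                vaf = np.clip(cf[None, :] * (mutc / totc)[:, None], 0, 1)
                sev = rng.choice(["MODIFIER", "LOW", "MODERATE"], size=n_b,
                                 p=[0.6, 0.39, 0.01])
                alt, tot = sample_reads(vaf, params.depth_mean, rng)
                rows_alt.append(alt)
                rows_tot.append(tot)
                for k in range(n_b):
                    fixed.append((chroms[k], int(positions[k]),
                                  sev[k], ""))

    # candidate-locus mutations
    for pl in placements:
        owner = pl["origin"]
        tetra = owner["gd"]
        total_cp = 4 if tetra else 2
        cf = cf_vector(owner, pl["edge"])
        if pl["zygosity"] == "homozygous":
            vaf = cf
        else:
            het_mut = 1
            vaf = cf * het_mut / total_cp
            sec = pl.get("secondary_edge")
            if sec is not None:
                cf_sec = cf_vector(owner, sec)
                vaf = (cf - cf_sec) * het_mut / total_cp + cf_sec
        chrom, lo, hi = locus_interval(pl["locus"])
        alt, tot = sample_reads(np.clip(vaf, 0, 1)[None, :], params.depth_mean, rng)
        rows_alt.append(alt)
        rows_tot.append(tot)
        sev = "MODERATE" if rng.random() < 0.7 else "HIGH"
        fixed.append((chrom, int(rng.integers(lo, hi)), sev, pl["locus"]))
        pl["severity"] = sev
        if pl.get("secondary_edge") is not None:
            pl["secondary_branch_label"] = _edge_label(owner, pl["secondary_edge"])
        pl.pop("secondary_edge", None)

    alt = np.vstack(rows_alt)
    tot = np.vstack(rows_tot)
    bases = np.array(list("ACGT"))
    n = len(fixed)
    ref = rng.choice(bases, size=n)
    alt_base = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    df = pd.DataFrame({
        "patient": patient_id,
        "chrom": [f[0] for f in fixed],
        "pos": [f[1] for f in fixed],
        "ref": ref, "alt": alt_base,
        "severity": [f[2] for f in fixed],
        "locus": [f[3] for f in fixed],
    })
    for i, s in enumerate(samples):
        df[f"{s}_alt"] = alt[:, i]
        df[f"{s}_tot"] = tot[:, i]
    return df


# ---------------------------------------------------------------------------
# cohort-level driver and truth serialization
# ---------------------------------------------------------------------------

def simulate_cohort(params: SimParams) -> tuple[Cohort, dict]:
    """Simulate ``params.n_patients`` patients; returns (cohort, truths).

    Outcomes alternate CO/NCO so the cohort is balanced; all randomness
    flows from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    meta_rows, snv_tables, cn_rows, truths = [], {}, [], {}
    for i in range(params.n_patients):
        pid = f"P{i + 1:03d}"
        outcome = "CO" if i % 2 == 0 else "NCO"
        truth, meta, snvs, cn = simulate_patient(params, rng, pid, outcome)
        truths[pid] = truth
        meta_rows.extend(meta)
        snv_tables[pid] = snvs
        cn_rows.extend(cn)
    cohort = Cohort(meta=pd.DataFrame(meta_rows), snvs=snv_tables,
                    cn=pd.DataFrame(cn_rows))
    return cohort, truths


def export_truth(truth: TruePatient, path) -> Path:
    payload = _io.forest_to_dict(truth.forest, origin_count=truth.origin_count)
    payload["tip_cf"] = truth.tip_cf
    payload["gd_branches"] = truth.gd_branches
    payload["placements"] = [
        {k: v for k, v in pl.items()} for pl in truth.placements
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def load_truth(path) -> TruePatient:
    payload = json.loads(Path(path).read_text())
    forest = _io.forest_from_dict(payload)
    return TruePatient(
        patient_id=payload["patient_id"], forest=forest,
        tip_cf=payload["tip_cf"], gd_branches=payload["gd_branches"],
        placements=payload["placements"], origin_count=payload["origin_count"],
    )
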