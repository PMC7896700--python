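"""Permutation and resampling tests on deconvoluted forests.

The generating process of within-patient phylogenies has no tractable
likelihood, so significance is assessed by permuting or resampling data on
the inferred forests themselves: 10,000 resampled data sets by default,
counting the proportion more extreme than the observation, resolving ties
at random, doubling the tail for two-tailed tests, and reporting
Benjamini-Hochberg q values within each test family. Spatial/temporal
clustering uses minimum parsimony state changes (unordered for labels,
linear-cost for cm positions) summed over a patient's trees with no
changes scored between disjoint trees; candidate-locus tests resample
mutation placements onto branches weighted by branch length (SNV count).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import Clade, PhylogenyForest

DEFAULT_RESAMPLES = 10_000


@dataclass
class PermutationResult:
    name: str
    observed: float
    null_mean: float
    n_resamples: int
    tail: str                 # "one" | "two"
    p_value: float
    p_repr: str
    seed: int | None = None
    q_value: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "observed": self.observed,
                "null_mean": self.null_mean, "p": self.p_value,
                "p_repr": self.p_repr, "q": self.q_value,
                "tail": self.tail, "n_resamples": self.n_resamples,
                "seed": self.seed, **self.extra}


def permutation_pvalue(observed: float, resampled, tail: str,
                       rng: np.random.Generator,
                       direction: str = "less") -> tuple[float, str]:
    """p from a resampled null with random tie-breaking.

    ``direction`` names the extreme side for a one-tailed test ("less":
    smaller values are more extreme). Two-tailed doubles the smaller tail
    fraction, capped at 1. Returns (numeric p, printable p); when no
    resample is as extreme the printable form is "<1/n" and the numeric
    value is floored at 1/n.
    """
    res = np.asarray(resampled, dtype=float)
    n = len(res)
    if n < 1:
        raise ValueError("need at least one resample")
    ties = int((res == observed).sum())
    tie_low = int(rng.binomial(ties, 0.5)) if ties else 0
    lower = int((res < observed).sum()) + tie_low
    upper = int((res > observed).sum()) + (ties - tie_low)
    if tail == "one":
        count = lower if direction == "less" else upper
        p = count / n
    elif tail == "two":
        p = min(1.0, 2.0 * min(lower, upper) / n)
    else:
        raise ValueError("tail must be 'one' or 'two'")
    if p == 0.0:
        return 1.0 / n, f"<{1.0 / n:g}"
    return p, f"{p:g}"


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def apply_bh(results: list[PermutationResult]) -> None:
    qs = bh_correct([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _sankoff(node: Clade, states: list, state_of: dict, cost) -> np.ndarray:
    if node.is_tip:
        vec = np.full(len(states), np.inf)
        vec[states.index(state_of[node.tip.biopsy_id])] = 0.0
        return vec
    total = np.zeros(len(states))
    for child in node.children:
        cvec = _sankoff(child, states, state_of, cost)
        total += np.min(cvec[None, :] + cost, axis=1)
    return total


def parsimony_changes(forest: PhylogenyForest, tip_states: dict,
                      mode: str = "unordered") -> float:
    """Minimum total state changes required by the forest.

    ``tip_states`` maps biopsy id to its state (all lineages of a biopsy
    share it). Unordered states cost 1 per change; ordered (numeric)
    states cost the absolute difference. Changes are never scored between
    disjoint trees.
    """
    for t in forest.tips():
        if t.tip.biopsy_id not in tip_states:
            raise ValueError(f"tip biopsy {t.tip.biopsy_id!r} unlabeled")
    total = 0.0
    for tree in forest.trees:
        seen = sorted({tip_states[t.tip.biopsy_id] for t in tree.tips()})
        if len(seen) == 1:
            continue
        if mode == "unordered":
            cost = 1.0 - np.eye(len(seen))
        elif mode == "ordered":
            vals = np.asarray(seen, dtype=float)
            cost = np.abs(vals[:, None] - vals[None, :])
        else:
            raise ValueError("mode must be 'unordered' or 'ordered'")
        total += float(np.min(_sankoff(tree, seen, tip_states, cost)))
    return total


def classify_upper_lower(gej_cm: dict) -> dict | None:
    """Assign biopsies to Lower/Upper halves of the segment.

    The lowest biopsy and those closer to it than to the highest are "L";
    the rest are "U". Equidistant biopsies join the less numerous group,
    or "U" on a tie. Returns None (patient excluded) when all biopsies sit
    at the same distance.
    """
    xs = np.array(list(gej_cm.values()), dtype=float)
    lo, hi = xs.min(), xs.max()
    if lo == hi:
        return None
    labels = {}
    equidistant = []
    for b, x in gej_cm.items():
        d_lo, d_hi = abs(x - lo), abs(x - hi)
        if d_lo < d_hi:
            labels[b] = "L"
        elif d_hi < d_lo:
            labels[b] = "U"
        else:
            equidistant.append(b)
    if equidistant:
        n_l = sum(1 for v in labels.values() if v == "L")
        n_u = sum(1 for v in labels.values() if v == "U")
        fill = "U" if n_u <= n_l else "L"
        for b in equidistant:
            labels[b] = fill
    return labels


# ---------------------------------------------------------------------------
# clustering tests (time point, upper/lower, cm from GEJ)
# ---------------------------------------------------------------------------

def _patient_labels(meta: pd.DataFrame, patient: str, labeling: str):
    sub = meta[meta["patient"] == patient]
    cm = dict(zip(sub["biopsy"], sub["gej_cm"]))
    if labeling == "time_point":
        return dict(zip(sub["biopsy"], sub["time_point"])), "unordered"
    if labeling == "upper_lower":
        labels = classify_upper_lower(cm)
        return labels, "unordered"
    if labeling == "gej_cm":
        return cm, "ordered"
    raise ValueError(f"unknown labeling {labeling!r}")


class _PatientScorer:
    """Caches parsimony scores per distinct biopsy-label assignment."""

    def __init__(self, forest: PhylogenyForest, biopsies: list, mode: str):
        self.forest = forest
        self.biopsies = biopsies
        self.mode = mode
        self._cache: dict[tuple, float] = {}

    def score(self, labels: tuple) -> float:
        val = self._cache.get(labels)
        if val is None:
            val = parsimony_changes(self.forest,
                                    dict(zip(self.biopsies, labels)), self.mode)
            self._cache[labels] = val
        return val


def clustering_test(forests: dict, meta: pd.DataFrame, labeling: str,
                    subgroup: str = "all",
                    n_resamples: int = DEFAULT_RESAMPLES,
                    seed: int = 0) -> PermutationResult:
    """Are same-label biopsies clustered on the forests? One-tailed.

    Observed statistic: parsimony changes summed over the subgroup's
    patients. Null: biopsy labels permuted within each patient (all
    lineages of a biopsy move together). Clustering shows as fewer changes
    than the permuted data.
    """
    rng = np.random.default_rng(seed)
    scorers, observed = [], 0.0
    for pid, forest in sorted(forests.items()):
        if forest.status != "resolved" or not forest.tips():
            continue
        sub = meta[meta["patient"] == pid]
        if subgroup != "all" and sub["outcome"].iloc[0] != subgroup:
            continue
        labels, mode = _patient_labels(meta, pid, labeling)
        if labels is None:
            continue
        biopsies = sorted(forest.biopsy_ids())
        vec = tuple(labels[b] for b in biopsies)
        scorer = _PatientScorer(forest, biopsies, mode)
        observed += scorer.score(vec)
        scorers.append((scorer, vec))
    if not scorers:
        raise ValueError(f"no patients in subgroup {subgroup!r}")

    null = np.zeros(n_resamples)
    for scorer, vec in scorers:
        arr = np.array(vec, dtype=object)
        for r in range(n_resamples):
            null[r] += scorer.score(tuple(arr[rng.permutation(len(arr))]))
    p, p_repr = permutation_pvalue(observed, null, "one", rng, direction="less")
    return PermutationResult(
        name=f"clustering[{labeling}]", observed=observed,
        null_mean=float(null.mean()), n_resamples=n_resamples, tail="one",
        p_value=p, p_repr=p_repr, seed=seed,
        extra={"subgroup": subgroup, "n_patients": len(scorers)})


def clustering_table(forests: dict, meta: pd.DataFrame,
                     n_resamples: int = DEFAULT_RESAMPLES,
                     seed: int = 0) -> list[PermutationResult]:
    """The nine clustering tests (3 criteria x all/CO/NCO) with family BH."""
    results = []
    for i, labeling in enumerate(["time_point", "upper_lower", "gej_cm"]):
        for j, subgroup in enumerate(["all", "CO", "NCO"]):
            results.append(clustering_test(
                forests, meta, labeling, subgroup, n_resamples,
                seed=seed + 7 * i + j))
    apply_bh(results)
    return results


# ---------------------------------------------------------------------------
# subclonality tests
# ---------------------------------------------------------------------------

def subclonality_tests(forests: dict, meta: pd.DataFrame,
                       n_resamples: int = DEFAULT_RESAMPLES,
                       seed: int = 0) -> list[PermutationResult]:
    """Four permutation tests on which samples harbor multiple lineages.

    A sample is subclonal when the forest shows it with two or more
    lineages (private-SNV substructure disregarded). Subclonality status
    is permuted across the whole data set; all tests are two-tailed. The
    TP1/TP2 comparison omits TP3 samples.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pid, forest in sorted(forests.items()):
        if forest.status != "resolved":
            continue
        sub_b = forest.subclonal_biopsies()
        msub = meta[meta["patient"] == pid]
        ul = classify_upper_lower(dict(zip(msub["biopsy"], msub["gej_cm"])))
        for _, row in msub.iterrows():
            if row["biopsy"] not in forest.biopsy_ids():
                continue
            rows.append({
                "patient": pid, "biopsy": row["biopsy"],
                "subclonal": row["biopsy"] in sub_b,
                "outcome": row["outcome"], "time_point": row["time_point"],
                "ul": None if ul is None else ul[row["biopsy"]],
            })
    df = pd.DataFrame(rows)
    status = df["subclonal"].to_numpy()

    def run(name, mask, statistic):
        obs = statistic(status, mask)
        null = np.empty(n_resamples)
        for r in range(n_resamples):
            null[r] = statistic(status[rng.permutation(len(status))], mask)
        p, p_repr = permutation_pvalue(obs, null, "two", rng)
        return PermutationResult(
            name=name, observed=float(obs), null_mean=float(null.mean()),
            n_resamples=n_resamples, tail="two", p_value=p, p_repr=p_repr,
            seed=seed, extra={"n_samples": int(mask.sum())})

    patients = df["patient"].to_numpy()

    def n_patients_hit(st, _mask):
        return len(np.unique(patients[st]))

    full = np.ones(len(df), dtype=bool)
    results = [run("subclonal_patient_clustering", full, n_patients_hit)]

    for name, column, target in [("subclonal_CO_vs_NCO", "outcome", "CO"),
                                 ("subclonal_U_vs_L", "ul", "U"),
                                 ("subclonal_TP1_vs_TP2", "time_point", "TP1")]:
        if column == "time_point":
            valid = df["time_point"].isin(["TP1", "TP2"]).to_numpy()
        elif column == "ul":
            valid = df["ul"].notna().to_numpy()
        else:
            valid = full
        in_target = (df[column] == target).to_numpy() & valid
        # status permuted across all samples; count subclonal in target class
        results.append(run(name, in_target,
                           lambda st, m=in_target: int((st & m).sum())))
    apply_bh(results)
    return results


# ---------------------------------------------------------------------------
# candidate-locus tests
# ---------------------------------------------------------------------------

class _ForestIndex:
    """Precomputed branch arrays for fast weighted re-placement."""

    def __init__(self, forest: PhylogenyForest):
        self.nodes = forest.branches()
        self.labels = []
        self.lengths = np.zeros(len(self.nodes))
        self.n_leaves = np.zeros(len(self.nodes))
        self.cf_sum = np.zeros(len(self.nodes))
        self.desc = []           # descendant node index sets (incl. self)
        index_of = {id(n): i for i, n in enumerate(self.nodes)}
        self.index_of_label = {}
        for i, n in enumerate(self.nodes):
            label = n.tip.label if n.is_tip else n.label
            self.labels.append(label)
            self.index_of_label[label] = i
            self.lengths[i] = n.length
            tips = n.tips()
            self.n_leaves[i] = len(tips)
            self.cf_sum[i] = sum(t.tip.cell_fraction or 0.0 for t in tips)
            self.desc.append(frozenset(index_of[id(m)] for m in n.walk()))

    def strictly_below(self, i: int) -> list[int]:
        return [j for j in self.desc[i] if j != i]


def _leaf_stats_for_placement(fx: _ForestIndex, primary: int,
                              secondary: list[int], zygosity: str,
                              zyg_filter: str) -> tuple[float, float]:
    """(leaves, cf) contributed by one placement under a zygosity filter."""
    if zyg_filter == "all":
        return fx.n_leaves[primary], fx.cf_sum[primary]
    if zygosity == "homozygous":
        if zyg_filter == "hom":
            return fx.n_leaves[primary], fx.cf_sum[primary]
        return 0.0, 0.0
    # heterozygous primary, possibly with tipward loss of wild type
    sec_leaves = sum(fx.n_leaves[j] for j in secondary)
    sec_cf = sum(fx.cf_sum[j] for j in secondary)
    if zyg_filter == "hom":
        return sec_leaves, sec_cf
    return fx.n_leaves[primary] - sec_leaves, fx.cf_sum[primary] - sec_cf


def expansion_test(forests: dict, placements: dict, locus: str,
                   zygosity_filter: str = "all",
                   n_resamples: int = DEFAULT_RESAMPLES,
                   seed: int = 0) -> list[PermutationResult]:
    """Do lineages carrying this locus's mutations spread farther than chance?

    Observed: total descendant leaves and total descendant-tip CF over
    mutation-carrying lineages, summed across patients. Null: each
    patient's mutations are re-placed on branches with probability
    proportional to branch length; placements with secondary
    loss-of-wild-type events draw an initial branch among those with
    enough strictly tipward branches, then the secondary events tipward of
    it. Two-tailed. Returns [leaves result, cell-fraction result].
    """
    rng = np.random.default_rng(seed)
    per_patient = []
    obs_leaves = obs_cf = 0.0
    for pid, forest in sorted(forests.items()):
        if forest.status != "resolved":
            continue
        pls = [p for p in placements.get(pid, []) if p.locus == locus]
        if not pls:
            continue
        fx = _ForestIndex(forest)
        specs = []
        for p in pls:
            primary = fx.index_of_label[p.branch_label]
            secondary = [fx.index_of_label[s] for s in p.secondary_events]
            l, c = _leaf_stats_for_placement(
                fx, primary, secondary, p.zygosity, zygosity_filter)
            obs_leaves += l
            obs_cf += c
            specs.append((p.zygosity, len(secondary)))
        per_patient.append((fx, specs))
    if not per_patient:
        raise ValueError(f"no placements for locus {locus!r}")

    null_leaves = np.zeros(n_resamples)
    null_cf = np.zeros(n_resamples)
    for fx, specs in per_patient:
        w = fx.lengths.astype(float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        pw = w / w.sum()
        n_below = np.array([len(fx.strictly_below(i)) for i in range(len(w))])
        for zyg, n_sec in specs:
            if n_sec == 0:
                picks = rng.choice(len(w), size=n_resamples, p=pw)
                for r, i in enumerate(picks):
                    l, c = _leaf_stats_for_placement(fx, i, [], zyg, zygosity_filter)
                    null_leaves[r] += l
                    null_cf[r] += c
            else:
                ok = np.flatnonzero(n_below >= n_sec)
                pw_ok = pw[ok] / pw[ok].sum()
                for r in range(n_resamples):
                    i = int(rng.choice(ok, p=pw_ok))
                    below = fx.strictly_below(i)
                    bw = w[below]
                    bw = bw / bw.sum() if bw.sum() > 0 else np.full(len(below), 1 / len(below))
                    sec = list(rng.choice(below, size=n_sec, replace=False,
                                          p=bw)) if len(below) > n_sec else below
                    l, c = _leaf_stats_for_placement(fx, i, sec, zyg, zygosity_filter)
                    null_leaves[r] += l
                    null_cf[r] += c

    out = []
    for metric, obs, null in [("leaves", obs_leaves, null_leaves),
                              ("cell_fraction", obs_cf, null_cf)]:
        p, p_repr = permutation_pvalue(obs, null, "two", rng)
        out.append(PermutationResult(
            name=f"expansion[{locus}/{metric}/{zygosity_filter}]",
            observed=obs, null_mean=float(null.mean()),
            n_resamples=n_resamples, tail="two", p_value=p, p_repr=p_repr,
            seed=seed, extra={"locus": locus, "metric": metric,
                              "zygosity": zygosity_filter,
                              "n_patients": len(per_patient)}))
    return out


def dispersion_test(forests: dict, placements: dict, locus: str,
                    n_resamples: int = DEFAULT_RESAMPLES,
                    seed: int = 0) -> PermutationResult:
    """Are a locus's mutations concentrated in few patients, or spread out?

    Observed: number of patients carrying at least one mutation in the
    locus. Null: the same total number of mutations falls across all
    patients' branches, weighted by branch length cohort-wide. Two-tailed.
    """
    rng = np.random.default_rng(seed)
    patient_of_branch, weights = [], []
    k = 0
    observed_patients = set()
    for pid, forest in sorted(forests.items()):
        if forest.status != "resolved":
            continue
        pls = [p for p in placements.get(pid, []) if p.locus == locus]
        k += len(pls)
        if pls:
            observed_patients.add(pid)
        for n in forest.branches():
            patient_of_branch.append(pid)
            weights.append(n.length)
    if k == 0:
        raise ValueError(f"no placements for locus {locus!r}")
    w = np.asarray(weights, dtype=float)
    pw = w / w.sum()
    patient_of_branch = np.asarray(patient_of_branch, dtype=object)
    picks = rng.choice(len(w), size=(n_resamples, k), p=pw)
    null = np.array([len(set(patient_of_branch[row])) for row in picks])
    obs = len(observed_patients)
    p, p_repr = permutation_pvalue(obs, null, "two", rng)
    return PermutationResult(
        name=f"dispersion[{locus}]", observed=float(obs),
        null_mean=float(null.mean()), n_resamples=n_resamples, tail="two",
        p_value=p, p_repr=p_repr, seed=seed,
        extra={"locus": locus, "n_mutations": k})


# ---------------------------------------------------------------------------
# ordering of mutation pairs (and genome doubling)
# ---------------------------------------------------------------------------

CONFIGS = ["same_branch", "A_first", "B_first", "skew"]


def _pair_config(fx: _ForestIndex, a: int, b: int) -> str:
    if a == b:
        return "same_branch"
    if b in fx.desc[a]:
        return "A_first"
    if a in fx.desc[b]:
        return "B_first"
    return "skew"


def _gd_branches(forest: PhylogenyForest, fx: _ForestIndex) -> list[int]:
    return [i for i, n in enumerate(fx.nodes) if n.gd]


def ordering_test(forests: dict, placements: dict, locus_a: str, locus_b: str,
                  n_resamples: int = 1000, seed: int = 0,
                  df: int = 6) -> PermutationResult:
    """Phylogenetic ordering of events in two loci (locus_b may be "GD").

    For each patient with both events, all A x B event pairs are scored as
    same-branch / A-ancestral / B-ancestral / skew and averaged within the
    patient; patient vectors are summed. Expectations come from re-placing
    the events at random, weighted by branch length, and the observed and
    expected category counts are compared with a chi-square heterogeneity
    statistic (default 6 df).
    """
    rng = np.random.default_rng(seed)
    per_patient = []
    observed = np.zeros(4)
    for pid, forest in sorted(forests.items()):
        if forest.status != "resolved":
            continue
        fx = _ForestIndex(forest)
        a_idx = [fx.index_of_label[p.branch_label]
                 for p in placements.get(pid, []) if p.locus == locus_a]
        if locus_b == "GD":
            b_idx = _gd_branches(forest, fx)
        else:
            b_idx = [fx.index_of_label[p.branch_label]
                     for p in placements.get(pid, []) if p.locus == locus_b]
        if not a_idx or not b_idx:
            continue
        vec = np.zeros(4)
        pairs = list(itertools.product(a_idx, b_idx))
        for a, b in pairs:
            vec[CONFIGS.index(_pair_config(fx, a, b))] += 1
        observed += vec / len(pairs)
        per_patient.append((fx, len(a_idx), len(b_idx), locus_b == "GD"))
    if not per_patient:
        raise ValueError("no patient carries both events")

    expected = np.zeros(4)
    for fx, n_a, n_b, b_is_gd in per_patient:
        w = fx.lengths.astype(float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        pw = w / w.sum()
        acc = np.zeros(4)
        a_draws = rng.choice(len(w), size=(n_resamples, n_a), p=pw)
        b_draws = rng.choice(len(w), size=(n_resamples, n_b), p=pw)
        for r in range(n_resamples):
            vec = np.zeros(4)
            pairs = list(itertools.product(a_draws[r], b_draws[r]))
            for a, b in pairs:
                vec[CONFIGS.index(_pair_config(fx, int(a), int(b)))] += 1
            acc += vec / len(pairs)
        expected += acc / n_resamples

    mask = expected > 0
    stat = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    p = float(sps.chi2.sf(stat, df))
    ratios = np.where(expected > 0, observed / np.maximum(expected, 1e-12), 0.0)
    most = CONFIGS[int(np.argmax(ratios))]
    return PermutationResult(
        name=f"ordering[{locus_a},{locus_b}]", observed=stat,
        null_mean=0.0, n_resamples=n_resamples, tail="two",
        p_value=max(p, np.finfo(float).tiny), p_repr=f"{p:g}", seed=seed,
        extra={"locus_a": locus_a, "locus_b": locus_b,
               "n_patients": len(per_patient), "df": df,
               "observed_counts": observed.tolist(),
               "expected_counts": expected.tolist(),
               "most_elevated": most})
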