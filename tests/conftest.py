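import numpy as np
import pandas as pd
import pytest

from beclone import (Cohort, SimParams, deconvolute_cohort, simulate_cohort)
from beclone.model import Clade, PhylogenyForest, new_tip


@pytest.fixture(scope="session")
def small_sim():
    """Six default-world patients with ground truth (GD and CN included)."""
    params = SimParams(n_patients=6, seed=11)
    cohort, truths = simulate_cohort(params)
    return cohort, truths


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    cohort, _truths = small_sim
    return deconvolute_cohort(cohort)


def build_toy_cohort(n_snvs: int = 12) -> Cohort:
    """Three biopsies, one patient, hand-written tables."""
    rng = np.random.default_rng(5)
    samples = ["P1_A", "P1_B", "P1_C"]
    meta = pd.DataFrame({
        "patient": "P1", "biopsy": ["A", "B", "C"], "sample": samples,
        "time_point": ["TP1", "TP1", "TP2"], "gej_cm": [1.0, 2.0, 5.0],
        "outcome": "NCO", "ploidy_class": "near_diploid",
        "gd_corroborated": False,
    })
    snvs = pd.DataFrame({
        "patient": "P1",
        "chrom": "1", "pos": np.arange(1, n_snvs + 1) * 1000,
        "ref": "A", "alt": "T", "severity": "MODIFIER", "locus": "",
    })
    for s in samples:
        snvs[f"{s}_alt"] = rng.integers(5, 30, size=n_snvs)
        snvs[f"{s}_tot"] = 60
    cn = pd.DataFrame([{"sample": s, "chrom": "1", "start": 1,
                        "end": 10_000_000, "major": 1, "minor": 1}
                       for s in samples])
    return Cohort(meta=meta, snvs=snvs, cn=cn)


def chain_tree(spec):
    """Build a tree from a nested spec: (length, children_or_tips).

    Tips are given as ("A-1", length, cf) triples.
    """
    def rec(node_spec):
        if isinstance(node_spec[0], str):
            label, length, cf = node_spec
            biopsy, _, idx = label.rpartition("-")
            tip = new_tip(biopsy, int(idx), cf)
            tip.n_snvs = length
            return tip
        length, children = node_spec
        node = Clade(n_snvs=length)
        for c in children:
            node.add_child(rec(c))
        return node

    return rec(spec)


def make_forest(patient_id, *tree_specs) -> PhylogenyForest:
    return PhylogenyForest(patient_id, [chain_tree(s) for s in tree_specs])
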