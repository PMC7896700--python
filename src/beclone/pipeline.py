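"""End-to-end driver: deconvolute a cohort and run the statistics suite."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as _io
from .assign import (assign_snvs_to_branches, cohort_placed_fractions,
                     place_candidate_mutations, placed_fraction)
from .deconvolve import DeconvConfig, deconvolute_patient
from .model import Cohort
from .partition import PartitionConfig
from .simulate import CANDIDATE_LOCI
from . import stats as _stats


def deconvolute_cohort(cohort: Cohort, part_config: PartitionConfig | None = None,
                       config: DeconvConfig | None = None,
                       candidate_loci: list[str] | None = None) -> dict:
    """Deconvolute every patient; returns a result bundle.

    Keys: ``forests`` (patient -> PhylogenyForest, branch lengths set from
    SNV assignment), ``placements`` (patient -> [CandidatePlacement]),
    ``placed`` (per-patient placed fraction summary), ``excluded``
    (unresolvable patients).
    """
    forests, placements, placed, excluded = {}, {}, {}, []
    loci = candidate_loci if candidate_loci is not None else CANDIDATE_LOCI
    for pid in cohort.patients:
        forest, partitions, pdata = deconvolute_patient(
            cohort, pid, part_config, config)
        if forest.status != "resolved":
            excluded.append(pid)
            forests[pid] = forest
            continue
        _assignments, summary = assign_snvs_to_branches(forest, pdata)
        if summary["n_usable"]:
            placed[pid] = placed_fraction(summary)
        placements[pid] = place_candidate_mutations(forest, pdata, loci)
        forests[pid] = forest
    bundle = {
        "forests": forests,
        "placements": placements,
        "placed": cohort_placed_fractions(placed) if placed else {},
        "excluded": excluded,
    }
    return bundle


def run_stats(bundle: dict, cohort: Cohort,
              n_resamples: int = 1000, seed: int = 0,
              loci: list[str] | None = None) -> dict:
    """Clustering, subclonality, and candidate-locus tests on a bundle."""
    forests = bundle["forests"]
    meta = cohort.meta
    results = {}
    results["clustering"] = [
        r.to_dict() for r in _stats.clustering_table(
            forests, meta, n_resamples=n_resamples, seed=seed)]
    results["subclonality"] = [
        r.to_dict() for r in _stats.subclonality_tests(
            forests, meta, n_resamples=n_resamples, seed=seed + 100)]

    present = sorted({p.locus for pls in bundle["placements"].values()
                      for p in pls})
    if loci is not None:
        present = [l for l in present if l in loci]
    expansion = []
    for i, locus in enumerate(present):
        for zf in ("all", "het", "hom"):
            try:
                expansion.extend(_stats.expansion_test(
                    forests, bundle["placements"], locus, zf,
                    n_resamples=n_resamples, seed=seed + 200 + i))
            except ValueError:
                continue
    _stats.apply_bh([r for r in expansion]) if expansion else None
    results["expansion"] = [r.to_dict() for r in expansion]

    dispersion = []
    for i, locus in enumerate(present):
        try:
            dispersion.append(_stats.dispersion_test(
                forests, bundle["placements"], locus,
                n_resamples=n_resamples, seed=seed + 300 + i))
        except ValueError:
            continue
    if dispersion:
        _stats.apply_bh(dispersion)
    results["dispersion"] = [r.to_dict() for r in dispersion]
    return results


def write_outputs(bundle: dict, results: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, forest in bundle["forests"].items():
        if forest.status == "resolved":
            _io.write_forest(forest, out / pid,
                             origin_count=getattr(forest, "origin_count", None))
    payload = {"placed_fraction": bundle["placed"],
               "excluded_patients": bundle["excluded"],
               "tests": results}
    (out / "stats.json").write_text(json.dumps(payload, indent=1) + "\n")
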