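"""Simulate a small multi-region Barrett's cohort with known ground truth.

Writes the three cohort tables (snvs.tsv, cn.tsv, meta.tsv) plus one
truth.json per patient, then prints what was generated.
"""

from pathlib import Path

from beclone import SimParams, export_truth, simulate_cohort, write_cohort

out = Path("scratch/example_cohort")
params = SimParams(n_patients=6, seed=1)
cohort, truths = simulate_cohort(params)
write_cohort(cohort, out)
for pid, truth in truths.items():
    export_truth(truth, out / f"{pid}.truth.json")

print(f"wrote {out}/snvs.tsv, cn.tsv, meta.tsv")
for pid, truth in sorted(truths.items()):
    n_tips = len(truth.forest.tips())
    n_snvs = len(cohort.patient_snvs(pid))
    print(f"{pid}: {truth.origin_count} origin(s), {n_tips} lineage tips, "
          f"{n_snvs} SNVs, {len(truth.placements)} candidate mutations")
# Each patient is 4-6 biopsies sequenced at ~60x; 'origins' counts disjoint
# clone trees (separate founding lineages of the Barrett's segment), and
# tips are (biopsy, lineage) pairs with true cell fractions.
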