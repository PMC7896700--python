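"""Deconvolute one simulated patient and compare against the ground truth.

Partitions the patient's SNVs by detected-sample subset, finds VAF peaks,
assembles the phylogeny forest, and prints it next to the truth.
"""

from beclone import (SimParams, assign_snvs_to_branches, deconvolute_patient,
                     placed_fraction, simulate_cohort)

cohort, truths = simulate_cohort(SimParams(n_patients=2, seed=3))
pid = cohort.patients[0]
forest, partitions, pdata = deconvolute_patient(cohort, pid)
assignments, summary = assign_snvs_to_branches(forest, pdata)

print(f"patient {pid}: status={forest.status}, "
      f"origins={forest.origin_count}")
for tree in truths[pid].forest.trees:
    print("  true    :", tree.to_newick())
for tree in forest.trees:
    print("  inferred:", tree.to_newick())
print("  tip cell fractions (inferred vs true):")
for tip in forest.tips():
    label = tip.tip.label
    true_cf = truths[pid].tip_cf.get(label)
    print(f"    {label}: {tip.tip.cell_fraction:.2f}"
          f" vs {true_cf:.2f}" if true_cf else f"    {label}: ?")
print(f"  placed fraction: {placed_fraction(summary):.3f} "
      f"({summary['n_placed']}/{summary['n_usable']} usable SNVs)")
print(f"  RF distance to truth: {forest.rf_distance(truths[pid].forest)}")
# Branch lengths in the Newick strings are SNV counts; tip labels are
# biopsy letter + lineage number; an RF distance of 0 means the inferred
# clades match the simulated truth exactly.
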