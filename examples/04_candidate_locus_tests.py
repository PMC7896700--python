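"""Clonal expansion, dispersion, and ordering of candidate-locus mutations.

Places functional TP53/CDKN2A/... mutations on the deconvoluted forests,
then asks whether mutant lineages cover more leaves and cells than a
random SNV (expansion), whether mutations concentrate in few patients
(dispersion), and which of two loci tends to mutate first (ordering).
"""

from beclone import SimParams, deconvolute_cohort, simulate_cohort
from beclone.stats import apply_bh, dispersion_test, expansion_test, ordering_test

from beclone import LocusParams

# a world where TP53/CDKN2A null-allele clones expand and MUC16 is neutral
loci = {
    "TP53": LocusParams(p_mut=0.7, expansion_bias=4.0),
    "CDKN2A": LocusParams(p_mut=0.7, expansion_bias=4.0),
    "MUC16": LocusParams(p_mut=0.7, expansion_bias=0.0),
}
cohort, _ = simulate_cohort(SimParams(n_patients=24, seed=8,
                                      candidate_loci=loci))
bundle = deconvolute_cohort(cohort)
forests, placements = bundle["forests"], bundle["placements"]

results = []
for locus in ["TP53", "CDKN2A", "MUC16"]:
    results.extend(expansion_test(forests, placements, locus, "all",
                                  n_resamples=2000, seed=1))
apply_bh(results)
print("expansion (two-tailed; observed vs branch-length-weighted null):")
for r in results:
    print(f"  {r.name:<34} {r.observed:8.1f} vs {r.null_mean:8.1f}   "
          f"p={r.p_repr} q={r.q_value:.4f}")

r = dispersion_test(forests, placements, "TP53", n_resamples=2000, seed=2)
print(f"dispersion[TP53]: {r.observed:.0f} patients carry a mutation "
      f"(null mean {r.null_mean:.1f}), p={r.p_repr}")

r = ordering_test(forests, placements, "CDKN2A", "TP53", seed=3)
print(f"ordering[CDKN2A,TP53]: chi2={r.observed:.1f} (df={r.extra['df']}), "
      f"p={r.p_repr}, most elevated: {r.extra['most_elevated']}")
# 'leaves' sums phylogeny tips descending from mutation-carrying branches
# across patients; 'cell_fraction' sums those tips' CFs. A small expansion
# p with observed > null means mutant clones spread farther than neutral
# SNVs -- the signature reported for TP53 and CDKN2A null-allele clones.
# The dispersion test compares how many patients carry the locus's
# mutations with a cohort-wide weighted re-placement: here the generator
# caps each locus at one mutation per patient, so mutations look more
# dispersed (more patients hit) than the cohort-wide null expects.
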