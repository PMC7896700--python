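# Methods

`beclone` automates a deconvolution procedure originally carried out as a
semi-automated expert analysis of multi-region Barrett's Esophagus (BE)
whole-genome data, and the permutation statistics built on its output.
This note records the model, the tunable parameters, what the synthetic
cohort does and does not emulate, the numerical choices, and the places
where the original procedure's description left the design open.

## Model and assumptions

A patient's BE segment is modelled as a forest of clonal lineages: one or
more founding lineages ("origins"), each diversifying as a rooted clone
tree. A bulk biopsy samples a mixture of lineages, each contributing a
cell fraction (CF); CFs within a biopsy sum to at most 1 and lineages
below ~15% of cells are treated as undetectable. Somatic SNVs accumulate
neutrally on branches (over 99% of SNVs in such data are MODIFIER/LOW
severity), so SNV counts measure branch lengths and the set of samples in
which an SNV is detected identifies the branch it arose on. A
heterozygous SNV on `m` of `t` local copies in a lineage at CF `f` has
expected VAF `f·m/t`; genome doubling (GD) places earlier mutations on 2
of 4 copies and later ones on 1 of 4, generating the diagnostic
factor-of-two peak split.

Key assumptions inherited from the source procedure: biallelic SNVs
only; private (single-sample) mutations are never deconvoluted; lineage
connections require 100+ shared SNVs; GD is only invoked where external
ploidy evidence corroborates it; copy-number calls are consumed as input,
never re-estimated.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `detection_min_alt` | 3 reads | alternate-read threshold defining "detected"; also the allelic-dropout regime |
| `min_peak_snvs`, `min_group_snvs`, `min_partition_snvs` | 100 SNVs | the recurring 100-SNV evidence floor (peak retention, group retention, biopsy retention, origin separation) |
| `bandwidth_scale`, `bandwidth_floor` | 0.5 × Silverman, 0.02 VAF | kernel smoother for peak finding |
| `peak_sd_min`, `peak_sd_max` | 0.01, 0.09 VAF | mixture-component spread clamp (read-noise band at ~60x) |
| `peak_min_sep` | 0.06 VAF | fits with closer components are rejected as noise splits |
| `merge_tol` | 0.03 VAF | kernel maxima closer than this merge |
| `cf_tol` | 0.10 | parent-lineage CF must cover child CFs within this slack |
| `ratio_tol` | 0.25 (relative) | tolerance on haplotype / factor-of-two peak ratios |
| `residual_min_cf` | 0.15 | smallest residual (ancestral-remnant) lineage reported |
| `budget_tol` | 0.05 | per-biopsy CF sum may reach 1.05 |
| `max_reclassifications` | 5 | dropout re-readings before a patient is unresolvable |
| `n_resamples` | 10,000 | permutation/resampling replicates |

## The synthetic cohort

The generator emulates the cohort structure the analysis was designed
for: 80 patients (40 cancer-outcome, 40 noncancer-outcome), two biopsies
per time point with 2–3 time points (third time point in a quarter of
NCO patients), ~60x Poisson depth with binomial allele sampling,
origin-count frequencies 43:29:5:1 for 1–4 origins, branch SNV counts
uniform on 150–700 (GD trunks 400–700 so both peak halves clear the
100-SNV floor), primary lineages at CF 0.5–0.95 and minority lineages at
0.2–0.4, genome doubling on ~12% of origin trunks, occasional clonal
2+1 regions, and per-locus functional-mutation probabilities for the 14
candidate loci with an expansion-bias knob (neutral = placement
proportional to branch length). Spatial structure is a 1-D territory
model: with probability `spatial_autocorr` an origin's clones are laid
out in cm order along the segment; time point is always independent of
clone structure. Branch SNV ranges were fixed a priori so that
single-sample dropout patterns (probability ≈0.06 per sample at VAF 0.1)
stay below the 100-SNV retention floor, the same consideration that
motivated the original threshold.

What it does **not** emulate: mutational signatures and indels,
subclonal or discordant copy-number calls (CN is clonal per chromosome),
ploidy mixtures within a biopsy (the case that made two real patients
unresolvable), sequencing artifacts and caller disagreement, nested
same-sample-set lineage chains (the generator removes configurations
whose branches are unidentifiable by construction), and multi-mutation
bursts per locus (at most one functional mutation per locus per patient,
so the dispersion test's cohort-wide null is not matched by the
generator — its observed statistic sits on the "dispersed" side by
construction). A green recovery test therefore establishes that the
algorithm inverts the stated generative model at realistic depth and
dropout, not that it handles every pathology of real tumor data.

## Numerical choices

- **Peak finding.** Gaussian-kernel density on a 512-point grid over
  [0,1]; local maxima merged within 0.03, keeping the higher. The
  bandwidth floor is 0.02 VAF: binomial noise at 60x has sd up to
  ~0.065, and a floor much below a third of that lets read noise split
  one cluster into several maxima.
- **Peak weights.** A purpose-built 1-D EM with component sd clamped to
  [0.01, 0.09]; the kernel maxima cap the component count and BIC picks
  the order; fits whose means sit closer than 0.06 VAF are rejected
  (every real mechanism here — haplotype ratios, factor-of-two GD, the
  0.15 CF detectability floor — separates peaks by more). An off-the-
  shelf unconstrained mixture was tried first and allowed one component
  to stretch across a neighboring small peak; the clamp is what makes
  the 100-SNV peak filter behave. The unconstrained fit survives as an
  independent oracle in the tests.
- **Detection debiasing.** Conditioning detection on ≥3 alternate reads
  biases low-VAF peak means upward (the truncated binomial mean); peak
  locations are debiased by inverting E[X/d | X ≥ 3] = observed mean via
  bisection. Matters below VAF ≈ 0.12, e.g. post-GD lineages at CF 0.2.
- **Assembly determinism.** No randomness anywhere in deconvolution:
  partitions are ordered (size, −SNVs, lexicographic); adoption of
  existing clades prefers the most derived compatible chain level;
  conflicts defer to the end of assembly and then reclassify smallest
  first. The original hand procedure resolved "better fit" questions by
  expert inspection and a second independent pass; this implementation
  is single-pass and quantifies the judgment as CF-cover feasibility
  with `cf_tol`.
- **Parsimony.** Both unordered and linear-cost counts run through a
  Sankoff dynamic program over the observed state set (exact for both
  costs, polytomies included); the test suite checks it against
  exhaustive enumeration.
- **Permutation p values.** `p = (#more extreme + Binomial(#ties, ½))/n`,
  doubled and capped for two-tailed tests; zero counts are reported as
  `<1/n` and floored at `1/n` numerically. BH correction is
  statsmodels' step-up.

## Open-design decisions

- **Branch lengths for resampling.** Assignment defines internal branch
  lengths (multi-sample SNVs only; discordant SNVs dropped), so pendant
  branches would all be zero and length-weighted nulls could never
  re-place a mutation on a tip lineage even though real placements land
  there. Tips therefore carry their biopsy's private SNV count as
  pendant support when the biopsy has a single lineage (private SNVs
  cannot be apportioned among several lineages); resampling weights use
  assigned + private support, while the conservation law "assigned
  branch lengths + discordant = usable SNVs" is kept on assigned counts.
- **Ordering chi-square df.** The heterogeneity test between observed
  and resampled configuration counts uses 6 df by convention of the
  source analysis; with four categories the choice is not derivable and
  the df is a parameter.
- **Within-patient permutation.** Clustering nulls permute labels among
  each patient's biopsies (the statistic is a per-patient tree
  property); cohort-wide permutation is neither needed nor implemented.
- **cm-from-GEJ permutation.** The ordered-trait null permutes the
  multiset of cm values among a patient's biopsies and rescores Wagner
  parsimony with cost = absolute cm difference.
- **Tetraploid single peaks.** In corroborated-GD samples a lone peak is
  read as post-doubling (1 of 4 copies). Branches above a GD event in
  such samples would be misread by a factor of two; with GD modelled on
  origin trunks this case does not arise in the simulated world, and it
  is flagged as a limitation for real data.
- **Unresolvable patients.** More than three stacked VAF peaks, or more
  than five dropout reclassifications, marks the patient unresolvable;
  such patients are excluded from all statistics, mirroring the
  exclusion of the two real patients whose partition sets admitted no
  tree.

## Limitations

Deletion-only loss of a candidate locus is not called (no mutation to
place); hom/het secondary-event re-placement assumes secondary events are
branch-length-weighted tipward of the initial branch; CF estimates for
lineages below ~0.2 CF in genome-doubled samples remain noisy even after
detection debiasing; and the calibration suite exercises the permutation
machinery on the simulator's true forests (label exchangeability holds
for inferred forests equally, but their additional estimation noise is
only covered by the recovery tests).
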