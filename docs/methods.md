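# Methods

## Study design the package models

The analysis assumes three small diploid populations genotyped genome-wide:
a case population fixed for the T15L5 vertebral formula (label `YC`,
5 animals) and two T14L5 control populations (`ZC`, another herd of the
same breed; `GY`, a diverged plateau population; 5 each), plus a larger
validation cohort (51 animals, 10 of them with the case phenotype) that is
genotyped only at shortlisted markers. All stages operate on biallelic SNVs
with diploid GT calls; indels and multiallelic records are dropped at
ingestion. Internally coordinates are 1-based as printed in VCF; interval
arithmetic against gene annotations uses 0-based half-open intervals.

## Fixation screening

A *population-level genotype* exists at a locus iff every member of the
population has the same non-missing genotype there (heterozygous fixation
included). Any missing call disqualifies the locus — no imputation — since
the definition is absolute. Candidate markers require fixed genotypes in
the case group and in the *pooled* control group that differ from each
other. Pooling all controls before assessing fixation is the stricter and
listing-order-free reading of screening against a combined control
population; a flag (`pool_controls=False`) instead demands per-population
fixation on a common genotype. The "eligible set" (fixed in both groups,
equal or not) is exposed separately because shared-locus Venn counts and
the screening pool answer different questions.

Gene context uses the nearest interval: `inside` when the marker position
falls in a gene, `within_5kb` when its distance to the interval is
≤ 5 000 bp (inclusive boundary), else `none`; per-gene counts are reported
separately for the two relations.

## Windowed statistics

* **π** per site is the unbiased estimator 2·c_ref·c_alt/(m(m−1)) over the
  m non-missing alleles; sites with m < 2 are skipped. The window value
  divides the summed site π by the full window length (per-bp diversity,
  the standard windowed-scan convention); `per_site=True` instead averages
  over variant sites. Default geometry is 50 kb windows with a 10 kb step;
  both are parameters because scan resolution is a study choice.
* **F_ST** uses the full two-population diploid Weir–Cockerham variance
  components (a, b, c) with observed heterozygosity, aggregated per window
  as Σa / Σ(a+b+c) (ratio of sums, the "weighted" estimator) — the
  standard choice for windowed scans and invariant to splitting a window's
  sites into sub-sums. Sites with a degenerate denominator are skipped;
  windows with no usable site report an absent value (NaN), never 0.
  Negative estimates are reported as-is.
* **Sweep flags**: the log₂ π-ratio is oriented control/case, so positive
  values mean diversity lost in the case group. Case-direction selection
  requires F_ST and the ratio both at or above their (1 − top_fraction)
  empirical quantiles (type-7, inclusive at the threshold, so full ties
  are all flagged); control-direction uses the negated ratio. Windows with
  π = 0 in either group, or below the minimum-site filter, are excluded
  *before* quantiles are taken but kept in the output unflagged. Fewer
  than 20 eligible windows is an error — the quantile would be
  meaningless.
* **LD decay** is the squared Pearson correlation of alt-dosage vectors
  (0/1/2) over samples with both calls present, binned by pair distance;
  zero-variance loci are skipped. For n samples and independent loci the
  expected r² is ≈ 1/(n−1), which the tests use as the null calibration.
* **(1−IBS)**: per locus the shared-allele count under best pairing equals
  2 − |dosage_i − dosage_j| for biallelic diploid calls; IBS averages the
  shared fraction over jointly non-missing loci.
* **Neighbor joining** is the standard Saitou–Nei agglomeration with the
  Q-criterion, hand-implemented so the contract is explicit: ties broken
  deterministically by index order, negative branch lengths clamped to 0
  with the deficit transferred to the sibling branch, optional rooting at
  the midpoint of the outgroup's pendant edge. NJ recovers any additive
  metric exactly (topology and lengths), which the tests verify against
  randomly generated additive trees and against an independent NJ
  implementation (scikit-bio).
* **PCA** mean-centers alt dosages and scales by √(p(1−p)) (the customary
  genotype-PCA normalisation), mean-imputes missing dosages, drops
  monomorphic loci and eigendecomposes the sample covariance. Components
  are eigenvalue-ordered; each component's sign is fixed so its
  largest-magnitude loading is positive; variance fractions are
  eigenvalues over the trace.

## Haplotype diversity and ranking

Around each focal marker, all loci within ±5 kb form a window; each
diploid contributes its two phased allele strings. Strings containing a
missing allele are dropped (wildcarding would conflate distinct
haplotypes); unphased heterozygous calls are an error because haplotype
identity would be ambiguous — the generator emits truth phase, and real
data should be phased upstream. Diversity is the count of distinct strings
in the population group; pooled groups (e.g. case+same-breed control)
count over the union of strings, so a pooled group of 10 diploids is
bounded by 20. Quartile classes use type-7 quartiles with inclusive ties;
when a degenerate distribution makes a record qualify as both preferred
and avoided, `avoided` wins (conservative marker selection).

Ranking is lexicographic: case-homozygous first (homozygous markers breed
true), then diversity class (preferred > neutral > avoided, in the
configured group), then per-gene and per-chromosome marker counts
(descending), with (chrom, pos) as the final tie-break. The source
priorities are stated without combination weights, so a deterministic,
auditable total order was chosen over a weighted sum; a weighted mode
exists for sensitivity analysis. Markers lacking a diversity record are
demoted to the end, never dropped silently. The default shortlist size is
13 (the number of loci taken to targeted genotyping in the reference
design).

## Prediction and evaluation

Major genotypes are strict plurality winners within a phenotype group;
ties make the locus unusable for that contrast. They are computed on the
reference panel only — query cohorts never update them. Scoring weights
are 3 (probability ≥ 0.9), 2 (≥ 0.8), 1 (rest); an unavailable probability
falls in the rest bucket with a logged warning. A genotype matching
neither major adds nothing to either score — the only choice that cannot
manufacture evidence; split and opposite variants are selectable for
comparison, and the score card's audit trail records every per-locus
decision. Calls require the score difference to *strictly* exceed the
contrast threshold (defaults: 1 for the total-vertebrae contrast, 4 for
the thoracic contrast); equal scores are always `unknown`.

Confusion tables put predicted labels (plus `unknown`) on rows and
observed labels on columns. Accuracy of prediction divides correct calls
by all calls of that label; representative capacity divides by all animals
observed with that label. Both are percentages rounded half-up to exactly
2 decimals; a zero denominator yields an absent value, never 0 or 100.
Inter-run genotype concordance compares normalized unordered genotypes of
shared sample×locus calls and flags loci below a configurable threshold
for exclusion, mirroring the cross-platform check that removes unreliable
markers before validation.

## Synthetic cohorts

Per locus an ancestral frequency is drawn Uniform(0.05, 0.95); each
population's frequency drifts around it under the Balding–Nichols model
(Beta with drift parameter F, default 0.03, which puts windowed F_ST on
the 0.02–0.06 scale typical of related yak populations; realized per-locus
F_ST averages ≈ F, verified in the calibration tests). Each population
has a haplotype pool (case pool 6, controls 10 by default — the smaller
case pool produces its higher LD and lower haplotype diversity); every
gamete is copied from the pool with a per-locus template-switch
probability (default 0.05), producing block LD that decays with distance.
The causal region (10 kb, 20 evenly spaced loci by default; background
loci are kept out of the span so the planted count is exact) is
overwritten in the pools — case all-alt, controls all-ref — so reference,
validation and truth phase stay consistent. An optional `sweep_halo`
homogenizes the case pool around the causal span to emulate a hard sweep
(reduced case diversity with controls still polymorphic), which is what a
π-ratio scan can detect; the fixed-difference region alone cannot carry a
π-ratio signal because both groups are monomorphic there. GQ is
30 + rounded Exponential(scale 15) floored at 3; PL is derived as 0 at the
called genotype, GQ at the nearer alternative and GQ+30 at the farther —
a documented synthetic convention, not a caller model. Missingness
(default 1%) masks whole calls. The validation cohort draws fresh diploids
from the same pools (41 control-phenotype, 10 case-phenotype by default).

The generator emulates the *statistical* structure the analysis consumes —
fixation contrasts, drift-scale differentiation, block LD, qualities,
missingness — not sequence-level reality: no recombination maps, no read
errors, no variant-calling artifacts, no relatedness within populations
beyond pool sharing. Passing tests therefore demonstrate the correctness
of the set/score/scan logic under the assumed model, not robustness to
upstream calling noise.

The noise-free limit used for exact-recovery checks sets zero drift, zero
missingness and per-locus independent draws (switch rate 1.0) from one
shared 100-haplotype pool, so background loci sit at intermediate shared
frequencies and only planted loci can be fixed-differential. Even so,
background heterozygous fixation in 5 case diploids against a
homozygous-fixed control is a ~10⁻⁵-per-locus event, so at genome scale a
handful of extra candidates can appear at some seeds — which is precisely
why a real fixation screen yields hundreds of candidates from a handful of
causal loci.

## Problem sizes

Tests and the acceptance script run cohorts of 10³–10⁴ loci and 15–75
diploids: large enough for the Monte-Carlo calibrations (drift, LD null,
quantile behaviour) and small enough to iterate quickly. Whole-genome
inputs stream through the same code paths; nothing in the implementation
assumes these sizes.

## Known limitations

* Functional-consequence annotation (exonic class, codon effects) is out
  of scope; gene context is interval overlap only.
* Phasing is consumed, not performed.
* The sweep scan's quantile thresholds are within-dataset empirical
  quantiles; they are not outlier tests and carry no significance level.
* The scoring predictor has no probabilistic calibration — it is a
  deterministic rule with an audit trail, evaluated by its confusion
  metrics.
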