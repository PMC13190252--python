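# Methods

## Dual-endpoint two-stage design

The design couples two binary endpoints — objective response and six-month
progression-free survival (PFS) — in an OR rule at both the interim and the
final analysis. Because a trial that continues on *either* endpoint can let
the other endpoint "ride along", the exact joint error of the OR rule has
no convenient closed form. The package therefore reports, as its canonical
operating characteristics, the *marginal* single-endpoint quantities: each
endpoint's two-stage rule evaluated in isolation by exact binomial
enumeration (no normal approximation), with the sum of the two marginal
type I errors as the Bonferroni-style overall bound. Joint quantities under
the full OR rule are available through a seeded Monte Carlo routine
(`joint_outcome_mc`) that simulates independent per-patient Bernoulli
outcomes and applies the actual decision functions.

The default configuration ships a null response rate of 0.20 rather than
the 0.23 historical benchmark: under exact enumeration, 0.23 yields a
marginal ORR type I error of ≈0.054 and an early-termination probability of
≈0.63, while 0.20 yields ≈0.020 and ≈0.727 — the pair of values the design
is documented to have. Both nulls are plain constructor arguments, so the
0.23 benchmark is selectable in one line. A related known gap: no simple
combination of the marginal type II errors (the independence product is
≈0.037) reproduces a composite type II error of 0.09, so the package does
not compute or report any "composite beta".

Endpoint independence is assumed wherever the two endpoints are combined
(early termination, the Monte Carlo simulator). In reality response and
PFS are positively correlated; the marginal quantities are unaffected, but
joint Monte Carlo estimates under correlated endpoints are out of scope.

## Interval estimation

Response proportions use the Clopper–Pearson construction from beta
quantiles, with the exact boundary conventions lower = 0 at zero successes
and upper = 1 at all successes (no continuity adjustments). The planning
margin of error for descriptive cohorts is the normal half-width
z·√(p(1−p)/n), conventionally at p = 0.5.

## Survival machinery

The product-limit estimator, Greenwood variance and numbers at risk are
computed directly (events precede censorings at tied times — the standard
convention, which the at-risk definition `t >= t_event` implements
automatically). Pointwise intervals use the complementary log-log
transform, which respects the [0, 1] range; the median's interval inverts
that pointwise band (Brookmeyer–Crowley flavor): the bound is the first
event time at which the respective band limit crosses 0.5, and a bound the
band never crosses is reported as not reached. Median follow-up uses the
reverse Kaplan–Meier method (flip the event indicator). Duration of
response is the product-limit median of per-responder times from response
start to progression/death.

Stratified Cox regression delegates to `statsmodels` `PHReg`, which
maximizes the stratified partial likelihood by Newton iteration; Breslow
tie handling is the default (it is the variant that is exactly specifiable
by a short formula and thus testable against a hand-written grid oracle),
with Efron available by flag. Constant covariates and strata with fewer
than two events are rejected up front rather than letting the optimizer
drift.

## Genomic-scar scoring

Inputs are merged allele-specific copy-number segments (1-based inclusive
coordinates; sex chromosomes excluded). The three metrics and their
thresholds:

* **NtAI** — allelically imbalanced segments (major ≠ minor) touching a
  telomere (endpoint within 1 Mb of a chromosome end), not crossing the
  centromere (strictly containing the centromere interval), and at least
  1 Mb long. The 1 Mb minimum is a noise guard; like every threshold here
  it is a keyword argument.
* **LST** — after discarding segments under 3 Mb and re-merging equal
  states per arm, each breakpoint whose flanking segments are both
  ≥ 10 Mb counts one transition. Segments spanning the centromere are
  clipped into arm pieces first; a breakpoint at the arm boundary itself
  never counts.
* **HRD-LOH** — segments with minor copy 0 and major ≥ 1, at least
  15 Mb, excluding segments covering ≥ 90% of their chromosome (the
  "whole-chromosome" rule, configurable).

HRD-sum is the unweighted total. Whole-genome duplication is reported as
the length-weighted autosomal fraction with major copy ≥ 2, called WGD
strictly above 0.5; it annotates the score but never modifies the sum.
Genome geometry ships as in-package tables: GRCh37/GRCh38 autosome lengths
with cytoband-acen centromere intervals (approximate by nature — scar
calls near centromere edges inherit that approximation), plus a simplified
uniform genome for simulation and tests.

## Neoantigen burden

Candidates are 8–11-residue peptides with predicted IC50 ≤ 500 nM, both
bounds inclusive. The burden Σ 1/IC50 is summed over *all* retained rows:
duplicate peptide/allele rows are deliberately kept by default, since
prediction tables list one row per peptide–allele pair and a peptide
presented by two alleles contributes twice; `--dedupe` collapses to unique
(sample, peptide, allele) rows for the alternative reading. Quartiles are
rank-based with ties assigned downward, so an all-tied cohort is all
quartile 1.

## ctDNA dynamics

Mean VAF is the unweighted arithmetic mean over somatic,
non-clonal-hematopoiesis, non-germline variants; a sample with no
qualifying variant is *undetected* with mean 0 (not missing), because an
assay that finds nothing tumor-derived is evidence of absence at its
sensitivity, and downstream deltas must remain defined. Samples failing QC
are non-evaluable: deltas involving them return a sentinel, never 0. The
molecular-residual-disease call is mean VAF < 5×10⁻⁴ by default — chosen
to sit above reported near-undetectable values (~1×10⁻⁴) and below the
0.1% assay floor; it is a declared package default, not a clinically
validated cut.

The rank-sum test enumerates the exact permutation distribution whenever
the pooled sample is ≤ 20 without ties (delegating to scipy's exact
method; an independent full-enumeration oracle backs it in the tests);
otherwise the normal approximation with tie-corrected variance and
continuity correction is used. Two identical groups return p = 1 by
convention.

## Synthetic cohorts

The generator emulates the study conditions: cohorts of 33/15/15 patients
with true response rates 0.35/0.08/0.14, exponential PFS (medians
8.3/4.8/3.3 months) and OS (28/18/10 months), measurable-at-baseline
fractions 20/33, 12/15 and 14/15, and a four-month durability window for
non-measurable patients. Censoring is an independent exponential with rate
chosen so the marginal censoring probability equals the configured rate
(0.15 by default). PFS and OS are drawn independently, so the ordering
OS ≥ PFS is not enforced — adequate for exercising estimators, not for
joint endpoint modelling. A separate helper plants a continuous covariate
with a known log hazard ratio for Cox parameter-recovery checks.

Scar genomes use the simplified 8-chromosome build with disjoint planting
slots so that planted truth is exact by construction: telomeric-imbalance
plants are 3–8 Mb (below the LST flank, so they never create transitions),
transition plants abut the centromere (exactly one countable breakpoint),
and interstitial LOH plants are placed so both flanks exceed 10 Mb — each
therefore contributes exactly two transitions, and the truth manifest
accounts `lst = n_lst + 2·n_loh`. Event counts are Poisson at
class-specific rates (high ≈ 6/5/3, low ≈ 1.5/1/0.5 per genome), giving
expected HRD-sums near 20 vs 4 — a scaled-down genome, so absolute scores
are not comparable to full-genome scores; only the high > low ordering and
truth equivalence are meaningful. Peptide tables draw lengths uniformly on
7–12 (straddling the filter) with log-normal IC50; ctDNA trajectories make
long-PFS patients mRD-negative with configurable probability and give
short-PFS patients positive deltas up to 0.013; mIF counts give HRD-class
samples ~2.5× higher cytotoxic T cell density. Everything is reproducible
from a single seed via spawned child seeds.

What passing tests on these cohorts shows: the estimators recover the
parameters the generator encodes under its idealized assumptions
(independence, exponential hazards, exact flags). What they do not show:
robustness to real-data features such as dependent censoring,
non-proportional hazards, segmentation noise, purity/ploidy error in
copy-number calls, or misclassified clonal-hematopoiesis variants.

## Problem sizes and numerics

Design enumerations are O(n1·n2) exact sums; all printed-precision
comparisons round probabilities to the printed decimals and percentages to
integers. The Cox fit uses Newton iteration to tolerance 1e−8 with a
100-iteration cap. Parameter-recovery checks use 5,000 synthetic patients
for the KM median (sampling error well under the ±0.3 tolerance) and 500
for Cox (planted effect recovered within 3 standard errors); Monte Carlo
cross-checks use 10⁶ replicates against exact formulas within 3 binomial
standard errors. These sizes keep the full suite under half a minute on a
single CPU while leaving each check's sampling error far below its
tolerance.

## Known limitations

* Marginal (not joint-exact) operating characteristics; joint quantities
  only by Monte Carlo under independence.
* RECIST classification consumes pre-computed best target-lesion changes;
  lesion-level bookkeeping (sums, nadirs, confirmation scans) is upstream.
* Scar thresholds follow the standard metric definitions; the exact
  NtAI size filter and whole-chromosome rule of any particular clinical
  implementation may differ — all cutoffs are arguments.
* The exploratory "durable undefined" response bookkeeping is a post hoc
  convention (non-measurable at baseline, progression free > 4 months),
  not a validated endpoint.
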