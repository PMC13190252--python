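# hrdmaint

Analytics for biomarker-stratified maintenance trials in metastatic
pancreatic cancer: the dual-endpoint two-stage phase 2 design and its exact
operating characteristics, response and time-to-event endpoint estimation,
homologous-recombination-deficiency (HRD) genomic-scar scoring,
affinity-weighted neoantigen burden, circulating-tumor-DNA (ctDNA) dynamics
and immune-correlate statistics — together with a fully seeded synthetic
cohort generator so every stage can be exercised end to end without
protected patient data.

The package is aimed at trial statisticians and translational analysts who
need the computational core of such a study as tested, reusable code:
design evaluation before a trial, and endpoint/biomarker summaries after.

## The models and statistics

**Two-stage dual-endpoint design.** Stage 1 enrolls `n1` patients and the
trial continues to `n2` more if the number of objective responses `R1` or
the number of six-month progression-free (PFS) successes `S1` reaches its
continuation threshold; the regimen is declared active if either endpoint
reaches its final threshold over all `n1 + n2` patients. Each endpoint's
marginal type I error and power are exact binomial enumerations of the
single-endpoint rule,

    P(pass) = Σ_{k=c}^{n1} Binom(k; n1, p) · P(Binom(n2, p) ≥ f − k),

with continuation threshold `c` and final threshold `f`; the probability of
early termination under both nulls is the independence product of the two
stage-1 stopping probabilities. Joint quantities under the full OR rule are
estimated by seeded Monte Carlo. Default design: `n1 = 20`, `n2 = 13`,
continue on `R1 ≥ 6` or `S1 ≥ 14`, active on `R ≥ 12` or `S ≥ 23`, nulls
(0.20, 0.53) and alternatives (0.43, 0.77).

**Efficacy endpoints.** Best overall response per RECIST v1.1 (−30% partial
response; +20% *and* ≥5 mm progression; new lesion dominates); objective
response and disease-control rates with Clopper–Pearson exact intervals
(beta-quantile construction); Kaplan–Meier product-limit curves with
Greenwood variance, complementary log-log landmark intervals,
Brookmeyer–Crowley-style median intervals, reverse-KM follow-up, duration
of response, and stratified Cox proportional hazards (Breslow ties).

**Genomic scars.** From allele-specific copy-number segments: telomeric
allelic imbalances (NtAI), large-scale state transitions (LST, ≥10 Mb
flanks after 3 Mb smoothing), and ≥15 Mb sub-chromosomal losses of
heterozygosity (HRD-LOH); the HRD-sum is their unweighted total, with
whole-genome-duplication status (autosomal fraction with major copy number
≥ 2) reported alongside.

**Neoantigens, ctDNA, immune correlates.** Candidate neoantigens are
8–11-mers with predicted binding IC50 ≤ 500 nM; the weighted burden is
Σ 1/IC50. Plasma mean variant-allele fraction averages somatic,
non-clonal-hematopoiesis variants; molecular residual disease is called
below a configurable mean-VAF threshold; longitudinal deltas are compared
across PFS groups by the exact Wilcoxon rank-sum test. mIF marker counts
are normalized to stromal cells and related to genomic scores by Pearson
correlation.

## Worked example

```sh
$ hrdmaint design-oc
quantity        value
alpha_orr       0.020060
alpha_pfs       0.028114
power_orr       0.809270
power_pfs       0.805932
pet_null        0.727188
alpha_sum       0.048174
```

The default design controls each endpoint's marginal type I error at 0.02
(ORR) and 0.028 (PFS) — overall bounded by their 0.048 sum — delivers ~81%
power against the alternatives 0.43/0.77, and stops early under the nulls
73% of the time.

```sh
$ hrdmaint simulate --out demo --seed 11
$ hrdmaint scar --seg demo/segments.seg --genome simplified
sample  ntai    lst     hrd_loh hrd_sum wgd     wgd_fraction
S1      5       12      5       22      False   0.0360
S2      1       2       1       4       False   0.0039
$ hrdmaint efficacy --clinical demo/clinical.csv --survival demo/survival.csv \
    --endpoint pfs --cohort A
endpoint  median  median_lower  median_upper  rate_at_6m  rate_lower  rate_upper
pfs       6.280   3.891         11.336        0.5264      0.3404      0.6824
```

`S1` is a scar-rich synthetic genome and `S2` a scar-poor one: the scorer
recovers exactly the events the generator planted (22 vs 4). The cohort-A
survival summary is a KM median with its inverted log-log interval and the
six-month landmark rate; at this small simulated sample size (n = 33) the
estimate scatters around the configured 8.3-month median.

Other subcommands: `neoburden` (weighted burden + quartiles), `ctdna`
(mean VAF, mRD calls, delta-VAF rank-sum by PFS group), `correlate`
(mIF density vs a genomic score).

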