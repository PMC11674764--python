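# Methods

## Scope and model

`rohkin` analyses the relationship between genomic homozygosity and a binary
disease outcome in an admixed cohort. Homozygosity is measured by runs of
homozygosity (ROH): contiguous stretches of homozygous genotypes marking
chromosome segments inherited identical-by-descent from both parents. Long
ROH indicate a recent common ancestor (consanguinity); many short ROH
indicate ancient, population-level inbreeding (drift). The package measures
both, separates them, and feeds the genomic inbreeding coefficient into a
case-control logistic model.

## ROH calling

The caller reimplements the classical SNP-array sliding-window scan:

1. a window of `window_snps` (default 30) consecutive SNPs slides one SNP at
   a time; a window is *homozygous* if it has ≤ `window_het_max` (1)
   heterozygous and ≤ `window_missing_max` (5) missing calls;
2. each SNP's hit rate is the homozygous fraction of the windows covering
   it; SNPs with hit rate ≥ `window_hit_threshold` (0.05) are flagged;
3. maximal flagged stretches become candidates, split where adjacent flagged
   SNPs are > `max_gap_kb` (1000) apart;
4. candidates are trimmed so they start and end on homozygous non-missing
   SNPs, then screened: ≥ `min_snps` (30), ≥ `min_length_kb` (300), density
   ≥ 1 SNP per `density_kb_per_snp` (30).

Numerical choices: windows are never truncated at chromosome ends (SNPs near
an edge are judged by the windows that do contain them, so the hit-rate
denominator shrinks); trimming precedes the count/length/density screen; the
300 kb parameter is a minimum segment length, not a window size — the
scanning window is SNP-count based. Chromosomes with fewer SNPs than one
window produce no calls. Missing genotypes never count as homozygous. The
vectorized implementation is held segment-for-segment equal to a literal
brute-force enumeration in the test suite.

## Inbreeding coefficients

* `F_IS` (systematic inbreeding): `(O(HOM) − E(HOM)) / (N − E(HOM))` per
  sample, with `E(HOM) = Σ_snp (1 − 2pq·N_snp/(N_snp − 1))` from sample
  allele frequencies (small-sample corrected, the convention of standard
  genotype toolkits); `N` is the sample's non-missing SNP count. Undefined
  (error) when `N = E(HOM)`.
* `F_ROH` (genomic inbreeding, proxy for total inbreeding `F_IT`): summed
  length of ROH **strictly** longer than 1.5 Mb divided by a 3 Gb autosomal
  denominator. The denominator is a convention, not a measurement; pipelines
  running on the scaled synthetic genome override it with the simulated map
  length so `F_ROH` stays a true fraction.
* Implied drift component: `F_ST = 1 − (1 − F_ROH)/(1 − F_IS)` from the
  partition `(1 − F_IT) = (1 − F_IS)(1 − F_ST)`. Negative values are
  reported as-is (they are informative: inbreeding avoidance).
* Length classes use half-open intervals [0.3, 0.5), [0.5, 1), [1, 2),
  [2, 4), [4, 8), [8, ∞) Mb; a segment of exactly 1.0 Mb falls in [1, 2).
* Inbreeding depression: `M_F = M_0 − 2F Σ d_i p̄_i q̄_i`, linear in `F`
  with slope `−2Σ d p q`; no depression without directional dominance.

## Pedigree simulation

Consanguineous matings are simulated by gene-dropping founder-labelled
haplotypes through the minimal pedigree of each class (second cousin,
first cousin, avuncular as uncle–niece with a double-first-cousin variant,
incest as parent–offspring with a sibling variant). Meiosis uses the
standard no-interference model: crossovers per chromosome ~
Poisson(genetic length in Morgans), breakpoints uniform in genetic
distance, sex-averaged uniform 1 cM/Mb map (configurable per chromosome).
The default genome has 22 autosomes with realistic human lengths (~2.88 Gb);
a 6 × 100 Mb scaled genome is used for fast tests.

Autozygosity is read directly off founder-label identity rather than by
genotyping and re-calling: with unrelated, non-inbred founders and no
drift, label-identity tracts are exactly the ROH an infinitely dense caller
would find, which keeps simulator validation independent of caller
behaviour. Expected autozygous fractions are the analytic kinship
coefficients 1/4, 1/8, 1/16, 1/64; the test suite checks them to
Monte-Carlo error at n = 5000.

## Origin classification

Two complementary rules, with all thresholds exposed as parameters because
the underlying geometry is qualitative:

* **NROH vs SROH**: an OLS line of NROH on SROH is fitted on an outbred
  reference panel (any (nroh, sroh) table can be supplied; the shipped
  default is a simulated drift-only panel, removing any external data
  dependency). A sample's shift is its SROH minus the baseline-implied SROH
  at its NROH. If the shift exceeds the second-cousin simulation cloud's
  mean shift, the Mahalanobis-nearest mating-class cloud is reported.
* **F_IS vs F_ROH plane**: F_IS below −`fis_tolerance` (default 0.01) →
  drift/isolation; otherwise strictly closer to the diagonal `F_IS = F_ROH`
  than to the horizontal `F_IS = 0` → consanguineous; ties and the rest →
  panmictic drift.

## Association model

Logistic regression (maximum likelihood, `statsmodels`) of case status on:
F_ROH × 100 (OR per 1 percentage point); female sex; age and age² with age
mean-centred before squaring (reduces collinearity; fitted probabilities are
unaffected); education as a six-level categorical with an explicit
"missing" level (baseline: secondary); BMI categories normal ≤ 25 <
overweight ≤ 30 < obesity; ancestry proportions × 100 (OR per percentage
point); and log2(PRS), so the PRS odds ratio is per doubling of the implied
gallstone-disease risk — the minimal reading of a "per doubling" effect for
a positive multiplicative score. Wald 95% CIs and p-values are reported;
interaction terms (F_ROH × sex/age/PRS/ancestry) add a likelihood-ratio
test against the main-effects model. Stratified odds ratios refit the full
model within strata (sex; age < / ≥ 60; PRS at-or-below / above the cohort
median). Non-convergence or separation is flagged on the result, never
silent; no multiple-testing correction is applied to interaction tests.

## Synthetic cohort generator

The generator is the package's study-conditions module: it fixes what the
tests and the acceptance experiments mean.

**Drift.** Each individual's two haplotypes are mosaics over a finite pool
of `H` founder haplotypes; mosaic labels switch at rate ρ per Mb (a Markov
jump to a uniform pool member). Where the two mosaics carry the same label
the individual is autozygous, so the stationary autozygous fraction is
1/H and tract lengths are exponential with mean `1/(2ρ(1 − 1/H))` Mb.
Small pools with fast switching reproduce the heavy burden of short
(0.3–1 Mb) ROH typical of high indigenous-ancestry groups. The published
burden of the Andean-like group (≈ 497 Mb of short ROH, i.e. ~17% of the
autosomes) pins the pool at H = 3 — extreme drift, but implied by the
numbers themselves.

**Consanguinity.** A configurable fraction of each group is routed through
the pedigree simulator; the offspring's autozygous intervals are overlaid
on the drift mosaics (second haplotype copies the first inside them).
Routing fractions are calibration artifacts (the source cohort reports no
within-group consanguinity rates) chosen to fatten the long-ROH tail of the
Mapuche-like groups.

**Calibration (one-time, scripts/calibrate_generator.py).** Per-group
(H, ρ) were tuned numerically against the published group F_ROH medians
(0.028 Andean-like, 0.026 Mapuche-like, 0.007 other-admixture, overall
median 0.009 with IQR 0.006–0.013) and, for the Andean-like group, jointly
against the called short-ROH burden on painted genotypes. Frozen values:
(3, 2.03), (5, 1.88), (8, 1.78), (4, 1.70), (6, 1.83), (7, 1.80) for the
Aymara–Quechua, Aymara–Quechua–European, European, Mapuche–Huilliche,
Mapuche–Huilliche–European and other-admixture groups.

**Genotype painting.** SNPs sit on a jittered grid of mean spacing 5 kb —
the genome-wide density of a ~610k-SNP array — with founder alleles drawn
Bernoulli(0.5) per founder per SNP. Inside ground-truth tracts every
painted SNP is homozygous by construction (a test invariant). Painted
panels of the high-drift group are genuinely out of Hardy–Weinberg
proportions (the drift is real, and the generator adds no genotyping
error), so genotype-level experiments apply the MAF screen but not the HWE
screen, which in real data targets genotyping artifacts.

**Covariates and outcome.** Group mix 2.8/4.9/2.8/2.0/46.8/40.7%; sex
43.3% male; bimodal age (younger population-based participants plus older
patients; median ≈ 37, IQR ≈ 27–58); education 12.7/43.4/3.9/1.7/13.2/25.0%
across the six levels; BMI ~ N(26.4, 4.8²) clipped (≈ 61% above 25);
PRS log-normal with median 0.445 and IQR ≈ 0.38–0.53. Outcomes are
Bernoulli draws from the logistic model with the published full-cohort
coefficients (female 3.48; age 1.18/yr, age² 0.99/yr²; education contrasts
2.65/0.47/0.22/0.57/0.14; BMI 1.34/1.27; ancestry 0.97 and 1.02 per
percentage point; PRS 2.75 per doubling; F_ROH 1.07 per 1%); the intercept
is solved by bisection so the case fraction hits the 15.3% target. A
second coefficient set plants stratum-specific F_ROH effects (1.19 in
males, 1.15 below age 60, 1.10 above the PRS median, null elsewhere) for
interaction and stratification experiments, and a third zeroes the F_ROH
effect for type-I-error studies.

**Problem sizes.** Association experiments use the tract-level sampler
(the compound-Poisson realization of the same mosaic process) at
n = 20,000 on the scaled genome with the map length as the F_ROH
denominator; genotype-resolution experiments use n = 30–200 panels.
These sizes give Monte-Carlo errors well inside the tolerances being
tested while keeping the default suite fast.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and realistic allele
frequency spectra; genotyping error and missingness; covariate
correlations beyond the group ↔ ancestry ↔ homozygosity link (education,
BMI and PRS are independent of ancestry in the generator, unlike in the
source population); geography; and any uncertainty in the ancestry
proportions, which are treated as known inputs throughout.

## Known limitations

* The drift process has a single timescale per group (one exponential tract
  length distribution); real populations superpose coalescent epochs. The
  calibrated single-scale process reproduces the printed short-ROH burden
  and F_ROH medians but slightly inflates called F_ROH relative to
  tract-level F_ROH (caller merging across short gaps).
* Wald CIs can misbehave under separation in small strata; such fits are
  flagged `converged=False` with NaN bounds rather than suppressed.
* The measured type-I error of the F_ROH test is nominal (95.3% CI coverage
  over 300 null replicates at n = 5000).
* `F_IS` in a structured cohort absorbs a Wahlund component: pooled allele
  frequencies across groups with different founder pools yield positive
  F_IS even without consanguinity. This mirrors real admixed data and is
  why the origin classifier, not F_IS alone, separates the sources.
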