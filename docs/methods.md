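# Methods

This note documents the statistical procedures implemented in `epimuscle`,
the synthetic-cohort generator that exercises them, and the numerical and
design choices a maintainer needs to know. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scales and transforms

Methylation is carried as beta-values β ∈ (0,1). Linear modelling uses the
M scale, M = log2(β′/(1−β′)) with β′ clamped into [ε, 1−ε], ε = 1e-6
(default `clamp_eps`). The clamp only matters for degenerate simulated
values at exactly 0 or 1 — intensity-ratio data cannot produce them — and
keeps M finite; the round trip is exact to well below 1e-9 inside the
clamped range. Both transforms are strictly monotone, so Spearman statistics
are identical on either scale (asserted as a cross-module test). Effect
sizes are reported on the beta scale (percentage points of methylation),
mirroring the dual ΔM / effect-size reporting convention of array studies.

## Quality control

* **Detection filter.** A probe is dropped when its detection p exceeds the
  threshold (default 0.01) in at least the given fraction of samples
  (default 50 %), evaluated per cell. The alternative reading — the probe's
  *mean* detection p over samples exceeding the threshold — is deliberately
  not implemented; the per-cell rule is the stricter, more common practice
  and is stated verbatim in the function contract.
* **SNP filter.** Probes flagged as overlapping a known polymorphism are
  dropped. Both filters only remove rows, hence commute (tested).
* **Stratified quantile normalization.** Applied to beta matrices (raw
  intensities are out of scope), within probe-type strata: each sample's
  values are replaced by the mean order statistics across samples; ties
  receive interpolated reference values, preserving within-sample ranks.
  Output is clamped into (0,1). Failed-detection cells are handled by the
  probe filter, never imputed.

## DMP calling

Per probe, OLS of M on [intercept, group, age, sex(female=1), BMI]; the
group coefficient is patients minus controls, so ΔM < 0 reads
"hypomethylated in former patients". The two-sided t-test uses residual
df = n − 5. Multiple testing uses the Benjamini–Hochberg step-up
(q_(i) = min_{j≥i} m·p_(j)/j), applied across the QC-retained probe set
only, never the pre-filter set. Plain per-probe variances are the default;
`moderate=True` enables empirical-Bayes shrinkage of the residual variances
toward a moment-matched scaled-inverse-χ² prior (the moderated-t idea),
which mainly matters at small sample sizes and is off by default because
the cohort sizes here (≈150) make it nearly a no-op.

Rank-deficient designs are rejected with the names of the aliased columns
(column-pivoted QR detection). A numerically exact fit yields an infinite t
and a p-value clipped to the smallest positive double rather than 0, so
that p stays in (0,1].

## Region and gene aggregation

A probe may link to several genes and several transcript regions; it is
counted at most once per region category (promoter = TSS200 ∪ TSS1500,
5′UTR, gene body, 3′UTR), so category counts can sum to more than the DMP
total. Percentages always use total DMPs as denominator, and
intergenic + linked = total is an enforced identity. DMGs (genes with ≥ 1
DMP) are classed hypo-only / hyper-only / mixed from the multiset of their
probes' directions; the three classes partition the DMG total by
construction and by test.

## Over-representation analysis

The universe is every gene with at least one probe on the filtered array,
not the genome. The gene-level test is the one-sided upper-tail
hypergeometric (observed overlap included, so a disjoint category has
p = 1). The probe-bias-corrected test models gene selection as a biased
urn: genes with more probes have more chances to harbour a selected probe,
summarized per category by the odds ω = mean in-category probe count /
mean out-of-category probe count, with the upper tail taken from Wallenius'
noncentral hypergeometric distribution (`scipy.stats.nchypergeom_wallenius`;
at ω = 1 it reduces exactly to the central test, verified exhaustively for
N ≤ 12, and it matches brute-force enumeration of the weighted sampling
process on small cases). The single-ω-per-category formulation is the
declared contract; per-gene weight vectors (as some bias-correcting tools
use internally) are a known refinement, not implemented. BH adjustment runs
within each call, mirroring separate per-database runs.

## Correlation enrichment

Spearman ρ is computed as Pearson on average-ranked rows, chunked over
probes so memory stays bounded; constant rows give NaN, excluded from all
counts with a logged tally. The group statistic is the proportion of pairs
with |ρ| strictly greater than τ (default 0.3, configurable). Comparisons:

* pooled two-proportion Z-test, no continuity correction, two-sided normal
  p; a pooled proportion of exactly 0 or 1 is degenerate (z = 0, p = 1,
  flagged). p-values below 2.220446e-16 are additionally rendered as
  "< 2.2e-16" in display strings while raw doubles are kept in machine
  output.
* asymptotic two-sample KS test: D = sup|F_a − F_b| over the pooled
  support; p = Q(λ) with λ = (√n_e + 0.12 + 0.11/√n_e)·D,
  n_e = n_a·n_b/(n_a+n_b). Q uses the alternating exponential series for
  λ ≥ 0.3 and the theta-function representation below (the two agree to
  machine precision at the crossover; Q(0) = 1).

Pairs are pooled as independent observations in the Z-test. This is a
deliberate fidelity choice: correlations sharing a probe or an RNA are
dependent, so the Z-test is anti-conservative as a hypothesis test and its
p-values are **not** calibrated under RNA-label permutation (the permutation
distribution of z_p is strongly skewed toward 0; measured, not corrected).
Treat the Z statistic as a standardized effect-size ordering, not a
calibrated test. Correlations use patients and controls jointly by default;
a patients-only flag exists because the restriction is defensible either
way and the choice is not decidable from first principles.

RNA labels (differentially expressed, strength-associated, pathway) are
accepted as inputs when available; otherwise simplified stand-ins are
computed: per-RNA OLS on [group, age, sex, BMI] with BH for DERNA status,
and Spearman correlation with the strength phenotype among patients (BH
across DERNAs only — non-DERNAs are never flagged) for strength
association. These stand-ins are labelling conveniences, not a re-creation
of a full count-based differential-expression analysis.

## Risk-factor association

Among patients only (exposures are undefined for controls; a design
alternative would code controls as zero, not implemented), one joint OLS
per DMP with the probe's **beta-value** as response — the deliberate scale
asymmetry with the DMP stage keeps coefficients in interpretable
beta-units per factor unit — and all factors as regressors (mutual
adjustment). Constant factors are dropped with a warning; perfectly
collinear factors are resolved by dropping the later column; categorical
factors are dummy-coded against a declared reference level. Significance is
unadjusted p < 0.05 by design (no multiplicity correction at this stage — a
fidelity choice). Classification: harmful iff (hypo ∧ coef < 0) ∨ (hyper ∧
coef > 0); zero coefficients are undefined and excluded with a tally. The
rule is antisymmetric in the coefficient sign (tested by negating exposure
columns).

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, with
defaults matching the emulated study conditions: 118 patients, 30 controls,
and (for tractable test runtimes) 2000 probes and 2000 RNAs. All
randomness derives from one seed through per-stage `SeedSequence` children;
identical configs give byte-identical outputs.

* **Baselines.** Probe means drawn from a bimodal mixture: Beta(2.5,22)
  (low mode ≈ 0.10) and Beta(22,2.5) (high mode ≈ 0.90) at 44 % each, plus
  a 12 % intermediate Beta(4,4) minority — the familiar two-peak beta
  density of methylation arrays.
* **Planted DMPs.** 15 % of probes carry a signed beta-scale shift; 63.6 %
  negative (hypo). Magnitudes are exponential, rescaled so the sample mean
  is exactly 0.026 and the largest is pinned at 0.25 (the configured mean
  and maximum absolute effects). Baselines of planted probes are resampled
  from the mixture until the shifted mean stays inside (0.02, 0.98).
* **Severity.** Patients get a disease-severity scalar ~ N(1, 0.5);
  controls sit at 0. Planted shifts enter as Δβ·severity, so the average
  patient shift equals Δβ while patients vary in how abnormal they are.
* **Noise and covariates.** Cell means (baseline + planted + covariate +
  exposure terms, clipped to (0.01, 0.99)) are mapped to M, Gaussian noise
  of sd 0.5 is added on the M scale (a free parameter — the emulated study
  reports no variance model — chosen to put typical per-probe t statistics
  in a realistic range), and mapped back. Age/sex/BMI have overlapping
  patient/control distributions and planted per-unit effects on a random
  20 % probe subset, giving genuine confounding that the adjusted models
  must absorb.
* **Exposures.** Binary (prevalence p) and duration (exponential days)
  variables for patients; each affects 30 % of planted probes with an
  effect signed like the probe's Δβ, i.e. planted as *harmful*.
* **Expression.** RNAs are log2-scale Gaussians (sd 1). 17.5 % are DERNAs
  (350 at the default size, matching the emulated study's DERNA count) with
  a 2-fold (1 log2 unit) group shift; each DERNA couples to a random
  planted DMP through a shared standardized signal whose loading is
  calibrated (via the Spearman↔Pearson binormal relation ρ_P = 2·sin(πρ_S/6))
  so the pooled-cohort Spearman with its partner probe is ≈ 0.5. 163/350 of
  DERNAs additionally load on standardized severity (λ = 1.3); the DE shift
  of those RNAs is sign-aligned with the severity loading, and that of the
  rest with the partner probe's direction, so the planted signals reinforce
  rather than cancel.
* **Strength phenotype.** strength = 100 − 15·severity + N(0,5): patients
  average ≈ 85 % of predicted with realistic spread, and strength-coupled
  RNAs correlate with strength through the shared severity factor.
* **Detection p.** ~U(0, 0.005) almost everywhere, a 0.2 % cell-failure
  fraction and 0.5 % wholly failed probes (which the detection filter
  removes).

What the generator does **not** emulate: chip/batch effects, probe
cross-reactivity, cell-type composition, count-based expression noise, or
any genome-real annotation (coordinates and gene links are synthetic).
Passing recovery tests therefore demonstrate the pipeline's statistical
correctness under its own assumptions, not robustness to those real-data
artifacts.

## Numerical choices and degenerate inputs

* BH is a vectorized step-up with stable sort; input order is preserved.
* p-values are floored at the smallest positive double, never 0.
* Wallenius tails are clipped into [0,1]; categories with no universe genes
  are skipped with a warning rather than erroring a whole run.
* Empty DMP tables are valid everywhere downstream (empty summaries, no
  comparisons) — an empty result is not an error.
* Comparisons with an empty side are skipped and logged.
* TSV floats are written at 10 significant digits, which makes repeated
  runs byte-identical without printing noise digits.

## Problem sizes in validation

The test suite and recovery properties run on default synthetic cohorts of
2000 probes × 2000 RNAs × 148 samples (twenty seeds for the FDR property,
ten for sensitivity), a size at which every planted-structure property is
stable while the whole suite completes in well under a minute. The
acceptance script's study-scale statistics are deterministic arithmetic on
the reported group sizes and proportions and run in milliseconds.
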