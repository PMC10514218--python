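# Methods

## Model and procedure

A subject's atrophy is quantified against a normative model of
gray-matter (GM) concentration built from cognitively normal (CN)
subjects on a common voxel grid. All volumes are assumed spatially
co-registered and modulated (values reflect tissue amount, so total
intracranial volume needs no separate covariate); no resampling or
spatial normalization is performed here.

For each smoothing level (Gaussian kernels of 0, 2, 4, 8 mm FWHM;
σ = FWHM/2.3548, applied per axis in voxel units, zero-padded at the grid
boundary so edge voxels are attenuated), the pipeline:

1. builds reference models from the smoothed CN maps —
   * *standard*: voxel-wise mean and sample SD (denominator n−1) over all
     eligible CN;
   * *bracket*: for each test subject, the k = 20 eligible CN nearest in
     age within a strict window |age − target| < h (h = 5 y or 2.5 y);
     ties in age distance break by ascending subject id. Subjects with
     fewer than k eligible CN in the window are skipped and logged —
     coverage, not failure;
   * *W-score*: per-voxel OLS of GM on age over CN; residual SD uses
     denominator n−2;
   eligibility optionally restricts CN to amyloid-negative
   (SUVR ≤ 1.11);
2. computes Z = (x − μ)/σ (or W = (x − ŷ(age))/σ_resid) inside a brain
   mask, with voxels of σ below a floor excluded as sentinels and counted
   per map (`flagged_voxels`);
3. counts voxels with Z strictly below each threshold (−2.5, −3.5, −4.5)
   per ROI and in total GM (union of all labels) — the extent score;
4. evaluates each grid cell's extent score as a CN-vs-MCI classifier:
   Mann-Whitney AUC (ties ½), DeLong variance and 95% CI, Youden-optimal
   cut-off reported as the midpoint between adjacent distinct scores
   (ties in J break toward higher specificity, then the lower cut-off);
5. compares reference strategies per cell with the paired DeLong test on
   the intersection of subjects scorable under both strategies (bracket
   coverage shrinks samples; pairing requires the intersection — the
   per-strategy unpaired AUC over all scorable subjects is reported in
   the AUC grid alongside);
6. tabulates CN-vs-MCI Wilcoxon rank-sum tests per cell at a per-test
   α = 0.0001, reporting the implied family-wise (Bonferroni) α = 0.0001·m
   over the m grid cells alongside.

Integer-age coverage of a bracket strategy is summarized by scanning
whole years across the CN age range padded by the half-width and
returning the widest contiguous run where selection succeeds.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| k | 20 | members per bracket reference |
| half-width | 5.0 / 2.5 y | strict age window ("10-/5-year brackets") |
| thresholds | −2.5, −3.5, −4.5 | Z levels defining subthreshold voxels |
| kernels | 0, 2, 4, 8 mm | FWHM of pre-standardization smoothing |
| ε (mask) | 0.05 | reference-mean GM level defining the brain mask |
| SD floor | 1e-4 | minimum σ for a voxel to receive a Z value |
| exclude_self | False | leave each CN out of their own reference |

Self-inclusion is the default because normative references are built
from the same CN sample that is later scored; the leave-one-out switch
exists because self-inclusion shrinks a CN member's own Z-scores with
weight 1/k — negligible for a 141-member standard reference, material
for k = 20 brackets (see "Null calibration" below).

The mask is derived once per smoothing level from the all-eligible-CN
mean map (mean > ε) and shared by all strategies, so extents are counted
over identical voxel sets and remain comparable across strategies. The
source data carry no explicit mask; this is the package's own policy.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not anatomy. Six disjoint ROI blocks (MTL, four lobar ROIs, other-GM)
partition the interior of a 24³ grid at 2 mm voxels. A subject's voxel
value in ROI r is

    g_r(age) · (1 − a_r·[amyloid+]) · (1 − m_r·[MCI]) · s_i + ε_v,

truncated at zero, with background exactly zero, where

* g_r(age) = g0·(1 − r1·(age−70) − r2·(age−70)²), g0 = 0.8,
  r1 = 0.004/yr, r2 = 0.0004/yr² — the quadratic term makes decline
  accelerate with age, which is precisely what breaks an all-ages
  reference;
* m_r = 0.15 in MTL and 0.10 in temporal GM, 0 elsewhere (focal MCI
  atrophy);
* a_r = 0.02 everywhere (the amyloid effect in CN is reported only as
  subtle; 2% is this package's choice, exposed in `CohortSpec`);
* s_i is a lognormal between-subject scale (σ = 0.05) and ε_v additive
  Gaussian voxel noise (SD 0.05).

Demographics default to the target study scale: 141 CN aged 73.45 ± 5.75
y and 91 MCI aged 70.84 ± 7.50 y (truncated normal on [60, 90], rounded
to 0.1 y), amyloid-positive fractions 0.24 (CN) and 0.46 (MCI), SUVR
drawn consistently with the 1.11 positivity rule. Each subject has an RNG
stream derived from (seed, id-hash), so cohorts are reproducible and
extensible without reshuffling.

What the generator does *not* model: real anatomy and registration
error, spatially correlated noise, scanner/site effects, non-Gaussian
tails, longitudinal change. Passing simulation tests therefore
demonstrates the internal consistency and statistical behavior of the
pipeline under its assumed generative model, not clinical performance.

## Simulation experiments

* **Strategy ordering** — 20 replicate cohorts at the default spec;
  within each, AUCs of standard vs bracket strategies for total GM at
  Z = −3.5, unsmoothed (the cell reported as optimal for this analysis);
  a paired sign test across replicates. Brackets dominate the standard
  reference because the standard σ is inflated by age heterogeneity and
  its μ mismatches old and young subjects.
* **Null calibration** — 50 replicates with the disease and amyloid
  effects off *and* the MCI age/amyloid distributions set equal to CN's:
  a genuine null requires exchangeable groups, otherwise the standard
  reference's age confounding produces a real AUC difference. These runs
  use leave-one-out references, because self-inclusion alone creates a
  true CN-vs-MCI score asymmetry (CN shrink their own reference) that a
  calibrated test must and does detect. Under this null the standard-AUC
  CIs cover 0.5 at the nominal rate and the DeLong strategy comparison
  rejects at ≈5%.
* **W-score recovery** — voxel-wise slope −0.004/yr with residual SD
  0.02 at n = 141 is recovered within three analytic standard errors;
  with the slope frozen at zero the W-map equals the corresponding Z-map
  to 1e−12.

Problem sizes (24³ grid, 232 subjects, single-cell scoring for the
replicate experiments; 16³ grids for unit-level fixtures) were chosen so
the full factorial run takes seconds and the replicate experiments a few
minutes on one CPU.

## Numerical choices

* AUC via midranks: exactly equals the exhaustive pairwise Mann-Whitney
  probability, including tied scores.
* Subthreshold uses strict Z < t; with continuous data the choice is
  measure-zero and is fixed for determinism.
* Counts are raw voxel counts (a mm³ column is emitted alongside).
* Smoothing truncates the Gaussian kernel at 8σ, making the separable
  filter match dense convolution to better than 1e−8.
* Degenerate DeLong variance (e.g. identical score vectors) returns
  p = 1.0 with an explicit `degenerate` flag.
* Rank-sum: exact enumeration for n1+n2 ≤ 12 without ties, else normal
  approximation with tie and continuity correction (p = 1 exactly at
  U = μ). Chi-square is Pearson without continuity correction. T-tests
  accept printed summaries (mean, SD, n) directly; the pooled variant
  reproduces the published demographic p-values.
* Reference SD uses n−1 and W-score residual SD n−2; the n−1 choice
  makes the member standardization identity (per-voxel member-Z mean 0,
  sample SD 1) exact, which the tests verify to 1e−10.

## Known limitations

* Grid compatibility is strict (identical shape and voxel size); no
  resampling, world-coordinate handling, or atlas alignment.
* No nonlinear normative models (GAMs, quantile regression), no site
  harmonization, no cluster-level inference.
* The W-score covariate set is age only; additional covariates would
  need model extension.
* Bracket references rebuild mean/SD per subject; for very large cohorts
  a per-integer-age cache would be the first optimization.
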