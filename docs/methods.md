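# Methods

This note documents the statistical procedures implemented in
`seafusion`, the defaults they run with, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make runs reproducible.

## Study design and the role of the day-pair

The design is a paired comparison: on each experimental day exactly one
treated and one control fish are processed, six days per exposure time
(3 h and 24 h). The day-pair is the atomic unit everywhere:

* **Pair centering** subtracts each day-pair's mean from both of its
  samples, per feature. Any additive per-day effect shared by the pair
  (instrument drift, batch handling) is removed exactly — after
  centering, the two rows of every pair sum to zero. The operation uses
  only the pairing, never the class labels, so it is safe to apply
  before cross-validation.
* **Cross-validation folds are day-pairs** ("venetian blind with paired
  deletion groups"): each fold holds out one day's control/treated pair;
  with 6 days per time point this is leave-one-pair-out with 6 folds.
  Autoscaling parameters are re-estimated on the training pairs of every
  fold; the held-out pair is centered by its own pair mean (label-free)
  and scaled with the training statistics.

Order of operations: pair centering per (day, time, site) first, then
autoscaling over the analysis set — the 12 samples of one time x site
for BE-PLS-DA, the 24 samples of one site for MFA (the MFA view shows
all four classes jointly). Zero-variance columns after centering are
dropped rather than imputed: they carry no discriminant information and
break unit-variance scaling. Missing intensities raise an error; the
workflow expects complete tables.

## MFA

Each quantitative block is autoscaled and then multiplied by
`sqrt(1/λ₁)`, where `λ₁` is the first eigenvalue of the block's own PCA;
this equalizes first-axis inertia (1 per block) so no block dominates by
scale or width alone. The global solution is the SVD-based PCA of the
concatenated weighted blocks. Eigenvalues are `s²/(n−1)`; the
contribution of variable *j* to dimension *s* is `100 · v_js²` (squared
loading of the weighted matrix, summing to 100% per dimension), and a
block's contribution is the sum over its variables.

The categorical "classes" variable (time x group, four levels) enters as
an additional block through its indicator matrix, each level column
divided by the square root of the level proportion and centered — the
standard MFA treatment of qualitative variables — and is weighted by its
own `1/λ₁` like any block. It is **active** by default (it shapes the
solution); `class_active=False` computes the solution from the
quantitative blocks only. The active choice makes the block-contribution
plot directly readable as "correlation between class belonging and each
platform"; the switch exists because either convention is defensible.

Sign convention: each dimension is flipped so its largest-magnitude
loading is positive, making score plots reproducible. Default dimensions
kept: 5 (the first two carry the interpretable structure in the study
design; the rest are diagnostics).

## PLS-DA, VIP, and backward elimination

PLS1 via NIPALS on the autoscaled matrix with response y = +1 (control)
/ −1 (treated); weights are unit-norm, X is deflated per component, and
the regression vector is `b = W (PᵀW)⁻¹ q`. Class prediction is the sign
of `ŷ`; an exact 0 is assigned to control and logged. With balanced
classes this symmetric coding has no tuning constant.

VIP for feature *j* over *A* components:
`VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` where
`SSY_a = q_a² · t_aᵀt_a` is the response variance captured by component
*a*; squared VIPs sum to the feature count.

Backward elimination loops: (1) choose the component count by
venetian-blind CV classification error for 1..`max_lv` (default 5),
ties to the smallest count; (2) fit on all samples at that count and
compute VIP; (3) remove the minimum-VIP feature (ties to the
lexicographically smallest id); (4) record both the classification error
and the RMSECV of the out-of-fold predictions. The loop runs to a single
feature, and the retained set at the cycle with the **lowest RMSECV** is
selected, refit, and reported with calibration and CV accuracies.

Why RMSECV and not classification error for the selection: with 12
samples and a separable effect, the classification error is 0 over long
stretches of the trace — it cannot rank candidate subsets. The
continuous prediction error keeps falling while uninformative variables
leave and rises again when informative ones start to go, giving a
well-defined optimum. This is the "best prediction error" rule as used
in chemometrics practice.

Percent elimination: for wide matrices (the fused muscle set has 1451
features) `drop_fraction` removes the bottom fraction of features per
cycle until `drop_floor` remain, then elimination proceeds one at a
time. The pipeline default is 10% down to 50 features, which makes a
fused run take seconds; exhaustive single elimination (`drop_fraction=0`)
is the reference behavior and the two can select slightly different
sets.

### What the cross-validated accuracy does and does not mean

The CV inside backward elimination is **internal, not nested**: the
elimination path is computed from full-data VIPs, so the per-cycle CV
error is selection-biased upward in accuracy. On pure-noise data with
hundreds of candidate features and 12 samples the selected model still
reports near-perfect "cross-validated" accuracy. This is a property of
the procedure itself, reproduced deliberately; the package therefore
also exposes the unbiased building block (`venetian_blind_cv` without
selection, whose null accuracy is at chance), and any claim about a real
dataset should rest on external validation or a permutation test of the
whole selection pipeline, not on the internal CV accuracy alone.

Similarly, exact support recovery at this sample size is limited by
chance correlation: with 6 day-pairs, a few hundred noise features and a
standardized effect of 3, noise features' sample correlations with the
class overlap the planted features' range, so *no* ranking rule can
reliably return the planted set with low contamination. The selected
panels should be read as discriminant panels, not as the complete list
of truly affected molecules.

## Microbiome statistics

* **Alpha diversity**: bias-corrected Chao1
  `S_obs + f₁(f₁−1)/(2(f₂+1))`, Shannon entropy (natural log; `base=2`
  available), and Simpson's index as Gini–Simpson `1 − Σp²` (the raw
  `Σp²` is available via `gini=False`). Computed on counts rarefied to
  10,000 reads (seeded subsampling without replacement; samples below
  the depth are dropped with a warning, mirroring the removal of
  under-sequenced samples). Kruskal–Wallis (tie-corrected, chi-square
  p, H = 0 for fully tied data) compares indices across groups.
* **Beta diversity**: Bray–Curtis dissimilarity, PCoA by Gower double
  centering (axes with non-positive eigenvalues are dropped with a
  warning), and PERMANOVA with seeded label permutations,
  `p = (1 + #{F* ≥ F}) / (1 + n_perm)`; 999 permutations by default.
* **TMM normalization**: per-sample factors from the weighted mean of
  trimmed log2 ratios against a reference sample (the one whose
  upper-quartile proportion is closest to the mean upper quartile),
  trimming 30% of M-values and 5% of A-values two-sided, weights the
  inverse delta-method variances, factors renormalized to geometric
  mean 1. These are the original method defaults; the implementation
  reproduces edgeR's `calcNormFactors(method="TMM")` to machine
  precision (asserted in the test suite).
* **Differential abundance**: per taxon, a negative-binomial GLM with
  log link, offset `log(library_size × TMM factor)`, and a group
  coefficient; dispersion is profiled per taxon by maximum likelihood
  (floored at 1e−8, no shrinkage), significance by the Wald z with
  two-sided normal p, and BH FDR within each contrast. Taxa with zero
  counts in both groups are excluded. Rarefaction is **not** applied
  before DAA — the offset handles depth.

  Caveat: the unshrunken Wald test is anticonservative at the study's
  group size (measured type-I ≈ 0.10–0.12 at n = 6+6 versus 0.045 at
  n = 25+25 in the suite's simulations). Interpreting borderline FDR
  values at n = 6 per group requires care; shrinkage estimators exist
  precisely for this regime but are outside this package's remit of
  reproducing the plain TMM + Wald chain.
* **Contrast set** (`run_comparisons`): six families — control vs
  treated at 3 h and at 24 h (per site), 3 h vs 24 h within control and
  within treated (per site), and pooled all-sites control vs treated at
  each time. Each contrast computes its own TMM factors and its own FDR
  family. Fold changes are reported as `2^log2FC` rounded to two
  significant figures, matching the reporting convention of
  family-level DAA tables.

## Synthetic data

The generator emulates the paired design, not the instruments:

* Feature values are `μ_j + δ_day + effect + ε` on a log-intensity-like
  scale: log-normal feature means `μ_j` (meanlog 2, sdlog 0.5), a day
  effect `δ ~ N(0, day_effect_sd)` shared **exactly** by the day's pair
  (this makes pair centering provably optimal and gives sharp tests),
  a planted shift of `±effect_size × noise_sd` on `n_planted` features
  per block for treated samples (optionally disjoint sets per time
  point, so all four classes separate), and Gaussian noise.
* OTU counts are negative binomial with mean
  `library_size × proportion × 2^log2fc` for planted taxa in the
  targeted group; `dispersion = 0` degenerates to Poisson. Library
  sizes are log-normal(`ln 10⁴`, 0.3), mirroring the 10,000-read
  comparison depth; proportions default to log-normal draws.
* Defaults mirror the study: 6 day-pairs per time, block sizes per site
  (muscle 921/464/66, skin 944/384/99, gills 380/108, eye 340), 58
  taxa, effect size 3, day effect sd 1, noise sd 1, NB dispersion 0.1.

Not emulated: correlated features (real lipid classes co-vary),
heteroscedastic intensity noise, missing values, compositional
artifacts beyond library size, taxonomic structure, or spoilage
kinetics. Passing tests therefore demonstrate correctness of the
*procedures* under a clean generative model, not performance claims for
real spectra.

## Determinism and numerics

All randomness flows through `numpy.random.Generator`s derived from one
master seed (`SeedSequence(seed, spawn_key=(stage,))`); identical
configuration and seed give byte-identical outputs. Tie-breaks are
deterministic everywhere (minimum VIP → smallest feature id; equal CV
error → fewer components / fewer features). Constant columns inside CV
folds are given unit scale so they contribute nothing rather than
dividing by zero. PCA reconstruction, scaling round-trips, score
orthogonality and contribution normalization are asserted at 1e−8–1e−12
in the suite. Written tables are TSV with `#` provenance headers
(version, seed, config hash).

## Problem sizes used in the validation suite

Simulation-backed tests run at the study's own scale where the claim
depends on it (fused 921/464/66 blocks, 6 day-pairs, 20 replicate
seeds) and at reduced widths (tens to hundreds of features) for
distributional checks that need many replicates — 500 datasets for the
PERMANOVA level, 500 null taxa for the Wald level, 50 seeds for the CV
null. The acceptance script uses the full fused width with 20 seeded
replicates.
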