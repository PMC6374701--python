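# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limits of what the test suite demonstrates.

## Two-tissue compartment model

The FDG kinetics of a volume of interest (VOI) are modelled by the standard
two-tissue compartment system: a free pool C1 and a phosphorylated pool C2,

dC1/dt = k1·Cp − (k2 + k3)·C1 + k4·C2,
dC2/dt = k3·C1 − k4·C2,  C1(0) = C2(0) = 0,

with the measured signal Cmodel = (1 − VB)(C1 + C2) + VB·Cp. Parameters and
units: k1 (plasma→tissue transport, 1/min), k2 (tissue→plasma, 1/min), k3
(hexokinase phosphorylation, 1/min), k4 (dephosphorylation, 1/min), VB
(fractional blood volume, unitless in [0, 1]). The net influx constant is
Ki = k1·k3/(k2 + k3), defined as 0 when k2 + k3 = 0.

**Solution.** The system is linear, so both compartments are convolutions of
Cp with a biexponential impulse response whose rates a1 ≤ a2 are the roots
of s² − (k2+k3+k4)s + k2·k4. The convolution is evaluated exactly for a
piecewise-linear Cp on a uniform fine grid (default step 0.01 min) with a
first-order recursive filter, and frame-averaged over the acquisition
intervals, which is what a scanner reports. A repeated root (measure-zero
set k2·k4 = ((k2+k3+k4)/2)²) is nudged by 1e-7 in k2. The analytic solution
agrees with a stiff LSODA integration to better than 1e-6 relative error
(tested).

**Input function.** The synthetic plasma curve is the Feng 4-parameter
bolus model, Cp(t) = (A1·τ − A2 − A3)e^(−l1 τ) + A2 e^(−l2 τ) + A3 e^(−l3 τ)
with τ = t − delay, clipped at zero; defaults (A1 = 850 kBq/mL/min,
A2 = 21, A3 = 20 kBq/mL, l1 = 4.1, l2 = 0.12, l3 = 0.01 /min, delay
0.3 min) give a sharp early peak and a slow tail typical of an
image-derived aorta curve. Any tabulated Cp is accepted.

**Fitting.** Bounded nonlinear least squares over (k1, k2, k3, k4, VB) with
rates in [0, 5]/min and VB in [0, 1]; uniform residual weights by default
(frame-duration weighting is a flag — scanner software conventions differ
and none is normative here). Multi-start: one fixed physiological start plus
seeded log-uniform draws (default 10 starts, seed + start index), early
stop at relative RSS < 1e-16, followed by a polish restart from the
incumbent with Jacobian-based variable scaling — this rescues the weakly
identifiable valley where k2 is near zero and k3 large. Standard errors come
from the Gauss-Newton covariance at the optimum.

**Frame schedule.** 28 frames over 60 min: 10×30 s, 5×60 s, 5×120 s,
8×300 s. Only the frame count and total duration are constrained by the
acquisition protocol being emulated; the schedule is config-overridable.

## SUV and fractal dimension

SUV = mean activity concentration (kBq/mL) over a late window (default
50–60 min) divided by injected dose per body weight in kBq/g (1 g ≈ 1 mL);
defaults 370 MBq and 75 kg.

The fractal dimension of a time-activity curve quantifies its heterogeneity
by box counting: the curve is normalized into the unit square (time and
activity each scaled by their range), treated as piecewise linear, and for
dyadic grid scales s = 2^i, i = 1..7, the number of s×s boxes the curve
intersects is counted per column from the curve's min/max in that column
(dense resampling at 4096 points). FD is the least-squares slope of
log N(s) on log s, clipped to [1, 2]. A constant curve has no activity range
and returns 1.0 by convention. The normalization makes FD invariant to
positive rescaling of the activities (tested). Scale count and the
normalization are implementation-defined choices, fixed and reported here
because box counting alone does not pin them down.

## Paired differential expression

Per gene, per-patient log2 differences d_i = tumor − normal; the moderated
statistic shrinks each gene's sample variance s² (df d = n−1) toward a
pooled prior: method-of-moments matching of the first two moments of the
observed s² across genes to a scaled inverse-chi-square prior yields
(d0, s0²); the posterior variance is (d0·s0² + d·s²)/(d0 + d) and the t
reference has d0 + d degrees of freedom. When the observed between-gene
dispersion of s² does not exceed chi-square sampling noise, d0 → ∞ and the
test pools completely. P-values are Benjamini-Hochberg adjusted
(statsmodels); significance requires adj_p < 0.05 and |log2FC| ≥ 1 (both
config-exposed). Three comparisons (all pairs, non-metastatic,
metastatic) are intersected into the consensus set.

## Spearman screen and MFA

The screen computes Spearman rho between every gene and each of the 8 PET
variables via rank transformation, with the asymptotic t approximation
p = 2·P(T_{n−2} ≥ |rho|·sqrt((n−2)/(1−rho²))). The filter is |rho| ≥ 0.6
and raw p < .05 — deliberately uncorrected, reproducing the screening
convention; a BH flag is available. Constant vectors are skipped with a
warning.

MFA: each variable is centered and scaled to unit population variance; each
block is divided by its leading singular value so its first principal
direction carries unit inertia and no block can dominate Dim1; one global
SVD of the concatenation follows. Block contribution to a dimension is the
sum of squared loadings of its variables (loadings are unit-norm per
dimension, so contributions sum to 100%). Components are oriented so the
largest-magnitude loading is positive. Identities used as oracles: a single
block reproduces plain PCA percent-variance exactly; duplicated blocks
contribute 50/50 on every dimension.

## Feature-set evaluation and aggregated lasso

Repeated stratified k-fold cross-validation (default 10 folds × 10 repeats
× 10 seeds) with a random forest (500 trees, sqrt(p) features per split —
defaults, config-exposed). Out-of-fold class probabilities are pooled per
repeat; ROC-AUC, sensitivity (recall on cancer) and specificity (recall on
control) are computed at a 0.5 cutoff, and aggregated as mean ± SD. Fold
and forest seeds derive deterministically from (seed, repeat, fold).

Aggregated lasso: per seed, a 10-fold CV binomial-deviance curve over a
40-point log-spaced lambda grid from lambda_max = max|X'(y − ȳ)|/n down two
decades; the one-standard-error rule picks the largest lambda whose mean CV
deviance is within one SE (sd across folds / sqrt(folds)) of the minimum;
the nonzero coefficients of the full-data fit at that lambda form the
per-seed set. L1 logistic fits use liblinear with C = 1/(n·lambda) and an
effectively unpenalized intercept. A degenerate single-class fold triggers
refolding with a derived seed. Features selected in ≥ 50% of seeds (default
100; config-exposed) form the final signature — the aggregation rule the
"total aggregated results" phrasing leaves open, fixed here as selection
frequency with a 0.5 cutoff.

## Signature scoring and survival

Signature genes are split into two groups by average-linkage hierarchical
clustering on 1 − Pearson distance over *normal* samples; Group1 is the
cluster with higher mean normal expression. Each gene is binarized against
its median across *cancer* samples only — strictly greater scores 1, a tie
scores 0 — and per-sample group scores are indicator means; a score > 0.5
labels the sample High, exactly 0.5 labels Low (the strict reading of the
rule; ties at the median and at 0.5 are not otherwise specified). KM
curves, the two-group log-rank test and the univariate Cox model (Efron
ties, Wald 95% CI on log-HR) are delegated to lifelines and verified
against hand-computed small-sample oracles in the tests.

## Synthetic cohort: what it emulates, and what it does not

Defaults encode the emulated study: 30 patients with paired tumor/normal
arrays (6 metastatic), 100 planted DE genes at |log2FC| = 2 with residual
SD 0.5 and a patient random effect (SD 0.3); 40 of the DE genes are coupled
to a per-patient latent tumor-metabolism factor z ~ N(0,1) with loading 0.8
added to their tumor expression. The same z drives log k3 (location
log 0.08, scale 0.5) with correlation equal to the loading; k1, k2, k4
(lognormal around 0.15, 0.40, 0.010 /min) and VB (logit-normal around 0.05)
are independent of z. Tumor TAC multiplicative frame noise grows with z
(1% to ~11%), so curve heterogeneity — hence FD — and late uptake — hence
SUV — track metabolism, reproducing the coupled {SUV, k3, FD, Ki} /
orthogonal {k1, k2, k4, VB} split. Normal-tissue curves use lower,
independently drawn rates.

The TCGA-like cohort (defaults 478 tumors, 41 normals) plants Group1 genes
high and Group2 genes low in normals with shared per-sample group factors
(so correlation clustering can find the groups), independent High/Low
states per tumor (±1.5 log2 around the cohort center), exponential event
times with hazard baseline_hazard · planted_hr^{High-Group2} (defaults
5e-4/day, HR 0.47), and independent uniform censoring on [0, 3000] days
thinned per stratum to the target censoring fraction (default 0.6) — the
simplest mechanism satisfying the non-informative censoring assumed by
KM/Cox.

The selection benchmark plants 12 informative features (7 tagged gene, 5
tagged PET; per-feature log-odds 1.0) among 90 background features drawn as
3 tightly co-expressed modules (within-module correlation 0.97, the
redundancy scale of same-transcript probe sets). This matters: with fully
independent background noise the lambda.1se rule retains 10–20 spurious
features regardless of implementation (glmnet behaves identically), because
each independent noise feature is its own lottery ticket; redundant modules
are pruned to at most a representative or two, which the selection-frequency
aggregation then discards.

Not emulated: probe-level microarray intensities, platform/batch structure,
RNA-seq counts, PET image voxels, VOI placement, partial-volume effects,
non-proportional hazards, or informative censoring. Passing tests
demonstrate that each estimator recovers what its own generative model
plants — they say nothing about robustness to the preprocessing artifacts
of real data.

## Problem sizes and determinism

The test suite and the acceptance script run at the sizes the recovery
properties are stated at (20 noise-free + 50 noisy kinetic fits; 200 null
and 20 planted DE replicates at 500 genes × 20 pairs; 60-sample CV
calibration with 3 full 10×10 schemes; 25-seed aggregated lasso at n = 200,
p = 102; 50 survival replicates at n = 400 and one null at n = 1000). The
end-to-end demo pipeline defaults to a reduced CV scheme (2 seeds × 3
repeats, 100 trees) and 20 lasso seeds to stay interactive; the full
10×10×10 / 100-seed study scheme is a configuration change.

All randomness flows from explicit seeds: generator streams are keyed per
component, pipeline stage seeds are SHA-256-derived from the global seed and
the stage name (so adding a stage never perturbs another stage's draws), and
two runs with the same config produce byte-identical artifacts (hashes in
the run report; verified in the tests).

## Known limitations

- The moderated-t prior is matched on the raw scale of s², not the log
  scale; for very small gene counts the d0 estimate is coarse (it then errs
  toward complete pooling, which is conservative for rank ordering).
- The kinetic fit's 1% round-trip guarantee holds for rates in
  [0.01, 1]/min and VB in [0.01, 0.2]; near-degenerate corners (k2 ≈ 0 with
  large k3) are rescued by the polish pass but have wide confidence
  intervals, as they should.
- FD values depend on the fixed dyadic-scale/box-counting conventions;
  comparisons are meaningful within this implementation only (n_scales is
  recorded alongside).
- The MFA variable coordinates use the correlation convention; sample
  coordinates are reported in the U·S scaling.
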