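# Methods

`cogreserve` implements a multivariate moderation analysis of cognitive
reserve (CR): it searches for a brain-activity pattern whose expression
weakens the link between Alzheimer's-type pathology and cognitive
performance, scores individuals on that pattern, and validates the score
cross-sectionally and longitudinally. Because the clinical data this kind
of analysis is designed for are access-restricted, the package ships a
synthetic-cohort generator with planted ground truth; every stage is
verified against the quantity it is supposed to recover.

## The moderation model

Let `beta_i` be subject-level subsequent-memory contrast values over the
`V` voxels of a task-active mask, `PL in [0, 1]` a scalar pathological-load
score, and `y` a (possibly Box-Cox-transformed) cognitive composite.
Conceptually, activity `A` can help cognition additively and/or by
moderating the pathology slope: `y = b0 + b1*A + (b2 + b3*A)*PL^2 + e`,
with pathology entering only through its square (empirically the better
single predictor of the composite). To work with whole activity patterns
instead of single regions, the maps are reduced by PCA of the mean-centered
data and the model becomes

    y = b0 + sum_p b1_p*PC_p + (b2 + sum_p b3_p*PC_p) * PL^2 + c*COV + e

with covariates age (centered), sex, TIV (centered) and site dummies;
education is deliberately excluded because it is itself a CR proxy. The
moderation coefficients are back-projected to voxel space,
`w_i = sum_p b3_p V_{p,i}`, and each subject is scored by
`CR_score = sum_i w_i beta_i`; the additive analogue of this aggregate
(from `b1_p`) is the brain-activity effect score, BAE.

The number of components `P` is selected by 10-fold cross-validation on
held-out R^2 (PCA re-fit inside each training fold so the held-out measure
is not optimistic; ties broken toward the smallest `P`). The default
candidate grid is 2..9: beyond that range CV differences are small relative
to their fold-to-fold variability, and a plain argmax over a long flat grid
drifts into noise-fitting components, which measurably degrades recovery of
the weight map. The grid is configurable.

## Pathological load

The three ATN markers — CSF A-beta 42:40 ratio (down with pathology), CSF
p-tau (up), TIV-corrected hippocampal volume (down) — are z-scored and
reduced to one dimension, by a 1-D t-SNE (perplexity 30, PCA
initialisation, >= 1000 iterations, fixed seed) or by the first principal
component; on realistic panels the two reductions correlate above 0.99.
A 1-D embedding's sign is arbitrary, so the coordinate is oriented to
correlate positively with the p-tau z-score (fallback: negatively with the
A-beta ratio) and min-max rescaled so the fitting sample spans [0, 1].
t-SNE has no parametric out-of-sample map; new subjects are scored by
inverse-distance-weighted nearest neighbours in biomarker z-space (a
documented limitation; the PCA method scores new data exactly). The
hippocampal-atrophy fallback score, for subjects without CSF, rescales
`-(hv/TIV)` to [0, 1] the same way.

## Quality control and outcome processing

Subjects are excluded when any rule statistic strictly exceeds its
threshold: more than 8 indoor/outdoor errors; absolute response bias above
1.5 (bias defined here as mean confidence rating minus the 5-point scale
midpoint — a symmetric convention, since the source convention is not
published); framewise displacement above 0.5 mm in any single volume or
above 0.2 mm in more than 2% of volumes (FD is the mean absolute
between-volume difference of the six rigid-body parameters, rotations
converted to arc length on a configurable 50 mm sphere); or extreme-outlier
betas (outside Q1 - 3*IQR .. Q3 + 3*IQR across subjects per voxel, linearly
interpolated quartiles, zero-IQR voxels never flag) in more than 10% of
masked voxels. Missing rule inputs flag the subject "unevaluable" rather
than silently keeping them.

The cognitive composite is the mean of five subtests, each z-scored to the
cognitively unimpaired subsample. For modelling, a Box-Cox transform
(default lambda 2.8) can be applied; the shift defaults to `1 - min(y)` so
the smallest shifted value is exactly 1, and both parameters are recorded.
The arcsine parametric modulator `arcsin((x-3)/2) * 2/pi` for confidence
ratings 1..5 is provided as a utility for first-level-model construction;
no GLM engine is included.

## Voxelwise inference

Subjects are resampled with replacement; model coefficients are
re-estimated on the *fixed* full-sample PCA basis (re-fitting the basis per
resample would misalign component signs and order; a sensitivity flag could
re-fit it, at the cost of alignment) and back-projected. Per voxel the B
resampled weights are sorted and the 95% bounds taken at the fixed order
statistics floor(0.025B)+1 and ceil(0.975B) — (126, 4875) at B = 5000 — so
a voxel is significant when its interval excludes zero. Singular resample
designs are redrawn (keeping B exact); more than 10% redraws aborts.
Significant voxels are grouped into connected components (26-connectivity
by default, configurable to 6 or 18), separately for positive and negative
weights since clusters are reported with a signed mean weight; components
under 50 voxels are dropped. Cluster descriptives include percent
concordance — the share of cluster voxels whose weight sign matches the
group-mean contrast there; a zero group mean counts as discordant.

## Validation models

Cross-sectionally, the CR score's moderating role is tested in a separate
model, `Performance = b0 + b1*BAE + b2*PL^2 + b3*CR_score*PL^2 + c*COV + e`:
the CR score enters only through the interaction, exactly as the model is
defined (a flag adds the main effect for sensitivity analysis), with BAE
controlling the additive pathway. An atrophy variant substitutes squared
hippocampal atrophy for PL^2. The CR-education association is a Pearson
correlation with a Fisher-z CI. Before any CR-score analysis, extreme
upper outliers (> Q3 + 3*IQR) are removed.

Longitudinally, the composite is modelled with a linear mixed model:
fixed effects atrophy^2, time (years since baseline, continuous,
uncentered), CR, all two-way products, the three-way CR x atrophy^2 x time
term, BAE and BAE x time, plus covariates; random subject intercepts and
slopes with unstructured covariance, REML estimation. The random-slope
term is assessed by an ML likelihood-ratio comparison against a
random-intercept-only model using the boundary-corrected
`0.5*chi2(1) + 0.5*chi2(2)` reference. Fixed-effect inference uses
large-sample Wald (z) intervals; at the sample sizes used here these are
near-nominal (the calibration suite verifies 95% +/- 3% coverage), and a
finite-sample denominator-df correction was judged not worth implementing.
If the outcome is exactly deterministic (zero residual), the mixed model is
degenerate and the report carries the OLS fixed effects with zero
variances; if the random-slope fit fails, the model falls back to a random
intercept only and flags non-convergence.

## Synthetic cohorts

The generator plants a latent severity `s_i ~ U(0, 1)` per subject and
derives everything from it.

* **Biomarkers.** A-beta ratio `0.10 - 0.06 s`, p-tau `15 + 70 s` pg/ml,
  corrected hippocampal volume `0.0062 - 0.0022 s` (TIV ~ N(1.55e6,
  1.4e5) mm^3), each plus Gaussian noise scaled as a fraction (default
  0.2) of the signal SD — enough noise that the three markers disagree,
  little enough that severity remains recoverable.
* **Contrast maps.** `beta_i = mean_map + expr_i * w*/||w*||^2 +
  sum_k z_ik * q_k + noise`, with the reserve pattern `w*` a set of signed
  Gaussian blobs (two positive, one negative by default — mimicking the
  topology of activation/deactivation reserve clusters without claiming
  anatomy), nuisance components `q_k` orthonormalised against it, and
  expression mean-centered, so the inner product of `w*` with a centered
  noise-free map returns expression exactly. Pattern scale (default 10)
  and per-voxel noise SD (default 1) put the per-voxel signal near SNR 1 —
  individual voxels are unreliable and recovery must pool across the map.
  Expression is independent of severity by default so moderation is
  identifiable separately from main effects.
* **Cognition.** `y = b0 + b1 z_1 + b2 s^2 + m*expr*s^2 + c*COV + site
  offsets + noise` with defaults b2 = -2, m = 1, cognition noise 0.3 on a
  composite whose SD is near 1 — a strong but not deterministic
  pathology-cognition link. Education is a noisy linear function of
  expression calibrated to a target correlation of 0.3 (a weak CR-proxy
  association).
* **Visits.** `PACC5(t) = baseline + (g0 + g_a*atrophy^2 +
  g_3*expr*atrophy^2) t + u0_i + u1_i t + noise` over 4 visits spaced 1.1
  years; positive `g_3` (default 0.25 against `g_a = -0.4`) means pattern
  expression attenuates atrophy-related decline.
* **QC failures.** Exactly `round(fraction * N)` subjects per rule (default
  2% each), disjoint across rules: error counts above 8, near-ceiling
  confidence ratings, a single 3.5 mm translation spike, or 15% of voxels
  offset far outside the across-subject outlier bounds.
* **Determinism.** Each stage draws from a sub-stream seeded by the master
  seed plus a fixed per-stage offset, so any stage is reproducible in
  isolation.

What the generator does **not** emulate: raw EPI time series, hemodynamics,
spatial autocorrelation of map noise (noise is i.i.d. per voxel), scanner
or site effects on voxel data (site shifts cognition only — the source
analyses do not characterise site effects on maps), non-Gaussian biomarker
tails, dropout or irregular visit schedules. Passing tests therefore show
the estimators are correct under the model's own assumptions, not that the
assumptions hold in any clinical sample.

## Numerical choices

* PCA via SVD with a deterministic sign convention (the largest-magnitude
  loading of each component is made positive) so weight maps reproduce
  across platforms. PC scores enter the design unstandardised; standardized
  coefficients (`b * SD(x) / SD(y)`, interactions standardised on the
  product column) are computed post hoc.
* Rank-deficient designs raise an error naming the dependent columns.
* Bonferroni-corrected p-values for the task-active mask are capped at 1
  and compared with `<=`, so `alpha = 1` includes every testable voxel;
  zero-variance voxels are excluded with a warning.
* The CI order statistics snap positions within 1e-9 of an integer before
  floor/ceil — `0.05 * 140` evaluates below 7.0 in floating point and
  would otherwise shift the lower index.
* Quantiles use linear interpolation between order statistics throughout.
* All exclusion thresholds are strict (`>`), as printed in the rules above.
* CR and BAE scores are computed on raw (uncentered) contrast values; the
  additive constant this induces is absorbed by intercepts and leaves
  correlations and interaction tests unchanged.

## Calibration studies and their problem sizes

The acceptance suite re-derives, from scratch: the CI index constants; the
exact agreement (<= 1e-8) between the component model at full order and
brute-force voxelwise-interaction OLS on a 6-voxel problem; <= 1e-6
recovery of all planted quantities on a noise-free cohort; pattern and
score recovery above 0.9 correlation at the default conditions (N = 300,
~3000 mask voxels, 10 seeds); a pooled null voxelwise significance rate of
5% +/- 2% at B = 1000 (100 null cohorts with a 16-component basis, so each
cohort contributes many quasi-independent weight-map directions — with few
components the per-cohort rate is heavy-tailed because the weight map lives
in a P-dimensional span); planted-support precision above 0.8 at B = 500
(support taken as |w*| above 1% of its maximum, since Gaussian blobs have
no hard edge); and 95% +/- 3% CI coverage of the cross-sectional and
longitudinal interaction terms over 200 null simulations each (the
longitudinal sims use 200 subjects x 4 visits, where Wald intervals are
already near-nominal).
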