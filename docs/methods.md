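# Methods

`honeyprint` classifies honey samples by harvest year, botanical origin and
geographical provenance from their ATR-FTIR fingerprint spectra, and ships a
seeded synthetic cohort generator so the whole pipeline can be exercised,
calibrated and tested without access to proprietary spectra.  This note
documents the statistical model, the generator, the numerical choices, and
what the synthetic results do and do not show.

## The classification model

**PLS-DA.** Class membership is one-hot coded into a dummy matrix
Y (n × c, columns in lexicographic class order) and regressed on the
autoscaled spectral matrix X by PLS2.  Components are extracted with NIPALS:
for each latent variable (LV) the inner loop iterates

    w ∝ X'u (unit norm),  t = Xw,  q = Y't / (t't),  u = Yq / (q'q)

to a relative score change below 1e-10 (at most 500 iterations), then X is
deflated by t p' with p = X't/(t't) and Y by t q'.  The regression matrix is
B = W (P'W)⁻¹ Q'; predictions ŷ = X_scaled B + ȳ are returned in dummy space
without clipping.  NIPALS is used in production because its per-component
weights, scores and Y-loadings are exactly the quantities VIP needs; an
independently coded SIMPLS serves as a numerical oracle in the test suite
(for a two-class dummy matrix the centred response has rank one, where the
two algorithms provably coincide; the multiclass check is done at full rank
against ordinary least squares instead).

Two decision rules map ŷ to labels.  The default, `argmax`, takes the
largest predicted response, breaking exact ties toward the lexicographically
first class.  `gaussian_threshold` fits one-dimensional Gaussians to the
in-class and out-of-class training predictions of each class, thresholds at
the equal-odds crossing (the midpoint for equal spreads), and assigns the
class exceeding its threshold by the largest margin; the threshold doubles
as the reported ROC operating point.

**Autoscaling.** Each variable is centred and divided by its standard
deviation (divisor n−1).  Columns with standard deviation below 1e-12 —
dead channels, which appear after aggressive feature elimination — are
centred only.  Scaling is refit inside every cross-validation training fold
by default so held-out statistics never leak into the model; `scale_once`
reproduces the fit-once alternative some chemometrics packages use.

**Venetian-blinds cross-validation.** Sample i (in stored data order) goes
to fold i mod s, with s = 10 splits by default.  Fold assignment is
deterministic given data order; the synthetic cohorts are emitted in a
seeded random permutation precisely so that these interleaved folds are not
class-sorted.  Samples are not stratified (faithful to the named scheme); a
warning is emitted if a training fold lacks a class, or if n < s (the folds
then collapse to leave-one-out).

**Model-size selection.** For each A = 1..A_max (default 20) the
cross-validated classification error average is computed: per class, the
one-vs-rest balanced error 1 − (sensitivity + specificity)/2, averaged over
classes.  The chosen number of LVs minimises this quantity, ties resolved
toward fewer components.  The per-LV curve also records the calibration
(training) error average and per-class RMSEC/RMSECV of the dummy
predictions; RMSEC is non-increasing in A by construction of the deflation,
whereas the calibration *classification* error is only typically, not
provably, monotone.

## Marker selection

Per-variable importance is measured two ways on the full-data fit at the
CV-chosen number of LVs:

* **VIP**: VIP_j = sqrt( p Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ) with
  SSY_a = (q_a'q_a)(t_a't_a); mean(VIP²) = 1 identically, which the tests
  exploit.
* **Selectivity ratio**: the scaled matrix is target-projected onto each
  class's regression vector; SR_jk is the ratio of explained to residual
  sum of squares of variable j (zero residual mapped to a large sentinel),
  aggregated over classes by the maximum.

Backward elimination then repeats: cross-validate the surviving variables;
rank variables by the geometric mean of their VIP and SR percentile ranks (a
combined rank is always well-defined, whereas the intersection of "lowest
VIP" and "lowest SR" sets can be empty); drop the lowest 10% (at least one
variable).  The loop stops after `patience` rounds (default 25) without a
new RMSECV minimum or at `min_vars` (default 5).

Two numerical choices here deserve emphasis, because the naive alternatives
demonstrably fail:

* **Groups are compared by the best class-mean RMSECV over model
  complexity**, not by the RMSECV at the error-chosen LV count.  The
  error-minimising LV count is a discrete quantity that shifts as variables
  are removed; RMSECV recorded at that moving target jumps by far more than
  one round's genuine improvement whenever the choice flips, which freezes
  the selection at whatever set preceded the first flip.
* **The returned marker set is the smallest visited group within
  `parsimony_se` (default 0.5) standard errors of the minimum RMSECV**, with
  the SE of an RMSE over n residuals taken as rmse/√(2n).  The strict argmin
  is ill-defined here: iterated selection makes the CV estimate of
  junk-containing groups optimistically biased by roughly one SE, so the
  trajectory bottoms out in a wide flat basin and the literal minimiser
  retains hundreds of uninformative variables.  The one-SE-style parsimony
  rule (familiar from penalised regression) resolves the tie toward the
  smaller set.  The generous patience default simply lets the loop explore
  the full descent at these problem sizes — the selected iteration is
  recovered from the trace, so late stopping costs only runtime.

## The synthetic cohort generator

The generator emulates the study conditions: 109 samples whose botanical ×
harvest-year × region margins match the published sample table exactly
(acacia 41 = 20+21, linden 30 = 19+11, colza 18 = 8+10, honeydew 20 = 13+7;
60/49 by year; 34 Transylvania + 20 Others, the remaining 55 region-
unlabelled), on a 550–4000 cm⁻¹ grid.  The published table fixes only the
two-way margins; the three-way allocation spreads each class's region labels
across years proportionally, keeping the region-year association weak.  The
grid spacing, 1225/1245 ≈ 0.9839 cm⁻¹, is chosen so the closed fingerprint
window [550, 1775] cm⁻¹ contains exactly 1246 variables — the
dimensionality the models are built on; the instrument's true data-point
spacing is not public, so this is a convention, not a claim.

Each spectrum is a sum of Gaussian bands times nuisance factors plus noise:

* **Broad background bands** (13 Gaussians, σ 10–180 cm⁻¹) sketch the
  canonical honey profile: the crystalline/M–O region near 600 cm⁻¹, the
  anomeric region, the dominant carbohydrate C–O stretch near 1030 cm⁻¹,
  the water/C=O band near 1645 cm⁻¹, C–H and O–H stretches.
* **Marker clusters**: thirteen groups of ten one-grid-point "lines"
  (unresolved fine structure), each line with its own amplitude jitter.
  Class effects multiply cluster amplitudes: harvest year 2021 modulates
  clusters near 650, 1060, 1094 and 1419 cm⁻¹; each botanical class raises
  one signature cluster (775, 862, 975, 1640 cm⁻¹) plus a mild paired
  effect at 650; Transylvanian origin modulates 600, 650, 710, 810, 872 and
  1180 cm⁻¹ — all inside the marker regions the corresponding real-data
  models report, so marker-recovery tests are meaningful.
* **Nuisances**: per-line mean-one log-normal amplitude jitter (sd 0.05),
  a mean-one log-normal global scatter factor (sd 0.005), a random
  quadratic baseline (coefficient sd 0.0005 a.u.) and i.i.d. Gaussian noise
  (sd 0.001 a.u.).  The log-normals are parameterised with μ = −s²/2 so
  every multiplicative nuisance has expectation exactly one and the
  class-mean spectrum converges to the noise-free template.  An optional
  per-sample, per-factor effect-strength spread (`effect_strength_sd`,
  default 0) lets classes overlap along the discriminant when desired.

One seed drives everything (cohort order is a seeded permutation; the
per-sample draw layout is fixed), so identical configurations give
bit-identical cohorts.  The frozen study preset lives in
`presets/study.yaml`.

**Design rationale for the marker geometry.**  Three failure modes of more
obvious designs motivated the line-cluster structure, and they are worth
recording because they are generic to RMSECV-driven elimination:

1. With a single Gaussian band per marker region (one shared jitter), the
   band's grid points are statistically redundant and backward elimination
   correctly keeps only a minimal subset — "recovering all informative
   points" is then not a property a well-behaved selector should have.
2. A truncated Gaussian's outer points carry ~10⁻³ of the peak signal:
   numerically undetectable no matter the effect size.
3. Botanical effects shared pairwise across classes make the one-vs-rest
   dummy responses non-affine in the class geometry, which keeps the
   4-class RMSECV floor high and the selection basin degenerate; exclusive
   signature clusters restore an (almost) affine class-to-dummy map.

Effect multipliers are deliberately weak per line (log-multipliers ≈ 0.09 to
0.18 against jitter sd 0.05), so that classification is driven by pooling
whole clusters and every line contributes measurably — and paired across
classes with opposite margin imbalance where clusters are shared, so that
the unbalanced design does not turn one factor's bands into proxies for
another factor's labels.

**What the generator does not emulate**: Mie scatter, the nonlinear
water-band response of real ATR spectra, instrument drift, correlated
chemical backgrounds, or any real biochemical covariance between factors.
Passing pipelines on this surrogate shows the machinery is correct and
well-calibrated under the stated noise model; it does not certify the
published accuracies on real honey.

## The three task presets

`run_task` trims to the fingerprint window, drops samples without the task's
label (the geographical model therefore uses the 54 region-labelled
samples), runs the elimination loop, cross-validates the final model on the
selected markers, and writes every artifact: marker list, selection trace,
per-LV CV curve, classification report (confusion matrix, per-class true
positive rates, calibration and cross-validated ROC curves), LV scores, and
a manifest making the run reproducible from config + seed.  On the frozen
preset the surrogate runs reach or exceed the corresponding published
cross-validated figures (checked by `scripts/acceptance.py` and the
acceptance test suite); marker counts land near 40 per task against initial
dimensionality 1246.

## Degenerate inputs and numerical edges

* Constant spectral columns: centred only, never divided by ~0.
* NIPALS on a numerically exhausted Y residual (late components of a
  near-full-rank fit): components that cannot move predictions
  (‖q‖‖t‖ ≤ 1e-8‖Y‖) are accepted silently, a loose fixed point (relative
  change < 1e-6) is accepted with a warning, and anything else raises.
* Selectivity ratios with zero residual map to a 1e12 sentinel rather than
  infinity so ranking stays well-defined.
* Windowing uses a 1e-8 absolute slack on the closed interval so grids
  built as `start + j·spacing` keep their endpoint.
* ROC curves enumerate thresholds at all distinct scores; areas are
  trapezoidal.

## Problem sizes

The shipped presets run the full pipelines (109 × 1246 fingerprint matrix,
ten-fold venetian blinds, ≈ 57 elimination rounds at A_max = 20) in well
under a minute each on one CPU core; the test suite and the acceptance
script are sized accordingly.
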