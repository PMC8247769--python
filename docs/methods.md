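# Methods

`fcdml` implements a complete resting-state fMRI analysis chain built
around functional connectivity density (FCD) mapping and support-vector
modelling: it identifies members of a clinical group from their FCD
maps, and predicts symptom improvement after treatment from FCD change
ratios. Because the kind of clinical fMRI dataset this analysis targets
is not publicly deposited, the package ships a synthetic cohort
generator that plants the statistical structure the analysis assumes,
so every stage can be validated against known ground truth.

## 1. Functional connectivity density

For a preprocessed run, the Pearson correlation is computed between the
time course of every in-mask voxel and every other in-mask voxel. A
connection exists when r exceeds a threshold (default **0.6**), strictly
and for positive correlations only; voxels with zero temporal variance
have no connections. Three per-voxel counts are derived:

* **gFCD** — number of connections to all other voxels (global degree);
* **lFCD** — size (minus one) of the spatially contiguous cluster grown
  from the voxel: 26-connected neighbours are admitted when their
  correlation *with the seed* exceeds the threshold, and growth proceeds
  only through admitted voxels;
* **lrFCD = gFCD − lFCD** — distant connections, non-negative by
  construction because every grown-cluster member is also a global
  connection of the seed.

The subtraction definition guarantees the decomposition identity
`gFCD = lFCD + lrFCD` exactly, at every voxel (a test asserts it). The
local-cluster (region-growing) reading of lFCD follows the original
FCD-mapping formulation; a simpler immediate-neighbour count is
available via `lfcd_mode="neighbors"`. An alternative growth criterion —
admitting a voxel by correlation with any already-admitted voxel rather
than with the seed — exists in the literature; the seed-correlation
reading is used here because it keeps lFCD ≤ gFCD structurally.

Implementation: in-mask series are standardized to unit norm and the
symmetric correlation product is evaluated as a single BLAS rank-k
update (`ssyrk`, float32) when the mask is at desk scale (≤ 9,000
voxels), or in voxel blocks of configurable size otherwise, so the full
N×N matrix need never be materialized. The region growth runs over the
thresholded upper triangle with a compiled (numba) breadth-first loop.
Both paths are verified exactly against brute-force O(N²) oracles.

Raw maps are integer counts; before group statistics they are smoothed
with a masked-normalized Gaussian kernel (default FWHM **6 mm**): the
kernel mass is renormalized within the mask, so a constant map stays
constant and interior counts are conserved to <0.1%. Maps are smoothed,
never time series. Smoothed raw counts (not globally rescaled values)
enter the statistics by default; a standardization step would be easy to
add in front of `voxelwise_ttest` but is deliberately not the default.

## 2. Preprocessing

The chain starts *after* realignment — motion parameters are an input,
never estimated — and is fixed in order:

1. **Discard** the first 5 volumes (pre-steady-state);
2. **Framewise displacement** from the 6 rigid-body parameters. Two
   formulas are provided: `jenkinson` (default) — RMS displacement of
   points in a 50 mm sphere under the frame-to-frame differential rigid
   transform, computed as sqrt(R²/5·tr(AᵀA) + |b|²); and `power` — sum
   of absolute backward differences with rotations scaled by the head
   radius. The voxel-wise RMS family is the default because the cited
   measures are rigid-transform based; both are exposed so the scrubbing
   rule can be audited under either.
3. **Motion QC**: a run is excluded when displacement relative to the
   reference frame strictly exceeds 2 mm translation or 2° rotation on
   any axis ("more than" is read strictly: exactly 2.0 passes).
4. **Nuisance regression**: OLS residuals against an intercept plus 26
   regressors — the 24-parameter motion model [p, p(t−1), p², p(t−1)²]
   and the mean CSF and WM signals. The solve uses the pseudoinverse
   (least-norm under rank deficiency); residuals are orthogonal to every
   confound to 1e−8 relative tolerance, which the float64 processing
   path preserves.
5. **Bandpass** 0.01–0.08 Hz, zero-phase (forward–backward) order-4
   Butterworth: a 0.04 Hz sinusoid is retained at ≥ 99% amplitude,
   0.005 Hz and 0.2 Hz are attenuated below 3%.
6. **Scrubbing** (optional, default on): frames with FD > 0.5 mm are
   removed *before* the FCD correlations are computed. A run is flagged
   (error) when fewer than 100 frames survive.

Regression precedes filtering; scrubbed frames are removed before
correlation. Neither ordering is dictated by the analysis being
emulated, so both are fixed, logged choices.

## 3. Feature selection and models

Voxelwise two-sample pooled-variance t tests (treated − control,
two-sided, df = n₁+n₂−2) select discriminative voxels at **p < 0.005**
(uncorrected); zero-variance voxels get p = 1 by convention.
Suprathreshold voxels are grouped by 26-connectivity, separately for
increases and decreases, and clusters below **20 voxels** are dropped.
Each cluster is summarized for each subject by its mean smoothed FCD
(`cluster-mean` mode; a per-voxel mode exists). Feature selection is
performed on the full sample before cross-validation — replicating the
emulated protocol — and the leakage this introduces is the reason the
classifier's null calibration is checked explicitly on null cohorts
using fixed truth-region features.

**Fisher score** per feature (classification ranking):

FS(i) = [n₁(m₁ᵢ−mᵢ)² + n₂(m₂ᵢ−mᵢ)²] / [n₁σ₁ᵢ² + n₂σ₂ᵢ²]

with group means m₁ᵢ, m₂ᵢ, grand mean mᵢ and *population* (divide-by-n)
group variances — the form consistent with the size-weighted sums; a
sample-variance option exists. The score is invariant to affine
rescaling of a feature. It is used for ranking/reporting, not for
scaling features.

**SVC**: RBF kernel, leave-one-out cross-validation. Per fold, features
are z-scored with training-fold statistics, (C, γ) are selected by inner
cross-validated accuracy on the training fold only (default grid
C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ on powers of 4; ties break toward smaller C,
then smaller γ), and the held-out prediction and signed decision value
are recorded. Accuracy/sensitivity/specificity come from held-out
predictions only; **AUC** is the normalized Mann–Whitney U statistic of
the pooled held-out decision values (ties counted half). Significance:
label permutation with the full LOOCV (including the inner search)
recomputed each round; p = (1 + #{perm ≥ observed}) / (n_perm + 1),
floored at 1/(n_perm+1), 1000 rounds by default.

**SVR**: per-subject change ratios (post − pre)/pre of the selected
cluster features predict the symptom-improvement ratio
(pre − post)/pre (oriented so that improvement is positive; zero
baselines are rejected). ε-SVR with RBF kernel (ε = 0.1), same LOOCV,
standardization and grid-search protocol; performance is the Pearson
correlation between actual and pooled held-out predicted values, with
the same permutation scheme. Feature contributions are reported by a
k-nearest-neighbour mutual-information estimate (k = 3, seeded); MI is
reporting-only — all selected features enter the SVR.

A caveat worth knowing: the pooled-LOOCV correlation is *negatively*
biased under the null (a model that predicts the training-fold mean
anti-correlates with the held-out value), so weakly negative r values
on null data are expected and the permutation test — which shares the
bias — remains calibrated.

## 4. Synthetic cohort generator

The generator emulates a two-group treatment study: `n_group_a = 30`
controls with one session and `n_group_b = 27` treated subjects with
pre- and post-treatment sessions; 255 frames at TR = 2 s; a 24³ grid of
3 mm voxels whose ellipsoidal brain contains ~5,200 analysis voxels
around a CSF/WM core (the core supplies the tissue nuisance signals).
Symptom scores mirror a severity questionnaire: treated baseline
62.9 ± 11.6 (clipped above the diagnostic cutoff 50), controls
29.9 ± 7.2, improvement fraction 0.26 ± 0.12.

FCD is a correlation-count statistic, so effects are planted in
**covariance**, never as mean shifts:

* **Background connectivity** — the mask is partitioned into ~4-voxel
  spatial blobs (Voronoi cells); blobs are scattered at random into
  ~16-voxel *communities* that share one latent signal. Each voxel mixes
  its community latent at weight u: x = u·L + √(1−u²)·ε, giving
  pairwise correlation uᵢuⱼ between community members. The baseline
  weight u₀ = √0.6 puts these correlations exactly at the connection
  threshold, where the edge probability is 1/2 — per-subject counts
  then fluctuate smoothly and symmetrically, which is what makes the
  null voxelwise t test calibrated. Per subject and voxel the weight is
  jittered by N(0, 0.05).
* **Latent spectra** — latents are synthesized with constant-modulus,
  random-phase spectra so each realization carries a *deterministic*
  amount of power into the 0.01–0.08 Hz analysis band. With white-noise
  latents, the χ² fluctuation of band power (~17% sd at ~70 effective
  degrees of freedom) modulated all of a community's edge probabilities
  together and induced strong community-wide dependence of the null
  counts; flat spectra remove that mechanism.
* **Planted effects** — each of the `n_effect_clusters = 3` clusters is
  a *pair* of distant 2-voxel-radius spheres (33 voxels each) sharing
  their own latent, so the group difference lives in local
  (within-sphere) and long-range (cross-sphere) connections alike and
  appears in all three map kinds. The treated group's mean coupling in
  a cluster is shifted by d·σᵤ/2 with alternating sign per cluster
  (increases and decreases): because both edge endpoints shift, the
  standardized between-group difference of the raw voxel counts is
  ≈ d (`effect_size_d`); measured ≈ 0.93–1.24 at nominal 1.2. Smoothing
  raises the voxel-level separation further by averaging the
  independent per-voxel jitter.
* **Treatment linkage** — each treated subject's post-session coupling
  in cluster c moves back toward baseline by scale·z₍s,c₎, where z₍s,c₎
  has exact in-sample correlation `treatment_signal_r` with that
  subject's improvement fraction and independent residuals across
  clusters (a shared rank-1 change factor would let the SVR latch onto
  a single latent and distorts the null).
* **Motion** — drift is a small-increment random walk (≈0.01 mm and
  1e−4 rad per frame, mean FD ≈ 0.02–0.04 mm); spikes are sustained
  translation steps of 0.6–1.0 mm at rate `motion_spike_rate` per
  frame, guaranteed to exceed the 0.5 mm scrubbing threshold under both
  FD formulas, with step directions alternating toward zero so the QC
  excursion limits are never tripped.

What the generator does **not** emulate: hemodynamic response shapes,
1/f and physiological noise spectra, anatomical geometry, spatial
autocorrelation of the noise, scanner drift/spike artifacts in the
data (motion corrupts only the motion traces, not the images), and
multi-site effects. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline machinery* under the
planted statistical structure, not performance on real fMRI.

## 5. Validation design and problem sizes

The test suite validates, at sizes chosen for a single CPU:

* exact brute-force agreement of gFCD/lFCD on 20 structured runs of
  ≤ 500 voxels × 200 frames, and the decomposition identity everywhere;
* null calibration of feature selection on 10 cohorts at full design
  scale (30 vs 27, ~5,200 voxels, 255 frames): pooled voxelwise
  rejection rate at p < 0.005 inside the 99% binomial interval computed
  at the number of *effectively independent* tests (total voxel tests
  / 8 — smoothing and community structure leave ≈ 8-voxel dependence
  units; at the raw voxel count the interval would be narrower than the
  true sampling variability of the rate under exact label
  exchangeability), and a median of 0 extent-thresholded clusters;
* planted-effect recovery at d = 1.2 on 10 full-scale cohorts: ≥ 2/3 of
  planted clusters recovered per map kind with ≥ 95% sign agreement;
* classifier sanity on a 16³ grid (~1,500 voxels): accuracy ≥ 0.9 and
  AUC ≥ 0.95 at d = 2 (30 vs 27); chance-level accuracy and calibrated
  200-round permutation p on 20 null cohorts (15 vs 12; the permutation
  rounds use a fixed singleton hyperparameter setting — calibration of
  the permutation machinery does not depend on the grid size);
* SVR recovery (planted r = 0.7 → pooled-fold r ≥ 0.5 in ≥ 8/10 seeds)
  and null calibration (mean |r| ≤ 0.2, permutation p > 0.05 in ≥ 9/10),
  both with a 40-subject treated group: at the emulated 27 the sampling
  spread of the pooled-LOOCV correlation (E|sample r| ≈ 0.16 under the
  null) saturates the 0.2 bound regardless of calibration;
* preprocessing filter/scrub/regression properties as in §2;
* end-to-end determinism of the bundled demo config (identical result
  checksums across two executions).

`scripts/acceptance.py` recomputes the full analysis once at the
emulated study design (30 vs 27, default generator) with 200
permutation rounds and a compact hyperparameter grid, and writes the
headline quantities (LOOCV accuracy, AUC, sensitivity/specificity,
permutation p values, SVR r, cluster count, motion statistics) to JSON.

## 6. Numerical choices and degenerate inputs

* Correlations in float32 via symmetric BLAS products; strict `>`
  threshold; zero-variance voxels have degree 0.
* Zero pooled variance in the t test → t = 0, p = 1 (never an error);
  both-group zero variance with different means in the Fisher score →
  +inf (flagged as perfectly separating).
* Permutation p values are floored at 1/(n_perm+1) and never 0.
* Grid-search ties break toward smaller C, then smaller γ; inner folds
  are stratified for classification and seeded.
* All randomness flows from one root seed, expanded per stage by
  hashing the stage name into a `SeedSequence`; generated cohorts are
  byte-identical given the same config.
* Constant SVR predictions (e.g. all targets inside the ε-tube) report
  r = 0 rather than NaN.

## 7. Known limitations

* Feature selection on the full sample (the emulated protocol) leaks
  group information into the classifier features; the optional
  `selection: nested` mode is the honest variant, at the price of a
  different feature set per fold. Results from the default mode should
  be read as replication of the protocol, not as unbiased estimates.
* lFCD at real-brain scale requires the in-memory thresholded triangle
  (~N²/2 bytes); above ~9,000 mask voxels only gFCD supports the
  blocked low-memory path.
* The Jenkinson-style FD uses the solid-sphere RMS formula with a fixed
  50 mm radius; it is a scalar per frame, not a per-voxel field.
* The generator's planted effect size is calibrated on the coupling
  scale; the realized count-scale d drifts with frame count and
  threshold (attenuation by edge-sampling noise, amplification by
  smoothing), so `effect_size_d` should be read as approximate at the
  raw voxel level.
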