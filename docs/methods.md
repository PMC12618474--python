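# Methods

This note records the models, the numerical choices, and the design
decisions behind `voltaskgen`, in the order data flows through the
package.

## Connectome construction

The generator's input is the voxel-to-ROI connectome: channel k at voxel v
is Pearson's r between voxel v's rest series and the mean series of ROI k.
"Full correlation" means plain Pearson on the supplied series — the
package assumes preprocessing (motion correction, nuisance cleaning)
happened upstream and applies no detrending or filtering of its own.
ROI signals are unweighted means over hard-label parcels when a label
volume is supplied and weight-normalized means for soft ICA maps; the
hard-label path is the default when both are possible.

Numerical choices:

- Zero-variance series (masked border voxels, constant channels) get a
  correlation of 0 with a `RuntimeWarning`, never NaN, so they cannot
  poison training.
- Long rest acquisitions are split into contiguous, non-overlapping
  segments (e.g. 4×1200 timepoints → eight 600-point segments); a trailing
  remainder shorter than one segment is dropped, keeping segments
  exchangeable. Segment connectomes can be used as separate training
  samples (augmentation) or averaged; training on segments and evaluating
  on the per-subject mean connectome are both supported, and which to use
  is the caller's choice.
- Canonical voxel order everywhere is ascending C-order linear index
  (last axis fastest); all feature matrices and masked vectors are
  reproducible bit for bit. Values outside the gray-matter mask are
  written as 0 in every emitted volume.
- Affines are compared entrywise at 1e-4 when checking grid agreement;
  disagreement raises rather than silently resampling.

## The generator

A volumetric U-Net maps (K, nx, ny, nz) connectomes to (C, nx, ny, nz)
contrast maps. Each encoder/decoder block is one 3D convolution
(3×3×3, stride 1, 'same' zero padding) + batch normalization + ReLU;
2×2×2 max pooling halves the spatial dims per level and trilinear
upsampling restores them; each skip connection passes through an additive
attention gate (skip and gating features projected by 1×1×1 convolutions
to an intermediate channel count — half the skip channels — summed, ReLU,
then a 1-channel sigmoid map that multiplies the skip features). The
output layer is a 1×1×1 convolution whose per-contrast weight/bias slices
are individually extractable and replaceable; everything before it is the
backbone. Defaults: depth 2, 16 base channels doubling per level
(experiments here use 8 to fit desk-scale grids), He initialization.
Inputs not divisible by 2^depth are zero-padded symmetrically and the
output cropped back.

The stack is implemented directly in NumPy with explicit backward passes
(sliding-window views + tensordot for the convolutions), an Adam
optimizer, and seeded initialization. This keeps training bit-reproducible
on one CPU; every layer's analytic gradient is verified against central
finite differences in float64 in the test suite.

## The CR-R loss

For a batch of N subjects with masked MSE d(·,·):

    L_R = (1/N) Σ_i d(x_i, x̂_i)
    L_C = (1/(N²−N)) Σ_{i≠j} d(x_j, x̂_i)
    L   = L_R + α·min(L_R − L_C + λ, 0)     λ = 1, α = 0.25

Choices worth recording:

- d is the *mean* (not sum) of squared errors over in-mask voxels of the
  selected contrast channels, so λ and α are comparable across grid sizes.
- Because d(x_j, x̂_i) ≠ d(x_i, x̂_j), L_C averages over all N(N−1)
  ordered cross pairs.
- The default hinge (`min_as_printed`) adds a *bonus* once the
  cross-subject error exceeds the reconstruction error by the margin λ.
  A `max_hinge` variant — penalizing batches where L_C fails to exceed
  L_R + λ, the standard margin reading — is provided and tested; both
  reduce to plain masked MSE at α = 0, and a single-subject batch falls
  back to L_R.
- The hinge indicator uses strict inequality; at the kink the
  subgradient 0 is taken.
- Out-of-mask voxels and unselected channels receive exactly zero
  gradient.

## Training, fine-tuning, transfer

Training minimizes CR-R with Adam (defaults mirroring the original
protocol: 100 epochs, batch 10, λ = 1, α = 0.25; the learning rate is not
stated there, so the Adam convention 1e-3 is the default). Batches are
reshuffled each epoch from the run seed; a flag can forbid two segments of
the same subject sharing a batch, since L_C would treat them as different
subjects. Model selection keeps the epoch with the lowest validation
masked MSE (plain L_R, not CR-R — reconstruction is what the validation
split is meant to guard, and it keeps selection comparable between
pretraining and fine-tuning). A non-finite loss aborts with a diagnostic
rather than training through NaNs.

Fine-tuning freezes the output layer (its parameters are excluded from the
optimizer; they are bit-identical before and after) and updates only the
backbone, with the loss restricted to the single contrast the target
dataset provides (50 epochs and lr 1e-4 by default). Transfer prediction
clones the fine-tuned backbone and swaps in the pretrained output-layer
slice of the requested contrast; with an unmodified backbone this is the
no-finetune path and reproduces the pretrained model's predictions
exactly.

## Baselines

- **Group average**: voxelwise mean of training maps, emitted for every
  test subject. Because all similarity-matrix rows are then identical,
  its raw and normalized diagonality indices are exactly 0 — an algebraic
  identity the tests assert at 1e-12.
- **Per-ROI linear model**: within each hard-label ROI, each voxel's K
  connectome values (+ intercept — not stated in the original recipe, but
  z-maps should not be forced through the origin; a flag disables it)
  predict its contrast value by OLS, voxels as samples; per-subject
  weights are averaged over training+validation subjects. One connectome
  per subject (mean over segments) is used. Rank-deficient designs fall
  back to the minimum-norm solution with a warning. The bookkeeping
  counts R × S × C fits (50 × 919 × 47 = 2,159,650 at the full study
  size). Features are raw correlations, not standardized.
- **Retest**: second-session maps passed through unchanged as the
  "prediction" of first-session maps, the empirical reliability ceiling.

## Evaluation statistics

The similarity matrix S holds r(predicted_i, actual_j) over in-mask
voxels; its diagonal is the reconstruction performance. The diagonality
index is mean(diag) − mean(off-diag), pooling all N(N−1) off-diagonal
entries in both directions; the normalized form divides by mean(diag) and
is undefined (raised) when that is 0. Fingerprinting is the fraction of
subjects whose diagonal entry is the *strict* row maximum — ties count as
failures (conservative and deterministic). Dice at a top-percentile
threshold compares the top-pct voxel sets (rank-based, k = round(pct·n),
ties at the cut broken by canonical voxel order); Dice AUC integrates the
curve by the trapezoid rule over a configurable grid, by default top 5%
to 50% in steps of 5 (the grid is recorded in every evaluation report),
normalized by the grid span.

## Phenotype harness

Features are either all gray-matter voxel values of a map or the
K(K−1)/2 upper-triangle entries of the ROI connectome. Ridge regression
(or ridge classification for binary targets) runs in 5-fold CV with
alpha = n_features / n_train per fold, so map features (many columns) are
regularized far more than connectome features. Continuous targets are
scored by Pearson r between held-out predictions and truth, binary ones by
balanced accuracy; binary folds are stratified to avoid single-class
training folds (the original protocol is silent on this). Permutation
significance reruns the full CV on shuffled targets and uses the plus-one
estimator p = (1 + #{null ≥ observed})/(P + 1), which can never return 0.
Modality comparisons use a paired t over fold scores with a sign-flip
permutation null (two-sided on |t|), Benjamini–Hochberg FDR across the
comparison family, and Cliff's delta on the two fold-score samples;
zero-variance differences are reported as a no-difference result (t = 0,
p = 1). Comparisons are meant to be run only between modalities that
individually survived permutation testing.

## Synthetic cohorts

The generator emulates the one assumption the whole pipeline rests on —
rest and task activity share a latent architecture — in a controlled
form:

- **Geometry**: an ellipsoidal mask on a 12³ grid (2 mm), K = 6 compact
  parcels from farthest-point seeds, C = 3 contrasts, T = 120 timepoints,
  32 subjects by default: small enough for minutes-scale CPU runs.
- **Rest**: voxel v in parcel k reads its parcel's latent signal plus
  cross-ROI leakage Σ_j ρ_j(v)·C_s[k,j]·s_j(t) and i.i.d. noise
  (SD 0.5). The subject coupling matrix C_s = c·(H f_s)/√F is a linear
  image of a latent fingerprint f_s (F = 4, scale c = 0.8). The spatial
  profiles ρ_j are smooth per-source-ROI fields spanning [−0.5, 2.5]:
  coupling topography varies by connection and flips sign (as
  anticorrelated networks do), which also gives the within-parcel
  connectome K directions of variation so the per-ROI linear readout is
  identifiable — with a single scalar profile the OLS baseline would be
  unidentifiable by construction.
- **Task**: maps are per-ROI affine functions of the subject's *empirical*
  connectome: template_amplitude·(b0 + b·conn_ref) for the template part
  (conn_ref = base-cohort mean connectome) plus
  subject_amplitude·g(b·(conn_s − conn_center)) plus noise (SD 0.3).
  In linear mode g is the identity and, with unit amplitudes, the map is
  exactly b0 + b·conn_s — the per-ROI linear baseline is well-specified
  and recovers it perfectly at zero noise. Nonlinear mode applies
  g(z) = σ_c·tanh(2.5·z/σ_c) to the standardized deviation readout,
  creating the regime where the network demonstrably out-reconstructs the
  linear baseline. Contrast heads share half their variance across
  contrasts, reflecting that task contrasts ride on a common functional
  architecture; this shared structure is what lets backbone adaptation
  learned on one contrast transfer to another.
- **Phenotypes**: y = effect·z(w·f_s) + √(1−effect²)·ε with effect 0.5 by
  default; a binary variant thresholds an independent copy at its median.
- **Transfer cohorts** reuse the same contrast heads, template reference,
  and readout scales while shifting the low-level rest statistics: a
  dataset-level coupling offset with entries ~ N(0, shift²) and rest
  noise inflated by (1 + shift). The deviation readout is centered at the
  generating cohort's own mean connectome — scanner-level mean shifts
  should not propagate into individual activation maps. With shift = 0
  and the base spec, the transfer generator reproduces the base cohort
  bit for bit.

What the generator does *not* emulate: hemodynamics and autocorrelated
BOLD noise, spatial noise correlations, motion and physiological
artifacts, site effects beyond a scalar shift, and realistic ICA map
geometry. Passing tests therefore demonstrate that the machinery recovers
known structure under its own assumptions, not that it will reach any
particular performance on real imaging data.

## Observed behavior at desk scale

With the defaults above (fixed seeds, 60 training epochs, 20/4/8 split),
the qualitative ordering of the predictors matches the motivating study:
the group average reconstructs best but carries exactly zero
discriminability; the network reconstructs markedly better than the
per-ROI linear baseline and keeps a positive normalized diagonality
index; retest scans show the highest discriminability. Fine-tuning on a
shifted cohort recovers reconstruction on the fine-tuned contrast and
improves the held-out contrast's diagonality, while its effect on
held-out reconstruction is mixed — the same trade-off the original
transfer experiments report. The linear-over-group-average ordering on
linearly generated cohorts emerges only in a low-noise regime (the tests
use task-noise SD 0.02 with T = 200): under the default noise the OLS
weight variance of the ill-conditioned within-ROI designs swamps the
subject signal and the group average wins, exactly as it does on real
data. All of these statements are computed, not assumed: each is asserted
by a test or reported by `scripts/acceptance.py`.

## Known limitations

- No GPU path; the NumPy stack targets desk-scale grids (~10⁴ voxels),
  not the 76×93×78 full-resolution grid of real studies.
- Two mask sizes quoted in the motivating study for the linear baseline
  vs the prediction features (157,461 vs 158,680 voxels) derive from
  files not distributable here and remain unreconciled; the package uses
  a single mask throughout.
- Exact feature-map counts, the attention-gate internals, and the
  fingerprinting/Dice-AUC definitions of the original supplementary
  material were not available; the choices above are explicit defaults
  and configurable.
- CIFTI/GIFTI surface formats, surface→volume projection, and fMRI
  preprocessing are out of scope.
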