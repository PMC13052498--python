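# Methods note

This note records what the package computes, the assumptions behind each
stage, the default parameters with their rationale, and the numerical
choices that affect reproducibility.

## Data model and preprocessing

A specimen is a voxel tensor `X ∈ R^{H×W×C}` of co-registered spectral
channel intensities plus binary tissue and tumor masks. All tensors are
min-max normalized to [0, 1] jointly over all channels (`minmax_normalize`);
joint rather than per-channel scaling preserves relative spectral contrast,
which is the discriminative signal. Pathologist annotations arrive as polygon
rings and are rasterized with an even-odd interior test evaluated at integer
pixel centers, with the half-open edge rule so shared edges are never counted
twice. Resizing is bilinear for voxels and nearest-neighbor for masks so
masks remain exactly binary.

Split assignment is grouped by `(patient_id, class)`: all slides of one
diagnostic class from one patient land in the same split, preventing
patient-level leakage; fractions (default 0.6/0.2/0.2) are apportioned per
class by the largest-remainder method over a seeded permutation.

## Pixel gate

Training pixels are sampled per slide (cap 20 000 per class per slide):
normal pixels from non-tumor tissue of every non-atypical slide, follicular/
papillary pixels only from tumor∩tissue of slides of that class. Anaplastic-
like ("atypical") slides never contribute training pixels, matching their
exclusion from the three-class diagnostic task.

The feature chain is: per-channel standardization using training-set
statistics (ε = 1e-8 guard against zero-variance channels) → PCA with up to
8 components (sklearn, full SVD; each loading's sign fixed so its largest
entry is positive, making stored bases run-comparable) → contextual
expansion: each component map contributes itself, Gaussian blurs at σ = 1 and
2 (reflect boundary, truncation 4σ), and the central-difference gradient
magnitude of each blurred map — 5 features per component, 40 for 8
components. A multinomial logistic regression (L2, C = 1.0, lbfgs) yields
per-pixel P(N), P(F), P(P); pixels outside tissue are NaN.

## Regional majority voting

A window of `window_px` (default 64) slides with stride `stride_px` (default
32); an extra flush window covers each border. Windows with fewer than 30
tissue pixels abstain. A window calls a tumor class when ≥ 85% of its tissue
pixels argmax to that class. The slide call is normal when no window fires,
otherwise the called tumor class; if both tumor classes fire, the larger
slide-wide argmax fraction wins (an exact tie resolves to follicular with a
warning). Validation only enforces the stated invariant
`window_px ≥ stride_px > 0`, so smaller windows are valid for smaller images:
the study's 45–64 px windows target full-resolution slides, and the package's
64 px phantom examples use a ratio-matched 24 px window with 12 px stride.

Accuracy uncertainty uses a patient-level bootstrap: patients are resampled
with replacement 2000 times, replicate accuracy is computed over the
aggregated slides, and the interval is the nearest-rank 2.5th/97.5th
percentile pair. With single-slide patients the replicate accuracy is
exactly `Binomial(n, k/n)/n`, giving the closed-form oracle used by the
tests (12/13 correct → lower endpoint 10/13 ≈ 0.769).

## SE-UNet and the hybrid loss

Encoder stages apply paired 3×3 conv + BatchNorm + ReLU, squeeze-and-
excitation in stages with at least `se_min_channels` channels
(GAP → bottleneck(÷`se_reduction`) → ReLU → sigmoid → channel rescale),
spatial dropout (10%), and a strided 3×3 downsampling convolution. The
bottleneck is conv–BN–ReLU, 20% dropout, conv–BN–ReLU. The decoder mirrors
with 2× nearest-neighbor upsampling, skip concatenation and paired
convolutions; a 1×1 convolution with sigmoid emits the tumor probability
map. Reference scale: input 256×256×23, filters (32, 64, 128, 256, 512),
bottleneck 1024, SE from 128 channels, reduction 16. The desk scale used in
tests and examples — (8, 16, 32) filters, bottleneck 48, SE from 16 channels,
reduction 4 on 64×64×8 inputs — is this package's own choice to keep CPU
training in tens of seconds; it preserves the topology (three downsamplings,
SE in the deeper stages) at ~1/40 the parameter count.

The loss is `L = 0.5·wBCE + 0.5·FocalTversky`. The Tversky index
`TI = TP/(TP + 0.7·FN + 0.3·FP)` uses soft (probabilistic) per-image counts;
the focal form is `(1 − TI)^0.75`. The BCE positive weight is
`min(1/prevalence, 5)` with prevalence measured once over the assembled
training masks. Hard counts are used only at evaluation.

Training: Adam (lr 1e-3), shuffled mini-batches, early stopping on the
validation hybrid loss (patience 10 at reference scale, 8 at desk scale)
with best weights *and* BatchNorm running statistics restored. Augmentation
applies one synchronized random draw per instance — flips, ±15° rotation,
[0.90, 1.10] isotropic zoom (bilinear for voxels, nearest for masks, zero
fill) — followed by center crop/pad to the working size and additive
Gaussian noise (σ = 0.001) on voxels only; tumor-containing images yield 4
augmented instances, empty images 1; validation/test data are never
augmented. The operating threshold t* maximizes mean validation Dice over
t ∈ [0.2, 0.9] step 0.05 (ties → smallest t).

Dataset assembly per target is gate-driven: slides the gate called normal or
the target class are retained; masks of non-target tumor classes never enter
(a gate-missed target slide retained via a "normal" call keeps its pathology
mask, since labels come from pathology, not from the gate). Atypical slides
join only when explicitly enabled and gated as the target.

## Channel ablation

Importance of channel c is the drop in split-aggregate (pooled-count)
Dice/IoU on the validation set when channel c is spatially permuted
independently per image (histogram preserved, spatial structure destroyed),
averaged over 3 seeded repeats; zeroing is available as a sanity mode.
Ranking is by ΔDice, ties by ΔIoU, then channel index. The reduced subset is
the sorted union of each model's top-6 channels; retraining on the subset
repeats the entire fitting procedure (gate included) from scratch.

## Phantom generator

The phantom emulates the *statistical* structure the pipeline assumes, not
autofluorescence-decay physics: class mean spectra are Gaussian bumps in
channel-index space over a common baseline (normal at C/4, follicular at
C/2, papillary at 3C/4; amplitude = `signature_separation`, default 4.0;
i.i.d. channel noise σ = 0.5), tissue is a perturbed ellipse on a dark
background, and tumors are thresholded low-pass random fields (at most 3
components) occupying 45–75% of tissue — tumor-dominant, as in resected
nodule sections. The atypical class is a per-pixel random follicular/
papillary mixture with 1.8× noise, mimicking anaplastic heterogeneity. Each
specimen draws from its own `SeedSequence([seed, index])` stream, so cohorts
are reproducible and specimens independent. Limits: no spatial noise
correlation, no decay-curve modeling, no imaging artifacts, no annotation
noise; absolute Dice/accuracy values on phantoms are therefore optimistic
and only ordering/threshold behaviors should be generalized.

## Numerical choices

- All network math is float64 NHWC numpy; convolution is im2col with
  TensorFlow-style 'same' padding; gradients of every layer are analytic and
  finite-difference-verified in `tests/test_nn.py`.
- Both-empty masks score Dice = IoU = 1 (a correct empty prediction is
  perfect); the empty penalty is undefined (error) on an empty region.
- Bootstrap percentiles use the nearest-rank definition
  (`k = ceil(p/100 · n)`), which reproduces the printed 0.769 exactly.
- Probability clipping in BCE uses ε = 1e-7 with zero gradient in the
  clipped region; the focal-Tversky gradient clips `1 − TI` at 1e-12 to
  avoid a singular exponent at perfect overlap.
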