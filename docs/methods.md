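# Methods

`perioeval` implements the quantitative machinery of a two-part evaluation of
resolution-improvement methods for periapical radiographs: (1) an observer
study in which ordinal image-quality ratings of competing upscaling methods
are compared with visual grading characteristics (VGC) analysis, and (2) a
classifier study in which binary periodontal-bone-loss (PBL) detectors built
on differently pre-processed inputs are compared through confusion-matrix
metrics and ROC/PR curves. Because clinical radiographs and human observers
are not distributable, a synthetic-data module emulates both, and the two
published summary fixtures (MOS score counts; confusion matrices) ship as
CSV so the pipelines run end to end offline.

## VGC analysis of ordinal ratings

Observers rate images on a 4-level mean-opinion-score (MOS) scale
(1 = poor, 2 = reasonable, 3 = good, 4 = very high). For a method M and a
rating population, the counts define probabilities P(x) and the top-down
cumulative C(x) = P(score ≥ x), evaluated at x = 4, 3, 2, 1 so that the
last value is exactly 1. The VGC curve for a pair (M_A, M_B) is the
polyline through (0, 0) followed by (C_A(x), C_B(x)) for x = 4…1, and its
AUC is the trapezoidal area. AUC > 0.5 means M_B's ratings stochastically
dominate M_A's.

Two conventions are deliberate and were validated against the published
AUC tables before being frozen:

- **The (0, 0) anchor.** The four cumulative-defined points alone do not
  reach the origin; prepending (0, 0) and applying the trapezoidal rule
  reproduces every published group-level AUC to the printed precision.
- **Group pooling.** Group curves (all experts, all lay observers) pool the
  members' ratings into one count table. This reproduces the published
  expert and lay columns exactly. The published *all-observers* column is
  **not** reproducible this way (pooled counts give, e.g., 0.601 for the
  first pair where 0.544 was printed, while the same pooled counts
  reproduce both group columns); the pooling used for that column is
  undocumented, so this package reports the pooled-count value and makes no
  claim of matching that column.

Consequences used as invariants: self-comparison AUC is exactly 0.5;
AUC(A,B) + AUC(B,A) = 1; moving rating mass of M_B upward never decreases
AUC(A,B).

The paired Wilcoxon signed-rank test (one-sided, H_A: B rated higher than A)
uses (observer, image) pairs as units, drops zero differences, mid-ranks
ties, enumerates the exact null for effective n ≤ 12 and otherwise uses a
tie-corrected normal approximation with continuity correction. Published
p-values depend on per-image score assignments that summary counts do not
determine, so only the test's internal correctness (against exhaustive sign
enumeration) is asserted.

## Resampling

The four interpolation kernels are implemented from first principles as
separable 1-D kernels: nearest (box, radius 0.5, half-open so each sample
has exactly one tap), triangle/bilinear (radius 1), Keys cubic with
a = −0.5 (radius 2), and 3-lobe Lanczos (radius 3). Resizing uses
half-pixel-center mapping `src = (dst + 0.5)·(in/out) − 0.5`,
clamp-to-edge boundaries, and per-output-pixel weight normalization —
the de-facto conventions of mainstream imaging tools. Normalization makes
every kernel a partition of unity, so constant images are exactly invariant
and an equal-size resize is the identity; the test suite checks the
separable pass against a brute-force non-separable evaluation of the same
mapping. Quantization to 8 bits rounds half away from zero and clips to
[0, 255] (a fixed, documented tie-break).

Downscaling (for degradation and for the evaluation protocol) uses exact
area-average integration over pixel-interval overlap. This choice is
neutral: the protocol compares *upscalers*, and using any of the candidate
kernels to downscale would favor its own inverse; area averaging also makes
the integer-factor case an exact block mean.

### SRCNN stage

The trainable stage follows the classical three-step super-resolution CNN
design: bicubic pre-upscale to the target size, then patch extraction
(9×9 filters), nonlinear mapping (1×1), and reconstruction (5×5), with
rectification after the first two stages. The desk-scale default uses
16/8/1 channels. Training minimizes mean squared reconstruction error by
full-batch gradient descent (NumPy forward/backward via im2col; gradients
verified against numerical differentiation), returns the lowest-loss
snapshot, and is deterministic given the seed. Weights start from a
near-identity initialization — center taps wire channel 0 through, plus
N(0, 1e-3) perturbation — so the untrained network approximates the bicubic
baseline and optimization refines from there; learning rate 0.01 for 300
iterations is stable for the default architecture on [0, 1]-normalized
intensities. Problem sizes in the shipped tests (20 pairs of 32×32 patches,
3 held-out 64×64 phantoms) are desk-scale choices that keep the
demonstration light while still showing a PSNR gain over plain bicubic
upscaling. Adversarial super-resolution (SRGAN) appears only as a method
label in rating data; training one is out of scope.

## Image-quality metrics and protocol

MSE, PSNR (10·log10(L²/MSE), L = 255 for the 8-bit images; +∞ for identical
images) and SSIM are computed against the full-resolution reference. SSIM
uses the canonical constants — 11×11 Gaussian window with σ = 1.5,
k1 = 0.01, k2 = 0.03, L = 255, population (Gaussian-weighted) variances —
and averages the local index over fully-interior window positions; the
implementation agrees with scikit-image's Gaussian-weighted SSIM to
~1e-10 and is checked against closed forms (zero-variance case;
sign change under intensity negation). The degrade-then-restore protocol
(default 720 → 128 → 720, both configurable) quantizes restored images to
8 bits before scoring and reports mean ± sample sd per method sorted by
MSE. The published metric table for this protocol was produced from the
clinical images and third-party trained super-resolution models, so its
values are illustrative context, not targets.

## Classifier evaluation

Confusion matrices use PBL as the positive class: sensitivity TP/(FN+TP),
specificity TN/(FP+TN), precision TP/(FP+TP), NPV TN/(FN+TN), accuracy
(TP+TN)/n, each also returned as an exact rational; a zero denominator
yields an explicit *undefined*, never 0. A matrix whose cells do not sum to
its declared n is flagged inconsistent and excluded from reproduction
claims (one of the twelve bundled fixture models is in this state,
kept verbatim).

ROC curves sweep the distinct scores descending with ties grouped, so the
trapezoidal ROC-AUC equals the rank statistic
P(score_pos > score_neg) + ½·P(equal) and is invariant under strictly
monotone score transforms. PR-AUC uses the step convention (precision at
each threshold held over that threshold's recall increment), recorded in
the report metadata since conventions differ.

Dataset preparation: global histogram equalization maps each occupied gray
level to round(255·cdf) (constant images pass through); augmentation
doubles PBL regions with horizontal flips and triples healthy regions with
horizontal + vertical flips, recording provenance; the split holds out
`test_per_class` originals per class untouched, then splits the remaining
originals 80:20 *before* augmentation so a source image and its flips never
straddle partitions. The published augmented-set totals do not factor
cleanly into any per-class op count, so op lists are configurable and the
totals are not asserted. Training the CNN classifiers themselves
(ResNet/Inception-scale transfer learning) is out of scope; the module
consumes confusion or prediction tables, bundled or simulated.

## Synthetic data

- **Phantom.** A stylized periapical scene: bright convex tooth strips,
  darker interproximal gaps, a bright crest band between teeth, and an
  optional radiolucent crestal defect — horizontal (uniform-depth band
  across the gap), vertical (wedge deepest against one tooth), or crater
  (parabolic two-walled trough). Depth is a fraction of crest-band height.
  Rendering is piecewise constant, then Gaussian blur, then additive
  Gaussian noise, then clipping to [0, 255]; with blur and noise off, a
  lesion changes pixels only inside its declared bounding box. Defaults
  (blur σ 1.2 px, noise sd 4 intensity units) produce soft edges and mild
  grain. The phantom makes no attempt at sensor physics, scatter, realistic
  noise spectra, or anatomy — passing tests demonstrate the downstream
  mathematics, not clinical realism.
- **Observer model.** A cumulative-threshold ordered-categorical model:
  latent = method quality + observer bias + N(0, σ) noise; three increasing
  thresholds cut the latent scale into MOS 1–4. This is the simplest model
  with the stochastic-dominance structure VGC assumes. Defaults: six
  methods in the canonical order (nearest < bilinear < bicubic < lanczos <
  srcnn < srgan) spaced 0.3 latent units apart, unit noise, thresholds
  (0, 0.75, 1.5), observer biases N(0, 0.3) in the study wrapper — spacing
  chosen so a 50-observer × 20-image study recovers the full ordering with
  high probability while single-observer tables remain noisy, as in real
  rating data.
- **Classifier simulator.** Scores from two unit-variance normals with
  means 0 and d, squashed by the logistic function into [0, 1]. The squash
  is strictly monotone, so the ROC-AUC keeps the binormal closed form
  Φ(d/√2), which the tests use as the oracle.

All generators are pure functions of (spec, seed) via NumPy's seeded
`default_rng`; fixtures are bit-reproducible.

## Known limitations

- Phantoms are geometric caricatures; results transfer to the method-level
  mathematics, not to clinical image statistics.
- VGC AUC is reported without confidence intervals (none are defined in
  the source analysis; multi-reader variance models are out of scope).
- The SRCNN is desk-scale and CPU-bound; it demonstrates the training and
  inference path, not state-of-the-art restoration quality.
- The all-observers pooling of the published AUC table and the published
  Wilcoxon p-values cannot be reproduced from the available summaries (see
  above); both are documented rather than matched.
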