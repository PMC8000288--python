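# perioeval

Evaluation toolkit for resolution improvement of periapical radiographs.
Periapical (intraoral) X-rays are the standard examination for periodontal
bone loss (PBL), but acquisition limits often leave them at low spatial
resolution, and clinicians routinely upscale them with interpolation-based
zoom. `perioeval` implements the quantitative machinery for judging such
upscaling methods — classical kernels (nearest, bilinear, bicubic, Lanczos)
and a small trainable super-resolution CNN — on two fronts:

1. **Observer study (VGC analysis).** Observers rate method-treated images
   on a 4-level mean opinion score (MOS). For methods M_A, M_B with
   top-down cumulative score distributions C(x) = P(score ≥ x), the visual
   grading characteristics (VGC) curve is the polyline through (0, 0) and
   (C_A(x), C_B(x)) for x = 4, 3, 2, 1; its trapezoidal AUC > 0.5 means
   M_B is rated better. A one-sided paired Wilcoxon signed-rank test
   (exact for n ≤ 12, tie-corrected normal otherwise) accompanies the AUC.
2. **Classifier study.** Binary PBL detectors evaluated from 2×2 confusion
   matrices (sensitivity, specificity, PPV, NPV, accuracy — also as exact
   rationals) and from scored predictions (ROC and precision–recall curves,
   with the ROC-AUC equal to the tie-aware rank statistic).

Around these sit full-reference image-quality metrics (MSE, PSNR, SSIM)
with a degrade-then-restore benchmarking protocol, and a synthetic-data
module (tooth/crest/lesion phantoms, a cumulative-threshold observer
simulator, a binormal classifier simulator) so everything runs without
clinical data. Published rating-count and confusion-matrix fixtures are
bundled as CSV. Intended users: medical-imaging researchers comparing
resampling or super-resolution pipelines, and anyone needing a tested VGC
implementation for ordinal observer data.

## Worked example

Compare the six methods on the bundled observer-study fixture (pooled
expert group, 25 ratings per method; pooled lay group, 85 per method):

```python
import perioeval as pe
from perioeval import datasets

table = datasets.load_study1_ratings()
m = pe.vgc_matrix(table, pairs=list(datasets.METHOD_PAIRS),
                  populations=["experts", "lay", "all"])
print(m.round(3).to_string(index=False))
```

```
method_a method_b  experts   lay   all
 nearest bilinear    0.454 0.652 0.601
 nearest  bicubic    0.479 0.733 0.673
 nearest  lanczos    0.592 0.791 0.746
 nearest    srcnn    0.634 0.830 0.785
 nearest    srgan    0.764 0.839 0.819
bilinear  bicubic    0.535 0.600 0.580
bilinear  lanczos    0.648 0.682 0.668
bilinear    srcnn    0.683 0.733 0.716
bilinear    srgan    0.796 0.748 0.761
 bicubic  lanczos    0.632 0.586 0.594
 bicubic    srcnn    0.675 0.641 0.647
 bicubic    srgan    0.804 0.667 0.702
 lanczos    srcnn    0.556 0.557 0.557
 lanczos    srgan    0.720 0.596 0.627
   srcnn    srgan    0.668 0.545 0.575
```

Each row is one ordered pair: e.g. experts' nearest–bilinear AUC 0.454
(slightly *below* 0.5 — experts tolerated nearest's aliasing more than
bilinear's blur), while bicubic–srgan at 0.804 shows a strong expert
preference for the GAN-upscaled images. The `all` column pools experts and
lay ratings (110 per method).

Classifier metrics from the bundled confusion matrices:

```python
from perioeval.pipeline import run_study2
res = run_study2("reports/study2", confusions=datasets.load_study2_confusions())
print(res["metrics"][["model", "accuracy", "consistent"]].head(3).to_string(index=False))
```

```
model Inception_Bilinear: confusion cells sum to 131, declared n = 104
          model  accuracy  consistent
 ResNet_Nearest  0.653846        True
ResNet_Bilinear  0.730769        True
 ResNet_Bicubic  0.740385        True
```

One fixture matrix (`Inception_Bilinear`) does not sum to its declared
test-set size; it is flagged `consistent = False` and excluded from any
reproduction claim.

A CLI mirrors the library: `perioeval study1|study2|protocol|synth|resize|iqm`
(see `perioeval --help`).

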