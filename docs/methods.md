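# Methods

`molarbovw` classifies panoramic dental radiographs into three
third-molar (wisdom tooth, "R8") complication groups — `R8_Lower`
(lower-jaw molars affected), `R8_Upper_Lower` (upper and lower affected)
and `R8_Null` (no affected molar) — using a classical bag-of-visual-words
(BoVW) pipeline.  This note records the model, its assumptions, the
parameters that matter, and the design decisions taken where the
procedure was genuinely open.

## Pipeline

1. **Grayscale conversion.** 3-channel input is reduced with Rec.601
   luma weights (0.299, 0.587, 0.114), rounded half-up.
2. **Smoothing.** A 3×3 median filter suppresses quantum mottle
   (photon-count speckle), then a bilateral filter (square 9×9 window,
   σ_color = σ_space = 75) removes the remaining noise while preserving
   anatomical edges.  With σ_space = 75 the spatial kernel is nearly
   flat over the 9-pixel window, so the operator behaves almost as an
   intensity-gated box blur: structure with spatial period below roughly
   10 px does not survive this stage.
3. **Edge detection.** Sobel X and Y gradients (cross-correlation with
   the standard 3×3 kernels), each rectified by absolute value and
   clipped to [0, 255], then blended with equal 0.5/0.5 weights into one
   edge image.
4. **ROI masking.** A fixed band — rows [300, 900), columns [490, 2200)
   on a 1200×2400 reference frame, rescaled proportionally for other
   sizes — marks where the four third molars sit.  The mask zeroes the
   exterior without cropping, so keypoint coordinates stay in the
   radiograph's frame.  The band covers 1,026,000 pixels at reference
   size.
5. **Feature extraction.** ORB (32-byte binary descriptors, packed from
   256 bits) or SIFT (128-d) keypoints and descriptors, computed on the
   masked edge image, capped at 500 per image by descending detector
   response.  SURF is part of the method contract (64-d) but has no
   implementation in the installed backend; requesting it raises a
   capability error rather than silently substituting another method.
6. **Vocabulary.** All descriptors pooled over the corpus are clustered
   with K-means (Lloyd's algorithm, k-means++ initialisation, tol 1e-4,
   max 300 iterations, empty clusters re-seeded from the point farthest
   from its assigned center).  The K cluster centers are the visual
   words.  The full-scale operating point is K = 2800; the synthetic
   preset uses K = 200.
7. **Encoding.** Each image becomes the histogram of its descriptors'
   Euclidean-nearest words (ties to the lowest index), L1-normalised by
   default so images with different keypoint counts are comparable.
8. **Classification.** Six classifiers — logistic regression, RBF-kernel
   SVM, an MLP with one hidden layer of 100 ReLU units, decision tree,
   gradient boosting, random forest — are compared under stratified
   10-fold cross-validation with a shared fold assignment (paired
   comparison).  Accuracy is the headline metric; the mean and the
   population standard deviation over the ten folds are reported, plus a
   pooled out-of-fold confusion matrix.

## Numerical conventions

- Every 8-bit conversion rounds half-up (`floor(x + 0.5)`); a single
  documented rule keeps the operators exactly reproducible against
  brute-force oracles.
- All windowed operators pad with reflect-101 (edge pixel not
  duplicated).  This avoids the dark frame a zero pad would create,
  which would otherwise spawn spurious edge keypoints at image borders.
- "Converting gradients to uint8" is implemented as absolute value then
  clip, retaining both edge polarities.
- ORB's binary descriptors are clustered and encoded in real space
  (bytes cast to reals, Euclidean distance) — the same plain K-means is
  applied to every extractor.  This is a known approximation; Hamming
  k-medoids would respect the binary metric but would break the uniform
  treatment.
- Detection runs on the ROI mask's bounding box and keypoints are
  offset back to image coordinates: equivalent under the containment
  contract, ~3× faster, and free of mask-boundary artifacts.
- The ORB corner (FAST) threshold defaults to 0.04 instead of the
  backend's 0.08: the detector input here is a rectified gradient map
  whose dynamic range is a fraction of full scale, so a threshold
  calibrated for natural full-range images finds nothing.
- The backend's SIFT exposes no per-keypoint response score; SIFT
  keypoints carry response 0 and the per-image cap keeps detector order.

## One seed, whole run

A single `global_seed` drives every stochastic stage through
`stage_seed(global_seed, stage_name) = sha256(stage_name)[:4] XOR
global_seed (mod 2^31)`.  Two runs with the same config and inputs
produce byte-identical descriptor files, vocabularies, fold assignments
and JSON reports.

## Vocabulary scope and cross-validation

By default one vocabulary is built from the whole corpus before
cross-validation (the default protocol).  This leaks
information across folds (test descriptors shape the codebook);
`strict_cv=true` rebuilds the vocabulary inside each fold from training
descriptors only.  The default follows the original protocol; the flag
exists because the strict variant is the statistically defensible one.

## The synthetic study

Clinical panoramic radiographs cannot ship with the package, so the
generator produces seeded phantoms carrying the statistical structure
the pipeline needs:

- smooth band-limited background (coarse Gaussian noise upsampled with
  cubic interpolation over a base exposure of ~85 gray levels) plus
  bright mandibular and maxillary arch bands;
- four molar sites at the canonical positions inside the ROI band, with
  small seeded jitter, each always carrying a faint smooth tooth bump;
- class-dependent *affected* molar structure: a tilted ellipse
  (tilt magnitude uniform in 15–45° from vertical, side random) whose
  interior carries a periodic texture at `molar_contrast` (default 60
  gray levels) — cross-hatch striation with 26 px period for lower
  molars, a nodule lattice with 16 px period for upper molars;
- quantum mottle as Poisson noise (variance = intensity) followed by
  additive Gaussian read noise (`noise_sigma`, default 8 gray levels).

Because BoVW discards keypoint positions, the class signal must be
textural, not positional.  The two jaw textures differ in *shape*
(crossing ridges vs. dot lattice), not merely in scale: ORB's pyramid
makes two scaled copies of the same pattern partially indistinguishable,
whereas structurally different patterns populate distinct regions of
descriptor space even after the smoothing chain.  The texture periods
sit above the ~10 px suppression scale of the bilateral stage for the
same reason.  Class semantics follow the clinical grouping: `R8_Null`
renders no affected structure (and consequently yields almost no ROI
keypoints after the edge chain — structureless images are a legitimate,
flagged outcome), `R8_Lower` affects the two lower sites,
`R8_Upper_Lower` all four.

What the phantoms deliberately do **not** model: real anatomy
(overlapping roots, bone trabeculae, sinus and canal shadows),
acquisition physics (beam filtration, fan-angle distortion, positioning
errors), device heterogeneity, and inter-patient variability.  Passing
the end-to-end checks therefore shows that the pipeline recovers a
textural class signal it is designed for — not that it reaches any
particular accuracy on clinical data.

Study conditions for the end-to-end checks: n = 150 phantoms at
1200×2400, balanced classes, generator seed 42, ORB, K = 200, ten
folds.  The image count and vocabulary size are a desk-scale analogue of
the original 447-image, K = 2800 study; K scales with the corpus'
pooled descriptor count (~25k descriptors here).  A seeded label
permutation serves as the negative control and must stay within the
three-class chance band.

## Known limitations

- The half-open ROI convention and the row/column reading of the band
  coordinates are one defensible interpretation; the `roi preview`
  subcommand writes a mask overlay so users can verify on their data.
- Whether features should be extracted from the edge image or from the
  smoothed pre-Sobel image is ambiguous in the underlying procedure;
  the edge image is the default, `use_edge_image=false` switches.
- Unstated classifier hyperparameters are pinned in
  `CLASSIFIER_DEFAULTS`; they are reproducible choices, not tuned
  optima.
- At image scales well below the reference frame the fixed-size
  bilateral window over-smooths relative textures; small-scale phantom
  work should extract from the raw grayscale (`--no-edge`).
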