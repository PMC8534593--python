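# Methods

This note documents the models, numerical choices and limitations behind
`busecho`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The phantom: a stated world, not a simulation

Every stage of the pipeline is exercised on synthetic phantoms that emulate
the first-order appearance of breast-ultrasound B-mode images:

* **Template.** A near-black border outside an elliptical field of view
  (encoded 0 in masks), mid-gray tissue inside it (127), and — for lesional
  classes — a hypoechoic elliptical lesion (255). Defaults: tissue mean 140,
  lesion mean 60 on the 8-bit scale; the generator enforces
  `lesion_mean < background_mean` because breast masses are hypoechoic.
* **Speckle.** Multiplicative unit-mean gamma noise with shape
  `1/speckle_scale²` (default scale 0.25, i.e. a pixelwise coefficient of
  variation of 25%). This is the standard first-order model of fully
  developed speckle; it reproduces the granular texture and
  intensity-dependent variance of ultrasound, nothing more.
* **Margins.** Benign lesions are exact ellipses. Malignant lesions perturb
  the boundary radius by a seeded low-order random Fourier series whose
  maximum deviation equals `boundary_irregularity` (default 0.25–0.45 in
  generated datasets), mimicking spiculated margins geometrically.
* **Geometry.** Dataset lesions draw semi-axes from 28–52 × 20–40 px at
  256×256 (about 5–13% of the frame), reflecting that clinical masses
  occupy an appreciable part of the field of view; centers keep the whole
  perturbed boundary at least 10% of the frame from the edge.

What the phantom deliberately does **not** model: acoustic point-spread
functions, attenuation/shadowing, posterior enhancement, tissue layering,
and operator artifacts. A green test on phantoms therefore establishes that
the pipeline's machinery is correct and well-calibrated on images with the
stated statistical structure — it does not establish clinical performance.
The separate mixture-image generator draws i.i.d. pixels from a known
four-Gaussian intensity mixture and exists purely to test the histogram
fit's parameter recovery.

## Histogram features

The 256-bin normalized intensity histogram is fitted with
`g(b) = Σ_{j=1..4} a_j exp(−(b−m_j)²/(2 s_j²))` by bounded nonlinear least
squares (`scipy.optimize.least_squares`, trust-region reflective), with
`a_j ≥ 0`, `m_j ∈ [0,255]`, `s_j ∈ [0.5, 255]`. The width floor of half an
intensity level prevents degenerate spikes on quantized data. Multi-start:
the first start anchors the means at the 12.5/37.5/62.5/87.5% quantile
positions of the histogram mass with width 10 bins; further starts (default
4 more) are seeded perturbations; the best residual wins and ties keep the
first. Components are returned sorted by mean, making the fit invariant to
initialization order.

Four Gaussians carry 12 parameters but the classification contract is a
fixed-length-4 vector; the default projection is the four sorted means,
which track where the mass of background, tissue and lesion intensity sits
(a lesional image gains a low-mean component near 60). Amplitudes, widths,
or any user-supplied 4-number functional of the model are selectable
alternatives, and the full parameter set stays accessible on the model.

## Eigen-image features

For M images of N² pixels, columns of `A` are the mean-centered image
vectors. Eigenpairs of the pixel covariance `A Aᵀ` (N²×N²) are computed
from the small matrix `AᵀA` (M×M): if `AᵀA v = λ v` then `A v` is an
eigenvector of `A Aᵀ` for the same λ. After centering at most M−1
eigenvalues are nonzero; eigenvectors are unit-normalized, tiny negative
eigenvalues are clipped to zero, vectors in the numerical null space
(squared norm below 1e-10 relative to the leading eigenvalue) are zeroed,
and signs are fixed by making each vector's largest-magnitude entry
positive so results are reproducible across LAPACK builds. Projection of an
image is `Wᵀ(x − μ)` with `W` the top-f eigenvectors; at full rank this
reconstructs training images exactly, and the projected training set's
scatter matrix is the diagonal of retained eigenvalues. The variance image
is the per-pixel mean squared deviation from the mean image.

This path is a companion to the histogram features (both are "the" feature
extractor in different parts of the source material); the classification
pipeline uses the histogram features by default.

## Classifiers

Decision tree, k-NN (k=5), RBF SVM (C=1) and Gaussian naive Bayes are the
scikit-learn estimators with seeded randomness; features are z-scored with
training-set statistics before the scale-sensitive k-NN and SVM. These
hyperparameters are conventional defaults surfaced explicitly in
`ClassifierSpec` — the source material does not record any. SVM scores for
ROC come from softmax-normalized one-vs-rest decision values (monotone in
the margins, which is all a ROC sweep uses).

## The CNNs

No deep-learning framework is assumed: both networks are implemented in
numpy with manual backpropagation (im2col 3×3 same-padding convolution,
batch normalization with running statistics, 2×2 max pooling with
first-maximum tie-break, nearest-neighbor upsampling, dense layer, Adam
with lr 1e-3, He-normal seeded initialization). Checkpoints capture both
trainable weights and batch-norm running statistics. All arithmetic is
float64 and single-threaded-deterministic: identical config and seed give
identical traces and weights.

Layer counting follows the convention that every named layer — including
input and output layers — counts:

* classifier (16 layers, 3 convolutions):
  `input, [conv, batchnorm, relu, maxpool]×3, fullyconnected, softmax,
  classoutput`; softmax output is a 3-class probability simplex.
* segmenter (11 layers, 3 convolutions):
  `input, conv, batchnorm, relu, maxpool, conv, relu, conv, upsample,
  pixelsoftmax, pixeloutput`; the 2-channel output is a per-pixel
  (non-tumor, tumor) softmax on the input grid.

The exact layer-by-layer composition of the original networks is not
recoverable from their description; these lists are a documented
reconstruction satisfying the stated totals, and both are overridable
through `NetConfig`. Training iterations are optimizer steps (the reference
budgets were 3000 and 5000); desk-scale defaults are much smaller and the
tests train at 16–64 px so the whole suite runs in well under a minute of
CNN time. Loss is cross-entropy for both tasks; the segmenter defaults to
inverse-frequency class weights estimated from the training masks because
tumor pixels are rare. Without a validation split, checkpoint selection
scores the full training set in inference mode.

## Morphology and localization

Thresholded probability maps (default threshold 0.5) are refined by
morphological closing with a disk of radius 5 px, then removal of connected
components smaller than 20 px (defaults chosen for the 256×256 grid; both
are config parameters — the source gives no operator sizes). Components use
8-connectivity so counts are reproducible. The lesion report describes the
largest remaining component: centroid (mean pixel coordinate), pixel area,
optional physical area `area × spacing²`, and bounding box. Size is
reported as **area**, not volume: a single 2-D frame carries no depth
information, and pretending otherwise would be dimensionally dishonest.

## Metrics

Sensitivity, precision and accuracy follow their confusion-count
definitions; a zero denominator raises an explicit error instead of
silently reporting 0. Specificity TN/(TN+FP) is provided as a labeled
addition. Multi-class matrices reduce to one-vs-rest counts (TP = diagonal
entry, FN = row remainder, FP = column remainder, TN = the rest). ROC
curves sweep thresholds over unique score values with ties grouped, so the
trapezoidal AUC equals the Mann–Whitney concordance statistic exactly; this
identity, and agreement with scikit-learn's independent implementation, are
asserted in tests. Segmentation is scored per image — the pixels of one
image are the ROC samples, ground-truth tumor pixels positive — and
summarized as the fraction of images with AUC strictly above a cutoff
(default 0.6). Multi-class classifier ROC is computed one-vs-rest per class
and macro-averaged, which is a labeled choice (micro-averaging is equally
defensible).

## Pipelines and reproducibility

A `RunConfig` carries every stage parameter plus one global seed; per-stage
seeds derive from it through `numpy.random.SeedSequence` spawn keys, so no
stage reuses another's stream. Outputs land under
`out_dir/run-<sha256(config)[:12]>/`, which makes mixing artifacts from
different configurations impossible and makes reruns overwrite their own
directory with byte-identical tables (floats are written at fixed
precision). The classification pipeline writes the feature table, per-model
confusion matrices and a five-row comparison table (model, AUC, error,
accuracy); the segmentation pipeline writes per-image AUCs, lesion-report
JSONs and a summary. Normal-class phantoms are excluded from segmentation
training and scoring: per-image ROC is undefined on single-class ground
truth, and such images are skipped with a logged reason wherever they
appear.

## Known limitations

* Phantom realism is first-order only (see above); accuracies on phantoms
  do not transfer to clinical data, and the published headline accuracies
  on the real dataset are out of scope here by design.
* The numpy CNNs are desk-scale: at 256×256 with thousands of iterations
  they are orders of magnitude slower than a GPU framework. They exist to
  make the full pipeline testable and deterministic, not to train clinical
  models.
* The benign-vs-malignant distinction in phantoms rests entirely on
  boundary irregularity, which intensity-histogram features barely see;
  classical-classifier accuracy at desk scale is correspondingly modest.
* The four-Gaussian histogram fit is non-convex; the seeded multi-start is
  deterministic but global optimality is only verified against a coarse
  grid-search oracle at test time.
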