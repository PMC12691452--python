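# Methods

## Problem setting and model

A whole-slide image (WSI) is far too large to classify directly, and
slide-level diagnoses do not localize to individual regions. The package
therefore treats each slide as a *bag* of instance tiles with a single
weak label (multiple-instance learning). The pipeline factorizes as

    F_ij = M(X_ij; Θ)        instance features from a frozen featurizer
    B_i  = A({F_ij}_j)       permutation-invariant aggregation
    ŷ_i  = C(B_i; Φ)         linear classifier with (temperature) softmax
    L(Φ) = (1/N) Σ_i CE(ŷ_i, y_i)

Four aggregators `A` are implemented: mean pooling, element-wise max
pooling, gated-tanh attention pooling (`α = softmax(wᵀ tanh(V F_j))`,
`B = Σ α_j F_j`), and K-TOP pooling — the instances are ranked by the raw
scorer output and only the top K contribute. The scorer is a two-layer
network Linear(d→m) → tanh → Linear(m→1) with biases; with zero biases
on the output layer it is exactly `wᵀ tanh(V F_j + c)`, so the attention
scorer and the "two linear layers with tanh" formulation are one
mechanism. A prediction-level baseline (`score_max`) takes the per-class
maximum over instance logits instead of pooling features.

### K-TOP weighting

Two K-TOP variants are shipped and tested, neither presented as
canonical:

* **renormalized** (default): the selected instances are combined with
  the softmax of their scores restricted to the selection. With K = n
  this is exactly attention pooling, and the scorer parameters remain on
  the gradient path for any K.
* **uniform**: the selected rows are averaged. With K = n this is
  exactly mean pooling. Because the average of a fixed selection is
  locally constant in the scores, this variant passes *no* gradient to
  the scorer; it is an inference-time/ablation mode.

Ties in the ranking are broken toward the lower instance index (stable
sort), making bag outputs deterministic; permutation invariance is
guaranteed only in the no-tie case and is tested as such.

### Temperature calibration

The classifier softmax is `p_i = e^{z_i/τ} / Σ_j e^{z_j/τ}`, stabilized
by max subtraction. τ defaults to 1 everywhere; the calibration sweep
evaluates τ ∈ {0.1, 0.3, 0.5, 1, 2, 5}. Rescaling by τ never changes
the argmax, so accuracy is invariant in τ (asserted exactly); only
probability sharpness — hence calibration and entropy — changes, and
output entropy is non-decreasing in τ. Whether τ should also scale the
*attention* softmax is genuinely open; the package defaults to
classifier-only and exposes `temperature_on_attention` as a config
switch.

## Tiling conventions

Coordinates are 0-based with half-open tile windows, row-major
traversal. Non-overlapping mode (default) uses floor division per axis
and discards partial edge tiles — the only mode consistent with the
961-tile worked example (⌊16000/512⌋² = 31² = 961). An overlap dialect
is provided for tissue continuity: `overlap_grid(..., overlap=50)` steps
by `tile − 50 = 462` pixels and clamps the last origin so the tile fits.
A literal 50-pixel *step* would produce ~90% overlap and ~10⁵ tiles per
slide, contradicting the efficiency goal, so it is not the default.

The brightness filter drops tiles whose mean intensity is strictly
below 25/255; a tile at exactly the threshold is kept. "Mean intensity"
is the unweighted channel mean (the simplest defensible reading; BT.601
luma weights are available via a flag). No bright-background filter is
applied by default; `max_mean` exists as an opt-in. Downscaling uses
Pillow's Lanczos resampling; 512 → 256 is an exact 4× reduction in pixel
count and bytes at equal bit depth. Pillow's decompression-bomb guard is
disabled (`MAX_IMAGE_PIXELS = None`) because gigapixel inputs are the
normal case and tiling is the mitigation.

## Bags and splits

Within a slide, tiles are selected uniformly at random over the
brightness-passing tiles (filtering is the only quantified selection
rule, so filter-then-uniform-sample is the faithful composition). A
slide with fewer than N kept tiles is sampled with replacement and
flagged rather than dropped; a slide with zero kept tiles is excluded
and listed in an exclusion report. Per-slide sampling streams derive
from CRC-32 of the slide id so bags are reproducible across processes.

Splits support ratio mode `(train_fraction, test_fraction)` with the
remainder as validation, exact count mode (e.g. 328/82/103), and
stratified multi-domain partitions. Stratification uses largest-remainder
allocation per class, keeping each part within one WSI of
proportionality; when explicit domain sizes force totals away from the
allocation, a repair step moves the classes that best restore
proportionality. The default domain-size rule is "as equal as possible,
last domain absorbs the remainder" (513 → 128/128/128/129); published
per-domain size and test-count vectors (127/127/127/132 with
25/25/25/28 testing) can be supplied explicitly to reproduce a given
accounting, since no natural remainder rule produces them from 513.

Training augmentations (random rotation ±90°, horizontal/vertical
flips, color jitter ±20%, random crop at 0.7–1.0 scale, Gaussian blur
σ ∈ [0.1, 1]) are implemented with Pillow; the protocol names the
transforms and the strengths are package defaults recorded in
`AugmentConfig`. Evaluation mode is a pure Lanczos resize to the model
input size, and setting all probabilities to zero makes the training
path identical to it.

## The NumPy model and training

No deep-learning framework is used. The featurizer `tiny_cnn` is a
three-block convolutional network (3→8→16→64 channels, valid 3×3
convolutions, ReLU, 2× average pooling, global average pooling; d = 64)
whose weights are drawn once from a fixed seed and frozen. Training
therefore fits the attention/K-TOP scorer and the linear classifier
only — a linear-probe regime with exact analytic gradients, including
through the selected-set softmax of K-TOP (the hard selection is
piecewise constant in the scores). Deep pretrained backbone names
(resnet18/resnet50/vit) are accepted in configs for interoperability
but raise a clear error when instantiated.

Instance features are standardized per dimension with statistics fitted
on the training bags (the raw random-projection features are badly
conditioned: large offsets, small variances). The optimizer is AdamW
(β = 0.9/0.999, decoupled weight decay 10⁻⁴ applied to weight matrices
only) under a one-cycle schedule (linear warmup from peak/25, cosine
anneal to peak/10⁴). The published full-scale recipe (learning rate
2×10⁻⁴, 25 epochs, batch 16, early-stopping patience 10) is the
`TrainConfig` default; the desk-scale linear-probe recipe used in the
synthetic experiments is lr 0.05, 5 epochs, batch 4, warmup 0.1, chosen
for O(1)-scale standardized features and short runs.

Two stability measures address a failure mode of hard top-K selection
trained jointly from scratch (selection lock-in: an arbitrary initial
selection starves the classifier, whose weak gradients cannot redirect
the scorer):

1. the scorer output layer is initialized at zero, so attention starts
   exactly uniform (= mean pooling) and sharpens only as it learns;
2. a soft-to-hard curriculum (`ktop_soft_epochs = 1`): the first epoch
   takes gradients through the full attention softmax (K = n), later
   epochs through the hard selection. Forward/evaluation always uses
   the hard top-K.

The best-validation-accuracy parameters are restored after training;
non-finite loss aborts with a diagnostic; `epochs = 0` returns the
initialized model with an empty report.

## Metrics

Per-class one-vs-rest TP/FP/FN/TN are derived from the confusion matrix
(rows = truth). Precision/recall/F1 are support-weighted by default —
the only averaging under which reported accuracy is algebraically
identical to averaged recall, matching the equal accuracy/recall
columns of the published experiment tables. Balanced accuracy is the
unweighted mean of per-class recalls (binary: (TPR+TNR)/2, the same
number). Specificity is one-vs-rest macro-averaged. Cohen's κ uses the
marginal-product chance agreement; the degenerate Pe = 1 case is defined
as 1 when Po = 1 and 0 otherwise, with a warning. Zero-denominator
classes contribute 0 with a logged note. AUROC/AUPRC are macro
one-vs-rest via scikit-learn (trapezoidal ROC, step-wise average
precision); classes without both positives and negatives are skipped
with a warning, and fewer than two distinct truth classes is an error.
Tests verify AUROC against an exhaustive Mann–Whitney pair-counting
oracle on small binary instances.

## Cross-domain protocol

Leave-one-domain-out: for each domain, a model is trained on the union
of the other domains' bags and evaluated on the held-out domain
(accuracy, balanced accuracy, AUROC, F1 as percentages). Derived
columns: the per-domain *gap* from the best-performing (reference)
domain, whose own entry is "-" and whose maximum equals the accuracy
range; Δ1 from a designated source domain; Δ2 from an externally
supplied best reference accuracy (a study's global best may come from a
different experiment). "Relative difference" is an absolute difference
in percentage points — the only reading consistent with the published
worked values. Consistency labels: a difference of 0–9 points
(boundary inclusive) is "high", above 9 "medium". Summaries report
means with sample (n−1) standard deviations; the gap summary excludes
the reference entry.

## Synthetic cohorts: what they emulate, and what not

Each synthetic slide has a near-white noisy background (mean > 200/255),
informative regions planted on a half-tile cell grid so the realized
informative fraction tracks the request to within one cell, tile-aligned
near-black artifact blocks (intensity < 13, guaranteed to fail the
brightness filter as whole tiles), and a per-domain stain shift — hue
rotation (±18° across domains) plus saturation scaling (0.8–1.2) in HSV
space applied to tissue pixels only. Class texture is an oriented
sinusoidal stripe field: hue, stripe period (64/48/32/24/16 px) and
orientation (0–144°) are parameterized by the label index, making the
five classes separable by simple color/texture statistics. Cohorts are
balanced per class with round-robin domain assignment within class, and
slide dimensions are drawn from a range and floored to tile-size
multiples. Generation is a pure function of the spec (byte-identical
under a fixed seed).

These cohorts exercise the *mechanics* of the pipeline — geometry,
filtering, sampling, aggregation, calibration, splits — and the
dilution phenomenon that motivates top-K selection. They do not emulate
nucleus-level morphology, stain chemistry, scanner optics, tissue-fold
or blur artifacts, or label noise; passing tests therefore demonstrate
correctness of the method's implementation and the expected ordering of
aggregators under sparse planted signal, not clinical performance on
real slides.

## Desk-scale study conditions

The planted-signal experiment uses a 4-domain cohort of 100 slides
(5 per class per domain) at 1024², tiles of 128 downscaled to 64, model
inputs of 32, bags of 50, informative fraction 0.08 (≈4 informative
instances per bag), artifact fraction 0.05, K = 5, 5 epochs, three
cohort seeds. At these sizes a full aggregator comparison runs in about
20 s per seed on one CPU, and the headline assertion — K-TOP test
accuracy ≥ mean pooling's in the median over seeds — is the robust core
of the full-scale ordering (mean < max < attention < K-TOP).

## Known limitations

* The featurizer is frozen and random-weight; end-to-end fine-tuning of
  a deep pretrained backbone is out of scope for this implementation.
* K-TOP uniform weighting cannot train its scorer (no gradient); use
  renormalized weighting for learning.
* Pyramid WSI containers (SVS/NDPI) are not parsed natively; inputs are
  plain PNG/TIFF rasters.
* Multiclass AUROC is one-vs-rest macro only.
* The synthetic stain shift is a global HSV perturbation, not a
  stain-deconvolution-based model.
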