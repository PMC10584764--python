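# Methods

## The detection problem

An inferior vena cava (IVC) filter is a small metallic cage implanted in the
abdominal vena cava to intercept blood clots. Retrievable models carry a
hook at the superior pole for endovascular removal; permanent models do not.
Because metal attenuates X-rays far more strongly than any tissue, a filter
appears on CT as a compact cluster of voxels above roughly +2000 HU —
brighter than cortical bone — but so do surgical clips, intravascular
stents, and spinal fusion hardware. The pipeline therefore separates three
concerns: *finding* metallic objects (pure physics, no learning), *deciding*
which metallic object is a filter (learned appearance), and *typing* a
confirmed filter as retrievable or not (learned morphology).

## Stage 1 — candidate generation

Scanning every axial slice for metal is wasteful; a maximum intensity
projection (MIP) preserves every supra-threshold voxel in a single 2-D
image. The axial MIP (collapsing z) gives each metallic object's (x, y)
footprint; the coronal MIP (collapsing y) gives its (x, z) footprint.
Both are thresholded at +2000 HU (the threshold is inclusive: a pixel at
exactly +2000 is kept) and partitioned into 8-connected components;
components under `min_component_px` (default 4) pixels are discarded as
noise. Each axial component is then paired with the coronal component whose
x interval overlaps it most — x is the axis the two projections share — and
the pair yields a 3-D center, a tight bounding box (x/y extent from the
axial component, z extent from the coronal one), and a fixed-size crop S
(default 64×64×96 voxels, z-elongated because filters are axially
elongated) padded with air (−1024 HU) at volume borders.

Two projections cannot disambiguate objects that overlap in x; ties are
broken by nearest x centroid, then larger component, and axial components
with no coronal partner are dropped with a warning. This rule is this
package's choice; dual-projection triangulation itself does not determine
it. The emitted detection box is the tight thresholded extent, not the
fixed-size crop box: localization stays at candidate granularity (no box
regression), while remaining comparable to a tight ground-truth box under
IoU.

## Stage 2/3 — classifiers

Both stages use the same two architectures, binary softmax classifiers over
the crop S trained by minimizing binary cross-entropy

    H = -(1/N) Σ [ y_i log p(y_i) + (1 - y_i) log(1 - p(y_i)) ]

with Adam (β₁ = 0.9, β₂ = 0.999) at a fixed learning rate, batch size 16,
probabilities clipped at 1e-7 before the logs, and early stopping on
validation loss with best-weights restoration.

* **mip2d** — the crop's axial MIP, z-score normalized, through a
  convolutional backbone, one fully connected layer (width 256), dropout
  0.5, and a 2-node softmax head.
* **recurrent** — a fixed-length sequence of axial slices (even striding:
  slice k of n maps to source index ⌊kZ/n⌋; short crops are padded with an
  ignore mask) through a shared per-slice backbone producing one feature
  vector per slice, then GRU(16) → dropout 0.5 → GRU(8) → 2-node softmax.
  The GRU treats the z axis as the sequence dimension; masked timesteps
  copy the hidden state forward, so the padding value provably never
  influences the output.

The detection stage leaves intensities untouched (HU floor −1024); the type
stage raises everything below 0 HU to 0, discarding air and lung while
keeping metal and the soft tissue around it.

Because no deep-learning framework is part of this package's dependency
set, the layers (3×3 convolution via im2col, 2×2 max pooling, dense,
inverted dropout, masked GRU) and Adam are implemented directly in numpy
(float32) with hand-derived backpropagation, verified against central
finite differences in the test suite. The published configuration's VGG-16
backbone remains a recognized configuration value, but building it raises a
clear error since there is no runtime to host pretrained ImageNet weights;
the `tiny` backbone — three 3×3 conv blocks (8, 16, 16 channels) with 2×2
pooling — is the supported and tested configuration.

### Learning-rate choices

Per-task defaults mirror the reference configuration: 1e-4 for detection,
1e-5 for type classification. The 1e-5 value is a *fine-tuning* rate,
appropriate when nudging pretrained weights; training the tiny backbone
from scratch at 1e-5 would need thousands of epochs, so the phantom studies
(tests and acceptance script) pass 1e-4 explicitly for both tasks. Early
stopping uses patience 5 by default; the type-stage phantom study uses
max_epochs 150 / patience 20: its validation loss improves slowly, and on a
30-sample validation split the per-epoch loss is noisy enough that a short
patience can fire mid-descent — the patience must span the noise. Stopping
is still governed by validation loss, not by the cap.

### Which architecture for which stage

Filter-vs-confounder discrimination is driven by in-plane shape (radial
cage versus blob/ring/rod), which the axial MIP preserves, so the mip2d
model is the economical choice for detection. The retrievable-type hook,
however, sits *above* the cage apex: the axial MIP projects it down onto
the cage where it is nearly invisible (a mip2d type classifier performs
near chance on phantoms), while the slice-sequence model sees the hook as
metal appearing in superior slices where a plain cage has none. The
recurrent model is therefore the type-stage configuration used in the
phantom studies — consistent with the reference results, where the
recurrent variant is also the stronger type classifier.

## Post-processing and pipeline

Per-candidate softmax probabilities are confidences. Detections below the
confidence threshold (default 0.7) are removed; greedy 3-D non-maximum
suppression (IoU threshold 0.5; ties by larger box then lower candidate id)
removes duplicate boxes. An empty final list means "no filter present" — on
a volume with no supra-threshold voxel the classifier is never invoked.
Type classification re-crops each surviving detection (32×32×64 around the
box center) with the 0-HU floor; `top1` mode classifies only the
highest-confidence detection, the configuration used for cohort-level
screening. The pipeline is a pure function of (volume, checkpoints,
config); reruns are byte-identical.

## Evaluation protocol

A detection is a true positive when its IoU with an unmatched ground-truth
box is ≥ 0.5, matching greedily in descending confidence (greedy never
beats optimal bipartite matching; tests verify it against the brute-force
optimum on small cases). Reported detection metrics: recall, precision, F1,
mean TP confidence. Classification metrics come from the standard confusion
rates; the ROC curve sweeps all distinct scores, AUC is trapezoidal (equal
to the pairwise concordance probability, verified in tests), and the
operating cut-off maximizes Youden's J = TPR − FPR on a validation set,
ties resolved toward the lower threshold (higher sensitivity). Metrics with
zero denominators are reported as absent, never coerced to 0 or 1.

## The phantom generator

Phantoms emulate the intensity regimes and shape contrasts the method
depends on, not anatomy: 128×128×160 voxels at 1×1×1 mm; soft-tissue body
of 40 ± 15 HU inside an elliptical air border (−1000 HU); a posterior bone
column at 1100 HU — dense, but below the metal threshold, exercising the
threshold's specificity; additive Gaussian noise (σ = 5 HU); metallic
objects painted at 2200–3000 HU. A filter is a conical cage of 4–8 thin
struts converging to a superior apex (cage radius ~9 voxels, height ~30);
the hooked variant adds a quarter-circle hook of radius 4 voxels rising
above the apex — the *only* voxel-level difference between the classes, an
ablation that makes the type-classification test a pure test of hook
sensitivity. Confounders: clip (compact blob), stent (hollow tube), spinal
rod (long z-aligned cylinder in the bone column). Randomized datasets
jitter placement, size (±25 %), strut count, phase, and HU per sample, and
keep objects disjoint in x so dual-projection triangulation is unambiguous.

What phantoms do **not** model: beam hardening and streak artifacts around
metal, partial-volume blur, anisotropic slice spacing, brand-specific
filter geometry, contrast enhancement, and anatomical clutter. Passing the
phantom studies therefore demonstrates that the pipeline's machinery is
correct and that the learning stages recover the signals the phantoms
contain; it does not certify clinical performance, which in the reference
setting required a curated hospital dataset and a pretrained backbone.

## Problem sizes and numerical choices

The phantom studies use 100 candidates per class for detection, 100 crops
per class for typing (70/15/15 train/validation/test splits), 20 phantoms
for candidate recall, and 10 filter-free volumes for the control cohort —
sizes at which every study runs on a single CPU in minutes. Degenerate
inputs are handled explicitly: constant crops z-score to all zeros (padded
air-only crops occur at volume borders); empty detection lists are valid
pipeline output; single-class training sets and single-class ROC inputs
raise data errors. The label-shuffle control uses a balanced permutation
(agreement with true labels forced near ½, validation labels shuffled too)
because at these sample sizes a raw shuffle can leave most labels in place,
and early stopping against true-labeled validation data would leak the true
concept into model selection.
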