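# Methods

`her2light` implements two lightweight convolutional networks for HER2
scoring of breast-cancer histopathology patches, the training protocol
around them, and the instrumentation (metrics, Grad-CAM, synthetic data)
needed to exercise the whole system at desk scale on a CPU.

## The classification problem

HER2 status is scored from immunohistochemistry (IHC) patches following the
ASCO/CAP factors: the fraction of positive tumour cells, the intensity of
the brown DAB membrane stain, and the completeness of each cell's membrane
ring, yielding the ordinal categories 0, 1+, 2+ (equivocal) and 3+
(positive). Three label groupings are supported: four-class (identity),
three-class (negative = {0, 1+}, borderline = 2+, positive = 3+) and binary
(negative vs positive, 2+ excluded). H&E patches carry no directly visible
HER2 marker, which makes H&E-based scoring the harder modality and the one
that benefits most from pretraining.

## Numerical engine

No GPU deep-learning framework is part of this package's dependency set; the
models run on a small reverse-mode autodiff engine written on numpy
(`her2light.nn`). It supports NHWC convolutions (im2col/col2im, grouped
depthwise variant), valid-padding max pooling, batch normalization, dense
layers, leaky-ReLU/SiLU/sigmoid/softmax activations, dropout, global
average/max pooling, residual adds, broadcast multiplies and concatenation —
enough to express both model families, CBAM attention, squeeze-excitation
blocks and Grad-CAM. Arithmetic is float32. Gradients are verified against
numeric directional derivatives in the test suite, and convolution/pooling
against direct-loop oracles.

Numerical choices:

* **Padding conventions.** Convolutions use "same" padding (output side
  `ceil(in/stride)`), pooling uses "valid" padding
  (`floor((in-k)/stride)+1`). This is the unique pair consistent with the
  published ATHER2 layer table (e.g. 256 -> 86 for a stride-3 conv forces
  same/ceil; 256 -> 254 for a stride-1 3x3 pool forces valid).
* **Batch-norm momentum 0.9, eps 1e-3.** With the short schedules used
  here (tens of epochs, a handful of batches per epoch) a 0.99 momentum
  leaves the moving statistics close to their initialization, making
  inference-mode predictions unrelated to training-mode behaviour;
  0.9 converges within a few dozen steps. A frozen batch-norm layer runs in
  inference mode, so freezing leaves all of its stored values bit-identical.
* **Initialization.** Truncated-normal variance scaling (fan-in), seeded;
  building a model twice with one seed yields identical weights.
* **Loss.** Binary or categorical cross-entropy on clipped probabilities
  (eps 1e-7); the L2 penalty (default 1e-4, kernels only) is applied as
  decoupled weight decay by the optimizer and added to the monitored loss.
* **Dropout** is active only in training mode; inference is deterministic.

## ATHER2

A two-branch CNN (total ~0.35 M parameters) on 512x512 RGB patches: a
common stem (3x3 conv, 16 channels; 2x2/2 max pool), a left branch of
strided 3x3 convolutions with a CBAM attention block after the first
convolution and 10% dropout, a right branch of 3x3 and 5x5 convolutions
with batch normalization, global average pooling on both branches (128
features each), concatenation (256), a 128-unit dense layer, and a 1-unit
sigmoid head for binary or a K-unit softmax head for multiclass tasks.
Leaky-ReLU (slope 0.3, configurable) is used on all conv and hidden dense
layers and L2 regularization on all conv/dense kernels.

The module ships a framework-free shape calculus (`shape_trace`) that
reproduces the published output-size column exactly, and the executed
model's activations match the calculus at every layer (tested).

**CBAM.** The layer table names the attention block without internals; the
canonical formulation is used: channel attention = sigmoid of a shared
two-layer MLP (bottleneck `C/r`, ReLU) applied to the global-average and
global-max pooled descriptors and summed; spatial attention = sigmoid of a
`k x k` convolution over the stacked channel-mean/channel-max maps; applied
channel-first, then spatial, after the L-1 convolution and before its pool.
Defaults `r = 16`, `k = 7`, MLP biases on (all configurable). With these
defaults ATHER2 totals 345,608 parameters versus the printed 345,531
(+0.022%): the printed total implies ~602 attention parameters, which no
canonical CBAM configuration produces exactly, so the total is treated as a
±0.3% contract rather than an equality. Similarly the printed 130
non-trainable parameters exceed the 128 batch-norm moving statistics by an
unexplained 2; the discrepancy is documented rather than forced.

## Block-pruned EfficientNetV2-B0

The EfficientNetV2-B0 backbone (stem; fused-MBConv stages 1-3; MBConv
stages 4-6 with squeeze-excitation at ratio 0.25 of the block input; 1x1
top conv to 1280 channels) is built with the canonical
`block{stage}{letter}_{op}` layer naming, so pruning is data: truncate at a
named stop layer and attach a fresh head. The five catalog entries are
SBN5..SBN1 with stop layers `block5e_add`, `block4c_add`, `block3b_add`,
`block2b_add`, `block1a_project_activation`.

**Head reconstruction.** The published text specifies only "a convolution
filter having a kernel size of 7 and 192 channels ... before the
classification head". The printed parameter table, however, pins the head
exactly: a head of conv 7x7x192 (with bias) -> batch norm -> activation ->
GAP -> dense 1024 -> dense output reproduces every printed subnetwork total
and non-trainable count exactly (SBN1 358,884/480 through SBN5
2,648,424/20,416, with 4-class output dense), and GAP -> batch norm ->
dense 1024 -> dense output reproduces the unpruned model's 7,240,276/63,168.
This reconstruction — in particular the 1024-unit hidden dense layer — is
therefore adopted, and the totals are asserted as exact equalities in the
tests. Blocks' stochastic-depth dropout is omitted (parameter-free, and the
desk-scale schedules are short enough not to need it).

ImageNet checkpoints are not bundled (the package is pure text);
`build_pruneff(..., pretrained=True)` therefore requires an explicit
backbone weights file saved from a previously trained backbone. The
weight-preservation contract of pruning (truncated extractor output equals
the full backbone's activation at the stop layer, bit-exactly) is
independent of where the weights came from and is tested with seeded
random weights.

## Training protocol

Adam; cross-entropy; batch size 24; up to 80 epochs; flips and ±10%
width/height shifts as augmentation; validation accuracy monitored with a
reduce-on-plateau schedule (factor 0.1) and early stopping with
best-weights restoration. Initial learning rate is one of
{6e-2, 6e-3, 6e-4}, larger for freshly initialized networks and smaller for
fine-tuning; the desk-scale experiments in the tests use 6e-3 for fresh
training and 6e-4 for full fine-tuning, which were stable at these cohort
sizes. Patience values are not given in the source description; defaults
are plateau patience 5 and early-stop patience 10 (the desk-scale tests
shorten these to 3/8 to fit their schedules). Early stopping restores the
best-validation weights, not the last ones. The learning-rate trace is a
step function with exact ratio 0.1 at each decrease; the wait counter
resets after a reduction.

Domain-specific pretraining: stage 1 trains the architecture on a related
histopathology source task; stage 2 replaces the classification head
(fresh initialization at the target arity), optionally freezes the first
`n` weighted layers (topological order from the input; the published "6
frozen layers" is interpreted this way, counting CBAM sublayers, since the
layers are not enumerated in the source), and fine-tunes. Feature weights
at the start of stage 2 equal the stage-1 result bit-exactly.

## Metrics

Accuracy, macro precision/recall/F1 (macro chosen as the conservative
average since the published tables do not state the averaging; weighted
averaging is available through the per-class table), AUC (standard binary,
or macro one-vs-rest for K > 2), per-class metrics, confusion matrices and
the Matthews correlation coefficient (multiclass covariance form; zero
denominator -> 0). The binary decision threshold is 0.5.
Accuracy/precision/recall/F1/AUC are reported in percent. The suite is
backed by scikit-learn except MCC, which is authored directly; everything
is cross-checked against brute-force oracles to 1e-12 in the tests.

## Grad-CAM

Weights are the spatial means of the target-class score gradient at the
chosen convolutional layer; the raw map is the ReLU of the
gradient-weighted sum of activation maps, bilinearly upsampled to the input
size and min-max normalized. For the sigmoid binary head the class score
is the pre-sigmoid logit (negated for the negative class) to avoid
saturation. `localization_score` quantifies attention against the
generator's membrane-ring masks: the fraction of heatmap mass inside the
mask, and its enrichment over the mask's area fraction (1 = no better than
uniform). Mid-depth layers (e.g. ATHER2's R-3) localize the ring
structures best in the synthetic study, consistent with the observation
that middle layers carry the stain-structure signal; R-3 is the CLI default
explanation layer.

## Synthetic cohorts

The generator emulates the patient-patch structure of the clinical
datasets: each synthetic patient has one HER2 score, one style offset
(hue rotation within ±0.05, brightness within ±0.08 — drawn once per
patient), and `patches_per_patient` patches. IHC patches place
non-overlapping elliptical blue nuclei on a pale background; a
score-dependent fraction of cells carries a brown ring arc with
score-dependent intensity and completeness. Default class profiles
(fraction, intensity, completeness): score 0 (0.02, 0.05, 0.1), 1+
(0.3, 0.3, 0.4), 2+ (0.5, 0.5, 0.9), 3+ (0.7, 0.9, 1.0) — a qualitative
encoding of the clinical factors, exposed as configuration. H&E patches
carry the class only through nucleus density and size, deliberately
subtler so the pretraining benefit is observable.

What the generator does **not** emulate: real stain variability and
artefacts, tissue architecture, nuclear pleomorphism, scanner effects, or
the intra-class heterogeneity of clinical slides. Passing the synthetic
studies therefore demonstrates that the machinery (architectures, training
loop, transfer workflow, attention maps) behaves correctly and reproduces
the *direction* of the published effects — it says nothing about clinical
accuracy on real slides.

## Desk-scale study sizes

The test suite runs on one CPU, so the synthetic studies are small by
design: the IHC learnability study uses 12 patients x 10 patches at
128x128 with a subject-wise one-third split; the pretraining-direction and
split-leakage studies use 9-12 patients x 8 patches at 96x96 with three
seeds each and medians compared. 96x96 is the smallest input that survives
ATHER2's stride stack. Larger cohorts and the published 512x512 resolution
are supported by the same code paths.

## Known limitations

* CPU-only and float32; training beyond a few thousand small patches is
  slow compared to a GPU framework.
* No bundled ImageNet weights, so the "transfer learning from ImageNet"
  arm can only be exercised with user-supplied backbone checkpoints;
  the domain-specific pretraining arm is fully self-contained.
* Multiclass AUC requires every class present in the evaluation split;
  otherwise AUC is reported as missing with a warning.
* The generator's class signal is far cleaner than clinical data; absolute
  accuracies on it are not comparable to published clinical numbers.
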