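# Methods

## Problem and model

The package targets binary segmentation of the myocardium — the muscular
ring around the left-ventricular cavity in short-axis cardiac MRI — and
the accounting of how much computation that segmentation costs.  The
central model, UwU-Net, is a deliberately shallow U-Net: an input
double-convolution block producing 24 channels, two
max-pool-plus-double-conv encoder stages (24→48→96 channels, so a 224×224
input reaches a 96-channel 56×56 bottleneck), two decoder stages of 2×2
transposed convolution (halving channels), skip concatenation and
double convolution, and a 1×1 output head emitting one logit map.  Every
3×3 convolution carries a bias and is followed by batch normalization and
the activation (ReLU by default, LeakyReLU slope 0.01 as a variant).

Those block conventions are the one reconstruction consistent with three
independently printed totals: with them, the closed forms

    DoubleConv(a→b) = 9ab + 9b² + 6b
    TransposedConv2×2(a→b) = 4ab + b
    OutConv1×1(a→c) = ac + c

give exactly 263,257 parameters for UwU-Net, 467,233 (0.467 M) for the
Small U-Net (same topology, base width 32), and 31,042,369 (31.042 M) for
the classic four-stage U-Net (base width 64).  We therefore treat the
reconstruction as forced and assert those counts exactly, both in closed
form and by enumerating the built model's trainable arrays.  The Small
U-Net's base width of 32 is itself part of this inference: it is the
width that reproduces the printed 0.467 M / 11.02 G under the same
conventions.  The ordering conv→BN→activation is standard U-Net practice
and does not affect any count.

A ResNet18-encoder U-Net is shipped as an *approximate* convenience
builder (residual-18 feature extractor, transposed-conv + double-conv
decoder over the four skip levels, a final upsampling stage back to input
resolution).  The reference decoder for that model is under-determined —
no convention we tried reproduces its published 14.321 M / 8.16 G — so
this builder carries no golden complexity assertions and is excluded from
acceptance checks.

## FLOP accounting

`uwunet.complexity` is pure arithmetic on the spec — nothing is measured
at runtime, so the numbers are hardware-independent and exact.  The
convention, fixed once: one multiply–accumulate costs 2 FLOPs and
convolutions (including transposed convolutions) are counted at the
*output* resolution, `2·K²·C_in·C_out·H_out·W_out`; bias adds cost 1 FLOP
per output element; inference-mode batch norm 2 per element; activations
1 per element; 2×2 max pooling 3 comparisons per output element; skip
concatenation and copies are free.  FLOPs are forward-pass, batch 1.
Under this convention the three reference GFLOP totals at 224×224 come
out at 6.186, 10.971 and 83.614 G — within 1 % of the published 6.24,
11.02 and 83.79 G.  The convolution MAC term alone accounts for >98 % of
every total (a property the test suite asserts), so the convention's
element-wise details are not load-bearing.  No convention we consider
defensible can make the LeakyReLU variant *cheaper* than ReLU, so the
published 6.22 G for that variant is not asserted.

## Metrics, loss, and statistics

IoU = |A∩B|/|A∪B| and Dice = 2|A∩B|/(|A|+|B|) on strictly binary masks,
with the 0/0 case (both masks empty) defined as 1: agreement on absence
is perfect agreement.  Dice = 2·IoU/(1+IoU) always; the suite verifies
this exhaustively over all pairs of 3×3 masks against a set-arithmetic
oracle.  The training loss is 0.5·BCE + 0.5·soft-Dice with smoothing
ε = 1 (the equal weighting is given; ε and the per-image-then-batch-mean
Dice reduction are package choices).  Test-set metrics are per-image
Dice/IoU averaged over images, not pooled pixel counts.  Per-run means
are aggregated as avg/min/max and the sample (n−1) standard deviation;
architectures are compared with a two-sided Welch t-test over per-run
means (the unequal-variance form, since nothing guarantees equal run
variance across architectures).

## Training protocol

Adam (β = 0.9/0.999), learning rate 1e-3 (a round value inside the tuned
range 1e-5…1e-1; the best tuned value is unpublished), batch size 32, at
most 100 epochs by default.  Splits are by **patient**: a 90:10
patient-level train/test partition (test count = max(1, round(0.1·n)),
seeded permutation of the canonically sorted patient list, so the plan is
order-invariant), and a further validation fold of 10 % of the *training*
patients drives early stopping on the validation hybrid loss (patience
10 epochs, min-delta 1e-4, best weights and batch-norm running statistics
restored).  Monitoring a validation fold rather than the test split keeps
the test patients untouched until evaluation.  Augmentation is applied
on the fly each epoch: horizontal flip with probability 0.5 and a
rotation drawn uniformly from ±30°, bilinear for the image, nearest
neighbor plus re-binarization for the mask, zero fill.

Weights are He-normal; the output head's bias starts at −3.0, the logit
of a ~5 % foreground prior.  With a zero-initialized head, the first
epochs are spent learning that the foreground is rare; starting from the
prior roughly halves the epochs to a given Dice on the phantom task.
This is the standard initialization for class-imbalanced dense
prediction and affects no parameter count.  Benchmark runs
use seed base+i for run i (i = 0..9 for the canonical 10-run protocol)
and re-draw the patient split each run, so runs differ in both
initialization and partition.

Everything derives from the config seed — initialization, splits,
shuffling, augmentation draws — and the NumPy backend is single-threaded
deterministic, so a repeated run is bit-identical.

## The NumPy backend

The networks and their training loop are implemented directly on NumPy:
convolution as im2col + GEMM with a hand-derived backward pass for every
layer, verified against float64 central finite differences at ~1e-7
relative error.  Layers keep a channel-major (C, N, H, W) layout
internally, which lets the convolution GEMMs read and write without large
transpose copies (the workloads here are memory-bandwidth-bound); the
public model API is the conventional (N, C, H, W).  Batch norm tracks
running statistics (momentum 0.1) for inference, the standard behavior.
Float32 is the working precision; a module switch to float64 exists for
gradient testing.

## The phantom generator

`uwunet.phantom` emulates the structure of the target cohort — 22
patients, 269 images, patient folders × therapy stage (A/B) × image type
(MAG/PS), 8-bit grayscale PNG with per-modality masks — without any real
data.  Each frame is an elliptical annulus (axis ratio 0.85–1.0) between
a patient-specific inner radius (18–31 px at 224, rescaled
proportionally for other sizes) and outer radius (ring thickness
6.5–13 px), centered near mid-image with ±9 px per-image jitter.
Magnitude images are dark background (0.15), bright cavity (0.75),
mid-gray ring (0.45); phase-contrast images swap cavity and ring levels
and double the noise; both get a 0.7 px edge blur, a random illumination
plane (±0.1 across the image) and Gaussian noise (σ = 0.08), clipped to
[0, 1].  The two modalities of one frame jitter their mask radii
independently by ±1.5 px, emulating separately drawn manual masks while
keeping mask and image geometry consistent within each modality.
Optional papillary-muscle blobs render at ring intensity inside the
cavity and are *excluded* from the mask by default (a config switch
includes them), mirroring the annotation ambiguity around those
structures.  Per-patient geometry persists across a patient's images, so
patient-level splitting genuinely changes what a model sees.  Therapy
stages A and B differ only by random stream, matching the absence of
systematic stage differences in the emulated cohort.  Ring area stays
within 0.5–8 % of pixels — the small-foreground regime that motivates
Dice-centred evaluation.

What the phantom does **not** emulate: MR physics (k-space, coils, flow
encoding, bias fields beyond a linear plane), pathology, anatomical
variability beyond ellipse geometry, or the intensity statistics of the
real scans (which are unpublished; the PS contrast polarity in
particular is a guess).  Passing phantom tests therefore demonstrates
that the pipeline is correct and that the architectures can learn a
small-annulus segmentation task end to end — not that real-data Dice
values are reproduced.  The published real-data figures (e.g. UwU-Net
Dice 0.8780 / IoU 0.7889) depend on external hospital data and
stochastic training and are deliberately not acceptance values here.

## Scaled-down learnability check

The stochastic acceptance check trains UwU-Net on a generated cohort of
12 patients / 200 images at 96×96 (default phantom parameters rescaled),
seeds 0–2, batch 32, learning rate 1e-3, up to 8 epochs with early
stopping (patience 3, best-validation weights restored) — problem sizes
chosen so the whole check runs on a single CPU in minutes — and requires
held-out mean Dice ≥ 0.85 on unseen phantom patients in at least 2 of 3
seeds.  In our runs the model crosses 0.85 around epoch 4–5 and sits
near 0.92 by epoch 8, so the 8-epoch cap is comfortably inside the
≤ 30-epoch envelope the protocol allows.

## Green-AI reporting

A trade-off point is (model, mean Dice, parameters, FLOPs).  A point is
*dominated* on an axis if another point is at least as accurate and
strictly cheaper, or strictly more accurate and at least as cheap; it is
Pareto-efficient otherwise.  The weak form of dominance matters: a model
that matches another's Dice with far fewer parameters should flag the
bigger model as dominated even when the Dice values are exactly equal,
which a strict-on-both-axes definition cannot do.  Efficiency is
evaluated separately for the parameter and FLOP axes, mirroring the
two-panel accuracy-vs-cost reading.

## Grad-CAM

For one image, the explanation score is the sum of output logits over
the predicted foreground (all logits when nothing is predicted).  Its
gradient is taken at a named stage (default: the last decoder
double-conv block, the finest feature map before the output head),
channel-averaged into weights, combined with the stage activations,
rectified, bilinearly upsampled to input size and min–max normalized; an
identically zero map is returned as-is when gradients vanish.  Target
layer and normalization are package choices — the reference work shows
only example visualizations.

## Known limitations

* The backend is CPU-bound NumPy: fine for the scaled-down phantom
  protocol, not for full-resolution 10-run benchmarks of the 31 M
  parameter U-Net; those run, but slowly.
* The ResNet18-U-Net is an approximation without golden numbers.
* Batch-norm statistics are estimated from few batches per epoch at
  phantom scale; evaluation quality early in training trails train-mode
  behavior until the running estimates settle.
* The phantom's realism limits are listed above; no claim about real-MRI
  performance follows from phantom results.
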