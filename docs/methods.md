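# Methods

`pulmorep` implements, at desk scale, a three-module system that turns a
chest-CT lung nodule into a finding sentence: (1) bronchopulmonary-segment
segmentation trained from sparse labels with an edge-smoothing loss, (2)
multi-label nodule-characteristic classification from a dual-resolution
patch pair, and (3) content-constrained sentence generation with a seq2seq
LSTM.  Everything is trainable and testable on built-in synthetic phantoms
and a synthetic sentence grammar; no clinical data is used or emulated
beyond its statistical shape.

## Segmentation from sparse labels

**Problem.** Intersegmental boundaries are invisible on CT, so dense segment
ground truth cannot be drawn reliably.  Supervision instead comes
*localized*: around a reported nodule the segment identity is known (from
the report text plus the annotation coordinate), and nothing is known
elsewhere.  A label map therefore carries segment IDs inside a ball around
the nodule and the sentinel `UNLABELED = -1` everywhere else.

**Losses.** The masked Dice loss scores only labeled voxels: per class
`D_c = 1 − (2Σp_c y_c + ε)/(Σp_c + Σy_c + ε)` with ε = 1e−5, averaged over
the classes present among labeled voxels.  Because boundary supervision is
absent, training adds an *edge loss*

    L_edge = Σ_n Σ_{x∈I_n} |∇h(f(x))|,    h = softmax(·/T),  T = 0.5

the summed Sobel-gradient magnitude of the temperature-softmaxed class
probability field.  `|∇·|` is defined per class as the L2 magnitude of the
three axis-aligned 3D Sobel responses ([1,2,1]⊗[1,2,1]⊗[−1,0,1] and
permutations), summed over classes; any consistent choice preserves the
smoothing intent, and this one keeps the loss a plain sum of per-class
terms.  Sobel borders use replicate padding so spatially constant fields
score exactly zero.  The loss is exposed in the raw-sum form above (that is
what the oracle tests pin down); the training loop uses the per-voxel mean
`L_edge/(N·|I|)` times a weight λ so that λ is independent of crop size.

**Edge-loss weight and scope.** The relative weighting of Dice and edge
terms is a free parameter of the method, and the two gradients are badly
mismatched in scale: the Sobel taps sum to 16 per axis and T = 0.5 doubles
logit sensitivity, so the per-voxel edge gradient is orders of magnitude
larger than the sparse-Dice gradient (which is normalised by small
labeled-region sums).  Sweeping λ over four decades on the phantom study
shows the regularisation profile directly: for λ ≳ 3e−3 the probability
field collapses toward a spatial constant (the degenerate zero of the edge
term) and segmentation fails; around 1e−3 and below the Dice trajectory is
preserved and the penalty acts on boundary fluctuation only.  Two further
choices keep the penalty aimed at its target.  First, during training the
loss is computed on the softmax over *segment* classes with the background
channel excluded: the clinical module operates within lobe regions, where
the class field is segments, and including background makes the penalty
fight the real, sharp lung border.  With background excluded, a uniform
drop of all segment logits at the border leaves the field constant and
unpenalised.  Second, the edge term starts after a 150-step warmup so the
Dice loss can establish the coarse segmentation the penalty is meant to
smooth.  The ablation harness defaults are λ = 1e−3 with that warmup;
`edge_loss_weight`, `edge_on_segment_field` and `edge_loss_warmup_steps`
are all config fields, and the public `edge_loss` op is generic over
whatever class field it is given.

**Network and training.** A small 3D U-Net: three resolution levels, two
(3×3×3 conv → GroupNorm → ReLU) blocks per level, max-pool descents,
nearest-neighbour ascents with skip concatenation, 1×1×1 class head;
desk-scale width 6→12→24 channels.  Three levels matter: with two the
receptive field (~15 voxels) is smaller than the distance from many
interior voxels to any anatomical cue, and the translation-equivariant
network cannot tell segments apart even on training data.  Normalization
matters just as much: without it the network cannot fit even its own
sparse supervision within a 300-step budget.  GroupNorm is used here
rather than batch norm because the batch size is 2, where batch statistics
are degenerate; it is batch-independent and needs no train/eval mode, so
training stays bit-deterministic.  Adam at 1e−3 (×0.1 at half the steps),
batch 2, 300 steps on random 24³ crops guaranteed to contain labeled
voxels; crops are the random-crop augmentation.  The full-scale
configuration of the clinical system (22-conv U-Net, 100,000 steps, 1 mm
resampling of real CT) is expressible through the same config but is not
the test target.

**Inference.** Per-voxel argmax (ties toward the lower class index, the
numpy convention, documented); when a lobe model is supplied its background
prediction masks the segment map.  A nodule box is assigned the set of
segment IDs occupying ≥ 10 % of the box volume; exact match is set
equality with the gold set, partial match non-empty intersection.

## Synthetic phantoms

A phantom is an ellipsoidal lung (≈ −900 HU, Gaussian noise sd 20 HU by
default) in a 0 HU body, partitioned into lobes by smooth low-frequency
surfaces and into segments by planes with a small random tilt, volumes
equalised by quantiles.  Planar segment boundaries are deliberate: the edge
loss exploits the near-linear geometry of real intersegmental planes, and a
curved ground truth would confound the ablation.  Each segment carries a
small bronchial cue: a soft-tissue tube from the hilum toward the segment
centroid with a few sub-branches fanning to the periphery — the minimal
stand-in for the airway tree, giving the network an image cue that ties
position to segment identity, exactly the information the clinical labels
are derived from (segment boundaries themselves remain invisible in
intensity; without such a cue the task is unlearnable for a
translation-equivariant network, since distinct segments are locally
identical).

Nodules render every characteristic with a deterministic rule, all inside
the preprocessing clip window [−1400, 200] HU except calcification, which
saturates at the top of the window as real calcification does: solid core
+50 HU, pure ground-glass −600 HU, part-solid = GGO rim with a solid core;
cavity and air bronchogram carve −900 HU pockets/channels; calcification
+800 HU and fat −100 HU foci; spiculation adds thin radial spikes,
lobulation/irregular-shape/ragged modulate the radial profile with random
angular polynomials of increasing degree; polygonal facets the boundary
with half-spaces; ill-defined margins alpha-blend into the background;
pleural contact renders a soft-tissue bridge to the nearest pleural point
(an error if the centre is farther from the pleura than one diameter);
pleural indentation renders a strand plus an inward notch of the border.
Boxes are 0-based half-open voxel intervals; world units enter only through
the voxel spacing.

What the phantom does **not** model: realistic CT texture, vessels and
airway trees beyond the one cue tube, incomplete fissures, reconstruction
kernels, inter-patient anatomical variability of real lungs.  Passing the
phantom studies therefore shows the machinery works and the losses act as
designed — not that clinical-scale accuracy would be reached.

## Nodule classification

The classifier input is a `PatchPair`: a *wide-area* patch (nodule box
expanded by 15 mm) and an *enlarged* patch (box only), each resampled to a
common grid and stacked along the channel axis, so context and fine
internal/marginal structure are visible simultaneously.  Desk default grid
is 12³ voxels (the full system uses finer grids; the patch size is a config
knob).  Outside-volume regions pad with 0, the normalized value of clipped
air.

The network is a VGG-style stack — desk scale: six 3×3×3 conv + BatchNorm
+ ReLU layers, max-pools after layers 2 and 4, global average pooling to
128 features, linear head to C = 16 logits (three opacity classes + 13
binary findings).  The pooled width is a config knob (`pooled_dim`,
default 128; the full-scale clinical system is described with 128 or 256
depending on the account).  True batch normalization (running statistics,
train/eval modes) is deliberate here: group- or instance-style
normalization subtracts each sample's spatial mean, which *is* the signal
for intensity-shift findings — with it, calcification detection sits at
chance while a max-intensity oracle on the same patches separates the
classes perfectly.  Batch 12 makes BN statistics sound.  AdamW; the desk
schedule is lr 3e−3 with a ×0.1 drop at 70 % of the steps (the full-scale
schedule, 1e−4 over 100,000 steps, is the same shape).  Training applies
the standard augmentation set — isotropic scaling (0.8–1.25) and unsharp
sharpness (amount 0–0.5), identical across the two channels — without
which the network memorizes the 150 desk-scale training nodules instead
of learning the finding features (train AUC 1.0, held-out ~0.6 on
calcification).  Translation jitter was evaluated and measurably hurts
(the nodule-centred geometry is legitimate signal), so it is off by
default.

Training uses the bootstrapping sigmoid cross-entropy for noisy labels:
soft mode blends the target with the prediction, `q = βt + (1−β)p`, hard
mode with the thresholded prediction; the loss is the mean of
`−[q log p + (1−q) log(1−p)]` over determinable classes (gradients flow
through both `p` terms in soft mode, following the original bootstrapping
formulation).  β is not stated in the source method; the default is soft
mode with β = 0.95, the convention of the bootstrapping literature.  β = 1
reduces exactly to plain BCE.  The three opacity classes are trained as
independent sigmoids to keep C = 16 uniform; at evaluation their argmax
resolves the type.

## Description generation

A content set — `<SEG>` and `<SIZE>` placeholders, one opacity token, any
binary finding tokens — is serialised in a fixed canonical order
(placeholders, opacity, then shape/margin/internal/external category
order; the input ordering is otherwise arbitrary and this choice makes
encoding injective).  A single-layer encoder LSTM reads the tokens; a
decoder LSTM with Luong *general* attention (bilinear score, context
concatenated with the decoder state through a tanh layer) emits the
sentence.  Decoding is greedy with a hard length cap, so generation is
deterministic; hidden 128, embedding 64, Adam 5e−3, teacher forcing.
Two details matter at small corpus sizes.  Encoder batches are
right-padded with the final state gathered at each item's true length —
left padding would warm the encoder state with PAD steps that never occur
at generation time, a train/test mismatch that measurably degrades greedy
decoding.  And the attentional layer additionally receives the multi-hot
encoding of the input content set at every step (`set_conditioning`):
attention alone binds content weakly when trained on a few hundred pairs
and then hallucinates plausible-but-absent findings or pads short inputs
to a "typical" finding count; conditioning phrase selection on the
explicit presence bits removes that failure mode.  Luong input feeding is
implemented but off by default (no benefit here).

The corpus is produced by a small English surrogate grammar (the clinical
corpus is Japanese; the system's logic — tokens, adequacy, substitution —
is language-independent, so the grammar is treated as opaque token
sequences).  Each content token has 1–2 surface realizations and sentences
come from two templates; the grammar is invertible (phrase matching
recovers exactly the content set) and decidable (a sentence is grammatical
iff some template + realization choice reproduces it verbatim), which
automates the adequacy and fluency checks that were manual in the clinical
workflow.  Report-side normalization mirrors the editing pipeline:
measurements → `<SIZE>`, anatomy mentions → `<SEG>`, finding variants
canonicalised, all other words dropped but returned as flags, never
silently.

Training enforces combination-disjoint splits (a shared content set across
splits raises).  After the base run the iterative self-augmentation loop
generates sentences for unseen combinations, keeps only those passing both
the adequacy check (inversion equals the input) and the grammar checker,
appends them, and continues training at a reduced rate — the mechanism that
extends compositional coverage beyond the seed corpus.

## Evaluation metrics

AUC is the tie-aware Mann–Whitney probability (equal to the trapezoidal
ROC area in exact arithmetic, better defined under ties).  The Youden
cutoff maximizes sensitivity + specificity − 1 over midpoints of adjacent
distinct scores plus sentinels, ties toward the lowest threshold.
Adequacy counts are set intersections/differences of content tokens.
Observer-test metrics score content against A/B/C/D gold ranks
(must/should/optional/wrong): agreement counts A/B content described by
both readers; per reader TP = described A/B, FN = missed A/B, FP =
described D, C ignored.  Paired study arms are compared with means ± SD and
a two-tailed paired t-test; zero-variance differences are flagged
degenerate rather than given a p-value.  "Partial match" for segment sets
is defined as non-empty intersection — the weakest agreement consistent
with exact ⇒ partial; gold may itself be a set (the ≥ 10 % rule applied to
the dense truth).

## Numerical infrastructure

No deep-learning framework is assumed: `pulmorep.nn` is a compact
reverse-mode autodiff engine over numpy (tape of closures, iterative
topological backward), with 3D convolution as im2col + GEMM (the input
gradient is the convolution with the flipped, channel-transposed kernel —
exact for stride 1, same padding), max pooling (gradient shared among tied
maxima), nearest-neighbour upsampling, and a fused
softmax-Sobel-magnitude edge-loss primitive.  All primitive gradients are
property-tested against central finite differences.  Float32 is used in
training; loss oracles run in float64.  Softmax and softplus use
max-subtraction / |z| splits for overflow safety.  With a fixed BLAS and
thread count every seeded pipeline stage is bit-reproducible; training
logs are compared row-wise in the test suite.

## Problem sizes

The default study conditions are: segmentation — 20 training phantoms
(48³ voxels at 1 mm, 2 lobes × 3 planar segments, nodules of 4–7 mm so the
nodule-box-to-segment proportion matches anatomy, sparse labels from 10 mm
balls), 20 evaluation phantoms, 300 steps, five paired seeds per arm;
classification — 150 training / 50 test nodules with independent
Bernoulli(½) cavity, calcification and spiculation signals, 500 steps,
five seeds per input condition; generation — 500 corpus pairs with
combination-disjoint splits (25 validation / 50 test combinations).  These
are the package's desk-scale choices: large enough for the qualitative
effects (edge-loss benefit, enlarged-input benefit, compositional
round-trip) to be measurable, small enough to run on one CPU.

## Known limitations

* Phantom segment identity is learnable only through the bronchial-cue
  tubes and the lung border; absolute-position ambiguity limits exact-match
  ceilings well below the clinical system's.
* At desk scale the edge loss is protective at best: weights large enough
  to reshape boundaries collapse the probability field, and at the largest
  non-collapsing weight the paired ablation finds nodule-box exact match
  unchanged arm-to-arm (the inequality of interest holds as an equality;
  the paired report flags the degenerate difference).  The boundary-level
  benefit reported for the full-scale clinical system is not reproduced at
  this problem size.
* The grammar's two templates and small lexicon make fluency easier than
  free-text Japanese; the fluency metric measures membership in *this*
  grammar only.
* The observer study itself (human readers) is out of scope; only its
  metrics are implemented, exercised on synthetic fixtures.
* Training at the published full scale (100,000 steps, 22-conv U-Net,
  4,500 nodules) is configurable but untested here.
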