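# pulmorep

Automatic generation of lung-nodule finding descriptions from chest-CT-like
volumes, built as three cooperating components plus the metric suite used to
evaluate them — all runnable end to end on built-in synthetic phantoms, with
no external data.

**Who this is for.** Researchers in medical-image analysis and radiology-NLP
who want a compact, fully inspectable implementation of (a) segmentation
from *sparse* (report-derived) labels with a boundary-smoothing "edge loss",
(b) multi-label nodule-characteristic classification from dual-resolution
patch pairs with a bootstrapping loss for noisy labels, and (c)
content-constrained report-sentence generation with automatic adequacy and
fluency checking.

## The system

Given a CT volume and a nodule box, the pipeline extracts the *contents* of
a finding — the bronchopulmonary segment, the size, and the imaging
characteristics — and realizes them as a sentence:

1. **Segment prediction** (`pulmorep.segnet`).  A 3D U-Net labels each
   voxel with a segment ID.  Training data is sparsely labeled: segment
   identity is known only inside a ball around each reported nodule
   (`pulmorep.phantom.sparsify_labels`).  Because no boundary supervision
   exists, the Dice loss (masked to labeled voxels) is augmented with the
   edge loss

       L_edge = Σ_n Σ_x |∇ h(f(x))|,   h = softmax(·/T),  T = 0.5

   — the summed Sobel-gradient magnitude of the temperature-softmaxed
   class-probability field, which penalizes fluctuating boundaries and
   exploits the near-planar geometry of intersegmental planes.  A nodule
   box is assigned every segment occupying ≥ 10 % of its volume; agreement
   with the gold set is scored as exact (set equality) or partial
   (non-empty intersection).

2. **Characteristic classification** (`pulmorep.classifier`).  A
   VGG-style 3D CNN with global average pooling reads a `PatchPair` — a
   wide-area patch (box + 15 mm margin) and an enlarged patch (box only)
   stacked along the channel axis — and emits 16 sigmoid scores: 3 opacity
   classes (solid / part-solid / pure ground-glass) and 13 binary findings
   (spiculation, lobulation, cavity, calcification, pleural contact, …).
   Training uses the bootstrapping sigmoid cross-entropy
   `−[q log p + (1−q) log(1−p)]` with `q = βt + (1−β)p` (soft mode), which
   tolerates noisy ground truth; β = 1 is exactly plain BCE.

3. **Description generation** (`pulmorep.textgen`).  A seq2seq LSTM with
   Luong general attention maps the canonically ordered content tokens to a
   sentence containing `<SEG>`/`<SIZE>` placeholders, substituted with the
   segment name and measurement afterwards.  An iterative self-augmentation
   loop generates sentences for unseen content combinations, keeps those
   passing the adequacy check (the sentence inverts to exactly its input
   content set) and the fluency check (grammar membership), and retrains.

`pulmorep.phantom` builds the study data: lungs partitioned into lobes and
planar segments with per-segment bronchial cue tubes, nodules rendered
deterministically from their finding vector, sparse labels, and an
invertible English sentence grammar (`pulmorep.grammar`).
`pulmorep.evaluation` implements segment match rates, Mann–Whitney AUC,
Youden cutoffs, adequacy TP/FP/FN, observer-test A/B/C/D content metrics
and paired t-tests.  `pulmorep.nn` is a small numpy autodiff engine that
powers all three models.

## Worked example

`examples/02_edge_loss.py` shows the edge loss doing its job — same two
regions, rougher boundary, higher penalty:

    constant field        : edge loss =      0.00  (exactly 0)
    flat planar boundary  : edge loss =  16383.80
    corrugated boundary   : edge loss =  22233.15

`examples/05_generate_descriptions.py` trains the generator on a small
corpus and realizes held-out content combinations:

    input : ['<SEG>', '<SIZE>', 'cavity', 'irregular_edge', 'part_solid',
             'pleural_indentation']
    output: in right S3 , a 11 mm part-solid nodule showing an irregular
            edge , an internal cavity and pleural indentation is noted .
            adequacy TP=6 FP=0 FN=0, grammatical=True

TP/FP/FN count content tokens recovered from the sentence against the
input; a fully adequate sentence has FN = FP = 0, and fluency is membership
in the generating grammar.  The remaining examples cover phantom
construction, sparse labels, segment assignment, classifier AUCs and the
observer-test metrics.

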