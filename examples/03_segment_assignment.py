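"""Train the segment model from sparse labels (small budget) and assign
segments to a nodule box with the >=10 %-of-box-volume rule.

A short demonstration run: a handful of phantoms and few training steps, so
the match rates printed here are below what the full desk-scale study
(scripts/acceptance.py, tests) reaches — the point is the workflow: sparse
supervision in, full segment map out, set-valued nodule assignment compared
against the dense ground truth.
"""

from pulmorep.evaluation import segment_match
from pulmorep.experiments import make_segmentation_cases
from pulmorep.segnet import (
    SegTrainConfig,
    predict_segments,
    segments_of_nodule,
    train_segmenter,
)

train_cases = make_segmentation_cases(8, seed=11)
eval_cases = make_segmentation_cases(4, seed=12)

config = SegTrainConfig(
    n_classes=7, base_channels=4, levels=3, steps=120,
    edge_loss_enabled=True, seed=0,
)
trained = train_segmenter([(c.volume, c.sparse) for c in train_cases], config)
print(f"trained {config.steps} steps; dice loss "
      f"{trained.log.dice_loss.iloc[0]:.3f} -> {trained.log.dice_loss.iloc[-1]:.3f}, "
      f"edge loss {trained.log.edge_loss.iloc[0]:.0f} -> {trained.log.edge_loss.iloc[-1]:.0f}")

for i, case in enumerate(eval_cases):
    _, pred = predict_segments(None, trained, case.volume)
    ids = segments_of_nodule(pred, case.box, frac=0.10)
    m = segment_match(ids, case.gold)
    print(f"case {i}: predicted segments {sorted(ids)} vs gold {sorted(case.gold)}"
          f"  exact={m['exact']} partial={m['partial']}")
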