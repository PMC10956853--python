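"""Train the dual-resolution nodule classifier on synthetic nodules and
report per-class AUC on held-out cases.

Nodules carry independent cavity / calcification / spiculation signals; the
classifier reads the wide-area + enlarged patch pair.  A short budget keeps
this quick; the full 150/50, 500-step study lives in the acceptance script.
"""

import numpy as np

from pulmorep.classifier import ClsTrainConfig, predict_findings, train_classifier
from pulmorep.evaluation import auc, youden_cutoff
from pulmorep.experiments import make_classification_cases
from pulmorep.findings import CLASS_NAMES

train_cases = make_classification_cases(100, seed=1)
test_cases = make_classification_cases(40, seed=2)

trained = train_classifier(train_cases, ClsTrainConfig(steps=400, seed=0))
print(f"loss {trained.log.loss.iloc[0]:.3f} -> {trained.log.loss.iloc[-1]:.3f} "
      f"over {len(trained.log)} steps (bootstrapping BCE, beta=0.95 soft)")

scores = predict_findings(trained, np.stack([p.stacked() for p, _ in test_cases]))
for name in ("cavity", "calcification", "spiculated"):
    k = CLASS_NAMES.index(name)
    y = np.array([int(getattr(fv, name)) for _, fv in test_cases])
    a = auc(scores[:, k], y)
    t = youden_cutoff(scores[:, k], y)
    print(f"{name:14s}: AUC {a:.3f}, Youden cutoff {t:.3f} "
          f"({y.sum()} positives of {len(y)})")
print("\nAUC is the probability a positive nodule outscores a negative one;")
print("the Youden cutoff is the operating threshold maximizing sens+spec-1.")
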