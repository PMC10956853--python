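"""Observer-test metrics on a toy reading session.

Gold content is ranked A (must describe), B (should), C (optional), D
(wrong).  Between two readers we count agreed A/B content; per reader we
accumulate TP (described A/B), FN (missed A/B) and FP (described D), and
compare paired per-case metrics with a two-tailed paired t-test.
"""

from pulmorep.evaluation import content_agreement, observer_counts, paired_comparison

cases = [
    {
        "gold": {"segment": "A", "size": "A", "spiculated": "B",
                 "cavity": "C", "fat": "D"},
        "reader1_draft": {"segment", "size", "spiculated"},
        "reader1_scratch": {"segment", "spiculated", "fat"},
        "reader2_draft": {"segment", "size", "spiculated", "cavity"},
        "reader2_scratch": {"segment", "size"},
    },
    {
        "gold": {"segment": "A", "size": "A", "pleural_contact": "B",
                 "calcification": "D"},
        "reader1_draft": {"segment", "size", "pleural_contact"},
        "reader1_scratch": {"segment", "size"},
        "reader2_draft": {"segment", "size", "pleural_contact"},
        "reader2_scratch": {"segment", "pleural_contact", "calcification"},
    },
]

for setting in ("draft", "scratch"):
    agreements, tps = [], []
    for case in cases:
        agreements.append(content_agreement(
            case[f"reader1_{setting}"], case[f"reader2_{setting}"], case["gold"]))
        tp, fn, fp = observer_counts(case[f"reader1_{setting}"], case["gold"])
        tps.append(tp)
    print(f"{setting:8s}: agreed A/B contents per case {agreements}, reader-1 TP {tps}")

draft_tp = [observer_counts(c["reader1_draft"], c["gold"])[0] for c in cases]
scratch_tp = [observer_counts(c["reader1_scratch"], c["gold"])[0] for c in cases]
rep = paired_comparison(draft_tp, scratch_tp)
print(f"\nreader-1 TP, draft vs scratch: {rep.mean_w:.1f}±{rep.sd_w:.1f} vs "
      f"{rep.mean_wo:.1f}±{rep.sd_wo:.1f}"
      + ("  (degenerate: zero-variance differences)" if rep.degenerate
         else f", paired t p={rep.p_two_tailed:.3f}"))
print("with only two toy cases this is illustrative, not inferential.")
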