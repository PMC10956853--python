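"""Evaluation metrics for segment prediction, nodule classification,
description generation, and the observer performance test.

Conventions:

* Segment agreement compares *sets* of segment IDs (a nodule box may span
  several segments under the ≥10 %-of-box-volume rule): exact match is set
  equality, partial match is non-empty intersection, so exact ⇒ partial.
* AUC is the tie-aware Mann–Whitney probability P(s⁺ > s⁻) + ½ P(tie); the
  Youden cutoff maximizes sensitivity + specificity − 1 over midpoints of
  adjacent distinct scores (plus sentinels below/above all scores), ties
  broken toward the lowest threshold.
* Generation adequacy counts content tokens: TP = input ∩ extracted,
  FP = extracted − input, FN = input − extracted.
* Observer-test metrics score described content against an A/B/C/D gold
  ranking (must / should / may be described / wrong): TP and FN accumulate
  A/B content, FP accumulates D content, C content is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "segment_match",
    "auc",
    "youden_cutoff",
    "adequacy_counts",
    "content_agreement",
    "observer_counts",
    "paired_comparison",
    "PairedReport",
]

RANKS = ("A", "B", "C", "D")


def segment_match(pred: set[int], gold: set[int]) -> dict[str, bool]:
    """Exact (set equality) and partial (non-empty intersection) agreement."""
    if not gold:
        raise ValueError("gold segment set is empty")
    pred = set(pred)
    gold = set(gold)
    exact = pred == gold
    return {"exact": exact, "partial": exact or bool(pred & gold)}


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if len(classes) < 2:
        raise ValueError("both classes must be present")


def auc(scores: Iterable[float], labels: Iterable[int]) -> float:
    """Area under the ROC curve (tie-aware Mann–Whitney form)."""
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels))
    _check_binary(labels)
    return float(roc_auc_score(labels, scores))


def youden_cutoff(scores: Iterable[float], labels: Iterable[int]) -> float:
    """Threshold maximizing the Youden index J = sensitivity + specificity − 1.

    A case is called positive when score > threshold.  Candidates are the
    midpoints between adjacent distinct scores plus sentinels below the
    minimum and above the maximum; ties in J are broken toward the lowest
    threshold.
    """
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels))
    _check_binary(labels)
    uniq = np.unique(scores)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best_t, best_j = None, -np.inf
    for t in cands:  # low to high; strict > keeps the first (lowest) maximizer
        called = scores > t
        sens = (called & (labels == 1)).sum() / n_pos
        spec = (~called & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def adequacy_counts(
    input_contents: frozenset | set, extracted: frozenset | set
) -> tuple[int, int, int]:
    """(TP, FP, FN) agreement between input and extracted content sets."""
    input_contents = set(input_contents)
    extracted = set(extracted)
    tp = len(input_contents & extracted)
    fp = len(extracted - input_contents)
    fn = len(input_contents - extracted)
    return tp, fp, fn


def _check_ranked(contents: Iterable[str], gold: Mapping[str, str]) -> None:
    missing = set(contents) - set(gold)
    if missing:
        raise KeyError(f"contents absent from the gold ranking: {sorted(missing)}")
    bad = {c: r for c, r in gold.items() if r not in RANKS}
    if bad:
        raise ValueError(f"invalid ranks (expected A/B/C/D): {bad}")


def content_agreement(
    contents_r1: frozenset | set, contents_r2: frozenset | set, gold: Mapping[str, str]
) -> int:
    """Number of A/B-ranked contents described by both observers."""
    shared = set(contents_r1) & set(contents_r2)
    _check_ranked(set(contents_r1) | set(contents_r2), gold)
    return sum(1 for c in shared if gold[c] in ("A", "B"))


def observer_counts(
    described: frozenset | set, gold: Mapping[str, str]
) -> tuple[int, int, int]:
    """(TP, FN, FP) for one observer's description against the gold ranking.

    TP: described A/B content; FN: A/B content not described; FP: described
    D content.  C content affects no count.
    """
    described = set(described)
    _check_ranked(described, gold)
    ab = {c for c, r in gold.items() if r in ("A", "B")}
    tp = len(described & ab)
    fn = len(ab - described)
    fp = sum(1 for c in described if gold[c] == "D")
    return tp, fn, fp


@dataclass(frozen=True)
class PairedReport:
    mean_w: float
    mean_wo: float
    sd_w: float
    sd_wo: float
    t_statistic: float
    p_two_tailed: float
    degenerate: bool = False  # zero variance of the paired differences


def paired_comparison(
    per_case_metric_w: Iterable[float], per_case_metric_wo: Iterable[float]
) -> PairedReport:
    """Means ± SD of two paired per-case metrics plus a two-tailed paired
    t-test.  Zero variance of the differences makes t/p undefined; the
    report is then flagged `degenerate` with NaN statistics."""
    a = np.asarray(list(per_case_metric_w), dtype=float)
    b = np.asarray(list(per_case_metric_wo), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 paired cases")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return PairedReport(
            float(a.mean()), float(b.mean()), float(a.std(ddof=1)), float(b.std(ddof=1)),
            float("nan"), float("nan"), degenerate=True,
        )
    t, p = stats.ttest_rel(a, b)
    return PairedReport(
        float(a.mean()), float(b.mean()), float(a.std(ddof=1)), float(b.std(ddof=1)),
        float(t), float(p),
    )
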