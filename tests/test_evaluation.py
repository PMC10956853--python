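"""Metric fixtures: hand-computed values and exhaustive oracles."""

import numpy as np
import pytest
from scipy import stats

from pulmorep.evaluation import (
    adequacy_counts,
    auc,
    content_agreement,
    observer_counts,
    paired_comparison,
    segment_match,
    youden_cutoff,
)


def auc_pairwise_oracle(scores, labels):
    """P(score+ > score-) + 0.5 P(tie) over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_scan_oracle(scores, labels):
    """Exhaustive scan over the same candidate set, first maximizer wins."""
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best_t, best_j = None, -np.inf
    for t in cands:
        called = scores > t
        j = (called & (labels == 1)).sum() / (labels == 1).sum() + (
            ~called & (labels == 0)
        ).sum() / (labels == 0).sum() - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t


class TestSegmentMatch:
    @pytest.mark.parametrize(
        "pred,gold,exact,partial",
        [
            ({3}, {3}, True, True),
            ({2, 5}, {5}, False, True),
            ({1}, {4}, False, False),
            ({2, 5}, {2, 5}, True, True),
            (set(), {1}, False, False),
        ],
    )
    def test_cases(self, pred, gold, exact, partial):
        m = segment_match(pred, gold)
        assert m == {"exact": exact, "partial": partial}

    def test_exact_implies_partial_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = set(rng.integers(1, 6, size=rng.integers(0, 4)).tolist())
            gold = set(rng.integers(1, 6, size=rng.integers(1, 4)).tolist())
            m = segment_match(pred, gold)
            assert not m["exact"] or m["partial"]

    def test_empty_gold_errors(self):
        with pytest.raises(ValueError):
            segment_match({1}, set())


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_four_point_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.random(n), 2)  # rounding creates ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12
            )

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(2)
        scores = rng.permutation(20) / 20.0
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestYoudenCutoff:
    def test_perfect_separation_gap_midpoint(self):
        t = youden_cutoff([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.45)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert youden_cutoff(scores, labels) == pytest.approx(
                youden_scan_oracle(scores, labels)
            )

    def test_all_tied_returns_lowest_candidate(self):
        t = youden_cutoff([0.4, 0.4, 0.4], [0, 1, 0])
        assert t == pytest.approx(-0.6)  # the below-minimum sentinel


class TestAdequacyCounts:
    def test_identical_sets(self):
        s = frozenset({"a", "b", "c", "d", "e"})
        assert adequacy_counts(s, s) == (5, 0, 0)

    def test_foreign_token_is_fp(self):
        assert adequacy_counts({"a", "b"}, {"a", "b", "x"}) == (2, 1, 0)

    def test_missing_token_is_fn(self):
        assert adequacy_counts({"a", "b"}, {"a"}) == (1, 0, 1)

    def test_conservation_property(self):
        rng = np.random.default_rng(4)
        universe = list("abcdefgh")
        for _ in range(50):
            inp = frozenset(rng.choice(universe, rng.integers(0, 8), replace=False))
            ext = frozenset(rng.choice(universe, rng.integers(0, 8), replace=False))
            tp, fp, fn = adequacy_counts(inp, ext)
            assert tp + fn == len(inp) and tp + fp == len(ext)


class TestObserverMetrics:
    GOLD = {"a1": "A", "a2": "A", "b": "B", "c": "C", "d": "D"}

    def test_agreement_hand_count(self):
        # observers overlap on {a1, b, c}: two of the shared are A/B-ranked
        r1 = {"a1", "a2", "b", "c"}
        r2 = {"a1", "b", "c", "d"}
        assert content_agreement(r1, r2, self.GOLD) == 2

    def test_agreement_all_shared_rank_c(self):
        assert content_agreement({"c"}, {"c"}, self.GOLD) == 0

    def test_agreement_same_three_a_ranks(self):
        gold = {"x": "A", "y": "A", "z": "A"}
        assert content_agreement({"x", "y", "z"}, {"x", "y", "z"}, gold) == 3

    def test_observer_counts_hand_case(self):
        gold = {"a": "A", "b": "B", "c": "C", "d": "D"}
        assert observer_counts({"a", "c", "d"}, gold) == (1, 1, 1)

    def test_observer_counts_perfect(self):
        assert observer_counts({"a1", "a2", "b"}, self.GOLD) == (3, 0, 0)

    def test_observer_counts_d_is_fp(self):
        assert observer_counts({"a1", "a2", "b", "d"}, self.GOLD) == (3, 0, 1)

    def test_monotonicity_property(self):
        described = {"a1"}
        tp0, fn0, fp0 = observer_counts(described, self.GOLD)
        tp1, fn1, fp1 = observer_counts(described | {"b"}, self.GOLD)
        assert (tp1, fn1, fp1) == (tp0 + 1, fn0 - 1, fp0)

    def test_unranked_content_errors(self):
        with pytest.raises(KeyError):
            observer_counts({"mystery"}, self.GOLD)


class TestPairedComparison:
    def test_identical_vectors_flagged_degenerate(self):
        rep = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.degenerate and np.isnan(rep.p_two_tailed)
        assert rep.mean_w == rep.mean_wo

    def test_textbook_five_pair_example(self):
        # differences (1,1,2,2,4): t = mean/ (sd/sqrt(5)), df=4
        a = [5.0, 6.0, 8.0, 9.0, 12.0]
        b = [4.0, 5.0, 6.0, 7.0, 8.0]
        rep = paired_comparison(a, b)
        d = np.array(a) - np.array(b)
        t_exact = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_exact = 2 * stats.t.sf(abs(t_exact), df=4)
        assert rep.t_statistic == pytest.approx(t_exact, abs=1e-12)
        assert rep.p_two_tailed == pytest.approx(p_exact, abs=1e-12)

    def test_swap_negates_t_preserves_p(self):
        a = [1.0, 3.0, 2.0, 5.0]
        b = [2.0, 1.0, 4.0, 4.5]
        r1 = paired_comparison(a, b)
        r2 = paired_comparison(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [1.0])
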