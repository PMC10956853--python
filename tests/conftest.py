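"""Shared fixtures.

The three study fixtures (segment ablation, classifier comparison,
generation round-trip) are expensive, so they are session-scoped and shared
between the acceptance tests that assert different properties of the same
run.
"""

import pytest

from pulmorep import experiments


@pytest.fixture(scope="session")
def ablation_result():
    """Paired edge-loss ablation at the desk-scale study conditions:
    20 training phantoms, 10 evaluation phantoms, 300 steps, 5 seeds/arm."""
    return experiments.run_segment_ablation(
        n_train=20, n_eval=10, seeds=(0, 1, 2, 3, 4), steps=300
    )


@pytest.fixture(scope="session")
def classifier_result():
    """Dual vs wide-only comparison: 150/50 nodules, 500 steps, 5 seeds."""
    return experiments.run_classifier_comparison(
        n_train=150, n_test=50, seeds=(0, 1, 2, 3, 4), steps=500
    )


@pytest.fixture(scope="session")
def generation_result():
    """Round-trip study: 500 corpus pairs, disjoint splits, 50 test combos."""
    return experiments.run_generation_roundtrip(n_pairs=500, n_val=25, n_test=50)
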