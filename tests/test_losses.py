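"""Oracle and analytic-limit tests for the three training losses.

Each loss is checked against an independent brute-force implementation
written as explicit loops over voxels/classes, plus hand-derived analytic
special cases.
"""

import math

import numpy as np
import pytest

from pulmorep.classifier import bootstrap_bce
from pulmorep.nn import Tensor
from pulmorep.segnet import (
    edge_loss,
    sobel_gradient_magnitude,
    sparse_dice_loss,
    temperature_softmax,
)
from pulmorep.volume import UNLABELED


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def softmax_oracle(vec, T):
    e = [math.exp(v / T) for v in vec]
    s = sum(e)
    return [v / s for v in e]


def sobel_oracle(field):
    """Triple-loop 3D Sobel with replicate padding.

    field: (C, D, H, W); returns the per-voxel magnitude summed over classes.
    """
    deriv = np.array([-1.0, 0.0, 1.0])
    smooth = np.array([1.0, 2.0, 1.0])
    c, d, h, w = field.shape
    out = np.zeros((d, h, w))
    for ci in range(c):
        g = np.zeros((3, d, h, w))
        for axis in range(3):
            taps = [deriv if ax == axis else smooth for ax in range(3)]
            for z in range(d):
                for y in range(h):
                    for x in range(w):
                        acc = 0.0
                        for dz in (-1, 0, 1):
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    zz = min(max(z + dz, 0), d - 1)
                                    yy = min(max(y + dy, 0), h - 1)
                                    xx = min(max(x + dx, 0), w - 1)
                                    acc += (
                                        taps[0][dz + 1]
                                        * taps[1][dy + 1]
                                        * taps[2][dx + 1]
                                        * field[ci, zz, yy, xx]
                                    )
                        g[axis, z, y, x] = acc
        out += np.sqrt((g**2).sum(axis=0))
    return out


def edge_loss_oracle(logits, T):
    """Softmax-per-voxel (scalar loop) composed with the Sobel oracle."""
    n, c, d, h, w = logits.shape
    total = 0.0
    for ni in range(n):
        probs = np.zeros((c, d, h, w))
        for z in range(d):
            for y in range(h):
                for x in range(w):
                    probs[:, z, y, x] = softmax_oracle(logits[ni, :, z, y, x], T)
        total += sobel_oracle(probs).sum()
    return total


def dice_oracle(probs, labels, eps=1e-5):
    """Per-class Dice over labeled voxels, mean over classes present."""
    c = probs.shape[0]
    flat_p = probs.reshape(c, -1)
    flat_l = labels.reshape(-1)
    sel = flat_l != UNLABELED
    dices = []
    for ci in range(c):
        y = (flat_l[sel] == ci).astype(float)
        if y.sum() == 0:
            continue
        p = flat_p[ci][sel]
        dices.append(1 - (2 * (p * y).sum() + eps) / (p.sum() + y.sum() + eps))
    return float(np.mean(dices))


def bootstrap_oracle(logits, targets, beta, mode):
    """Scalar-loop bootstrapping sigmoid cross-entropy."""
    total, count = 0.0, 0
    for z, t in zip(np.ravel(logits), np.ravel(targets)):
        p = 1.0 / (1.0 + math.exp(-z))
        if mode == "soft":
            q = beta * t + (1 - beta) * p
        else:
            q = beta * t + (1 - beta) * (1.0 if p > 0.5 else 0.0)
        total += -(q * math.log(p) + (1 - q) * math.log(1 - p))
        count += 1
    return total / count


# ---------------------------------------------------------------------------
# temperature softmax
# ---------------------------------------------------------------------------

class TestTemperatureSoftmax:
    def test_symmetry(self):
        for T in (0.5, 1.0, 7.0):
            np.testing.assert_allclose(temperature_softmax(np.zeros(2), T), [0.5, 0.5])

    def test_paper_temperature_example(self):
        # logits (1, 0) at T=0.5: (e^2/(e^2+1), 1/(e^2+1))
        got = temperature_softmax(np.array([1.0, 0.0]), 0.5)
        e2 = math.exp(2.0)
        np.testing.assert_allclose(got, [e2 / (e2 + 1), 1 / (e2 + 1)], atol=1e-12)
        np.testing.assert_allclose(got, [0.8808, 0.1192], atol=1e-4)

    def test_overflow_safety(self):
        got = temperature_softmax(np.array([1000.0, 0.0]), 0.5)
        assert np.isfinite(got).all()
        np.testing.assert_allclose(got, [1.0, 0.0], atol=1e-12)

    def test_rows_sum_to_one_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(4, 6, 5)) * 5
        p = temperature_softmax(z, 0.5, axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        p2 = temperature_softmax(z + 13.7, 0.5, axis=1)
        np.testing.assert_allclose(p, p2, atol=1e-9)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vec = rng.normal(size=4) * 3
            T = rng.uniform(0.2, 2.0)
            np.testing.assert_allclose(
                temperature_softmax(vec, T), softmax_oracle(vec, T), atol=1e-12
            )

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            temperature_softmax(np.zeros(2), 0.0)


# ---------------------------------------------------------------------------
# Sobel magnitude
# ---------------------------------------------------------------------------

class TestSobelMagnitude:
    def test_constant_field_is_zero(self):
        field = np.full((2, 4, 4, 4), 0.37)
        np.testing.assert_array_equal(sobel_gradient_magnitude(field), 0.0)

    def test_step_function_locality(self):
        field = np.zeros((1, 5, 5, 5))
        field[0, :, :, 3:] = 1.0  # plane between x=2 and x=3
        mag = sobel_gradient_magnitude(field)
        assert (mag[:, :, [0, 1]] == 0).all() and (mag[:, :, 4] == 0).all()
        assert (mag[:, :, 2:4] > 0).all()

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        field = rng.random((2, 5, 5, 5))
        np.testing.assert_allclose(
            sobel_gradient_magnitude(field), sobel_oracle(field), atol=1e-6
        )

    def test_rejects_thin_grid(self):
        with pytest.raises(ValueError):
            sobel_gradient_magnitude(np.zeros((1, 2, 5, 5)))


# ---------------------------------------------------------------------------
# edge loss
# ---------------------------------------------------------------------------

class TestEdgeLoss:
    def test_constant_logits_exactly_zero(self):
        logits = np.broadcast_to(np.array([1.0, -0.5, 2.0])[:, None, None, None],
                                 (3, 5, 5, 5)).copy()
        assert edge_loss(logits, T=0.5) == 0.0

    def test_matches_composed_oracle(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(2, 3, 5, 5, 5)) * 2
        got = edge_loss(logits, T=0.5)
        want = edge_loss_oracle(logits, 0.5)
        assert got == pytest.approx(want, abs=1e-6 * max(1.0, abs(want)))

    def test_boundary_area_linearity(self):
        # confident two-region fields split by a plane: doubling the plane's
        # cross-section doubles the loss
        def planar_field(h, w):
            logits = np.zeros((2, 8, h, w))
            logits[0, :4] = 8.0
            logits[1, 4:] = 8.0
            return logits

        small = edge_loss(planar_field(4, 4), T=0.5)
        big = edge_loss(planar_field(8, 4), T=0.5)
        assert big == pytest.approx(2 * small, rel=1e-6)

    def test_gradient_finite_difference(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(1, 2, 4, 4, 4))
        t = Tensor(base.copy())
        t.requires_grad = True
        edge_loss(t, T=0.5).backward()
        eps = 1e-6
        for _ in range(10):
            idx = tuple(rng.integers(0, s) for s in base.shape)
            up, dn = base.copy(), base.copy()
            up[idx] += eps
            dn[idx] -= eps
            num = (edge_loss(up, 0.5) - edge_loss(dn, 0.5)) / (2 * eps)
            assert t.grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-8)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            assert edge_loss(rng.normal(size=(1, 2, 4, 4, 4)), T=0.5) >= 0.0


# ---------------------------------------------------------------------------
# sparse Dice loss
# ---------------------------------------------------------------------------

class TestSparseDiceLoss:
    def test_perfect_prediction_near_zero(self):
        labels = np.random.default_rng(6).integers(0, 3, size=(4, 4, 4))
        probs = np.eye(3)[labels].transpose(3, 0, 1, 2).astype(float)
        assert sparse_dice_loss(probs, labels) == pytest.approx(0.0, abs=1e-4)

    def test_unlabeled_voxels_ignored_exactly(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, size=(4, 4, 4)).astype(np.int16)
        labels[2:] = UNLABELED
        probs = rng.dirichlet(np.ones(3), size=(4, 4, 4)).transpose(3, 0, 1, 2)
        base = sparse_dice_loss(probs, labels)
        probs2 = probs.copy()
        probs2[:, 2:] = rng.dirichlet(np.ones(3), size=(2, 4, 4)).transpose(3, 0, 1, 2)
        assert sparse_dice_loss(probs2, labels) == base

    def test_half_overlap_hand_value(self):
        # 1D toy: prediction covers {0,1}, truth covers {1,2}; both the
        # foreground and the complementary background class have Dice 1/2
        labels = np.array([0, 1, 1, 0]).reshape(1, 1, 4)
        probs = np.zeros((2, 1, 1, 4))
        probs[1, 0, 0, [0, 1]] = 1.0
        probs[0, 0, 0, [2, 3]] = 1.0
        assert sparse_dice_loss(probs, labels) == pytest.approx(0.5, abs=1e-5)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            shape = tuple(rng.integers(2, 7, size=3))
            c = int(rng.integers(2, 5))
            labels = rng.integers(-1, c, size=shape).astype(np.int16)
            if (labels != UNLABELED).sum() == 0:
                labels.flat[0] = 0
            probs = rng.dirichlet(np.ones(c), size=shape).transpose(3, 0, 1, 2)
            got = sparse_dice_loss(probs, labels)
            assert got == pytest.approx(dice_oracle(probs, labels), abs=1e-6)

    def test_all_unlabeled_errors(self):
        probs = np.full((2, 3, 3, 3), 0.5)
        labels = np.full((3, 3, 3), UNLABELED, dtype=np.int16)
        with pytest.raises(ValueError, match="no supervision"):
            sparse_dice_loss(probs, labels)


# ---------------------------------------------------------------------------
# bootstrapping sigmoid cross-entropy
# ---------------------------------------------------------------------------

class TestBootstrapBCE:
    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            z = rng.normal(size=(3, 4)) * 3
            t = rng.integers(0, 2, size=(3, 4)).astype(float)
            beta = rng.uniform(0.05, 1.0)
            mode = ("soft", "hard")[rng.integers(2)]
            got = bootstrap_bce(z, t, beta, mode)
            assert got == pytest.approx(bootstrap_oracle(z, t, beta, mode), abs=1e-9)

    def test_beta_one_is_plain_bce(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(5, 4)) * 2
        t = rng.integers(0, 2, size=(5, 4)).astype(float)
        p = 1 / (1 + np.exp(-z))
        plain = float(np.mean(-(t * np.log(p) + (1 - t) * np.log(1 - p))))
        for mode in ("soft", "hard"):
            assert bootstrap_bce(z, t, 1.0, mode) == pytest.approx(plain, abs=1e-12)

    def test_confident_correct_limit(self):
        z = np.array([[30.0, -30.0]])
        t = np.array([[1.0, 0.0]])
        assert bootstrap_bce(z, t, 0.8, "soft") == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_log2(self):
        # logit 0 (p=1/2), t=1, beta=0.8 -> q=0.9; loss = -log(1/2) = log 2
        got = bootstrap_bce(np.array([0.0]), np.array([1.0]), 0.8, "soft")
        assert got == pytest.approx(math.log(2.0), abs=1e-12)

    def test_mask_excludes_classes(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=(4, 3))
        t = rng.integers(0, 2, size=(4, 3)).astype(float)
        mask = np.ones_like(t, dtype=bool)
        mask[:, 1] = False
        got = bootstrap_bce(z, t, 0.9, "soft", mask=mask)
        want = bootstrap_oracle(z[:, [0, 2]], t[:, [0, 2]], 0.9, "soft")
        assert got == pytest.approx(want, abs=1e-9)
        # perturbing the excluded class changes nothing
        z2 = z.copy()
        z2[:, 1] += 100
        assert bootstrap_bce(z2, t, 0.9, "soft", mask=mask) == pytest.approx(got, abs=1e-12)

    def test_beta_out_of_range(self):
        with pytest.raises(ValueError):
            bootstrap_bce(np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError):
            bootstrap_bce(np.zeros(2), np.zeros(2), 1.2)
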