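"""Segmentation stage: training loop contracts, prediction, nodule-segment
assignment, checkpointing."""

import numpy as np
import pytest

from pulmorep.nn import Tensor
from pulmorep.segnet import (
    SegTrainConfig,
    UNet3D,
    load_segmenter,
    predict_segments,
    save_segmenter,
    segments_of_nodule,
    train_segmenter,
)
from pulmorep.volume import UNLABELED, Box, LabelMap, Volume


def tiny_dataset(n=2, shape=(16, 16, 16), n_classes=3, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        v = Volume(rng.random(shape, dtype=np.float32))
        lab = np.full(shape, UNLABELED, dtype=np.int16)
        lab[4:12, 4:12, 4:12] = rng.integers(0, n_classes, (8, 8, 8))
        out.append((v, LabelMap(lab)))
    return out


def tiny_config(**kw):
    base = dict(n_classes=3, base_channels=4, steps=5, crop_shape=(8, 8, 8), seed=0)
    base.update(kw)
    return SegTrainConfig(**base)


class TestTrainSegmenter:
    def test_loss_log_shape_and_finite(self):
        trained = train_segmenter(tiny_dataset(), tiny_config())
        assert list(trained.log.columns) == ["step", "dice_loss", "edge_loss", "total"]
        assert len(trained.log) == 5
        assert np.isfinite(trained.log.total).all()

    def test_lambda_zero_reproduces_plain_dice_run(self):
        """edge_loss_enabled with weight 0 gives step-identical losses to an
        edge-loss-free run at the same seed."""
        with_zero = train_segmenter(
            tiny_dataset(), tiny_config(edge_loss_enabled=True, edge_loss_weight=0.0)
        )
        without = train_segmenter(tiny_dataset(), tiny_config(edge_loss_enabled=False))
        np.testing.assert_array_equal(
            with_zero.log.dice_loss.values, without.log.dice_loss.values
        )

    def test_seeded_determinism_bitwise(self):
        t1 = train_segmenter(tiny_dataset(), tiny_config(edge_loss_enabled=True))
        t2 = train_segmenter(tiny_dataset(), tiny_config(edge_loss_enabled=True))
        assert t1.log.equals(t2.log)
        for a, b in zip(t1.model.parameters(), t2.model.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            train_segmenter([], tiny_config())

    def test_item_without_labels_errors(self):
        v = Volume(np.zeros((16, 16, 16), dtype=np.float32))
        lab = LabelMap(np.full((16, 16, 16), UNLABELED, dtype=np.int16))
        with pytest.raises(ValueError, match="no labeled voxels"):
            train_segmenter([(v, lab)], tiny_config())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SegTrainConfig(temperature=0.0)
        with pytest.raises(ValueError):
            SegTrainConfig(edge_loss_weight=-1.0)
        with pytest.raises(ValueError):
            SegTrainConfig(steps=0)


class _OracleModel:
    """Duck-typed stand-in emitting one-hot logits of a fixed label map."""

    levels = 1

    def __init__(self, labels, n_classes):
        self.labels = labels
        self.n_classes = n_classes

    def __call__(self, x):
        onehot = np.eye(self.n_classes, dtype=np.float32)[self.labels]
        logits = onehot.transpose(3, 0, 1, 2)[None] * 10.0
        return Tensor(logits)


class TestPredictSegments:
    def test_oracle_model_reproduces_truth(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, (8, 8, 8))
        v = Volume(rng.random((8, 8, 8), dtype=np.float32))
        _, pred = predict_segments(None, _OracleModel(labels, 4), v)
        assert np.array_equal(pred.data, labels)

    def test_lobe_masking_zeroes_background(self):
        rng = np.random.default_rng(2)
        seg_labels = rng.integers(1, 4, (8, 8, 8))  # segment everywhere
        lobe_labels = np.zeros((8, 8, 8), dtype=int)
        lobe_labels[:4] = 1  # lung only in the top half
        v = Volume(rng.random((8, 8, 8), dtype=np.float32))
        lobes, pred = predict_segments(
            _OracleModel(lobe_labels, 2), _OracleModel(seg_labels, 4), v
        )
        assert (pred.data[4:] == 0).all()
        assert np.array_equal(pred.data[:4], seg_labels[:4])
        assert np.array_equal(lobes.data, lobe_labels)

    def test_argmax_tie_breaks_to_lowest_class(self):
        class Tie:
            levels = 1

            def __call__(self, x):
                return Tensor(np.ones((1, 3) + x.data.shape[2:], dtype=np.float32))

        v = Volume(np.zeros((4, 4, 4), dtype=np.float32))
        _, pred = predict_segments(None, Tie(), v)
        assert (pred.data == 0).all()

    def test_incompatible_shape_errors(self):
        net = UNet3D(3, base_channels=4, levels=2)
        v = Volume(np.zeros((7, 8, 8), dtype=np.float32))  # not divisible by 2
        with pytest.raises(ValueError, match="divisible"):
            predict_segments(None, net, v)


class TestSegmentsOfNodule:
    def _labelmap(self, fractions: dict[int, int]):
        """1D layout with the requested voxel counts per segment ID."""
        vals = sum(([sid] * n for sid, n in fractions.items()), [])
        return LabelMap(np.array(vals, dtype=np.int16).reshape(1, 1, -1))

    def test_box_fully_inside_one_segment(self):
        lm = self._labelmap({3: 20})
        assert segments_of_nodule(lm, Box((0, 0, 0), (1, 1, 20))) == {3}

    def test_85_15_split_keeps_both(self):
        lm = self._labelmap({2: 17, 5: 3})
        assert segments_of_nodule(lm, Box((0, 0, 0), (1, 1, 20))) == {2, 5}

    def test_95_5_split_keeps_majority_only(self):
        lm = self._labelmap({2: 19, 5: 1})
        assert segments_of_nodule(lm, Box((0, 0, 0), (1, 1, 20))) == {2}

    def test_background_excluded_but_counted_in_denominator(self):
        lm = self._labelmap({0: 18, 7: 2})  # 10% exactly
        assert segments_of_nodule(lm, Box((0, 0, 0), (1, 1, 20))) == {7}

    def test_bad_fraction_rejected(self):
        lm = self._labelmap({1: 10})
        with pytest.raises(ValueError):
            segments_of_nodule(lm, Box((0, 0, 0), (1, 1, 10)), frac=0.0)


def test_checkpoint_roundtrip(tmp_path):
    trained = train_segmenter(tiny_dataset(), tiny_config())
    path = tmp_path / "seg.npz"
    save_segmenter(trained, path)
    loaded = load_segmenter(path)
    assert loaded.config == trained.config
    v = Volume(np.random.default_rng(3).random((16, 16, 16), dtype=np.float32))
    _, p1 = predict_segments(None, trained, v)
    _, p2 = predict_segments(None, loaded, v)
    assert np.array_equal(p1.data, p2.data)
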