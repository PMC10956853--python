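"""Image preprocessing shared by segmentation and classification.

The pipeline follows common chest-CT practice: resample to isotropic 1 mm
voxels, clip HU to [−1400, 200] and linearly normalize to [0, 1], then (for
classification) extract a dual-resolution patch pair: a *wide-area* patch
covering the nodule box expanded by a 15 mm margin, and an *enlarged* patch
covering the box alone, both resampled to one grid and stacked along the
channel axis so the network sees context and fine structure simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Box, LabelMap, Volume

__all__ = [
    "HU_CLIP_LO",
    "HU_CLIP_HI",
    "PatchPair",
    "resample_isotropic",
    "normalize_hu",
    "extract_patch_pair",
    "augment",
]

HU_CLIP_LO = -1400.0
HU_CLIP_HI = 200.0

AUGMENT_OPS = ("sharpness", "scaling", "random_crop")


@dataclass
class PatchPair:
    """Wide-area + enlarged patches of one nodule, channel order fixed
    (wide first)."""

    wide: np.ndarray
    enlarged: np.ndarray

    def __post_init__(self):
        self.wide = np.asarray(self.wide, dtype=np.float32)
        self.enlarged = np.asarray(self.enlarged, dtype=np.float32)
        if self.wide.shape != self.enlarged.shape:
            raise ValueError(
                f"patch shapes differ: wide {self.wide.shape} vs enlarged {self.enlarged.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.wide.shape

    def stacked(self) -> np.ndarray:
        """(2, D, H, W) channel-stacked array, wide first."""
        return np.stack([self.wide, self.enlarged])


def resample_isotropic(v: Volume | LabelMap, target_mm: float) -> Volume | LabelMap:
    """Resample to `target_mm` spacing on all axes.

    Trilinear interpolation for volumes, nearest-neighbour for label maps;
    the physical extent is preserved to within one voxel.  A volume already
    at the target spacing is returned as a bit-equal copy.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    if any(s <= 0 for s in v.spacing):
        raise ValueError(f"non-positive input spacing {v.spacing}")
    if all(abs(s - target_mm) < 1e-12 for s in v.spacing):
        return v.copy()
    out_shape = tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(v.shape, v.spacing)
    )
    factors = [o / n for o, n in zip(out_shape, v.shape)]
    is_label = isinstance(v, LabelMap)
    data = ndimage.zoom(
        v.data,
        factors,
        order=0 if is_label else 1,
        mode="nearest",
        grid_mode=True,
    )
    data = data[: out_shape[0], : out_shape[1], : out_shape[2]]
    spacing = (target_mm,) * 3
    return LabelMap(data, spacing) if is_label else Volume(data, spacing)


def normalize_hu(v: Volume, lo: float = HU_CLIP_LO, hi: float = HU_CLIP_HI) -> Volume:
    """Clip HU to [lo, hi] and map linearly onto [0, 1]."""
    if lo >= hi:
        raise ValueError(f"require lo < hi, got lo={lo}, hi={hi}")
    data = np.clip((v.data - lo) / (hi - lo), 0.0, 1.0)
    return Volume(data.astype(np.float32), v.spacing)


def _crop_padded(data: np.ndarray, box: Box, fill: float) -> np.ndarray:
    """Crop `box` from `data`, zero/`fill`-padding where it leaves the grid."""
    out = np.full(box.shape, fill, dtype=data.dtype)
    src = box.clamp(data.shape)
    # dst slice start = src.start - box.start; length = src extent
    dst = tuple(
        slice(s0 - b0, s0 - b0 + (s1 - s0))
        for s0, s1, b0 in zip(src.start, src.stop, box.start)
    )
    out[dst] = data[src.slices]
    return out


def _resize_to(data: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    if data.shape == tuple(out_shape):
        return data.astype(np.float32)
    factors = [o / n for o, n in zip(out_shape, data.shape)]
    res = ndimage.zoom(data.astype(np.float32), factors, order=1, mode="nearest", grid_mode=True)
    return res[: out_shape[0], : out_shape[1], : out_shape[2]].astype(np.float32)


def extract_patch_pair(
    v: Volume,
    box: Box,
    margin_mm: float = 15.0,
    out_shape: tuple[int, int, int] = (12, 12, 12),
) -> PatchPair:
    """Extract the classifier input for one nodule.

    `wide` is the box expanded by `margin_mm` (in mm, via the volume spacing),
    `enlarged` the box alone; both are resampled to `out_shape`.  Regions
    beyond the volume edge are filled with 0, the normalized value of clipped
    air, so border nodules keep the intensity convention.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if not box.inside(v.shape):
        raise ValueError(f"box {box} not inside volume of shape {v.shape}")
    wide_box = box.expand_mm(margin_mm, v.spacing)
    wide = _resize_to(_crop_padded(v.data, wide_box, 0.0), out_shape)
    enlarged = _resize_to(v.data[box.slices], out_shape)
    return PatchPair(wide, enlarged)


def augment(
    x: Volume | np.ndarray,
    ops_config: dict,
    seed: int,
    labels: LabelMap | None = None,
):
    """Seeded data augmentation: sharpness (unsharp masking), scaling, and
    random cropping.

    `ops_config` maps op name to its parameter: ``sharpness: [lo, hi]``
    (amount range), ``scaling: [lo, hi]`` (isotropic factor range),
    ``random_crop: side_voxels``.  Ops are applied in that fixed order.
    Label maps receive the identical geometric transforms with
    nearest-neighbour interpolation and are never intensity-transformed.
    Returns the augmented input, or an (input, labels) tuple when labels are
    given.
    """
    unknown = set(ops_config) - set(AUGMENT_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    is_volume = isinstance(x, Volume)
    data = x.data.copy() if is_volume else np.array(x, dtype=np.float32)
    if not is_volume and data.ndim == 4:
        # channel-stacked patches: identical transform per channel
        out = np.stack(
            [augment(data[c], ops_config, seed) for c in range(data.shape[0])]
        )
        return out.astype(np.float32)
    lab = labels.data.copy() if labels is not None else None

    if "sharpness" in ops_config:
        lo, hi = ops_config["sharpness"]
        amount = rng.uniform(lo, hi)
        blurred = ndimage.gaussian_filter(data, sigma=1.0)
        data = data + amount * (data - blurred)

    if "scaling" in ops_config:
        lo, hi = ops_config["scaling"]
        factor = rng.uniform(lo, hi)
        if abs(factor - 1.0) > 1e-12:
            shape0 = data.shape
            data = ndimage.zoom(data, factor, order=1, mode="nearest")
            data = _center_match(data, shape0)
            if lab is not None:
                lab = ndimage.zoom(lab, factor, order=0, mode="nearest")
                lab = _center_match(lab, shape0)

    if "random_crop" in ops_config:
        side = int(ops_config["random_crop"])
        if all(side == s for s in data.shape):
            # crop side equals the input: act as translation jitter by
            # edge-padding first, so fixed-size patches keep their shape
            data = np.pad(data, 2, mode="edge")
            if lab is not None:
                lab = np.pad(lab, 2, mode="edge")
        starts = [int(rng.integers(0, max(1, s - side + 1))) for s in data.shape]
        sl = tuple(slice(st, st + min(side, s)) for st, s in zip(starts, data.shape))
        data = data[sl].copy()
        if lab is not None:
            lab = lab[sl].copy()

    if is_volume:
        out = Volume(data, x.spacing)
    else:
        out = data.astype(np.float32)
    if labels is not None:
        return out, LabelMap(lab, labels.spacing)
    return out


def _center_match(data: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center-crop or pad (edge values) `data` to `shape`."""
    out = data
    for ax, (cur, tgt) in enumerate(zip(out.shape, shape)):
        if cur > tgt:
            start = (cur - tgt) // 2
            out = np.take(out, range(start, start + tgt), axis=ax)
        elif cur < tgt:
            before = (tgt - cur) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, tgt - cur - before)
            out = np.pad(out, pad, mode="edge")
    return out
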