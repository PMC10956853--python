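"""Containers for CT-like volumes, integer label maps and voxel boxes.

Conventions used throughout the package:

* arrays are indexed (z, y, x) but treated symmetrically; ``spacing`` gives the
  per-axis voxel size in millimetres in the same order;
* boxes are 0-based, half-open voxel intervals (``start`` inclusive, ``stop``
  exclusive); world coordinates enter only through ``spacing``;
* sparse label maps mark unsupervised voxels with :data:`UNLABELED` (−1);
  0 is background, positive integers are lobe (1–5) or segment (1–18) IDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

UNLABELED = -1

__all__ = ["UNLABELED", "Volume", "LabelMap", "Box", "load_volume", "load_labelmap"]


@dataclass(frozen=True)
class Box:
    """Axis-aligned 0-based half-open voxel box."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.start, self.stop)):
            raise ValueError(f"empty box: start={self.start} stop={self.stop}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    def center_voxel(self) -> tuple[float, float, float]:
        """Continuous box centre in voxel coordinates."""
        return tuple((a + b - 1) / 2.0 for a, b in zip(self.start, self.stop))

    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def inside(self, grid_shape: tuple[int, ...]) -> bool:
        return all(a >= 0 and b <= s for a, b, s in zip(self.start, self.stop, grid_shape))

    def expand_mm(self, margin_mm: float, spacing: tuple[float, ...]) -> "Box":
        start = tuple(a - int(round(margin_mm / s)) for a, s in zip(self.start, spacing))
        stop = tuple(b + int(round(margin_mm / s)) for b, s in zip(self.stop, spacing))
        return Box(start, stop)

    def clamp(self, grid_shape: tuple[int, ...]) -> "Box":
        start = tuple(max(0, a) for a in self.start)
        stop = tuple(min(s, b) for b, s in zip(self.stop, grid_shape))
        return Box(start, stop)

    def to_json(self) -> dict:
        return {"start": list(self.start), "stop": list(self.stop)}

    @staticmethod
    def from_json(obj: dict) -> "Box":
        return Box(tuple(obj["start"]), tuple(obj["stop"]))

    @staticmethod
    def from_mask(mask: np.ndarray) -> "Box":
        """Tight bounding box of the True voxels."""
        if not mask.any():
            raise ValueError("mask is empty")
        idx = np.nonzero(mask)
        return Box(
            tuple(int(a.min()) for a in idx),
            tuple(int(a.max()) + 1 for a in idx),
        )


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """Scalar 3D image (HU or normalized intensities) with voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 3:
            raise ValueError("Volume requires a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), _affine(self.spacing))
        nib.save(img, str(path))


@dataclass
class LabelMap:
    """Integer label grid aligned with a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 3:
            raise ValueError("LabelMap requires a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the map."""
        vals = np.unique(self.data)
        return vals[vals > 0]

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), self.spacing)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), _affine(self.spacing))
        nib.save(img, str(path))


def _spacing_of(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asarray(img.dataobj, dtype=np.float32), _spacing_of(img))


def load_labelmap(path: str | Path) -> LabelMap:
    img = nib.load(str(path))
    return LabelMap(np.asarray(img.dataobj, dtype=np.int16), _spacing_of(img))
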