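"""Nodule imaging findings: the 14-item characteristic list and its
16-class vector encoding.

The classifier predicts C = 16 sigmoid outputs: three mutually exclusive
opacity flags (solid / part-solid / pure ground-glass) plus 13 binary
finding flags covering shape, margin, internal and external characteristics.
Classes that cannot be determined for a case ("undeterminable") are masked
out of both training loss and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

OPACITY_CLASSES: tuple[str, ...] = ("solid", "part_solid", "pure_ggo")

BINARY_CLASSES: tuple[str, ...] = (
    "irregular_shape",      # vs round
    "ill_defined",          # vs well-defined margin
    "irregular_edge",       # vs smooth edge
    "spiculated",
    "lobulated",
    "ragged",
    "polygonal",
    "air_bronchogram",
    "cavity",
    "calcification",
    "fat",
    "pleural_contact",
    "pleural_indentation",
)

CLASS_NAMES: tuple[str, ...] = OPACITY_CLASSES + BINARY_CLASSES
N_CLASSES = len(CLASS_NAMES)  # 16

__all__ = [
    "OPACITY_CLASSES",
    "BINARY_CLASSES",
    "CLASS_NAMES",
    "N_CLASSES",
    "FindingVector",
]


@dataclass(frozen=True)
class FindingVector:
    """Ground-truth or predicted characteristics of one nodule.

    `opacity` is one of :data:`OPACITY_CLASSES`; each name in
    :data:`BINARY_CLASSES` is a boolean attribute; `undeterminable` lists
    class names excluded from supervision and scoring.
    """

    opacity: str = "solid"
    irregular_shape: bool = False
    ill_defined: bool = False
    irregular_edge: bool = False
    spiculated: bool = False
    lobulated: bool = False
    ragged: bool = False
    polygonal: bool = False
    air_bronchogram: bool = False
    cavity: bool = False
    calcification: bool = False
    fat: bool = False
    pleural_contact: bool = False
    pleural_indentation: bool = False
    undeterminable: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.opacity not in OPACITY_CLASSES:
            raise ValueError(f"unknown opacity {self.opacity!r}; expected one of {OPACITY_CLASSES}")
        unknown = set(self.undeterminable) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"undeterminable lists unknown classes: {sorted(unknown)}")
        object.__setattr__(self, "undeterminable", frozenset(self.undeterminable))

    # ---- vector encodings ------------------------------------------------
    def to_array(self) -> np.ndarray:
        """{0,1} target vector of length 16 (opacity one-hot, then binaries)."""
        vec = np.zeros(N_CLASSES, dtype=np.float64)
        vec[OPACITY_CLASSES.index(self.opacity)] = 1.0
        for i, name in enumerate(BINARY_CLASSES):
            vec[len(OPACITY_CLASSES) + i] = float(getattr(self, name))
        return vec

    def determinable_mask(self) -> np.ndarray:
        """Boolean length-16 mask; False entries are excluded from the loss."""
        return np.array([name not in self.undeterminable for name in CLASS_NAMES])

    def positive_tokens(self) -> frozenset[str]:
        """Content tokens this vector realizes: the opacity plus positive flags."""
        toks = {self.opacity}
        toks.update(name for name in BINARY_CLASSES if getattr(self, name))
        return frozenset(toks)

    # ---- (de)serialisation ----------------------------------------------
    def to_json(self) -> dict:
        out = {"opacity": self.opacity}
        out.update({name: bool(getattr(self, name)) for name in BINARY_CLASSES})
        if self.undeterminable:
            out["undeterminable"] = sorted(self.undeterminable)
        return out

    @staticmethod
    def from_json(obj: dict) -> "FindingVector":
        kwargs = dict(obj)
        if "undeterminable" in kwargs:
            kwargs["undeterminable"] = frozenset(kwargs["undeterminable"])
        return FindingVector(**kwargs)

    @staticmethod
    def from_scores(scores: np.ndarray, threshold: float = 0.5) -> "FindingVector":
        """Resolve per-class sigmoid scores into a finding vector.

        The opacity type is the argmax of the three opacity scores (they are
        trained as independent sigmoids but are mutually exclusive semantically);
        binary flags use `threshold`.
        """
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} scores, got shape {scores.shape}")
        opacity = OPACITY_CLASSES[int(np.argmax(scores[: len(OPACITY_CLASSES)]))]
        flags = {
            name: bool(scores[len(OPACITY_CLASSES) + i] > threshold)
            for i, name in enumerate(BINARY_CLASSES)
        }
        return FindingVector(opacity=opacity, **flags)

    def replace(self, **changes) -> "FindingVector":
        return replace(self, **changes)
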