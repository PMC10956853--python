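"""Synthetic CT-like lung phantoms with segment anatomy and rendered nodules.

The phantom emulates the anatomy the segmentation task assumes: a lung region
(ellipsoid, ≈ −900 HU against a 0 HU soft-tissue background) partitioned into
lobes by smooth, gently curved surfaces, with each lobe subdivided into
bronchopulmonary segments by near-planar boundaries with a small random tilt.
Planar segment boundaries are deliberate: the edge-smoothing loss exploits
exactly this property of real intersegmental planes, so the phantom isolates
the effect the loss is designed to produce.

Nodules are rendered deterministically from a :class:`FindingVector`: every
one of the 14 characteristic items has a geometric/intensity rendering rule
(solid ≈ +50 HU, pure ground-glass ≈ −600 HU, cavity = internal air pocket,
calcification = saturating +800 HU focus, spiculation = radial spikes, and so
on).  Sparse "localized" ground truth is produced by keeping dense labels
only within a given radius of a nodule box and marking everything else
UNLABELED, mirroring how report-derived annotations label only the
neighbourhood of the reported lesion.

HU constants sit inside the preprocessing clip window [−1400, 200], except
calcification which intentionally saturates at the upper clip, as real
calcifications do under that normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .findings import FindingVector
from .volume import UNLABELED, Box, LabelMap, Volume

__all__ = [
    "PhantomConfig",
    "NoduleSpec",
    "HU_AIR_LUNG",
    "HU_BACKGROUND",
    "HU_SOLID",
    "HU_GGO",
    "HU_CALCIFICATION",
    "HU_FAT",
    "make_lung_phantom",
    "render_nodule",
    "sparsify_labels",
    "sample_nodule_center",
]

HU_AIR_LUNG = -900.0
HU_BACKGROUND = 0.0
HU_SOLID = 50.0
HU_GGO = -600.0
HU_CALCIFICATION = 800.0  # saturates the [-1400, 200] clip window
HU_FAT = -100.0
HU_STRAND = -150.0  # pleural-indentation strand
HU_BRONCHUS = 0.0  # soft-tissue peribronchial bundle


@dataclass(frozen=True)
class PhantomConfig:
    """Anatomy and noise settings for one phantom.

    Desk-scale default is 2 lobes × 3 segments on a 48³ grid at 1 mm; the
    full five-lobe / 18-segment anatomy is available as
    ``PhantomConfig(grid_shape=(128,)*3, n_lobes=5, segments_per_lobe=4)``
    (any per-lobe segment count; real lungs have 18 segments over 5 lobes).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lobes: int = 2
    segments_per_lobe: int = 3
    noise_sd: float = 20.0
    render_bronchi: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if self.n_lobes < 1 or self.segments_per_lobe < 1:
            raise ValueError("n_lobes and segments_per_lobe must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # each lobe band needs a few voxels of lung along the stacking axis
        lung_extent = int(0.84 * self.grid_shape[0])
        if lung_extent < 4 * self.n_lobes:
            raise ValueError(
                f"grid too small to host {self.n_lobes} lobes: lung spans ~{lung_extent} "
                f"voxels along axis 0 but {4 * self.n_lobes} are needed"
            )

    @property
    def n_segments(self) -> int:
        return self.n_lobes * self.segments_per_lobe


@dataclass(frozen=True)
class NoduleSpec:
    """One nodule: placement, size, ground-truth findings, rendered extent."""

    center: tuple[int, int, int]
    diameter_mm: float
    findings: FindingVector = field(default_factory=FindingVector)
    rendered_box: Box | None = None
    seed: int = 0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")

    def to_json(self) -> dict:
        out = {
            "center": list(self.center),
            "diameter_mm": self.diameter_mm,
            "findings": self.findings.to_json(),
            "seed": self.seed,
        }
        if self.rendered_box is not None:
            out["rendered_box"] = self.rendered_box.to_json()
        return out

    @staticmethod
    def from_json(obj: dict) -> "NoduleSpec":
        return NoduleSpec(
            center=tuple(obj["center"]),
            diameter_mm=obj["diameter_mm"],
            findings=FindingVector.from_json(obj["findings"]),
            rendered_box=Box.from_json(obj["rendered_box"]) if "rendered_box" in obj else None,
            seed=obj.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# phantom anatomy
# ---------------------------------------------------------------------------

def _voxel_grid(shape):
    return np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")


def make_lung_phantom(config: PhantomConfig) -> tuple[Volume, LabelMap, LabelMap]:
    """Build (volume, lobe labels, segment labels) for one phantom.

    The lung is an ellipsoid; lobes are bands along axis 0 separated by
    smooth low-frequency surfaces with volumes equalised by quantiles;
    segments split each lobe by parallel planes with a small random tilt.
    Segment IDs enumerate 1..n_lobes*segments_per_lobe; lobe IDs 1..n_lobes.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    zz, yy, xx = _voxel_grid(shape)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.42 * s for s in shape]
    lung = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0

    # ---- lobes: smooth curved surfaces stacked along axis 0 -------------
    lobes = np.zeros(shape, dtype=np.int16)
    z_in_lung = zz[lung]
    qs = np.quantile(z_in_lung, np.linspace(0, 1, config.n_lobes + 1)[1:-1]) if config.n_lobes > 1 else []
    lobe_idx = np.zeros(shape, dtype=np.int16)
    for q in qs:
        amp = rng.uniform(0.5, 1.0)
        ph_y, ph_x = rng.uniform(0, 2 * np.pi, 2)
        fy, fx = rng.uniform(0.5, 1.0, 2)
        surface = q + amp * (
            np.sin(2 * np.pi * fy * yy / shape[1] + ph_y)
            + np.sin(2 * np.pi * fx * xx / shape[2] + ph_x)
        ) / 2.0
        lobe_idx += (zz > surface).astype(np.int16)
    lobes[lung] = 1 + lobe_idx[lung]

    # ---- segments: tilted parallel planes within each lobe --------------
    segments = np.zeros(shape, dtype=np.int16)
    coords = np.stack([zz, yy, xx])
    for li in range(1, config.n_lobes + 1):
        in_lobe = lobes == li
        # modest inter-phantom tilt jitter: segmental anatomy is largely
        # consistent across subjects, and the boundary stays near-planar
        normal = np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), 1.0])
        normal /= np.linalg.norm(normal)
        proj = np.tensordot(normal, coords, axes=1)
        d = proj[in_lobe]
        cuts = np.quantile(d, np.linspace(0, 1, config.segments_per_lobe + 1)[1:-1])
        idx = np.zeros(d.shape, dtype=np.int16)
        for cut in np.atleast_1d(cuts):
            idx += (d > cut).astype(np.int16)
        segments[in_lobe] = (li - 1) * config.segments_per_lobe + 1 + idx

    # ---- intensities ------------------------------------------------------
    vol = np.full(shape, HU_BACKGROUND, dtype=np.float32)
    vol[lung] = HU_AIR_LUNG
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=int(lung.sum()))
        vol[lung] += noise.astype(np.float32)

    # ---- bronchi: one soft-tissue tube from the hilum into each segment --
    # The visible cue that ties image content to segment identity, standing
    # in for the bronchial tree real segment labels are derived from.  The
    # intersegmental boundaries themselves stay invisible in intensity.
    if config.render_bronchi:
        hilum = np.array(center)
        coords_flat = np.stack([zz, yy, xx]).reshape(3, -1)

        def draw_tube(a: np.ndarray, b: np.ndarray, radius: float) -> None:
            d = b - a
            length = np.linalg.norm(d)
            if length < 1e-6:
                return
            d = d / length
            rel = coords_flat - a[:, None]
            t = d @ rel
            radial2 = (rel**2).sum(axis=0) - t**2
            tube = (t >= 0) & (t <= length) & (radial2 <= radius**2)
            vol[tube.reshape(shape) & lung] = HU_BRONCHUS

        for sid in range(1, config.n_segments + 1):
            in_seg = segments == sid
            if not in_seg.any():
                continue
            centroid = np.array([g[in_seg].mean() for g in (zz, yy, xx)])
            draw_tube(hilum, centroid, 1.2)
            # sub-branches fanning from the centroid toward the segment
            # periphery, so every neighbourhood of the segment sees its airway
            seg_pts = np.argwhere(in_seg)
            for _ in range(4):
                target = seg_pts[rng.integers(len(seg_pts))].astype(float)
                draw_tube(centroid, centroid + 1.15 * (target - centroid), 0.9)

    spacing = tuple(config.spacing_mm)
    return Volume(vol, spacing), LabelMap(lobes, spacing), LabelMap(segments, spacing)


def sample_nodule_center(
    segments: LabelMap,
    rng: np.random.Generator,
    min_border_mm: float = 0.0,
    max_border_mm: float | None = None,
) -> tuple[int, int, int]:
    """Pick a random in-lung voxel, optionally constrained by its distance to
    the pleural (lung) border in millimetres."""
    lung = segments.data > 0
    dist = ndimage.distance_transform_edt(lung, sampling=segments.spacing)
    ok = lung & (dist >= min_border_mm)
    if max_border_mm is not None:
        ok &= dist <= max_border_mm
    coords = np.argwhere(ok)
    if len(coords) == 0:
        raise ValueError("no in-lung voxel satisfies the border-distance constraints")
    z, y, x = coords[rng.integers(len(coords))]
    return int(z), int(y), int(x)


# ---------------------------------------------------------------------------
# nodule rendering
# ---------------------------------------------------------------------------

def _angular_field(dirs: np.ndarray, rng: np.random.Generator, degree: int) -> np.ndarray:
    """Smooth random function of direction: a random polynomial of the unit
    direction components of the given degree, scaled to max |f| == 1."""
    m = dirs.shape[1]
    f = np.zeros(m)
    n_terms = 6
    for _ in range(n_terms):
        coef = rng.normal()
        idx = rng.integers(0, 3, size=degree)
        term = np.ones(m)
        for i in idx:
            term = term * dirs[i]
        f += coef * term
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def render_nodule(
    volume: Volume, segments: LabelMap, spec: NoduleSpec
) -> tuple[Volume, NoduleSpec]:
    """Render one nodule into a copy of `volume`; returns the new volume and
    the spec with its tight `rendered_box` filled in.

    Every finding flag has a deterministic rendering rule (seeded by
    ``spec.seed``); see the module docstring for the intensity constants.
    Raises if the centre is outside the lung, or if pleural contact is
    requested at a centre more than one diameter from the pleura.
    """
    f = spec.findings
    cz, cy, cx = spec.center
    shape = volume.shape
    if not all(0 <= c < s for c, s in zip(spec.center, shape)):
        raise ValueError(f"center {spec.center} outside grid {shape}")
    if segments.data[cz, cy, cx] <= 0:
        raise ValueError(f"nodule center {spec.center} is not inside the lung")
    spacing = np.asarray(volume.spacing)
    r_vox = spec.diameter_mm / 2.0 / spacing  # per-axis radius in voxels
    rng = np.random.default_rng(spec.seed)

    lung = segments.data > 0
    # distance to pleura and nearest pleural voxel (for contact/indentation)
    dist_map, nearest = ndimage.distance_transform_edt(
        lung, sampling=volume.spacing, return_indices=True
    )
    border_dist_mm = float(dist_map[cz, cy, cx])
    pleural_pt = nearest[:, cz, cy, cx].astype(float)

    if f.pleural_contact and border_dist_mm > spec.diameter_mm:
        raise ValueError(
            f"pleural contact requested but center is {border_dist_mm:.1f} mm from the "
            f"pleura (> diameter {spec.diameter_mm:.1f} mm)"
        )

    # local working cube
    ext = np.maximum((1.9 * r_vox + 4).astype(int), 5)
    lo = np.maximum([cz, cy, cx] - ext, 0)
    hi = np.minimum([cz, cy, cx] + ext + 1, shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(*(np.arange(a, b, dtype=np.float64) for a, b in zip(lo, hi)), indexing="ij")
    # offsets in mm from the centre
    off = np.stack([(zz - cz) * spacing[0], (yy - cy) * spacing[1], (xx - cx) * spacing[2]])
    dist_mm = np.sqrt((off**2).sum(axis=0))
    r_mm = spec.diameter_mm / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(dist_mm > 0, off / dist_mm, 0.0)
    dirs_flat = dirs.reshape(3, -1)

    # ---- radial profile rho(direction), nominal 1.0 ----------------------
    rho = np.ones(dirs_flat.shape[1])
    if f.irregular_shape:
        rho = rho + 0.22 * _angular_field(dirs_flat, rng, degree=1)
    if f.lobulated:
        rho = rho + 0.18 * _angular_field(dirs_flat, rng, degree=2)
    if f.ragged:
        rho = rho + 0.12 * _angular_field(dirs_flat, rng, degree=4)
    rho = np.clip(rho, 0.55, 1.6).reshape(dist_mm.shape)

    # normalized radial coordinate u = dist / (r * rho); u <= 1 is inside
    with np.errstate(divide="ignore"):
        u = dist_mm / (r_mm * rho)
    if f.irregular_edge:
        # voxel-scale jitter of the boundary
        u = u + rng.uniform(-0.12, 0.12, size=u.shape)
    if f.polygonal:
        # facet the boundary with six random half-spaces
        for _ in range(6):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            plane = np.tensordot(n, off, axes=1)
            u = np.maximum(u, plane / (0.82 * r_mm))

    # ---- opacity / alpha --------------------------------------------------
    if f.ill_defined:
        alpha = np.clip((1.35 - u) / 0.7, 0.0, 1.0)
    else:
        alpha = (u <= 1.0).astype(np.float64)

    if f.opacity == "solid":
        intensity = np.full(u.shape, HU_SOLID)
    elif f.opacity == "pure_ggo":
        intensity = np.full(u.shape, HU_GGO)
    else:  # part-solid: GGO rim around a solid core
        intensity = np.where(u <= 0.55, HU_SOLID, HU_GGO)

    out = volume.copy()
    local = out.data[sl].astype(np.float64)
    changed = alpha > 0.05
    local = (1.0 - alpha) * local + alpha * intensity
    core_val = HU_SOLID if f.opacity != "pure_ggo" else HU_GGO

    # ---- spiculation: thin radial spikes ---------------------------------
    if f.spiculated:
        n_spikes = 10
        for _ in range(n_spikes):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            t = np.tensordot(d, off, axes=1)  # mm along the spike
            radial = np.sqrt(np.maximum((off**2).sum(axis=0) - t**2, 0.0))
            spike = (t > 0.5 * r_mm) & (t < 1.7 * r_mm) & (radial < 0.8)
            local[spike] = core_val
            changed |= spike

    # ---- internal characteristics ----------------------------------------
    def _focus(center_off_mm: np.ndarray, radius_mm: float) -> np.ndarray:
        d2 = ((off - center_off_mm[:, None, None, None]) ** 2).sum(axis=0)
        return d2 <= radius_mm**2

    if f.air_bronchogram:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        t = np.tensordot(axis, off, axes=1)
        radial = np.sqrt(np.maximum((off**2).sum(axis=0) - t**2, 0.0))
        channel = (radial < max(0.8, 0.08 * r_mm)) & (u <= 0.95)
        local[channel] = HU_AIR_LUNG
        changed |= channel

    if f.cavity:
        cav = _focus(np.array([0.1 * r_mm, 0.0, 0.0]), max(0.4 * r_mm, 1.1))
        cav &= u <= 0.9
        if not cav.any():  # guarantee at least the centre voxel
            cav = dist_mm <= spacing.min()
        local[cav] = HU_AIR_LUNG
        changed |= cav

    if f.calcification:
        # central-pattern calcification: a substantial dense core, as in
        # benign calcified granulomas
        calc = _focus(np.array([-0.2 * r_mm, 0.1 * r_mm, 0.0]), max(0.3 * r_mm, 1.2))
        calc &= u <= 0.9
        if not calc.any():
            calc = dist_mm <= spacing.min()
        local[calc] = HU_CALCIFICATION
        changed |= calc

    if f.fat:
        fat = _focus(np.array([0.0, -0.2 * r_mm, 0.2 * r_mm]), max(0.18 * r_mm, 1.1))
        fat &= u <= 0.9
        if not fat.any():
            fat = dist_mm <= spacing.min()
        local[fat] = HU_FAT
        changed |= fat

    out.data[sl] = local.astype(np.float32)

    # ---- external characteristics (may extend beyond the local cube) -----
    full_changed = np.zeros(shape, dtype=bool)
    full_changed[sl] = changed

    if f.pleural_contact or f.pleural_indentation:
        vec = pleural_pt - np.array([cz, cy, cx], dtype=float)
        seg_len = np.linalg.norm(vec * spacing)
        gz, gy, gx = _voxel_grid(shape)
        goff = np.stack(
            [(gz - cz) * spacing[0], (gy - cy) * spacing[1], (gx - cx) * spacing[2]]
        )
        if seg_len > 0:
            d = vec * spacing
            d /= np.linalg.norm(d)
            t = np.tensordot(d, goff, axes=1)
            radial = np.sqrt(np.maximum((goff**2).sum(axis=0) - t**2, 0.0))
            if f.pleural_contact:
                # soft-tissue bridge from the nodule surface to the pleura,
                # tapering outward, so the nodule touches the lung border
                taper = 0.6 * r_mm - 0.3 * r_mm * np.clip(t / max(seg_len + r_mm, 1e-6), 0, 1)
                bridge = (t >= 0) & (t <= seg_len + spacing.max()) & (radial <= np.maximum(taper, 0.8))
                bridge &= lung
                out.data[bridge] = core_val
                full_changed |= bridge
            if f.pleural_indentation:
                strand = (t >= 0.8 * r_mm) & (t <= seg_len + spacing.max()) & (radial <= 0.8)
                strand &= lung
                out.data[strand] = HU_STRAND
                full_changed |= strand
                notch = ((goff - (d * seg_len)[:, None, None, None]) ** 2).sum(axis=0) <= (
                    1.8 * spacing.max()
                ) ** 2
                notch &= lung
                out.data[notch] = HU_BACKGROUND
                full_changed |= notch

    box = Box.from_mask(full_changed)
    return out, replace(spec, rendered_box=box)


# ---------------------------------------------------------------------------
# sparse (localized) labels
# ---------------------------------------------------------------------------

def sparsify_labels(dense: LabelMap, box: Box, radius_mm: float) -> LabelMap:
    """Keep dense labels within `radius_mm` of the box centre; everything
    else becomes UNLABELED.  The input map is not modified."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    center = box.center_voxel()
    grids = _voxel_grid(dense.shape)
    d2 = sum(
        ((g - c) * s) ** 2 for g, c, s in zip(grids, center, dense.spacing)
    )
    keep = d2 <= radius_mm**2
    out = np.full(dense.shape, UNLABELED, dtype=np.int16)
    out[keep] = dense.data[keep]
    return LabelMap(out, dense.spacing)
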