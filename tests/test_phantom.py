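"""Phantom generator: anatomy contracts, nodule rendering rules, sparse labels."""

import numpy as np
import pytest

from pulmorep.findings import FindingVector
from pulmorep.phantom import (
    HU_AIR_LUNG,
    NoduleSpec,
    PhantomConfig,
    make_lung_phantom,
    render_nodule,
    sample_nodule_center,
    sparsify_labels,
)
from pulmorep.volume import UNLABELED, Box, LabelMap


@pytest.fixture(scope="module")
def phantom():
    cfg = PhantomConfig(n_lobes=2, segments_per_lobe=3, seed=0)
    return make_lung_phantom(cfg)


@pytest.fixture(scope="module")
def phantom_no_bronchi():
    """Bronchi-free phantom: rendering-geometry tests need a background of
    pure lung so nodule intensities are not confounded by cue tubes."""
    cfg = PhantomConfig(n_lobes=2, segments_per_lobe=3, render_bronchi=False, seed=0)
    return make_lung_phantom(cfg)


class TestMakeLungPhantom:
    def test_segment_ids_are_exactly_one_to_six(self, phantom):
        _, _, segs = phantom
        assert sorted(segs.labels().tolist()) == [1, 2, 3, 4, 5, 6]

    def test_determinism_bit_identical(self, phantom):
        v1, l1, s1 = phantom
        v2, l2, s2 = make_lung_phantom(PhantomConfig(n_lobes=2, segments_per_lobe=3, seed=0))
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(l1.data, l2.data)
        assert np.array_equal(s1.data, s2.data)

    def test_different_seed_differs(self, phantom):
        v1, _, _ = phantom
        v2, _, _ = make_lung_phantom(PhantomConfig(n_lobes=2, segments_per_lobe=3, seed=1))
        assert not np.array_equal(v1.data, v2.data)

    def test_zero_noise_single_hu_per_tissue(self):
        v, _, segs = make_lung_phantom(
            PhantomConfig(noise_sd=0, render_bronchi=False, seed=3)
        )
        assert set(np.unique(v.data[segs.data > 0])) == {HU_AIR_LUNG}
        assert set(np.unique(v.data[segs.data == 0])) == {0.0}

    def test_zero_noise_with_bronchi_two_tissue_classes(self):
        from pulmorep.phantom import HU_BRONCHUS

        v, _, segs = make_lung_phantom(PhantomConfig(noise_sd=0, seed=3))
        assert set(np.unique(v.data[segs.data > 0])) == {HU_AIR_LUNG, HU_BRONCHUS}

    def test_labels_partition_lung(self, phantom):
        _, lobes, segs = phantom
        # same support, no unlabeled voxels inside the lung
        assert ((segs.data > 0) == (lobes.data > 0)).all()
        # each lobe's segments are its own contiguous ID block
        for li in np.unique(lobes.data[lobes.data > 0]):
            ids = np.unique(segs.data[lobes.data == li])
            assert set(ids) == set(range((li - 1) * 3 + 1, li * 3 + 1))

    def test_full_scale_anatomy_available(self):
        cfg = PhantomConfig(grid_shape=(64, 64, 64), n_lobes=5, segments_per_lobe=3, seed=0)
        _, lobes, segs = make_lung_phantom(cfg)
        assert len(np.unique(lobes.data[lobes.data > 0])) == 5
        assert len(segs.labels()) == 15

    def test_rejects_grid_too_small_for_lobes(self):
        with pytest.raises(ValueError, match="grid too small"):
            PhantomConfig(grid_shape=(16, 16, 16), n_lobes=5)

    def test_rejects_tiny_grid(self):
        with pytest.raises(ValueError, match="grid_shape"):
            PhantomConfig(grid_shape=(8, 48, 48))


class TestRenderNodule:
    def _render(self, phantom, findings, diameter=9.0, min_border=8.0, seed=7):
        v, _, segs = phantom
        rng = np.random.default_rng(42)
        center = sample_nodule_center(segs, rng, min_border_mm=min_border)
        spec = NoduleSpec(center=center, diameter_mm=diameter, findings=findings, seed=seed)
        return render_nodule(v, segs, spec)

    def test_cavity_has_air_voxel_inside_box(self, phantom):
        vol, spec = self._render(phantom, FindingVector(cavity=True))
        region = vol.data[spec.rendered_box.slices]
        assert (region < -800).any()

    def test_calcification_has_high_voxel(self, phantom):
        vol, spec = self._render(phantom, FindingVector(calcification=True))
        assert (vol.data[spec.rendered_box.slices] >= 400).any()

    def test_solid_round_nodule_is_spherical(self, phantom_no_bronchi):
        """Sphericity of the rendered solid mask, via an independent
        marching-cubes surface-area + voxel-count oracle."""
        pytest.importorskip("skimage")
        from skimage.measure import marching_cubes, mesh_surface_area

        vol, spec = self._render(phantom_no_bronchi, FindingVector(), diameter=10.0)
        box = spec.rendered_box
        mask = (vol.data[box.slices] > -100).astype(float)
        volume_vox = mask.sum()
        verts, faces, _, _ = marching_cubes(np.pad(mask, 1), 0.5)
        area = mesh_surface_area(verts, faces)
        sphericity = np.pi ** (1 / 3) * (6 * volume_vox) ** (2 / 3) / area
        assert sphericity > 0.85  # pinned from seeded runs; an ideal ball gives ~0.99

    def test_pure_ggo_stays_subsolid(self, phantom_no_bronchi):
        vol, spec = self._render(phantom_no_bronchi, FindingVector(opacity="pure_ggo"))
        region = vol.data[spec.rendered_box.slices]
        assert region.max() <= -500

    def test_part_solid_has_core_and_rim(self, phantom):
        vol, spec = self._render(phantom, FindingVector(opacity="part_solid"), diameter=11.0)
        region = vol.data[spec.rendered_box.slices]
        assert (region > 0).any() and ((region > -700) & (region < -500)).any()

    def test_rendered_box_inside_grid_and_tight(self, phantom):
        v, _, _ = phantom
        vol, spec = self._render(phantom, FindingVector(spiculated=True, lobulated=True))
        box = spec.rendered_box
        assert box.inside(v.shape)
        assert (vol.data[box.slices] != v.data[box.slices]).any()

    def test_input_volume_untouched(self, phantom):
        v, _, _ = phantom
        before = v.data.copy()
        self._render(phantom, FindingVector(cavity=True))
        assert np.array_equal(v.data, before)

    def test_determinism(self, phantom):
        v1, s1 = self._render(phantom, FindingVector(irregular_shape=True, ragged=True))
        v2, s2 = self._render(phantom, FindingVector(irregular_shape=True, ragged=True))
        assert np.array_equal(v1.data, v2.data)
        assert s1.rendered_box == s2.rendered_box

    def test_pleural_contact_touches_border(self, phantom):
        v, _, segs = phantom
        rng = np.random.default_rng(5)
        center = sample_nodule_center(segs, rng, min_border_mm=1.0, max_border_mm=3.0)
        spec = NoduleSpec(center=center, diameter_mm=8.0,
                          findings=FindingVector(pleural_contact=True), seed=1)
        vol, out = render_nodule(v, segs, spec)
        # some rendered soft-tissue voxel is adjacent to a non-lung voxel
        changed = vol.data != v.data
        lung = segs.data > 0
        from scipy import ndimage
        border = lung & ~ndimage.binary_erosion(lung)
        assert (changed & border).any()

    def test_pleural_contact_too_far_errors(self, phantom):
        v, _, segs = phantom
        rng = np.random.default_rng(6)
        center = sample_nodule_center(segs, rng, min_border_mm=15.0)
        with pytest.raises(ValueError, match="pleural contact"):
            render_nodule(v, segs, NoduleSpec(center=center, diameter_mm=6.0,
                                              findings=FindingVector(pleural_contact=True)))

    def test_center_outside_lung_errors(self, phantom):
        v, _, segs = phantom
        with pytest.raises(ValueError, match="inside the lung"):
            render_nodule(v, segs, NoduleSpec(center=(0, 0, 0), diameter_mm=6.0))


class TestSparsifyLabels:
    def test_radius_covering_grid_is_identity(self, phantom):
        _, _, segs = phantom
        box = Box((20, 20, 20), (25, 25, 25))
        out = sparsify_labels(segs, box, radius_mm=1000.0)
        assert np.array_equal(out.data, segs.data)

    def test_tiny_radius_keeps_center_voxel_only(self, phantom):
        _, _, segs = phantom
        box = Box((20, 20, 20), (25, 25, 25))  # odd extent: integer centre
        out = sparsify_labels(segs, box, radius_mm=1e-6)
        labeled = np.argwhere(out.data != UNLABELED)
        assert labeled.shape == (1, 3) and (labeled[0] == (22, 22, 22)).all()

    def test_ball_count_matches_brute_force(self, phantom):
        _, _, segs = phantom
        box = Box((21, 23, 19), (26, 28, 24))
        radius = 10.0
        out = sparsify_labels(segs, box, radius)
        cz, cy, cx = box.center_voxel()
        count = 0
        for z in range(segs.shape[0]):
            for y in range(segs.shape[1]):
                for x in range(segs.shape[2]):
                    if (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius**2:
                        count += 1
        assert (out.data != UNLABELED).sum() == count

    def test_only_removes_information(self, phantom):
        _, _, segs = phantom
        box = Box((20, 20, 20), (25, 25, 25))
        out = sparsify_labels(segs, box, radius_mm=8.0)
        labeled = out.data != UNLABELED
        assert np.array_equal(out.data[labeled], segs.data[labeled])
        # idempotent at the same radius
        again = sparsify_labels(out, box, radius_mm=8.0)
        assert np.array_equal(again.data, out.data)
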