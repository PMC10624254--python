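"""Phantom generation and volume-assembly rules."""

import numpy as np
import pytest

from voxdosim.phantom import (
    DEFAULT_HEAD_TISSUES,
    SKIN_THICKNESS_MM,
    default_head_radii,
    make_layered_head,
    merge_with_priority,
    perturb_mask,
    resample_scalar,
    resample_volume,
    supplant_unassigned,
)
from voxdosim.segmetrics import dice
from voxdosim.volume import LabelVolume


class TestLayeredHead:
    def test_single_sphere_volume_matches_analytic(self):
        vol = make_layered_head([50.0], ["Muscle"], spacing=1.0)
        v_vox = int((vol.data == 1).sum()) * vol.voxel_volume_mm3
        v_true = 4.0 / 3.0 * np.pi * 50.0**3
        assert abs(v_vox - v_true) / v_true < 0.05

    def test_default_skin_thickness_is_one_mm(self):
        radii = default_head_radii(80.0)
        assert radii[0] - radii[1] == pytest.approx(SKIN_THICKNESS_MM)

    def test_five_layer_shells_nested_and_nonempty(self):
        vol = make_layered_head(default_head_radii(80.0), DEFAULT_HEAD_TISSUES,
                                spacing=2.0)
        boxes = {}
        for lab in range(1, 6):
            m = vol.data == lab
            assert m.any(), f"layer {lab} empty"
            idx = np.argwhere(m)
            boxes[lab] = (idx.min(axis=0), idx.max(axis=0))
        # outer layers bound inner layers
        for outer, inner in zip(range(1, 5), range(2, 6)):
            lo_o, hi_o = boxes[outer]
            lo_i, hi_i = boxes[inner]
            assert np.all(lo_o <= lo_i) and np.all(hi_o >= hi_i)

    @pytest.mark.parametrize("spacing", [2.0, 1.0, 0.5])
    def test_shell_volume_converges_with_refinement(self, spacing):
        vol = make_layered_head([40.0, 30.0], ["Skin", "Muscle"], spacing=spacing)
        v_shell = int((vol.data == 1).sum()) * vol.voxel_volume_mm3
        v_true = 4.0 / 3.0 * np.pi * (40.0**3 - 30.0**3)
        tol = {2.0: 0.10, 1.0: 0.05, 0.5: 0.025}[spacing]
        assert abs(v_shell - v_true) / v_true < tol

    def test_air_cavity_labeled_internal_air(self):
        vol = make_layered_head([40.0, 30.0], ["Skin", "Muscle"], spacing=2.0,
                                air_cavity=((0.0, 0.0, 0.0), 10.0))
        cav_lab = max(vol.labels)
        assert vol.labels[cav_lab] == "Air"
        assert (vol.data == cav_lab).any()

    def test_rejects_nondecreasing_radii(self):
        with pytest.raises(ValueError, match="decreasing"):
            make_layered_head([30.0, 30.0], ["Skin", "Muscle"], spacing=1.0)

    def test_rejects_spacing_coarser_than_inner_shell(self):
        with pytest.raises(ValueError, match="thickness"):
            make_layered_head([40.0, 39.0, 38.0], ["Skin", "Bone (Cortical)",
                                                   "Muscle"], spacing=3.0)

    def test_skin_snaps_to_voxel_on_coarse_grid(self):
        # 1 mm skin on a 2 mm grid: snapped outward, still non-empty
        vol = make_layered_head([40.0, 39.0, 20.0],
                                ["Skin", "Muscle", "Brain (grey matter)"],
                                spacing=2.0)
        assert (vol.data == 1).any()


class TestMergeWithPriority:
    def test_higher_label_wins_on_overlap(self):
        a = np.zeros((4, 4, 4), bool); a[:3] = True
        b = np.zeros((4, 4, 4), bool); b[1:] = True
        out = merge_with_priority([(3, a), (7, b)])
        assert (out.data[1:3] == 7).all()
        assert (out.data[0] == 3).all()

    def test_disjoint_masks_keep_labels(self):
        a = np.zeros((4, 4, 4), bool); a[0] = True
        b = np.zeros((4, 4, 4), bool); b[3] = True
        out = merge_with_priority([(2, a), (5, b)])
        assert (out.data[0] == 2).all() and (out.data[3] == 5).all()
        assert (out.data[1:3] == 0).all()

    def test_matches_per_voxel_max_oracle(self, rng):
        masks = [(int(lab), rng.random((6, 6, 6)) < 0.4) for lab in (1, 2, 3)]
        out = merge_with_priority(masks)
        expect = np.zeros((6, 6, 6), dtype=int)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    covering = [lab for lab, m in masks if m[i, j, k]]
                    expect[i, j, k] = max(covering) if covering else 0
        assert np.array_equal(out.data, expect)

    def test_order_independent_and_idempotent(self, rng):
        masks = [(lab, rng.random((5, 5, 5)) < 0.5) for lab in (4, 9, 2)]
        a = merge_with_priority(masks).data
        b = merge_with_priority(masks[::-1]).data
        assert np.array_equal(a, b)
        # re-merging the result's per-label masks reproduces it
        remerged = merge_with_priority(
            [(lab, a == lab) for lab in np.unique(a) if lab != 0]).data
        assert np.array_equal(a, remerged)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            merge_with_priority([(1, np.ones((3, 3, 3), bool)),
                                 (2, np.ones((4, 4, 4), bool))])


class TestSupplant:
    def _vol(self, data):
        labels = {int(v): f"t{v}" for v in np.unique(data) if v != 0}
        return LabelVolume(np.asarray(data, dtype=np.int32), (1.0, 1.0, 1.0),
                           labels=labels)

    def test_no_holes_is_identity(self):
        d = np.ones((4, 4, 4), dtype=np.int32)
        out = supplant_unassigned(self._vol(d), d > 0)
        assert np.array_equal(out.data, d)

    def test_single_hole_takes_nearest_label(self):
        d = np.zeros((5, 5, 5), dtype=np.int32)
        d[2, 2, 1] = 5          # nearest labeled voxel to the hole at (2,2,2)
        d[0, 0, 0] = 3
        body = np.zeros((5, 5, 5), bool)
        body[2, 2, 1] = body[2, 2, 2] = body[0, 0, 0] = True
        out = supplant_unassigned(self._vol(d), body)
        assert out.data[2, 2, 2] == 5

    def test_equidistant_tie_goes_to_smallest_label(self):
        d = np.zeros((5, 5, 5), dtype=np.int32)
        d[2, 2, 1] = 9
        d[2, 2, 3] = 2
        body = d > 0
        body[2, 2, 2] = True
        out = supplant_unassigned(self._vol(d), body)
        assert out.data[2, 2, 2] == 2

    def test_labeled_voxels_unchanged_and_no_holes_left(self, rng):
        d = (rng.random((8, 8, 8)) < 0.1).astype(np.int32)
        d *= rng.integers(1, 5, d.shape).astype(np.int32)
        if not d.any():
            d[0, 0, 0] = 1
        body = np.ones(d.shape, bool)
        vol = self._vol(d)
        out = supplant_unassigned(vol, body)
        assert (out.data[d > 0] == d[d > 0]).all()
        assert (out.data != 0).all()

    def test_rejects_empty_volume(self):
        d = np.zeros((3, 3, 3), dtype=np.int32)
        with pytest.raises(ValueError, match="no labeled voxel"):
            supplant_unassigned(self._vol(d), np.ones((3, 3, 3), bool))


class TestResample:
    def test_identity_at_same_spacing(self, rng):
        data = rng.random((9, 7, 5))
        out, sp = resample_scalar(data, 1.0, 1.0)
        assert np.allclose(out, data, atol=1e-12)

    def test_constant_preserved(self):
        out, _ = resample_scalar(np.full((11, 11), 3.25), 1.0, 0.7)
        assert np.allclose(out, 3.25, atol=1e-6)

    def test_ramp_downsample_matches_kernel_sum_oracle(self):
        # independent direct Lanczos-3 evaluation, written from the kernel
        # definition L(x) = sinc(x) sinc(x/3), taps renormalized at edges
        data = np.arange(24, dtype=float) ** 1.5
        out, _ = resample_scalar(data, 1.0, 2.0)

        def lanczos(x, a=3):
            if abs(x) >= a:
                return 0.0
            if x == 0:
                return 1.0
            import math
            return (math.sin(math.pi * x) / (math.pi * x)
                    * math.sin(math.pi * x / a) / (math.pi * x / a))

        expected = []
        for j in range(out.size):
            x = j * 2.0
            num = den = 0.0
            for i in range(data.size):
                w = lanczos(x - i)
                num += w * data[i]
                den += w
            expected.append(num / den)
        assert np.allclose(out, expected, atol=1e-9)

    def test_label_volume_stays_integral(self):
        vol = make_layered_head([20.0, 12.0], ["Skin", "Muscle"], spacing=1.0)
        out = resample_volume(vol, 2.0)
        assert np.issubdtype(out.data.dtype, np.integer)
        assert set(np.unique(out.data)) <= {0, 1, 2}
        # physical extent preserved within one voxel
        for ax in range(3):
            before = vol.shape[ax] * vol.spacing[ax]
            after = out.shape[ax] * out.spacing[ax]
            assert abs(before - after) <= 2.0 + 1e-9

    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            resample_volume(np.zeros((4, 4, 4)), 0.0, spacing=1.0)


class TestPerturbMask:
    @pytest.fixture
    def cube(self):
        m = np.zeros((16, 16, 16), bool)
        m[3:13, 3:13, 3:13] = True
        return m

    def test_zero_magnitude_is_identity(self, cube):
        out = perturb_mask(cube, "boundary-noise", 0, seed=1)
        assert np.array_equal(out, cube)
        assert dice(out, cube) == 1.0

    def test_erode_then_dilate_is_morphological_opening(self, cube):
        from scipy import ndimage
        k = 2
        opened = perturb_mask(perturb_mask(cube, "erode", k, seed=0),
                              "dilate", k, seed=0)
        struct = ndimage.generate_binary_structure(3, 1)
        oracle = ndimage.binary_opening(cube, structure=struct, iterations=k)
        assert np.array_equal(opened, oracle)
        # the cube interior survives opening
        assert opened[5:11, 5:11, 5:11].all()

    def test_fixed_seed_reproducible(self, cube):
        a = perturb_mask(cube, "boundary-noise", 1, seed=42)
        b = perturb_mask(cube, "boundary-noise", 1, seed=42)
        c = perturb_mask(cube, "boundary-noise", 1, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_boundary_noise_flips_only_near_surface(self, cube):
        out = perturb_mask(cube, "boundary-noise", 1, seed=7)
        changed = out ^ cube
        assert changed.any()
        assert not changed[5:11, 5:11, 5:11].any()

    def test_rejects_magnitude_exceeding_mask(self, cube):
        with pytest.raises(ValueError, match="exceeds"):
            perturb_mask(cube, "dilate", 99, seed=0)
        with pytest.raises(ValueError, match="annihilates"):
            perturb_mask(cube, "erode", 8, seed=0)
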