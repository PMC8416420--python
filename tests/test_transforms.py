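"""Rigid transforms, mask warping, overlap, and the two searches."""

import numpy as np
import pytest

from virtsamp.sampling import BlockMask, BlockSpec, make_slice_stack, place_block
from virtsamp.transforms import (
    DisplacementField,
    RigidTransform,
    ap_slab_search,
    apply_transform_to_mask,
    load_transform,
    move_mask,
    percent_overlap,
    resample_mask_to_grid,
    rigid_overlap_optimize,
    rotation_angle_deg,
    save_transform,
)
from virtsamp.volume import Grid


def box_mask(grid, lo, hi, **kw) -> BlockMask:
    data = np.zeros(grid.shape, dtype=np.uint8)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return BlockMask(grid, data, **kw)


class TestRigidTransform:
    def test_matrix_is_orthonormal(self, rng):
        t = RigidTransform(tuple(rng.uniform(-1, 1, 3)), (1.0, -2.0, 3.0), (5.0, 0.0, 0.0))
        r = t.matrix()[:3, :3]
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_inverse_composes_to_identity(self, rng):
        t = RigidTransform(tuple(rng.uniform(-0.5, 0.5, 3)), tuple(rng.uniform(-10, 10, 3)),
                           tuple(rng.uniform(-5, 5, 3)))
        assert np.allclose(t.matrix() @ t.inverse().matrix(), np.eye(4), atol=1e-9)

    def test_text_serialization_roundtrip(self, tmp_path):
        t = RigidTransform((0.1, -0.2, 0.05), (3.0, 1.0, -4.0), (1.0, 2.0, 3.0))
        path = tmp_path / "xfm.txt"
        save_transform(t, path)
        assert np.allclose(load_transform(path), t.matrix(), atol=1e-9)


class TestApplyTransform:
    def test_identity_is_identity(self, mm2_grid, rng):
        m = box_mask(mm2_grid, (5, 6, 7), (15, 16, 17))
        out = apply_transform_to_mask(m, RigidTransform(), mm2_grid)
        assert np.array_equal(out.data, m.data)

    def test_one_voxel_translation_shifts_indices(self, mm2_grid):
        m = box_mask(mm2_grid, (5, 6, 7), (15, 16, 17))
        t = RigidTransform(translation=(2.0, 0.0, 0.0))  # one voxel pitch
        out = move_mask(m, t)
        assert out.voxel_count == m.voxel_count
        assert np.array_equal(out.data[6:16, 6:16, 7:17], m.data[5:15, 6:16, 7:17])

    def test_composed_half_voxel_roundtrip_is_identity(self, mm2_grid):
        m = box_mask(mm2_grid, (5, 6, 7), (15, 16, 17))
        fwd = RigidTransform(translation=(1.0, 0.0, 0.0)).matrix()
        back = RigidTransform(translation=(-1.0, 0.0, 0.0)).matrix()
        out = apply_transform_to_mask(m, back @ fwd, mm2_grid)
        assert np.array_equal(out.data, m.data)

    def test_empty_result_raises_unless_allowed(self, mm2_grid):
        m = box_mask(mm2_grid, (5, 6, 7), (8, 9, 10))
        t = RigidTransform(translation=(500.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="empty"):
            move_mask(m, t)
        out = move_mask(m, t, allow_empty=True)
        assert out.voxel_count == 0

    def test_constant_displacement_field_equals_translation(self, mm2_grid):
        m = box_mask(mm2_grid, (5, 6, 7), (15, 16, 17))
        vec = np.zeros(mm2_grid.shape + (3,))
        vec[..., 0] = -4.0  # pull: target + v = source, i.e. forward shift +4
        field = DisplacementField(mm2_grid, vec)
        via_field = apply_transform_to_mask(m, field, mm2_grid)
        via_rigid = move_mask(m, RigidTransform(translation=(4.0, 0.0, 0.0)))
        assert np.array_equal(via_field.data, via_rigid.data)


class TestPercentOverlap:
    def test_identical_masks_100(self, mm2_grid):
        m = box_mask(mm2_grid, (5, 6, 7), (15, 16, 17))
        assert percent_overlap(m, m) == 100.0

    def test_disjoint_masks_0(self, mm2_grid):
        a = box_mask(mm2_grid, (2, 2, 2), (6, 6, 6))
        b = box_mask(mm2_grid, (20, 20, 20), (30, 30, 30))
        assert percent_overlap(a, b) == 0.0

    def test_partial_overlap_hand_counted(self, mm2_grid):
        # reference of 200 voxels, sample covering exactly 50 of them
        ref = box_mask(mm2_grid, (10, 10, 10), (20, 14, 15))  # 10*4*5 = 200
        samp = box_mask(mm2_grid, (10, 10, 10), (15, 12, 15))  # 5*2*5 = 50 inside
        assert percent_overlap(samp, ref) == pytest.approx(25.0)

    def test_empty_reference_rejected(self, mm2_grid):
        a = box_mask(mm2_grid, (2, 2, 2), (6, 6, 6))
        b = BlockMask(mm2_grid, np.zeros(mm2_grid.shape, dtype=np.uint8))
        with pytest.raises(ValueError, match="empty reference"):
            percent_overlap(a, b)

    def test_denominator_variants_consistent(self, mm2_grid):
        a = box_mask(mm2_grid, (5, 5, 5), (15, 15, 15))
        b = box_mask(mm2_grid, (10, 5, 5), (20, 15, 15))
        inter = 5 * 10 * 10
        assert percent_overlap(a, b, "reference") == pytest.approx(100 * inter / 1000)
        assert percent_overlap(a, b, "sample") == pytest.approx(100 * inter / 1000)
        assert percent_overlap(a, b, "union") == pytest.approx(100 * inter / 1500)
        assert percent_overlap(a, b, "dice") == pytest.approx(100 * 2 * inter / 2000)

    def test_invariant_under_common_rigid_motion(self):
        g = Grid((60, 70, 60), np.eye(4))
        stack = make_slice_stack(g, 4.0)
        a = place_block(stack, BlockSpec("A", 6, (30.0, 30.0), (20.0, 16.0)))
        b = place_block(stack, BlockSpec("B", 6, (34.0, 33.0), (20.0, 16.0)))
        before = percent_overlap(a, b)
        t = RigidTransform((0.05, -0.04, 0.08), (3.0, -2.0, 4.0), (30.0, 30.0, 30.0))
        after = percent_overlap(move_mask(a, t), move_mask(b, t))
        assert abs(after - before) <= 2.0  # re-voxelization tolerance


class TestApSlabSearch:
    def _stack(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = [-39, -59, -39]
        g = Grid((40, 60, 40), aff)
        return make_slice_stack(g, 4.0)

    def test_identical_masks_stay_put(self):
        stack = self._stack()
        blk = place_block(stack, BlockSpec("MFG", 10, (0.0, 0.0)))
        res = ap_slab_search(blk, blk, stack)
        assert res.info["slab_offset"] == 0
        assert res.percent_overlap == 100.0

    def test_known_two_slab_offset_recovered(self):
        stack = self._stack()
        samp = place_block(stack, BlockSpec("MFG", 10, (0.0, 0.0)))
        ref = place_block(stack, BlockSpec("MFG", 8, (0.0, 0.0)))
        ref.method = "reference"
        res = ap_slab_search(samp, ref, stack)
        assert res.info["slab_offset"] == -2
        assert res.percent_overlap == 100.0

    def test_inplane_disjoint_defaults_to_zero_offset(self):
        stack = self._stack()
        samp = place_block(stack, BlockSpec("A", 10, (-22.0, -22.0), (12.0, 12.0)))
        ref = place_block(stack, BlockSpec("B", 10, (22.0, 22.0), (12.0, 12.0)))
        res = ap_slab_search(samp, ref, stack)
        assert res.percent_overlap == 0.0
        assert res.info["slab_offset"] == 0

    def test_matches_exhaustive_enumeration(self, rng):
        # oracle: literally translate the mask to every admissible slab and count
        stack = self._stack()
        for _ in range(10):
            s_slab = int(rng.integers(3, stack.n_slabs - 3))
            r_slab = int(rng.integers(3, stack.n_slabs - 3))
            samp = place_block(
                stack, BlockSpec("A", s_slab, tuple(rng.uniform(-8, 8, 2)), (20.0, 16.0))
            )
            ref = place_block(
                stack, BlockSpec("B", r_slab, tuple(rng.uniform(-8, 8, 2)), (20.0, 16.0))
            )
            res = ap_slab_search(samp, ref, stack)
            best = -1.0
            for k in range(-s_slab, stack.n_slabs - s_slab):
                shifted = np.zeros_like(samp.data)
                nv = int(round(k * stack.thickness_mm / 2.0))  # 2 mm voxels
                if nv == 0:
                    shifted = samp.data.copy()
                elif nv > 0:
                    shifted[:, nv:, :] = samp.data[:, :-nv, :]
                else:
                    shifted[:, :nv, :] = samp.data[:, -nv:, :]
                if shifted.sum() == 0:
                    continue
                ov = 100.0 * ((shifted > 0) & (ref.data > 0)).sum() / (ref.data > 0).sum()
                best = max(best, ov)
            assert res.percent_overlap == pytest.approx(best, abs=1e-9)


class TestRigidOptimize:
    def test_identity_pair_returns_identity(self, mm2_grid):
        blk = box_mask(mm2_grid, (10, 12, 10), (24, 14, 22))
        res = rigid_overlap_optimize(blk, blk, seed=0)
        assert res.percent_overlap == 100.0
        assert res.transform.param_norm() < 1e-6

    def test_known_rotation_translation_recovered(self):
        # 8 degrees about the AP axis plus 6 mm translation, 1 mm grid
        aff = np.eye(4)
        aff[:3, 3] = [-60, -70, -60]
        g = Grid((121, 141, 121), aff)
        stack = make_slice_stack(g, 4.0)
        blk = place_block(stack, BlockSpec("MFG", 17, (0.0, 0.0)))
        true = RigidTransform(
            (0.0, np.radians(8.0), 0.0), (4.0, 2.0, -4.0), tuple(blk.centroid_world())
        )
        ref = move_mask(blk, true)
        res = rigid_overlap_optimize(blk, ref, seed=0)
        assert res.percent_overlap >= 95.0
        assert rotation_angle_deg(res.transform, true) <= 1.5
        c = blk.centroid_world()
        err = np.linalg.norm(res.transform.apply(c)[0] - true.apply(c)[0])
        assert err <= 1.0  # one voxel

    def test_never_below_guided_start(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = [-39, -59, -39]
        g = Grid((40, 60, 40), aff)
        stack = make_slice_stack(g, 4.0)
        samp = place_block(stack, BlockSpec("A", 12, (2.0, 3.0)))
        ref = move_mask(
            place_block(stack, BlockSpec("A", 9, (0.0, 0.0))),
            RigidTransform((0.03, 0.02, -0.04), (1.0, 0.5, -1.0), (0.0, 0.0, 0.0)),
        )
        guided = ap_slab_search(samp, ref, stack)
        res = rigid_overlap_optimize(samp, ref, guided=guided, seed=0)
        assert res.percent_overlap >= guided.percent_overlap
        assert guided.percent_overlap >= percent_overlap(samp, ref)


def test_resample_mask_between_grids_preserves_geometry(mm2_grid):
    blk = box_mask(mm2_grid, (10, 10, 10), (20, 18, 20))
    fine_aff = mm2_grid.affine.copy()
    fine_aff[:3, :3] /= 2.0
    fine = Grid(tuple(2 * s for s in mm2_grid.shape), fine_aff)
    out = resample_mask_to_grid(blk, fine)
    # 8x the voxel count up to a boundary shell
    assert abs(out.voxel_count - 8 * blk.voxel_count) / (8 * blk.voxel_count) < 0.2
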