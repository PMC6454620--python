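import numpy as np
import pytest

from memseg3d.shape_features import (
    cell_surface_area,
    cell_volume,
    classify_boundary_cells,
    interface_ratio_matrix,
    match_labels,
    multilabel_dice,
    neighbor_face_counts,
    per_cell_dice,
)
from memseg3d.stack_io import LabelVolume, NucleusRecord

from .oracles import dice_by_sets


def _ball_volume(shape, center, r, label=1):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    ball = sum((g - c) ** 2 for g, c in zip(grids, center)) <= r * r
    return LabelVolume(ball.astype(np.int32) * label)


class TestVolume:
    def test_unit_voxels(self):
        vol = np.zeros((5, 5, 5), dtype=np.int32)
        vol.ravel()[:10] = 1
        assert cell_volume(LabelVolume(vol), 1, (1, 1, 1)) == 10.0

    def test_anisotropic_spacing(self):
        vol = np.zeros((5, 5, 5), dtype=np.int32)
        vol.ravel()[:10] = 1
        assert cell_volume(LabelVolume(vol), 1, (0.5, 0.5, 1.0)) == 2.5

    def test_phantom_ellipsoid_close_to_analytic(self):
        a, b, c = 9.0, 7.0, 5.0
        grids = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        ell = sum(((g - 12) / s) ** 2 for g, s in zip(grids, (a, b, c))) <= 1
        vol = LabelVolume(ell.astype(np.int32))
        analytic = 4 / 3 * np.pi * a * b * c
        assert cell_volume(vol, 1, (1, 1, 1)) == pytest.approx(analytic, rel=0.05)

    def test_volumes_partition_the_grid(self, small_phantom):
        t = small_phantom.truth
        total = sum(cell_volume(t, int(l), (1, 1, 1)) for l in t.cell_labels())
        assert total + (t.labels == 0).sum() == np.prod(t.shape)

    def test_absent_label_rejected(self):
        with pytest.raises(ValueError):
            cell_volume(LabelVolume(np.ones((2, 2, 2), dtype=np.int32)), 5)


class TestSurfaceArea:
    def test_single_voxel_cube(self):
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[1, 1, 1] = 1
        assert cell_surface_area(LabelVolume(vol), 1, (1, 1, 1)) == 6.0

    def test_two_voxel_bar(self):
        vol = np.zeros((4, 3, 3), dtype=np.int32)
        vol[1:3, 1, 1] = 1
        assert cell_surface_area(LabelVolume(vol), 1, (1, 1, 1)) == 10.0

    def test_sphere_face_count_vs_isosurface(self):
        """Face counting carries the ~1.5 voxelization factor; the
        triangulated isosurface tracks the analytic 4*pi*r^2 within 5%."""
        vol = _ball_volume((25, 25, 25), (12, 12, 12), 10)
        analytic = 4 * np.pi * 10 ** 2
        faces = cell_surface_area(vol, 1, (1, 1, 1), method="faces")
        iso = cell_surface_area(vol, 1, (1, 1, 1), method="isosurface")
        assert faces / analytic == pytest.approx(1.5, abs=0.1)
        assert iso == pytest.approx(analytic, rel=0.05)

    def test_grid_border_faces_counted(self):
        vol = np.ones((2, 2, 2), dtype=np.int32)
        assert cell_surface_area(LabelVolume(vol), 1, (1, 1, 1)) == 24.0


class TestNeighborsAndBoundary:
    def test_face_counts_symmetric(self, small_phantom):
        t = small_phantom.truth
        labs = [int(l) for l in t.cell_labels()]
        counts = {l: neighbor_face_counts(t, l) for l in labs}
        for a in labs:
            for b, n in counts[a].items():
                if b == 0:
                    continue
                assert counts[b][a] == n

    def test_27_cell_block_has_one_interior(self):
        core = np.arange(1, 28, dtype=np.int32).reshape(3, 3, 3)
        vol = np.zeros((5, 5, 5), dtype=np.int32)
        vol[1:4, 1:4, 1:4] = core
        flags = classify_boundary_cells(LabelVolume(vol))
        interior = [l for l, b in flags.items() if not b]
        assert interior == [14]  # the central label

    def test_single_cell_in_background_is_boundary(self):
        vol = _ball_volume((10, 10, 10), (5, 5, 5), 3)
        assert classify_boundary_cells(vol)[1] is True

    def test_phantom_split_matches_adjacency(self, small_phantom):
        t = small_phantom.truth
        flags = classify_boundary_cells(t)
        for l in t.cell_labels():
            touches_bg = 0 in neighbor_face_counts(t, int(l))
            # 26-adjacency can only add boundary cells over face adjacency
            if touches_bg:
                assert flags[int(l)]


class TestInterfaceRatios:
    def _records(self, labels, time=1):
        return [
            NucleusRecord(time, f"C{l}", l, (1.0, 1.0, 1.0)) for l in labels
        ]

    def test_single_neighbor_column_is_one(self):
        vol = np.zeros((4, 2, 2), dtype=np.int32)
        vol[:2], vol[2:] = 1, 2
        df = interface_ratio_matrix([(1, LabelVolume(vol))], "C1", self._records([1, 2]))
        assert df.loc["C2", 1] == pytest.approx(1.0)

    def test_symmetric_sandwich_splits_evenly(self):
        vol = np.zeros((6, 4, 4), dtype=np.int32)
        vol[:2], vol[2:4], vol[4:] = 2, 1, 3
        df = interface_ratio_matrix([(1, LabelVolume(vol))], "C1", self._records([1, 2, 3]))
        assert df.loc["C2", 1] == pytest.approx(0.5)
        assert df.loc["C3", 1] == pytest.approx(0.5)

    def test_engineered_contact_areas(self):
        """Contacts built with 30/50/20 shared faces give those ratios."""
        vol = np.zeros((10, 10, 4), dtype=np.int32)
        vol[:, :, 1] = 1
        vol[0:3, :, 0] = 2    # 30 faces with cell 1
        vol[3:8, :, 0] = 3    # 50 faces
        vol[8:10, :, 0] = 4   # 20 faces
        df = interface_ratio_matrix(
            [(1, LabelVolume(vol))], "C1", self._records([1, 2, 3, 4]),
            include_background=False,
        )
        assert df.loc["C2", 1] == pytest.approx(0.3, abs=0.05)
        assert df.loc["C3", 1] == pytest.approx(0.5, abs=0.05)
        assert df.loc["C4", 1] == pytest.approx(0.2, abs=0.05)

    def test_columns_sum_to_one_over_time(self, small_phantom):
        t = small_phantom.spec.time
        recs = small_phantom.lineage
        focal = next(r.name for r in recs if r.time == t)
        df = interface_ratio_matrix(
            [(t, small_phantom.truth)], focal, recs, include_background=True
        )
        np.testing.assert_allclose(df.sum(axis=0).to_numpy(), 1.0, atol=1e-9)

    def test_absent_focal_time_omitted(self):
        vol = np.zeros((4, 2, 2), dtype=np.int32)
        vol[:2], vol[2:] = 1, 2
        df = interface_ratio_matrix(
            [(1, LabelVolume(vol)), (2, LabelVolume(vol))],
            "C1",
            self._records([1, 2], time=1),  # no records at t=2
        )
        assert list(df.columns) == [1]


class TestMultilabelDice:
    def test_perfect_overlap(self, small_phantom):
        assert multilabel_dice(small_phantom.truth, small_phantom.truth) == 1.0

    def test_disjoint_supports(self):
        a = np.zeros((4, 4, 4), dtype=np.int32)
        b = np.zeros_like(a)
        a[:2], b[2:] = 1, 1
        assert multilabel_dice(LabelVolume(a), LabelVolume(b)) == 0.0

    def test_hand_case_three_quarters(self):
        """8-voxel truth cell, 6 recovered plus 2 stray: 2*6/(8+8) = 0.75."""
        truth = np.zeros((4, 4, 4), dtype=np.int32)
        truth[0:2, 0:2, 0:2] = 1
        seg = np.zeros_like(truth)
        seg[0:2, 0:2, 0:2] = 1
        seg[0, 0, 0] = 0
        seg[1, 1, 1] = 0
        seg[3, 3, 2:4] = 1
        assert multilabel_dice(LabelVolume(truth), LabelVolume(seg)) == pytest.approx(0.75)

    def test_symmetric_under_swap_with_bijection(self):
        """When truth and segmentation carry the same cells under permuted
        labels plus disagreement voxels, the score is direction-free."""
        rng = np.random.default_rng(9)
        a = rng.integers(1, 4, size=(6, 6, 6)).astype(np.int32)  # no background
        b = ((a + 1) % 3 + 1).astype(np.int32)                   # permuted labels
        b[0, 0] = a[0, 0]                                        # some disagreement
        va, vb = LabelVolume(a), LabelVolume(b)
        assert multilabel_dice(va, vb) == pytest.approx(multilabel_dice(vb, va))

    def test_label_permutation_recovered_by_matching(self, small_phantom):
        t = small_phantom.truth
        perm = np.zeros(t.labels.max() + 1, dtype=np.int32)
        labs = t.cell_labels()
        perm[labs] = np.roll(labs, 1)
        assert multilabel_dice(t, LabelVolume(perm[t.labels])) == 1.0

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            truth = rng.integers(0, 4, size=(5, 5, 5)).astype(np.int32)
            seg = rng.integers(0, 4, size=(5, 5, 5)).astype(np.int32)
            vt, vs = LabelVolume(truth), LabelVolume(seg)
            expected = dice_by_sets(truth, seg, match_labels(vt, vs))
            assert multilabel_dice(vt, vs) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multilabel_dice(
                LabelVolume(np.ones((2, 2, 2), dtype=np.int32)),
                LabelVolume(np.ones((3, 3, 3), dtype=np.int32)),
            )

    def test_per_cell_dice_bounds(self, small_phantom):
        pc = per_cell_dice(small_phantom.truth, small_phantom.truth)
        assert all(v == 1.0 for v in pc.values())
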