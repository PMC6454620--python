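import numpy as np
import pytest

from memseg3d.preprocess import (
    HessianEigensystem,
    StructureTag,
    binarize,
    build_intensity_matrix,
    classify_structure,
    enhance_membrane,
    extract_threshold_line,
    gaussian_smooth,
    hessian_eigensystem,
    normalize_slices,
)
from memseg3d.stack_io import IntensityStack


def _discrete_gauss_center(sigma: float) -> float:
    # the truncated, normalized sampled-Gaussian weight at 0 (radius 4*sigma)
    r = int(4.0 * sigma + 0.5)
    x = np.arange(-r, r + 1)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w[r] / w.sum()


class TestGaussianSmooth:
    def test_zero_sigma_is_identity(self):
        stack = IntensityStack(np.random.default_rng(0).random((5, 5, 5)))
        out = gaussian_smooth(stack, 0.0)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_constant_preserved(self):
        out = gaussian_smooth(IntensityStack(np.full((6, 6, 6), 2.5)), 1.3)
        np.testing.assert_allclose(out.voxels, 2.5)

    def test_impulse_center_weight(self):
        """A single bright voxel smooths to the separable kernel's central
        weight, computed independently from the sampled Gaussian."""
        vox = np.zeros((15, 15, 15))
        vox[7, 7, 7] = 1000.0
        out = gaussian_smooth(IntensityStack(vox), 1.0)
        expected = 1000.0 * _discrete_gauss_center(1.0) ** 3
        assert out.voxels[7, 7, 7] == pytest.approx(expected, rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(IntensityStack(np.zeros((3, 3, 3))), -1.0)


class TestIntensityMatrix:
    def test_uniform_slice_single_bin(self):
        vox = np.zeros((4, 4, 3))
        vox[:, :, 1] = 50.0
        mat = build_intensity_matrix(IntensityStack(vox), n_bins=8, background_cutoff=1.0)
        assert (mat.counts[1] > 0).sum() == 1

    def test_cutoff_above_max_flags_empty_rows(self):
        vox = np.zeros((4, 4, 3))
        vox[:, :, 0] = 10.0
        vox[:, :, 1] = 60.0
        mat = build_intensity_matrix(IntensityStack(vox), n_bins=8, background_cutoff=20.0)
        assert mat.empty_slices[0] and not mat.empty_slices[1]
        assert mat.counts[0].sum() == 0

    def test_two_valued_slice_mass_split(self):
        """30% of the foreground at one value, 70% at another: the raw row
        splits its mass 0.3 / 0.7 before smoothing."""
        vox = np.zeros((10, 10, 1))
        vox.ravel()[:30] = 40.0
        vox.ravel()[30:] = 80.0
        mat = build_intensity_matrix(IntensityStack(vox), n_bins=4, background_cutoff=1.0)
        row = mat.counts[0] / mat.counts[0].sum()
        assert sorted(row[row > 0]) == pytest.approx([0.3, 0.7])

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            build_intensity_matrix(IntensityStack(np.ones((3, 3, 3))), n_bins=1)


class TestThresholdLine:
    def _matrix(self, vox, **kw):
        return build_intensity_matrix(IntensityStack(vox), **kw)

    def test_identical_slices_give_constant_line(self):
        rng = np.random.default_rng(2)
        sl = rng.random((12, 12)) * 100
        vox = np.dstack([sl] * 6)
        mat = self._matrix(vox, n_bins=16, background_cutoff=1.0)
        line = extract_threshold_line(mat, 2.0)
        assert np.ptp(line) == 0

    def test_line_at_largest_qualifying_bin(self):
        """With counts decreasing in intensity, the line sits at the last
        bin whose smoothed count still clears the threshold."""
        vox = np.concatenate(
            [np.full(60, 10.0), np.full(30, 30.0), np.full(10, 50.0)]
        ).reshape(10, 10, 1)
        mat = self._matrix(vox, n_bins=3, background_cutoff=1.0, smooth_sigma=(0, 0))
        line = extract_threshold_line(mat, 25.0)
        assert line[0] == pytest.approx(mat.bin_centers[1])

    def test_attenuated_phantom_line_tracks_decay(self, clean_phantom):
        """Across mirror slices the line ratio follows the per-slice decay
        factor within 10%."""
        sm = gaussian_smooth(clean_phantom.membrane, 1.0)
        mat = build_intensity_matrix(sm, n_bins=64)
        per = mat.counts.sum(axis=1)
        line = extract_threshold_line(mat, 0.02 * np.median(per[per > 0]))
        atten = clean_phantom.spec.z_attenuation
        nz = len(line)
        bulk = per >= 0.5 * np.median(per[per > 0])
        checked = 0
        for z in range(nz // 2):
            zm = nz - 1 - z
            if not (bulk[z] and bulk[zm]):
                continue
            expected = atten ** (zm - z)
            assert line[zm] / line[z] == pytest.approx(expected, rel=0.10)
            checked += 1
        assert checked >= 5

    def test_unreachable_threshold_rejected(self):
        vox = np.full((4, 4, 2), 9.0)
        mat = self._matrix(vox, n_bins=4, background_cutoff=1.0)
        with pytest.raises(ValueError):
            extract_threshold_line(mat, 1e9)


class TestNormalizeSlices:
    def test_constant_line_is_identity(self):
        stack = IntensityStack(np.random.default_rng(3).random((4, 4, 6)))
        out = normalize_slices(stack, np.full(6, 50.0))
        np.testing.assert_allclose(out.voxels, stack.voxels)

    def test_two_slice_ratio(self):
        vox = np.ones((3, 3, 2))
        out = normalize_slices(IntensityStack(vox), np.array([100.0, 50.0]))
        np.testing.assert_allclose(out.voxels[:, :, 0], 1.0)
        np.testing.assert_allclose(out.voxels[:, :, 1], 2.0)

    def test_midline_slice_untouched(self):
        vox = np.ones((2, 2, 5))
        line = np.array([100.0, 90.0, 80.0, 70.0, 60.0])
        out = normalize_slices(IntensityStack(vox), line)
        np.testing.assert_allclose(out.voxels[:, :, 2], 1.0)  # midline
        np.testing.assert_allclose(out.voxels[:, :, 3], 90.0 / 70.0)
        np.testing.assert_allclose(out.voxels[:, :, 4], 100.0 / 60.0)

    def test_idempotent_on_symmetric_line(self):
        stack = IntensityStack(np.random.default_rng(4).random((4, 4, 6)) + 1)
        line = np.array([80.0, 60.0, 40.0, 40.0, 60.0, 80.0])
        once = normalize_slices(stack, line)
        twice = normalize_slices(once, line)
        np.testing.assert_allclose(twice.voxels, once.voxels)

    def test_dim_deep_direction_inverts_factor(self):
        vox = np.ones((2, 2, 2))
        out = normalize_slices(IntensityStack(vox), np.array([100.0, 50.0]),
                               direction="dim_deep")
        np.testing.assert_allclose(out.voxels[:, :, 1], 0.5)

    def test_zero_line_clamped_with_warning(self):
        vox = np.ones((2, 2, 2))
        with pytest.warns(UserWarning, match="clamped"):
            out = normalize_slices(IntensityStack(vox), np.array([100.0, 0.0]))
        np.testing.assert_allclose(out.voxels, 1.0)


class TestHessian:
    def test_constant_stack_near_zero_eigenvalues(self):
        # truncated sampled-derivative kernels leave a ~1e-4 relative residual
        eigs = hessian_eigensystem(IntensityStack(np.full((8, 8, 8), 5.0)), 1.0)
        np.testing.assert_allclose(eigs.eigenvalues, 0.0, atol=5e-3)

    def test_quadratic_in_z(self):
        """f = z^2 has Hessian diag(0, 0, 2); the dominant eigenvector is
        the z axis."""
        nx = 20
        z = np.arange(nx, dtype=float)
        vox = np.broadcast_to(z ** 2, (nx, nx, nx)).copy()
        eigs = hessian_eigensystem(IntensityStack(vox), 1.5, compute_eigenvectors=True)
        c = (10, 10, 10)
        np.testing.assert_allclose(eigs.eigenvalues[c], [0.0, 0.0, 2.0], atol=0.05)
        e3 = eigs.eigenvectors[c][:, 2]
        assert abs(e3[2]) == pytest.approx(1.0, abs=1e-6)

    def test_eigenvalue_ordering_and_trace(self):
        """|l1| <= |l2| <= |l3| everywhere; their sum equals the Laplacian."""
        from scipy import ndimage as ndi

        rng = np.random.default_rng(6)
        vox = ndi.gaussian_filter(rng.random((12, 12, 12)) * 100, 1.0)
        stack = IntensityStack(vox)
        eigs = hessian_eigensystem(stack, 1.0)
        a = np.abs(eigs.eigenvalues)
        assert (a[..., 0] <= a[..., 1] + 1e-12).all()
        assert (a[..., 1] <= a[..., 2] + 1e-12).all()
        lap = sum(
            ndi.gaussian_filter(vox, 1.0, order=tuple(2 * (ax == i) for ax in range(3)))
            for i in range(3)
        )
        np.testing.assert_allclose(eigs.eigenvalues.sum(axis=-1), lap, atol=1e-8)

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(7)
        from scipy import ndimage as ndi

        vox = ndi.gaussian_filter(rng.random((8, 8, 8)), 1.0)
        eigs = hessian_eigensystem(IntensityStack(vox), 1.0, compute_eigenvectors=True)
        v = eigs.eigenvectors
        gram = np.einsum("...ij,...ik->...jk", v, v)
        np.testing.assert_allclose(gram, np.broadcast_to(np.eye(3), gram.shape), atol=1e-10)


class TestEnhanceAndBinarize:
    def test_degenerate_zero_stack(self):
        eigs = hessian_eigensystem(IntensityStack(np.zeros((6, 6, 6))), 1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            out = enhance_membrane(eigs)
        np.testing.assert_array_equal(out.voxels, 0.0)

    def test_range_and_argmax(self, plane_stack):
        stack, _ = plane_stack
        enh = enhance_membrane(hessian_eigensystem(stack, 1.0))
        assert enh.voxels.min() >= 0 and enh.voxels.max() == 1.0

    def test_plane_brighter_than_ball_interior(self):
        """Membrane enhancement favors the sheet over the blob interior."""
        from scipy import ndimage as ndi

        vox = np.zeros((32, 32, 32))
        vox[:, :, 10] = 100.0
        X, Y, Z = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
        ball = (X - 16) ** 2 + (Y - 16) ** 2 + (Z - 24) ** 2 <= 16
        vox[ball] = 100.0
        stack = IntensityStack(ndi.gaussian_filter(vox, 1.0))
        enh = enhance_membrane(hessian_eigensystem(stack, 1.0)).voxels
        interior = (X - 16) ** 2 + (Y - 16) ** 2 + (Z - 24) ** 2 <= 4
        assert enh[:, :, 10].mean() > enh[interior].mean()

    def test_plane_recall_at_half_threshold(self, plane_stack):
        stack, mask = plane_stack
        enh = enhance_membrane(hessian_eigensystem(stack, 1.0))
        out = binarize(enh, 0.5)
        assert (out & mask).sum() / mask.sum() >= 0.9

    def test_binarize_boundaries(self, plane_stack):
        stack, _ = plane_stack
        enh = enhance_membrane(hessian_eigensystem(stack, 1.0))
        assert binarize(enh, 0.0).all()
        with pytest.raises(ValueError):
            binarize(enh, 1.1)


class TestClassifyStructure:
    @pytest.mark.parametrize(
        "eigvals, tag",
        [
            ((0.1, 0.2, 5.0), StructureTag.PLANE),
            ((0.5, 2.0, 3.0), StructureTag.STICK),
            ((2.0, 3.0, 4.0), StructureTag.BALL),
            ((0.1, 0.2, 0.3), StructureTag.NONE),
        ],
    )
    def test_magnitude_rules(self, eigvals, tag):
        eigs = HessianEigensystem(np.array(eigvals).reshape(1, 1, 1, 3))
        assert classify_structure(eigs, 1.0)[0, 0, 0] == tag
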