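import numpy as np
import pytest

import splenotex as st
from splenotex.glcm import (GLCM2, GLCM3, DEFAULT_ANGLES, displacement_offsets,
                            find_peak, texture_curves)


def glcm3d_oracle(vol, dx, dy, dz, levels):
    """Brute-force triple loop over every voxel, skipping out-of-bounds."""
    nz, ny, nx = vol.shape
    counts = np.zeros((levels, levels, levels), dtype=np.int64)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                x2, y2 = x + dx, y + dy
                z3 = z + dz
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z3 < nz):
                    continue
                counts[vol[z, y, x], vol[z, y2, x2], vol[z3, y2, x]] += 1
    return counts


def glcm2d_oracle(img, dx, dy, levels):
    ny, nx = img.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for y in range(ny):
        for x in range(nx):
            x2, y2 = x + dx, y + dy
            if 0 <= x2 < nx and 0 <= y2 < ny:
                counts[img[y, x], img[y2, x2]] += 1
    return counts


class TestDisplacementOffsets:
    @pytest.mark.parametrize("d, theta, expected", [
        (1, 0, (1, 0, 1)),
        (1, 90, (0, 1, 0)),
        (2, 45, (1, 1, 1)),     # round(1.414) = 1
        (1, 135, (-1, 1, -1)),  # cos 135 < 0
        (3, 45, (2, 2, 2)),     # round(2.12) = 2
    ])
    def test_rounded_offsets(self, d, theta, expected):
        off = displacement_offsets(d, theta)
        assert (off.dx, off.dy, off.dz) == expected
        assert off.dx == off.dz

    def test_chessboard_convention_at_diagonals(self):
        off = displacement_offsets(2, 45, convention="chessboard")
        assert (off.dx, off.dy) == (2, 2)
        off = displacement_offsets(2, 135, convention="chessboard")
        assert (off.dx, off.dy) == (-2, 2)

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            displacement_offsets(0, 0)


class TestGlcm2d:
    def test_constant_image_all_mass_on_diagonal(self):
        g = st.compute_glcm2d(np.full((4, 4), 3, dtype=np.uint8), 1, 0, levels=8)
        assert g.P[3, 3] == 1.0 and g.P.sum() == 1.0

    def test_two_column_image_single_pair(self):
        img = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        g = st.compute_glcm2d(img, 1, 0, levels=2)
        assert g.valid_pair_count == 2
        assert g.P[0, 1] == 1.0

    @pytest.mark.parametrize("theta", DEFAULT_ANGLES)
    @pytest.mark.parametrize("d", [1, 2])
    def test_matches_double_loop_oracle(self, rng, d, theta):
        img = rng.integers(0, 8, size=(8, 8)).astype(np.uint8)
        g = st.compute_glcm2d(img, d, theta, levels=8)
        off = displacement_offsets(d, theta)
        counts = glcm2d_oracle(img, off.dx, off.dy, 8)
        np.testing.assert_allclose(g.P, counts / counts.sum())

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            st.compute_glcm2d(np.zeros((4, 4), dtype=np.uint8), 1, 0, levels=1)


class TestGlcm3d:
    def test_constant_volume_all_mass_on_diagonal(self):
        g = st.compute_glcm3d(np.full((3, 3, 3), 2, dtype=np.uint8), 1, 0,
                              levels=4)
        assert g.P[2, 2, 2] == 1.0

    def test_theta_90_mass_confined_to_j_equals_k(self, rng):
        vol = rng.integers(0, 6, size=(4, 6, 6)).astype(np.uint8)
        g = st.compute_glcm3d(vol, 2, 90, levels=6)
        off_diag = g.P.copy()
        for j in range(6):
            off_diag[:, j, j] = 0
        assert off_diag.sum() == 0

    def test_coordinate_coded_2x2x2_volume(self):
        zz, yy, xx = np.mgrid[0:2, 0:2, 0:2]
        vol = (xx + 2 * yy + 4 * zz).astype(np.uint8)
        g = st.compute_glcm3d(vol, 1, 0, levels=8)
        assert g.valid_triple_count == 2
        assert g.P[0, 1, 4] == 0.5 and g.P[2, 3, 6] == 0.5
        assert g.P.sum() == 1.0

    def test_volume_too_thin_in_z_rejected(self):
        vol = np.zeros((1, 6, 6), dtype=np.uint8)
        with pytest.raises(ValueError, match="no valid"):
            st.compute_glcm3d(vol, 1, 0, levels=2)

    @pytest.mark.parametrize("theta", DEFAULT_ANGLES)
    def test_matches_triple_loop_oracle(self, rng, theta):
        for _ in range(3):
            shape = tuple(rng.integers(3, (7, 11, 11)[i] + 1) for i in range(3))
            vol = rng.integers(0, 8, size=shape).astype(np.uint8)
            for d in (1, 2, 3):
                off = displacement_offsets(d, theta)
                counts = glcm3d_oracle(vol, off.dx, off.dy, off.dz, 8)
                if counts.sum() == 0:
                    continue
                g = st.compute_glcm3d(vol, d, theta, levels=8)
                np.testing.assert_allclose(g.P, counts / counts.sum())
                assert g.P.sum() == pytest.approx(1.0)


class TestAngleAveraging:
    def test_single_angle_identical_to_direct(self, rng):
        vol = rng.integers(0, 8, size=(5, 8, 8)).astype(np.uint8)
        avg = st.average_over_angles(vol, 2, angles=[45], levels=8)
        direct = st.compute_glcm3d(vol, 2, 45, levels=8)
        np.testing.assert_array_equal(avg.P, direct.P)

    def test_mean_of_separately_computed_matrices(self, rng):
        vol = rng.integers(0, 8, size=(6, 10, 10)).astype(np.uint8)
        avg = st.average_over_angles(vol, 2, levels=8)
        explicit = np.mean([st.compute_glcm3d(vol, 2, t, levels=8).P
                            for t in DEFAULT_ANGLES], axis=0)
        np.testing.assert_allclose(avg.P, explicit)
        assert avg.P.sum() == pytest.approx(1.0)

    def test_constant_volume_four_angles(self):
        avg = st.average_over_angles(np.full((4, 6, 6), 5, dtype=np.uint8),
                                     1, levels=8)
        assert avg.P[5, 5, 5] == pytest.approx(1.0)


def sparse_glcm3(entries, levels=5):
    P = np.zeros((levels, levels, levels))
    for (i, j, k), w in entries.items():
        P[i, j, k] = w
    return GLCM3(levels=levels, P=P, valid_triple_count=1)


class TestFeatures3d:
    def test_diagonal_mass_gives_zero_contrast_unit_homogeneity(self):
        g = sparse_glcm3({(1, 1, 1): 0.5, (3, 3, 3): 0.5})
        assert st.contrast3d(g) == 0.0
        assert st.homogeneity3d(g) == 1.0

    def test_single_off_diagonal_entry(self):
        g = sparse_glcm3({(0, 1, 2): 1.0})
        assert st.contrast3d(g) == 6.0
        assert st.homogeneity3d(g) == pytest.approx(1 / 7)

    def test_matches_brute_force_summation(self, rng):
        P = rng.random((6, 6, 6))
        P /= P.sum()
        g = GLCM3(levels=6, P=P, valid_triple_count=1)
        expected_c = expected_h = 0.0
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    w = (i - j) ** 2 + (i - k) ** 2 + (j - k) ** 2
                    expected_c += P[i, j, k] * w
                    expected_h += P[i, j, k] / (1 + w)
        assert st.contrast3d(g) == pytest.approx(expected_c)
        assert st.homogeneity3d(g) == pytest.approx(expected_h)

    def test_unnormalised_input_rejected(self):
        g = sparse_glcm3({(0, 1, 2): 2.0})
        with pytest.raises(ValueError, match="normalis"):
            st.contrast3d(g)
        with pytest.raises(ValueError, match="normalis"):
            st.homogeneity3d(g)


class TestFeatures2d:
    def test_diagonal_and_off_diagonal_examples(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        g = GLCM2(levels=4, P=P, valid_pair_count=1)
        assert st.contrast2d(g) == 0.0 and st.homogeneity2d(g) == 1.0
        P = np.zeros((4, 4))
        P[0, 2] = 1.0
        g = GLCM2(levels=4, P=P, valid_pair_count=1)
        assert st.contrast2d(g) == 4.0
        assert st.homogeneity2d(g) == pytest.approx(1 / 5)

    def test_matches_skimage_reference_on_same_matrix(self, rng):
        """Independent textbook implementation (skimage graycoprops) agrees
        on the identical unsymmetrised, normalised matrix."""
        from skimage.feature import graycoprops

        P = rng.random((8, 8))
        P /= P.sum()
        g = GLCM2(levels=8, P=P, valid_pair_count=1)
        ref = P[:, :, None, None]
        assert st.contrast2d(g) == pytest.approx(
            graycoprops(ref, "contrast")[0, 0])
        assert st.homogeneity2d(g) == pytest.approx(
            graycoprops(ref, "homogeneity")[0, 0])


class TestStructuralInvariants:
    def test_theta90_contrast_is_twice_2d_contrast_of_pair_marginal(self, rng):
        """With dx = dz = 0 the second and third points coincide, so the
        triple weight collapses to 2 (i-j)^2."""
        vol = rng.integers(0, 8, size=(5, 9, 9)).astype(np.uint8)
        g3 = st.compute_glcm3d(vol, 3, 90, levels=8)
        pair = g3.P.sum(axis=2)  # marginal over k (all mass has j == k)
        g2 = GLCM2(levels=8, P=pair, valid_pair_count=g3.valid_triple_count)
        assert st.contrast3d(g3) == pytest.approx(2 * st.contrast2d(g2))

    def test_grey_level_reversal_leaves_features_unchanged(self, rng):
        vol = rng.integers(0, 8, size=(5, 8, 8)).astype(np.uint8)
        rev = (7 - vol).astype(np.uint8)
        for theta in DEFAULT_ANGLES:
            g = st.compute_glcm3d(vol, 2, theta, levels=8)
            gr = st.compute_glcm3d(rev, 2, theta, levels=8)
            assert st.contrast3d(g) == pytest.approx(st.contrast3d(gr))
            assert st.homogeneity3d(g) == pytest.approx(st.homogeneity3d(gr))

    def test_contrast_and_homogeneity_move_oppositely(self):
        """Widening the index separation of a two-mass matrix raises
        contrast and lowers homogeneity."""
        contrasts, homogs = [], []
        for sep in (1, 2, 3, 4):
            g = sparse_glcm3({(0, sep, sep): 0.5, (2, 2, 2): 0.5}, levels=8)
            contrasts.append(st.contrast3d(g))
            homogs.append(st.homogeneity3d(g))
        assert np.all(np.diff(contrasts) > 0)
        assert np.all(np.diff(homogs) < 0)


class TestTextureCurves:
    def test_constant_volume_flat_curves(self):
        vol = np.full((4, 8, 8), 3, dtype=np.uint8)
        curves = texture_curves(vol, d_range=range(1, 4), levels=8)
        assert np.all(curves["contrast"].values == 0)
        assert np.all(curves["homogeneity"].values == 1)

    def test_single_point_curve_equals_direct_feature_call(self, rng):
        vol = rng.integers(0, 8, size=(5, 8, 8)).astype(np.uint8)
        curve = texture_curves(vol, metrics=("contrast",),
                               d_range=[2], levels=8)["contrast"]
        direct = st.contrast3d(st.average_over_angles(vol, 2, levels=8))
        assert curve.values[0] == pytest.approx(direct)

    def test_streaming_matches_matrix_route(self, rng):
        """Per-angle streamed features equal features of the explicitly
        averaged matrices (both are linear in P)."""
        vol = rng.integers(0, 8, size=(6, 10, 10)).astype(np.uint8)
        curves = texture_curves(vol, d_range=range(1, 4), levels=8)
        for pos, d in enumerate(range(1, 4)):
            cs = [st.contrast3d(st.compute_glcm3d(vol, d, t, levels=8))
                  for t in DEFAULT_ANGLES]
            assert curves["contrast"].values[pos] == pytest.approx(np.mean(cs))

    def test_smaller_features_peak_at_smaller_displacement(self):
        small = st.generate_feature_image(
            st.FeatureImageSpec(image_size=120, ln_radius=7, mz_thickness=2))
        large = st.generate_feature_image(
            st.FeatureImageSpec(image_size=120, ln_radius=14, mz_thickness=4))
        kw = dict(metrics=("contrast",), dimensionality="2D",
                  d_range=range(1, 41), levels=256)
        p_small = find_peak(texture_curves(small, **kw)["contrast"])
        p_large = find_peak(texture_curves(large, **kw)["contrast"])
        assert p_small.displacement < p_large.displacement


class TestFindPeak:
    def test_symmetric_triplet_peaks_at_centre(self):
        curve = st.TextureCurve("s", "contrast", "3D", [9, 10, 11], [1, 3, 1])
        peak = find_peak(curve)
        assert peak.displacement == pytest.approx(10.0)
        assert not peak.at_boundary

    def test_parabola_vertex_recovered(self):
        d = np.arange(10, 27)
        values = -(d - 18.2) ** 2
        curve = st.TextureCurve("s", "contrast", "3D", d, values)
        assert find_peak(curve).displacement == pytest.approx(18.2, abs=1e-9)

    def test_monotone_curve_flags_boundary(self):
        curve = st.TextureCurve("s", "contrast", "3D", [1, 2, 3], [1, 2, 3])
        peak = find_peak(curve)
        assert peak.at_boundary and peak.displacement == 3

    def test_flat_curve_has_no_unique_peak(self):
        curve = st.TextureCurve("s", "contrast", "3D", [1, 2, 3], [2, 2, 2])
        with pytest.raises(ValueError, match="no unique peak"):
            find_peak(curve)
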