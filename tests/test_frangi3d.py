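"""Hessian scale space, eigenanalysis and vesselness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fiberorient3d import frangi3d, tuning
from fiberorient3d.phantoms import make_cylinder
from fiberorient3d.volume import VolumeImage

S_TERM_CEILING = 1.0 - np.exp(-2.0)  # structureness term at S = S_max


def dense_hessian_oracle(data, sigma):
    """Direct dense convolution with analytically differentiated 3D
    Gaussian kernels (the independent reference for the separable path)."""
    r = int(4.0 * sigma + 0.5)
    ax = np.arange(-r, r + 1, dtype=np.float64)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    g1 = np.exp(-(ax**2) / (2 * sigma**2))
    g1 /= g1.sum()  # matches the normalized sampled-Gaussian convention
    g = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    out = {}
    polys = {"xx": (x**2 / sigma**4 - 1 / sigma**2),
             "yy": (y**2 / sigma**4 - 1 / sigma**2),
             "zz": (z**2 / sigma**4 - 1 / sigma**2),
             "xy": x * y / sigma**4, "xz": x * z / sigma**4,
             "yz": y * z / sigma**4}
    for name, p in polys.items():
        kernel = g * p
        out[name] = sigma**2 * ndimage.convolve(data.astype(np.float64),
                                                kernel, mode="reflect")
    return out


class TestScaleSpaceHessian:
    def test_constant_image_zero_hessian(self):
        vol = VolumeImage(np.full((12, 12, 12), 5.0, np.float32))
        h = frangi3d.scale_space_hessian(vol, 1.5)
        # residual ~ the truncated-kernel tail times the gray level
        for c in h.components.values():
            np.testing.assert_allclose(c, 0.0, atol=1e-2)

    def test_linear_ramp_zero_second_derivatives(self):
        x = np.arange(24, dtype=np.float32)
        vol = VolumeImage(np.broadcast_to(x, (24, 24, 24)).copy())
        h = frangi3d.scale_space_hessian(vol, 2.0)
        interior = tuple([slice(9, -9)] * 3)
        # ~0 up to the truncated-kernel tail (linear in the ramp value)
        for c in h.components.values():
            np.testing.assert_allclose(c[interior], 0.0, atol=1e-2)

    def test_gaussian_spot_closed_form_center_curvature(self):
        # G_sigma * (A exp(-r^2/2s^2)) stays Gaussian; the normalized
        # Hessian diagonal at the center is -sigma^2 A s^3 / (s^2+sigma^2)^2.5
        s, sigma, A, n = 3.0, 2.0, 100.0, 20
        ax = np.arange(-n, n + 1, dtype=np.float64)
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        vol = VolumeImage(A * np.exp(-(x**2 + y**2 + z**2) / (2 * s**2)))
        h = frangi3d.scale_space_hessian(vol, sigma)
        expected = -sigma**2 * A * s**3 / (s**2 + sigma**2) ** 2.5
        for name in ("xx", "yy", "zz"):
            assert h.components[name][n, n, n] == pytest.approx(expected,
                                                                rel=1e-3)
        assert h.components["xy"][n, n, n] == pytest.approx(0.0, abs=1e-4)

    def test_separable_path_matches_dense_convolution_oracle(self, rng):
        data = ndimage.gaussian_filter(
            rng.random((20, 20, 20)), 1.0).astype(np.float32)
        sigma = 2.0
        vol = VolumeImage(data)
        h = frangi3d.scale_space_hessian(vol, sigma)
        oracle = dense_hessian_oracle(data, sigma)
        r = int(4.0 * sigma + 0.5)
        interior = tuple([slice(r, -r)] * 3)
        for name in h.components:
            got = h.components[name][interior].astype(np.float64)
            want = oracle[name][interior]
            scale = np.abs(want).max()
            np.testing.assert_allclose(got, want, atol=1e-6 * scale)

    def test_anisotropic_voxels_rejected(self):
        vol = VolumeImage(np.zeros((5, 5, 5), np.float32), (1.0, 0.88, 0.88))
        with pytest.raises(ValueError, match="isotropize"):
            frangi3d.scale_space_hessian(vol, 1.0)

    def test_matrices_exactly_symmetric(self, rng):
        vol = VolumeImage(rng.random((8, 8, 8), dtype=np.float32))
        m = frangi3d.scale_space_hessian(vol, 1.0).matrices()
        np.testing.assert_array_equal(m, np.swapaxes(m, -1, -2))


def hessian_from_matrix(m):
    m = np.asarray(m, dtype=np.float32)[None, None, None]
    comps = {"xx": m[..., 0, 0], "xy": m[..., 0, 1], "xz": m[..., 0, 2],
             "yy": m[..., 1, 1], "yz": m[..., 1, 2], "zz": m[..., 2, 2]}
    return frangi3d.HessianField(comps, 1.0, 1.0)


class TestEigenDecompose:
    def test_diagonal_matrix(self):
        e = frangi3d.eigen_decompose(hessian_from_matrix(
            np.diag([0.0, -4.0, -9.0])))
        np.testing.assert_allclose(e.eigenvalues[0, 0, 0], [0, -4, -9])
        # v1 = x-axis; the z >= 0 tie-break maps it to +x
        np.testing.assert_allclose(np.abs(e.eigenvectors[0, 0, 0, 0]),
                                   [1, 0, 0], atol=1e-12)
        assert e.eigenvectors[0, 0, 0, 0, 0] > 0

    def test_cylinder_interior_is_tube_like(self, z_cylinder):
        h = frangi3d.scale_space_hessian(z_cylinder.volume, 1.25)
        e = frangi3d.eigen_decompose(h)
        nz, ny, nx = h.shape
        w = e.eigenvalues[nz // 2, ny // 2, nx // 2]
        v1 = e.eigenvectors[nz // 2, ny // 2, nx // 2, 0]
        assert abs(w[0]) < 0.2 * abs(w[1])      # lambda1 ~ 0 along the axis
        assert w[1] < 0 and w[2] < 0            # negative for bright tubes
        assert w[1] == pytest.approx(w[2], rel=0.2)
        angle = np.degrees(np.arccos(min(abs(v1[2]), 1.0)))
        assert angle < 2.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6))
    def test_reconstruction_and_ordering(self, vals):
        m = np.array([[vals[0], vals[1], vals[2]],
                      [vals[1], vals[3], vals[4]],
                      [vals[2], vals[4], vals[5]]])
        e = frangi3d.eigen_decompose(hessian_from_matrix(m))
        w = e.eigenvalues[0, 0, 0].astype(np.float64)
        v = e.eigenvectors[0, 0, 0].astype(np.float64)  # rows
        assert np.all(np.diff(np.abs(w)) >= -1e-5 * max(1, np.abs(w).max()))
        recon = (v.T * w) @ v
        np.testing.assert_allclose(recon, m, atol=1e-5 * max(1.0, np.abs(m).max()))
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-6)

    def test_v1_hemisphere_convention(self, rng):
        m = rng.random((3, 3)); m = m + m.T
        e = frangi3d.eigen_decompose(hessian_from_matrix(m))
        v1 = e.eigenvectors[0, 0, 0, 0]
        assert v1[2] > 0 or (v1[2] == 0 and (v1[1] > 0 or
                                             (v1[1] == 0 and v1[0] >= 0)))


class TestFrangiFeatures:
    def eigenfield(self, lams):
        w = np.asarray(lams, np.float32).reshape(1, 3)
        return frangi3d.EigenField(w, np.eye(3, dtype=np.float32)[None], 1.0)

    def test_isotropic_blob_maximizes_both_ratios(self):
        f = frangi3d.frangi_features(self.eigenfield([-5, -5, -5]))
        assert f.r_b[0] == pytest.approx(1.0)
        assert f.r_a[0] == pytest.approx(1.0)
        assert f.s[0] == pytest.approx(np.sqrt(75))

    def test_plate_drives_aspect_ratio_to_zero(self):
        f = frangi3d.frangi_features(self.eigenfield([0, -1e-4, -8]))
        assert f.r_a[0] < 2e-5

    def test_degenerate_background_convention(self):
        f = frangi3d.frangi_features(self.eigenfield([0, 0, 0]))
        assert f.r_b[0] == 0.0 and f.r_a[0] == 1.0 and f.s[0] == 0.0

    def test_ranges_on_random_eigenvalues(self, rng):
        w = np.sort(rng.normal(size=(500, 3)), axis=1)
        w = np.take_along_axis(w, np.argsort(np.abs(w), axis=1), axis=1)
        f = frangi3d.frangi_features(
            frangi3d.EigenField(w.astype(np.float32), None, 1.0))
        assert np.all((f.r_b >= 0) & (f.r_b <= 1 + 1e-6))
        assert np.all((f.r_a >= 0) & (f.r_a <= 1 + 1e-6))
        assert np.all(f.s >= 0)


class TestVesselness:
    def test_auto_gamma_definition_and_fallback(self):
        assert frangi3d.auto_gamma(np.array([1.0, 10.0, 3.0])) == 5.0
        assert frangi3d.auto_gamma(np.zeros(5)) == 1.0

    def test_zero_branch_positive_lambda(self):
        f = frangi3d.FrangiFeatures(np.zeros(2, np.float32),
                                    np.ones(2, np.float32),
                                    np.full(2, 10.0, np.float32))
        lam = np.array([[0.0, 1.0, -5.0], [0.0, -1.0, 5.0]], np.float32)
        v = frangi3d.vesselness(f, lam, gamma=5.0)
        np.testing.assert_array_equal(v, 0.0)

    def test_ideal_tube_response(self):
        # R_B=0, R_A=1, S=S_max with gamma=S_max/2: V = 1 - exp(-2)
        f = frangi3d.FrangiFeatures(np.zeros(1, np.float32),
                                    np.ones(1, np.float32),
                                    np.full(1, 10.0, np.float32))
        lam = np.array([[0.0, -7.0, -7.0]], np.float32)
        v = frangi3d.vesselness(f, lam, alpha=0.001, beta=1.0, gamma=5.0)
        assert v[0] == pytest.approx(S_TERM_CEILING, abs=1e-4)

    def test_blob_suppressed_by_exp_half(self):
        lam = np.array([[0.0, -7.0, -7.0]], np.float32)
        tube = frangi3d.FrangiFeatures(np.zeros(1, np.float32),
                                       np.ones(1, np.float32),
                                       np.full(1, 10.0, np.float32))
        blob = frangi3d.FrangiFeatures(np.ones(1, np.float32),
                                       np.ones(1, np.float32),
                                       np.full(1, 10.0, np.float32))
        v_tube = frangi3d.vesselness(tube, lam, beta=1.0, gamma=5.0)
        v_blob = frangi3d.vesselness(blob, lam, beta=1.0, gamma=5.0)
        assert v_blob[0] / v_tube[0] == pytest.approx(np.exp(-0.5), rel=1e-4)

    def test_invalid_sensitivities_rejected(self):
        f = frangi3d.FrangiFeatures(np.zeros(1, np.float32),
                                    np.ones(1, np.float32),
                                    np.ones(1, np.float32))
        lam = np.zeros((1, 3), np.float32)
        with pytest.raises(ValueError):
            frangi3d.vesselness(f, lam, alpha=0.0)
        with pytest.raises(ValueError):
            frangi3d.vesselness(f, lam, beta=-1.0)


class TestMultiscale:
    def test_single_scale_equals_multiscale_of_one(self, z_cylinder):
        a = frangi3d.single_scale_frangi(z_cylinder.volume, 1.25)
        b = frangi3d.multiscale_frangi(z_cylinder.volume, [1.25])
        np.testing.assert_array_equal(a.vesselness, b.vesselness)
        np.testing.assert_array_equal(a.orientation, b.orientation)

    def test_duplicated_scale_idempotent(self, z_cylinder):
        a = frangi3d.multiscale_frangi(z_cylinder.volume, [1.25])
        b = frangi3d.multiscale_frangi(z_cylinder.volume, [1.25, 1.25])
        np.testing.assert_array_equal(a.vesselness, b.vesselness)
        np.testing.assert_array_equal(a.orientation, b.orientation)
        assert np.all(b.scale_index <= 0)  # earlier scale wins ties

    def test_max_semantics(self, z_cylinder):
        scales = [1.0, 1.5]
        multi = frangi3d.multiscale_frangi(z_cylinder.volume, scales)
        singles = [frangi3d.single_scale_frangi(z_cylinder.volume, s)
                   for s in scales]
        np.testing.assert_allclose(
            multi.vesselness,
            np.maximum(singles[0].vesselness, singles[1].vesselness))

    def test_bad_scale_lists_rejected(self, z_cylinder):
        with pytest.raises(ValueError):
            frangi3d.multiscale_frangi(z_cylinder.volume, [])
        with pytest.raises(ValueError):
            frangi3d.multiscale_frangi(z_cylinder.volume, [1.5, 1.0])
        with pytest.raises(ValueError):
            frangi3d.multiscale_frangi(z_cylinder.volume, [-1.0])

    def test_vesselness_bounds_and_orientation_norm(self, z_cylinder_result):
        v = z_cylinder_result.vesselness
        assert v.min() >= 0.0 and v.max() <= 1.0
        on = v > 0
        norms = np.linalg.norm(z_cylinder_result.orientation[on], axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-5)

    def test_raw_response_peaks_at_half_radius(self):
        """The un-compensated axis response of a cylinder is strongest
        at scale = radius/2 (the scale-selection working rule)."""
        ph = make_cylinder(2.0, aspect_ratio=8, px_per_um=4.0, pad_um=8.0)
        responses = {s: tuning._axis_raw_structureness(ph.volume, s)
                     for s in (0.5, 1.0, 2.0)}
        assert max(responses, key=responses.get) == 1.0

    def test_scale_normalization_equalizes_calibres(self):
        """sigma^2-normalized axis structureness at sigma = r/2 is
        calibre-invariant (the point of normalized derivatives)."""
        values = []
        for r in (2.0, 3.0, 4.0):
            ph = make_cylinder(r, aspect_ratio=6, px_per_um=2.0, pad_um=8.0)
            h = frangi3d.scale_space_hessian(ph.volume, r / 2.0)
            nz, ny, nx = h.shape
            values.append(float(h.structureness()[nz // 2, ny // 2, nx // 2]))
        assert max(values) / min(values) < 1.15


class TestRotationEquivariance:
    @pytest.mark.parametrize("axis,ref", [
        ((1, 1, 0), None),
        ((0.5, 0.5, np.sqrt(0.5)), None),
    ])
    def test_oblique_cylinder_orientation_recovered(self, axis, ref):
        """Filtering a rotated cylinder recovers the rotated axis within
        the grid-interpolation tolerance of 3 degrees."""
        a = np.asarray(axis, float) / np.linalg.norm(axis)
        ph = make_cylinder(2.5, aspect_ratio=6, px_per_um=1.0, axis=a,
                           pad_um=6.0)
        res = frangi3d.multiscale_frangi(ph.volume, [1.0, 1.25, 1.5])
        # median orientation over confident voxels well inside the tube
        strong = res.vesselness > 0.8 * res.vesselness.max()
        vecs = res.orientation[strong]
        dots = np.clip(np.abs(vecs @ a), 0, 1)
        assert np.degrees(np.arccos(np.median(dots))) < 3.0


class TestVectorsToAngles:
    @pytest.mark.parametrize("vec,phi,elev", [
        ((1, 0, 0), 0.0, 0.0),
        ((0, 0, 1), 0.0, 90.0),
        ((1, 1, 0), 45.0, 0.0),
        ((0, 1, 0), -90.0, 0.0),   # +y folds onto the -90 azimuth label
        ((-1, 1, 0), -45.0, 0.0),
    ])
    def test_reference_directions(self, vec, phi, elev):
        v = np.asarray(vec, float) / np.linalg.norm(vec)
        p, e = frangi3d.vectors_to_angles(v)
        assert float(p) == pytest.approx(phi, abs=1e-9)
        assert float(e) == pytest.approx(elev, abs=1e-9)

    def test_axial_sign_invariance(self, rng):
        v = rng.normal(size=(100, 3))
        p1, e1 = frangi3d.vectors_to_angles(v)
        p2, e2 = frangi3d.vectors_to_angles(-v)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            frangi3d.vectors_to_angles(np.zeros(3))
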