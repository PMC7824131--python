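"""Plane parameterization, rasterization, fitting, transforms, extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalmsp import geometry as geo


class TestNormalizePlane:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((2, 0, 0, 0), (1, 0, 0, 0)),
            ((-1, 0, 0, 3), np.array([1, 0, 0, -3]) / np.sqrt(10)),
            ((0, -2, 0, 0), (0, 1, 0, 0)),
        ],
    )
    def test_examples(self, raw, expected):
        p = geo.normalize_plane(raw)
        assert np.allclose(p.vector, expected)
        assert np.isclose(np.linalg.norm(p.vector), 1.0)

    def test_idempotent(self):
        p = geo.normalize_plane((3.0, -1.0, 2.0, 5.0))
        q = geo.normalize_plane(p.vector)
        assert np.allclose(p.vector, q.vector)

    @pytest.mark.parametrize("bad", [(0, 0, 0, 1), (0, 0, 0, 0), (np.nan, 1, 0, 0)])
    def test_degenerate(self, bad):
        with pytest.raises(geo.InvalidPlaneError):
            geo.normalize_plane(bad)


class TestPlaneFromAngles:
    def test_identity_rotations(self):
        p = geo.plane_from_angles((40, 40, 40), 0.0, 0.0)
        assert np.allclose(p.normal, [1, 0, 0])
        assert np.isclose(-p.offset, 40)  # plane x = 40

    def test_thirty_degree_tilt(self):
        p0 = geo.plane_from_angles((40, 40, 40), 0.0, 0.0)
        p = geo.plane_from_angles((40, 40, 40), 30.0, 0.0)
        assert np.isclose(geo.dihedral_angle(p, p0), 30.0, atol=1e-9)

    def test_passes_through_seed(self):
        seed = (17.3, 21.0, 9.5)
        p = geo.plane_from_angles(seed, 12.0, -25.0)
        assert abs(p.signed_distance(seed)) < 1e-9

    @given(
        ta=st.floats(-30, 30),
        tc=st.floats(-30, 30),
        sx=st.floats(5, 60),
    )
    @settings(deadline=None, max_examples=50)
    def test_angle_round_trip(self, ta, tc, sx):
        p = geo.plane_from_angles((sx, 31.0, 28.0), ta, tc)
        ra, rc = geo.angles_from_plane(p)
        assert abs(ra - ta) < 1e-6
        assert abs(rc - tc) < 1e-6


class TestRasterize:
    def test_axis_aligned_count(self):
        p = geo.normalize_plane((1, 0, 0, -2))  # plane x = 2
        mask = geo.rasterize_plane(p, (5, 5, 5), 0.5)
        assert mask.sum() == 25

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_any_axis_aligned_is_n_squared(self, axis):
        coeffs = [0.0, 0.0, 0.0, -3.0]
        coeffs[axis] = 1.0
        mask = geo.rasterize_plane(geo.normalize_plane(coeffs), (7, 7, 7), 0.5)
        # brute-force oracle: count voxels within half-thickness
        grid = np.argwhere(np.ones((7, 7, 7), dtype=bool))
        dist = np.abs(grid[:, axis] - 3.0)
        assert mask.sum() == (dist <= 0.5).sum() == 49

    def test_outside_volume_warns_all_zero(self):
        p = geo.normalize_plane((1, 0, 0, 10))  # x = -10
        with pytest.warns(geo.PlaneOutsideVolumeWarning):
            mask = geo.rasterize_plane(p, (5, 5, 5), 0.5)
        assert mask.sum() == 0

    def test_matches_brute_force_for_oblique_plane(self):
        p = geo.plane_from_angles((2.5, 2.5, 2.5), 20.0, -10.0)
        mask = geo.rasterize_plane(p, (5, 5, 5), 0.5)
        pts = np.argwhere(np.ones((5, 5, 5), dtype=bool)).astype(float)
        dist = np.abs(p.signed_distance(pts)).reshape(5, 5, 5)
        assert np.array_equal(mask > 0, dist <= 0.5)


class TestFitPlane:
    def test_round_trip_recovery_within_envelope(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            seed = 40 + rng.uniform(-3, 3, 3)
            p = geo.plane_from_angles(seed, *rng.uniform(-30, 30, 2))
            fitted = geo.fit_plane_from_mask(geo.rasterize_plane(p, (80, 80, 80), 0.5))
            assert geo.dihedral_angle(p, fitted) < 0.1
            assert abs(fitted.offset - p.offset) < 0.5

    def test_insufficient_support(self):
        with pytest.raises(geo.InsufficientSupportError):
            geo.fit_plane_from_mask(np.zeros((8, 8, 8)))

    def test_collinear_support_is_degenerate(self):
        mask = np.zeros((10, 10, 10))
        mask[:, 4, 4] = 1.0  # a single voxel line
        with pytest.raises(geo.DegenerateFitError):
            geo.fit_plane_from_mask(mask)

    def test_soft_mask_weights_guide_fit(self):
        # strong weights on the true plane, weak speckle elsewhere
        p = geo.plane_from_angles((16, 16, 16), 10.0, 5.0)
        mask = geo.rasterize_plane(p, (32, 32, 32), 0.5) * 0.9
        rng = np.random.default_rng(0)
        mask += rng.uniform(0, 0.45, mask.shape)
        fitted = geo.fit_plane_from_mask(np.clip(mask, 0, 1), 0.5)
        assert geo.dihedral_angle(p, fitted) < 5.0


class TestRigidTransform:
    def test_identity(self):
        p = geo.normalize_plane((1, 0, 0, -3))
        m = geo.transform_between_planes(p, p)
        assert np.allclose(m.R, np.eye(3), atol=1e-12)
        assert np.allclose(m.t, 0, atol=1e-12)

    def test_parallel_translation(self):
        a = geo.normalize_plane((1, 0, 0, 0))
        b = geo.normalize_plane((1, 0, 0, -5))
        m = geo.transform_between_planes(a, b)
        assert np.allclose(m.R, np.eye(3))
        assert np.allclose(m.t, [5, 0, 0])

    def test_rotation_between_orthogonal_planes(self):
        a = geo.normalize_plane((1, 0, 0, 0))
        b = geo.normalize_plane((0, 1, 0, 0))
        m = geo.transform_between_planes(a, b)
        pts = np.array([[0.0, 1.0, 2.0], [0.0, -4.0, 7.0], [0.0, 0.0, 0.0]])
        mapped = m.apply(pts)
        assert np.abs(b.signed_distance(mapped)).max() < 1e-6

    def test_mapped_points_land_on_target(self, rng):
        for _ in range(20):
            a = geo.plane_from_angles(rng.uniform(10, 50, 3), *rng.uniform(-30, 30, 2))
            b = geo.plane_from_angles(rng.uniform(10, 50, 3), *rng.uniform(-30, 30, 2))
            m = geo.transform_between_planes(a, b)
            # orthonormal in-plane frame of a
            n = a.normal
            v = np.cross(n, [0, 0, 1.0])
            v /= np.linalg.norm(v)
            w = np.cross(n, v)
            p0 = -a.offset * n
            pts = p0 + np.outer(rng.uniform(-20, 20, 50), v) + np.outer(
                rng.uniform(-20, 20, 50), w
            )
            assert np.abs(a.signed_distance(pts)).max() < 1e-9
            assert np.abs(b.signed_distance(m.apply(pts))).max() < 1e-6

    def test_rotation_invariants_and_inverse(self, rng):
        a = geo.plane_from_angles((20, 20, 20), 17.0, -8.0)
        b = geo.plane_from_angles((25, 18, 22), -25.0, 12.0)
        m = geo.transform_between_planes(a, b)
        assert np.abs(m.R.T @ m.R - np.eye(3)).max() < 1e-9
        assert abs(np.linalg.det(m.R) - 1) < 1e-9
        comp_r = m.inverse().R @ m.R
        comp_t = m.inverse().apply(m.apply(np.zeros(3)))
        assert np.abs(comp_r - np.eye(3)).max() < 1e-9
        assert np.abs(comp_t).max() < 1e-9

    def test_non_unit_rotation_rejected(self):
        with pytest.raises(ValueError):
            geo.RigidTransform(np.eye(3) * 2.0, np.zeros(3))


class TestExtractMsp:
    def test_constant_volume(self):
        vol = np.full((16, 16, 16), 0.7)
        p = geo.plane_from_angles((8, 8, 8), 10.0, -5.0)
        img = geo.extract_msp_image(vol, p)
        inside = img[4:12, 4:12]
        assert np.allclose(inside, 0.7)

    def test_axis_aligned_equals_stored_slice(self, rng):
        vol = rng.random((12, 13, 14))
        p = geo.normalize_plane((1, 0, 0, -5))  # x = 5
        img = geo.extract_msp_image(vol, p)
        assert np.allclose(img, vol[5], atol=1e-12)

    def test_invariant_to_coefficient_rescaling(self, rng):
        vol = rng.random((16, 16, 16))
        p = geo.plane_from_angles((8, 8, 8), 14.0, 9.0)
        img1 = geo.extract_msp_image(vol, p)
        img2 = geo.extract_msp_image(vol, geo.Plane(*(p.vector * 1.0)), out_dims=None)
        assert np.allclose(img1, img2)

    def test_non_intersecting_plane_raises(self):
        vol = np.zeros((8, 8, 8))
        with pytest.raises(geo.EmptySliceError):
            geo.extract_msp_image(vol, geo.normalize_plane((1, 0, 0, 100)))

    def test_symmetry_plane_maximizes_reflection_correlation(self, small_phantom):
        s = small_phantom
        base = geo.extract_msp_image(s.volume, s.gt_plane)

        def refl_corr(plane):
            refl = geo.reflect_volume(s.volume, plane)
            return np.corrcoef(s.volume.ravel(), refl.ravel())[0, 1]

        true_corr = refl_corr(s.gt_plane)
        for da in (-8.0, -5.0, 5.0, 8.0):
            tilted = geo.plane_from_angles(
                s.gt_seed, s.theta_axi + da, s.theta_cor
            )
            assert refl_corr(tilted) < true_corr
        assert base.shape == (32, 32)
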