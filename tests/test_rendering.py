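"""DRR rendering against closed forms, an independent exact oracle, and
finite differences."""

import numpy as np
import pytest

from fluoropose.geometry import (
    Intrinsics,
    RadiologicParams,
    detector_grid_camera,
    pose_from_radiologic,
    se3_exp,
)
from fluoropose.rendering import (
    LabelMap3D,
    Volume3D,
    XRay2D,
    hu_to_mu,
    normalize_intensity,
    render,
    render_jacobian,
    render_labels,
)


def _cube_volume(n=64, spacing=2.0, mu=0.02, half=50.0):
    """Homogeneous cube of attenuation mu embedded in air; the cube boundary
    falls exactly on voxel boundaries so Siddon path lengths are exact."""
    idx = np.arange(n)
    c = (n - 1) / 2
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    inside = (
        (np.abs((X - c) * spacing) < half)
        & (np.abs((Y - c) * spacing) < half)
        & (np.abs((Z - c) * spacing) < half)
    )
    return Volume3D.centered(np.where(inside, mu, 0.0), spacing)


def _brute_force_drr(vol, T, K):
    """Independent Siddon oracle: per-voxel AABB ray clipping.

    For every voxel, intersect the ray with that voxel's axis-aligned box
    (slab method) and accumulate mu times the clipped length — O(V) per ray
    and algorithmically unrelated to plane-marching traversal.
    """
    C = T.inverse()
    s_w = C.translation
    q_w = C.apply(detector_grid_camera(K).reshape(-1, 3))
    d = q_w - s_w
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    shape = vol.shape
    # voxel AABBs in world coordinates (axis-aligned orientation assumed)
    assert np.allclose(vol.orientation, np.eye(3))
    out = np.zeros(len(u))
    nz = np.argwhere(vol.voxels != 0)
    lo_all = vol.origin + (nz - 0.5) * vol.spacing
    hi_all = vol.origin + (nz + 0.5) * vol.spacing
    mu_all = vol.voxels[nz[:, 0], nz[:, 1], nz[:, 2]]
    for r in range(len(u)):
        ur = np.where(np.abs(u[r]) < 1e-300, 1e-300, u[r])
        t1 = (lo_all - s_w) / ur
        t2 = (hi_all - s_w) / ur
        tmin = np.minimum(t1, t2).max(axis=1)
        tmax = np.maximum(t1, t2).min(axis=1)
        seg = np.clip(tmax - tmin, 0.0, None)
        out[r] = (seg * mu_all).sum()
    return out.reshape(K.shape)


class TestHuConversion:
    def test_linear_formula_and_clamp(self):
        ct = Volume3D.centered(
            np.full((16, 16, 16), -1000.0), 1.0, units="hu"
        )
        ct.voxels[0, 0, 0] = 0.0
        ct.voxels[0, 0, 1] = 1000.0
        mu = hu_to_mu(ct, mu_water=0.02)
        assert mu.voxels[0, 0, 0] == pytest.approx(0.02)  # water
        assert mu.voxels[0, 0, 1] == pytest.approx(0.04)  # dense bone
        assert mu.voxels[1, 0, 0] == 0.0  # air clamps at zero
        assert mu.units == "mu"

    def test_non_hu_input_refused(self):
        vol = Volume3D.centered(np.zeros((16, 16, 16)), 1.0, units="mu")
        with pytest.raises(ValueError, match="HU"):
            hu_to_mu(vol)

    def test_rendering_refuses_unconverted_hu(self):
        ct = Volume3D.centered(np.zeros((16, 16, 16)), 1.0, units="hu")
        K = Intrinsics(sdd=1000.0, height=4, width=4, delx=2.0, dely=2.0)
        with pytest.raises(ValueError, match="hu_to_mu"):
            render(ct, pose_from_radiologic(RadiologicParams(), 700.0), K)

    def test_minmax_normalization(self):
        rng = np.random.default_rng(0)
        vol = Volume3D.centered(rng.uniform(100, 900, (16, 16, 16)), 1.0, units="mu")
        out = normalize_intensity(vol)
        assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0
        assert out.units == "normalized"


class TestLineIntegrals:
    def test_homogeneous_cube_closed_form(self):
        """Central orthogonal ray through a 100 mm cube of mu=0.02/mm
        integrates to exactly 2.0."""
        vol = _cube_volume()
        K = Intrinsics(sdd=1000.0, height=1, width=1, delx=2.0, dely=2.0)
        T = pose_from_radiologic(RadiologicParams(), 700.0)
        siddon = render(vol, T, K, method="siddon").pixels[0, 0]
        tril = render(vol, T, K, method="trilinear", n_points=600).pixels[0, 0]
        assert siddon == pytest.approx(2.0, rel=1e-3)
        assert tril == pytest.approx(2.0, rel=5e-3)

    def test_ray_missing_volume_is_zero(self):
        vol = _cube_volume(n=32)
        K = Intrinsics(sdd=1000.0, height=1, width=1, delx=2.0, dely=2.0, x0=400.0)
        T = pose_from_radiologic(RadiologicParams(), 700.0)
        for method in ("siddon", "trilinear"):
            assert render(vol, T, K, method=method).pixels[0, 0] == 0.0

    def test_siddon_matches_independent_voxel_clipping_oracle(self):
        """Siddon's plane-marching equals per-voxel AABB clipping to 1e-6 on
        random 16^3 volumes viewed by an 8x8 detector at 20 random poses."""
        rng = np.random.default_rng(5)
        vol = Volume3D.centered(rng.uniform(0.0, 0.05, (16, 16, 16)), 3.0)
        K = Intrinsics(sdd=800.0, height=8, width=8, delx=8.0, dely=8.0)
        worst = 0.0
        for _ in range(20):
            p = RadiologicParams(*rng.uniform(-60, 60, 3), *rng.uniform(-30, 30, 3))
            T = pose_from_radiologic(p, 500.0)
            ours = render(vol, T, K, method="siddon").pixels
            oracle = _brute_force_drr(vol, T, K)
            worst = max(worst, np.abs(ours - oracle).max())
        assert worst < 1e-6

    def test_trilinear_agrees_with_siddon_on_smooth_phantom(self, smooth_volume,
                                                            detector64, oblique_pose):
        a = render(smooth_volume, oblique_pose, detector64, method="siddon").pixels
        b = render(
            smooth_volume, oblique_pose, detector64, method="trilinear",
            n_points=4 * max(smooth_volume.shape),
        ).pixels
        assert np.abs(a - b).mean() / a.max() <= 0.01

    def test_rendered_pixels_nonnegative(self, smooth_volume, detector64, oblique_pose):
        for method in ("siddon", "trilinear"):
            img = render(smooth_volume, oblique_pose, detector64, method=method)
            assert img.pixels.min() >= 0.0

    def test_sparse_ray_subset_equals_full_rendering(self, smooth_volume, detector64,
                                                     oblique_pose):
        rng = np.random.default_rng(6)
        rc = np.stack(
            [rng.integers(0, 64, 40), rng.integers(0, 64, 40)], axis=1
        )
        for method in ("siddon", "trilinear"):
            full = render(smooth_volume, oblique_pose, detector64, method=method)
            sparse = render(
                smooth_volume, oblique_pose, detector64, method=method, ray_subset=rc
            )
            assert np.array_equal(
                sparse.pixels[rc[:, 0], rc[:, 1]], full.pixels[rc[:, 0], rc[:, 1]]
            )
            untouched = np.ones((64, 64), dtype=bool)
            untouched[rc[:, 0], rc[:, 1]] = False
            assert np.all(sparse.pixels[untouched] == 0.0)

    def test_anisotropic_spacing_cube(self):
        """Path length bookkeeping is exact for non-cubic voxels too."""
        vox = np.full((20, 10, 16), 0.01)
        vol = Volume3D.centered(vox, [1.0, 4.0, 2.0])
        K = Intrinsics(sdd=1000.0, height=1, width=1, delx=1.0, dely=1.0)
        T = pose_from_radiologic(RadiologicParams(), 700.0)
        # frontal ray runs along world -y = volume axis 1: 10 voxels * 4 mm
        assert render(vol, T, K, method="siddon").pixels[0, 0] == pytest.approx(
            0.01 * 40.0, rel=1e-9
        )


class TestKernelConsistency:
    def test_numba_and_numpy_paths_agree(self, smooth_volume, detector64,
                                         oblique_pose):
        """The fused JIT kernel and the pure-NumPy reference compute the
        same trilinear line integrals."""
        import fluoropose._kernels as kernels

        fast = render(smooth_volume, oblique_pose, detector64, "trilinear",
                      n_points=64).pixels
        state = kernels.HAVE_NUMBA
        try:
            kernels.HAVE_NUMBA = False
            slow = render(smooth_volume, oblique_pose, detector64, "trilinear",
                          n_points=64).pixels
        finally:
            kernels.HAVE_NUMBA = state
        assert np.allclose(fast, slow, rtol=1e-12, atol=1e-14)


class TestPoseGradient:
    def test_jacobian_matches_central_differences(self, smooth_volume, detector64):
        """Analytic pose Jacobian of the mean pixel intensity vs central
        finite differences, all 6 tangent directions, < 1e-2 relative."""
        T = pose_from_radiologic(
            RadiologicParams(15.0, -10.0, 4.0, 6.0, -10.0, 5.0), 700.0
        )
        img, J = render_jacobian(smooth_volume, T, detector64, n_points=128)
        C = T.inverse()
        steps = [1e-5] * 3 + [1e-3] * 3
        for k in range(6):
            xi = np.zeros(6)
            xi[k] = steps[k]
            fp = render(
                smooth_volume, (C @ se3_exp(xi)).inverse(), detector64,
                "trilinear", n_points=128,
            ).pixels.mean()
            fm = render(
                smooth_volume, (C @ se3_exp(-xi)).inverse(), detector64,
                "trilinear", n_points=128,
            ).pixels.mean()
            fd = (fp - fm) / (2 * steps[k])
            an = J[k].mean()
            assert an == pytest.approx(fd, rel=1e-2, abs=1e-12), f"direction {k}"


class TestLabelRendering:
    @staticmethod
    def _nested_shell(n=48, spacing=2.0):
        idx = np.arange(n)
        c = (n - 1) / 2
        X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
        r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2) * spacing
        labels = np.zeros((n, n, n), dtype=np.int32)
        labels[(r >= 24.0) & (r < 36.0)] = 1  # shell
        labels[r < 12.0] = 2  # core
        mu = np.where(labels == 1, 0.03, np.where(labels == 2, 0.05, 0.0))
        vol = Volume3D.centered(mu, spacing)
        return vol, LabelMap3D.like(vol, labels)

    def test_partition_sums_to_full_rendering(self, detector64):
        vol, lm = self._nested_shell()
        T = pose_from_radiologic(RadiologicParams(alpha=25.0, beta=-15.0), 700.0)
        per = render_labels(vol, lm, [0, 1, 2], T, detector64, method="siddon")
        total = sum(img.pixels for img in per.values())
        full = render(vol, T, detector64, method="siddon").pixels
        assert np.abs(total - full).max() <= 1e-5 * max(full.max(), 1e-12)

    def test_shell_chord_length_closed_form(self):
        """The central ray crosses the shell twice: integral = 2 * thickness
        * mu_shell (within voxelization tolerance of ~1 voxel)."""
        vol, lm = self._nested_shell()
        K = Intrinsics(sdd=1000.0, height=1, width=1, delx=2.0, dely=2.0)
        T = pose_from_radiologic(RadiologicParams(), 700.0)
        shell = render_labels(vol, lm, [1], T, K, method="siddon")[1].pixels[0, 0]
        expected = 2.0 * (36.0 - 24.0) * 0.03
        assert shell == pytest.approx(expected, abs=2.0 * 0.03 * 2.0)

    def test_disjoint_spheres_isolation(self, detector64):
        n = 48
        idx = np.arange(n)
        c = (n - 1) / 2
        X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
        labels = np.zeros((n, n, n), dtype=np.int32)
        labels[(X - c + 12) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 < 36] = 1
        labels[(X - c - 12) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 < 36] = 2
        vol = Volume3D.centered(np.where(labels > 0, 0.04, 0.0), 2.0)
        lm = LabelMap3D.like(vol, labels)
        T = pose_from_radiologic(RadiologicParams(), 700.0)
        only1 = render_labels(vol, lm, [1], T, detector64, method="siddon")[1]
        both = render(vol, T, detector64, method="siddon")
        sphere2_rays = (
            render_labels(vol, lm, [2], T, detector64, method="siddon")[2].pixels > 0
        )
        sphere1_rays = only1.pixels > 0
        # rays through sphere 2 only must be dark in the sphere-1 rendering
        assert np.all(only1.pixels[sphere2_rays & ~sphere1_rays] == 0.0)
        assert np.any(sphere2_rays & ~sphere1_rays)

    def test_missing_structure_raises(self, detector64):
        vol, lm = self._nested_shell()
        T = pose_from_radiologic(RadiologicParams(), 700.0)
        with pytest.raises(ValueError, match="absent"):
            render_labels(vol, lm, [7], T, detector64)

    def test_misaligned_label_map_raises(self, detector64):
        vol, lm = self._nested_shell()
        lm2 = LabelMap3D(lm.labels, lm.spacing * 2, lm.origin, lm.orientation)
        T = pose_from_radiologic(RadiologicParams(), 700.0)
        with pytest.raises(ValueError, match="aligned"):
            render_labels(vol, lm2, [1], T, detector64)


class TestValidation:
    def test_non_finite_voxels_rejected(self, detector64, frontal_pose):
        vox = np.zeros((16, 16, 16))
        vox[0, 0, 0] = np.nan
        vol = Volume3D.centered(np.nan_to_num(vox), 1.0)
        vol.voxels[0, 0, 0] = np.nan  # bypass constructor check deliberately
        with pytest.raises(ValueError, match="finite"):
            render(vol, frontal_pose, detector64)

    def test_pixel_shape_must_match_intrinsics(self):
        K = Intrinsics(sdd=1000.0, height=8, width=8, delx=1.0, dely=1.0)
        with pytest.raises(ValueError, match="match"):
            XRay2D(np.zeros((4, 4)), K)
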