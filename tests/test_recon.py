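"""Gridding/NUFFT operators, sensitivities, CG-SENSE and reformatting."""

import numpy as np
import pytest

from respigate.phantom_sim import Ellipsoid, analytic_kspace, rasterize
from respigate.recon import (
    GriddingOperator,
    ImageVolume,
    SensitivityMaps,
    cg_sense,
    density_compensation,
    estimate_sensitivities,
    forward_nufft,
    gridding_adjoint,
    nudft_direct,
    rotate_then_grid,
    slab_sum,
)
from respigate.trajectory import (
    TrajectoryConfig,
    build_spoke_table,
    nyquist_spoke_count,
    readout_radii,
)


def _radial_coords(matrix, n_readout, n_spokes, phi=(0.4656, 0.6823)):
    cfg = TrajectoryConfig(
        phi1=phi[0], phi2=phi[1], n_spokes_total=n_spokes, si_every=0,
        matrix=matrix, n_readout=n_readout,
    )
    table = build_spoke_table(cfg)
    radii = readout_radii(n_readout)
    return radii, radii[None, :, None] * table.directions[:, None, :]


class TestDensityCompensation:
    def test_center_weight_positive_finite(self):
        radii = readout_radii(32)
        w = density_compensation(radii, 100)
        assert w[16] > 0 and np.isfinite(w).all()

    def test_weights_symmetric_about_center(self):
        radii = readout_radii(32)
        w = density_compensation(radii, 100)
        np.testing.assert_allclose(w[1:16], w[17:][::-1], rtol=1e-12)


class TestNufft:
    def test_forward_matches_direct_dft(self):
        rng = np.random.default_rng(7)
        for m, n_pts in ((8, 100), (16, 200)):
            vol = rng.standard_normal((m, m, m)) + 1j * rng.standard_normal((m, m, m))
            coords = rng.uniform(-0.5, 0.5, (n_pts, 3))
            direct = nudft_direct(vol, coords)
            approx = forward_nufft(vol, coords)
            err = np.abs(approx - direct).max() / np.abs(direct).max()
            assert err < 1e-5

    def test_delta_at_center_gives_constant_samples(self, rng):
        m = 16
        vol = np.zeros((m, m, m), dtype=complex)
        vol[m // 2, m // 2, m // 2] = 1.0
        coords = rng.uniform(-0.5, 0.5, (50, 3))
        s = forward_nufft(vol, coords)
        np.testing.assert_allclose(s, 1.0, atol=1e-5)

    def test_linearity(self, rng):
        m = 12
        a = rng.standard_normal((m, m, m)) + 1j * rng.standard_normal((m, m, m))
        b = rng.standard_normal((m, m, m)) + 1j * rng.standard_normal((m, m, m))
        coords = rng.uniform(-0.5, 0.5, (64, 3))
        np.testing.assert_allclose(
            forward_nufft(a + 2 * b, coords),
            forward_nufft(a, coords) + 2 * forward_nufft(b, coords),
            atol=1e-8 * np.abs(forward_nufft(a, coords)).max(),
        )

    def test_adjointness(self, rng):
        m = 12
        coords = rng.uniform(-0.5, 0.5, (150, 3))
        op = GriddingOperator(coords, m)
        x = rng.standard_normal((m, m, m)) + 1j * rng.standard_normal((m, m, m))
        y = rng.standard_normal(150) + 1j * rng.standard_normal(150)
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6


class TestGriddingAdjoint:
    def test_dc_sample_grids_to_uniform_image(self):
        op = GriddingOperator(np.zeros((1, 3)), 16)
        img = op.adjoint(np.array([1.0 + 0j])).real
        assert (img.max() - img.min()) / abs(img.mean()) < 0.01

    def test_fully_sampled_sphere_amplitude(self):
        m, voxel = 32, 4.0
        n_spokes = nyquist_spoke_count(m)
        radii, coords = _radial_coords(m, 2 * m, n_spokes)
        ell = Ellipsoid((0.0, 0.0, 0.0), (40.0, 40.0, 40.0), 1.0)
        samp = analytic_kspace([ell], coords / voxel)[0]
        w = density_compensation(radii, n_spokes)
        vol = gridding_adjoint(
            samp, coords, np.broadcast_to(w, samp.shape), m, voxel_mm=voxel
        )
        truth = rasterize([ell], m, voxel, supersample=2)
        inside = truth > 0.9
        assert vol.values.real[inside].mean() == pytest.approx(1.0, abs=0.1)


class TestCgSense:
    @pytest.fixture(scope="class")
    def uniform_setup(self):
        m, voxel = 32, 4.0
        n_spokes = nyquist_spoke_count(m)
        radii, coords = _radial_coords(m, 2 * m, n_spokes)
        ell = Ellipsoid((8.0, -4.0, 0.0), (48.0, 36.0, 30.0), 1.0)
        samp = analytic_kspace([ell], coords / voxel)[0][:, None, :]
        samp = np.swapaxes(samp, 1, 1)  # (spokes, 1 coil, readout)
        maps = SensitivityMaps(
            maps=np.ones((1, m, m, m), dtype=complex),
            mask=np.ones((m, m, m), dtype=bool),
        )
        w = density_compensation(radii, n_spokes)[None, :]
        return m, voxel, coords, samp, maps, w

    def test_consistent_with_gridding_and_refines_toward_truth(self, uniform_setup):
        # on fully sampled single-coil data the CG solution keeps the
        # gridding amplitude calibration while correcting the residual
        # point-spread error of the plain adjoint
        m, voxel, coords, samp, maps, w = uniform_setup
        vol, info = cg_sense(samp, coords, maps, w, voxel_mm=voxel)
        grid = gridding_adjoint(
            samp[:, 0, :], coords, np.broadcast_to(w, samp[:, 0, :].shape),
            m, oversampling=1.5, width=4, voxel_mm=voxel,
        )
        truth = rasterize(
            [Ellipsoid((8.0, -4.0, 0.0), (48.0, 36.0, 30.0), 1.0)], m, voxel,
            supersample=3,
        )
        inside = truth > 0.9
        assert vol.values.real[inside].mean() == pytest.approx(
            grid.values.real[inside].mean(), rel=0.05
        )
        e_cg = np.linalg.norm(vol.values.real - truth) / np.linalg.norm(truth)
        e_grid = np.linalg.norm(grid.values.real - truth) / np.linalg.norm(truth)
        assert e_cg < e_grid
        assert np.linalg.norm(vol.values - grid.values) < 0.15 * np.linalg.norm(
            grid.values
        )

    def test_residual_non_increasing(self, uniform_setup):
        m, voxel, coords, samp, maps, w = uniform_setup
        _, info = cg_sense(samp, coords, maps, w, n_iter=4, voxel_mm=voxel)
        r = info["residual_norms"]
        assert all(r[i + 1] <= r[i] * (1 + 1e-6) for i in range(len(r) - 1))

    def test_empty_bin_rejected(self, uniform_setup):
        m, voxel, coords, samp, maps, w = uniform_setup
        with pytest.raises(ValueError):
            cg_sense(samp[:0], coords[:0], maps, w[:, :0], voxel_mm=voxel)


class TestRotateThenGrid:
    @pytest.fixture(scope="class")
    def offset_sphere(self):
        m, voxel = 32, 4.0
        n_spokes = nyquist_spoke_count(m)
        radii, coords = _radial_coords(m, 2 * m, n_spokes)
        ell = Ellipsoid((24.0, 0.0, 0.0), (20.0, 20.0, 20.0), 1.0)
        samp = analytic_kspace([ell], coords / voxel)[0][:, None, :]
        maps = SensitivityMaps(
            maps=np.ones((1, m, m, m), dtype=complex),
            mask=np.ones((m, m, m), dtype=bool),
        )
        w = density_compensation(radii, n_spokes)[None, :]
        return m, voxel, coords, samp, maps, w

    def test_identity_rotation_is_identical(self, offset_sphere):
        m, voxel, coords, samp, maps, w = offset_sphere
        a, _ = cg_sense(samp, coords, maps, w, voxel_mm=voxel)
        b, _ = rotate_then_grid(samp, coords, np.eye(3), maps, w, voxel_mm=voxel)
        np.testing.assert_allclose(np.abs(b.values), np.abs(a.values), atol=1e-10)

    def test_90deg_rotation_moves_center(self, offset_sphere):
        m, voxel, coords, samp, maps, w = offset_sphere
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        vol, _ = rotate_then_grid(samp, coords, rot, maps, w, voxel_mm=voxel)
        mag = np.abs(vol.values)
        peak = np.unravel_index(np.argmax(mag), mag.shape)
        # object at +x maps into the rotated frame at +/-y
        assert abs(peak[0] - m // 2) <= 1
        assert abs(abs(peak[1] - m // 2) - 6) <= 1  # 24 mm / 4 mm voxels

    def test_rotated_recon_matches_rotated_object_recon(self, offset_sphere):
        # rotating the k-space coordinates by R reorients the image so the
        # object appears at R @ center; it must match a reconstruction of
        # that rotated object on the original coordinates exactly (no
        # interpolation loss)
        m, voxel, coords, samp, maps, w = offset_sphere
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rotated, _ = rotate_then_grid(samp, coords, rot, maps, w, voxel_mm=voxel)
        straight, _ = cg_sense(samp, coords, maps, w, voxel_mm=voxel)
        # exact 90-degree index-space rotation of the straight recon:
        # x'(q) = x(R^T q), i.e. E[i, j, k] = x[j, (2c - i) % m, k]
        c = m // 2
        expected = np.transpose(straight.values, (1, 0, 2))[
            (2 * c - np.arange(m)) % m
        ]
        err = np.linalg.norm(np.abs(rotated.values) - np.abs(expected))
        assert err < 0.03 * np.linalg.norm(np.abs(expected))

    def test_non_orthonormal_rejected(self, offset_sphere):
        m, voxel, coords, samp, maps, w = offset_sphere
        with pytest.raises(ValueError):
            rotate_then_grid(samp, coords, np.eye(3) * 2.0, maps, w, voxel_mm=voxel)


class TestSlabSum:
    def test_constant_volume_sums_to_four(self):
        vol = np.full((8, 8, 8), 1.0 + 1.0j)
        out = slab_sum(vol, 4)
        assert out.shape == (8, 8, 2)
        np.testing.assert_allclose(out, 4.0 + 4.0j)

    def test_antiphase_slices_cancel(self):
        vol = np.zeros((4, 4, 4), dtype=complex)
        vol[:, :, 0] = 1.0
        vol[:, :, 1] = -1.0
        out = slab_sum(vol, 4)
        np.testing.assert_allclose(out, 0.0)

    def test_176_slices_give_44_thick(self):
        vol = np.zeros((4, 4, 176), dtype=complex)
        assert slab_sum(vol, 4).shape == (4, 4, 44)

    def test_snr_gain_is_sqrt4(self, rng):
        noise = rng.standard_normal((32, 32, 64)) + 1j * rng.standard_normal(
            (32, 32, 64)
        )
        thin_sd = np.abs(noise[:, :, 0]).std()
        thick_sd = np.abs(slab_sum(noise, 4)).std() / 4.0  # per-slice scale
        # complex summation: noise grows by sqrt(4) while signal grows by 4
        assert thick_sd * 2 == pytest.approx(thin_sd, rel=0.2)


class TestSensitivities:
    def test_uniform_single_coil_is_flat(self, static_acq):
        maps = estimate_sensitivities(
            static_acq, n_spokes=400, matrix=32, lowres_matrix=16
        )
        # with one coil the normalized map is unit magnitude inside the mask
        mags = np.abs(maps.maps[:, maps.mask])
        rss = np.sqrt((mags**2).sum(axis=0))
        np.testing.assert_allclose(rss, 1.0, atol=1e-6)

    def test_weighted_alignment_with_truth(self, small_acq):
        maps = estimate_sensitivities(small_acq, n_spokes=10_000, lowres_matrix=24)
        cm = small_acq.truth.coil_model
        truth = cm.maps_on_grid(48, small_acq.voxel_mm)
        ref = truth[0] / np.maximum(np.abs(truth[0]), 1e-30)
        truth = truth * np.conj(ref)[None]
        rss = np.sqrt((np.abs(truth) ** 2).sum(axis=0))
        truth = truth / np.maximum(rss, 1e-30)
        # per-voxel complex alignment, weighted by object intensity (the map
        # is only identifiable where the object generates signal)
        align = np.abs(
            np.einsum("cv,cv->v", np.conj(maps.maps[:, maps.mask]),
                      truth[:, maps.mask])
        )
        from respigate.phantom_sim import PhantomConfig, phantom_state

        obj = rasterize(
            phantom_state(0.0, 6.0, 0.0, PhantomConfig()), 48,
            small_acq.voxel_mm, supersample=2,
        )
        weights = np.abs(obj)[maps.mask]
        assert (align * weights).sum() / weights.sum() > 0.95

    def test_too_few_spokes_rejected(self, static_acq):
        with pytest.raises(ValueError):
            estimate_sensitivities(static_acq, n_spokes=100_000)


class TestImageVolume:
    def test_non_cubic_rejected(self):
        with pytest.raises(ValueError):
            ImageVolume(values=np.zeros((4, 4, 5), dtype=complex), voxel_mm=1.0)

    def test_bad_orientation_rejected(self):
        with pytest.raises(ValueError):
            ImageVolume(
                values=np.zeros((4, 4, 4), dtype=complex),
                voxel_mm=1.0,
                orientation=np.ones((3, 3)),
            )
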