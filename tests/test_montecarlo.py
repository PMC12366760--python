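"""Momentum-transfer Monte Carlo: determinism, oracles, perturbations, fluence."""

import numpy as np
import pytest

from scotkit import cde, montecarlo as mc, speckle
from scotkit.medium import BoxInclusion, OpticalMedium, VoxelGrid


def _reflectance_ratio_diffusion(med, rho, mua):
    """Semi-infinite diffusion reflectance ratio R(mua)/R(0) (flux form)."""
    z0, zb = med.z0, med.zb
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2 * zb)

    def R(mu):
        ueff = np.sqrt(3.0 * mu * med.musp)
        return z0 * (ueff * r1 + 1) * np.exp(-ueff * r1) / r1**3 + (
            z0 + 2 * zb
        ) * (ueff * r2 + 1) * np.exp(-ueff * r2) / r2**3

    return R(mua) / R(0.0)


class TestSimulateHistories:
    def test_seeded_determinism(self, phantom):
        a = mc.simulate_histories(phantom, rho=15.0, n_photons=50_000, seed=7)
        b = mc.simulate_histories(phantom, rho=15.0, n_photons=50_000, seed=7)
        np.testing.assert_array_equal(a.L, b.L)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.exit_radius, b.exit_radius)

    def test_history_invariants(self, mc_run):
        assert mc_run.n_detected <= mc_run.n_photons
        assert np.all(mc_run.L > 0)
        assert np.all(mc_run.Y >= 0)
        # per-region momentum transfer never exceeds the total
        assert np.all(mc_run.Y_region <= mc_run.Y[:, None] + 1e-12)
        assert np.all(np.abs(mc_run.exit_radius - 30.0) <= 0.5)

    def test_no_detection_raises(self, phantom):
        with pytest.raises(RuntimeError):
            mc.simulate_histories(phantom, rho=200.0, n_photons=200, seed=0)

    def test_hdf5_roundtrip(self, mc_run, tmp_path):
        p = tmp_path / "run.h5"
        mc_run.to_hdf5(p)
        back = mc.McRun.from_hdf5(p)
        np.testing.assert_array_equal(back.L, mc_run.L)
        np.testing.assert_array_equal(back.Y_region, mc_run.Y_region)
        assert back.medium == mc_run.medium
        assert back.seed == mc_run.seed


class TestG1FromHistories:
    def test_absorption_reweighting_identity(self, mc_run, tau_grid):
        base = mc.g1_from_histories(mc_run, tau_grid)  # medium has mua = 0
        rew = mc.g1_from_histories(mc_run, tau_grid, mua=0.0)
        np.testing.assert_array_equal(base.values, rew.values)

    def test_absorption_weights_match_diffusion_reflectance(self, mc_run):
        """mean exp(-mua L) over histories vs the analytic reflectance ratio."""
        mua = 0.005
        mc_ratio = np.mean(np.exp(-mua * mc_run.L))
        diff_ratio = _reflectance_ratio_diffusion(mc_run.medium, 30.0, mua)
        assert mc_ratio == pytest.approx(diff_ratio, rel=0.05)

    def test_baseline_matches_analytic_semiinfinite(self, mc_run, tau_grid):
        """Normalized MC g1 tracks the correlation-diffusion solution to ~1%."""
        g1 = mc.g1_from_histories(mc_run, tau_grid).values
        # oracle averaged over the actual detected exit radii
        med = mc_run.medium
        G = np.zeros_like(tau_grid)
        for rv in mc_run.exit_radius:
            G += cde.g1_semiinf(med, med.Db0, float(rv), tau_grid)
        g1an = G / G[0]
        m = g1 > 0.01
        assert np.max(np.abs(g1[m] - g1an[m])) < 0.015

    def test_normalization_and_monotonicity(self, mc_run, tau_grid):
        g1 = mc.g1_from_histories(mc_run, tau_grid, mua=0.01).values
        assert g1[0] == pytest.approx(1.0)
        assert np.all(np.diff(g1) <= 1e-12)

    def test_region_perturbation_accelerates_decay(self, mc_run, tau_grid):
        base = mc.g1_from_histories(mc_run, tau_grid).values
        pert = mc.g1_from_histories(
            mc_run, tau_grid, region_rdb=[2.0, 1.0, 1.0, 1.0]
        ).values
        assert np.all(pert[1:] <= base[1:] + 1e-15)

    def test_infinite_flow_limit_removes_region_photons(self, mc_run, tau_grid):
        """rDb -> infinity: only photons avoiding the region contribute."""
        g1 = mc.g1_from_histories(
            mc_run, tau_grid, region_rdb=[1e12, 1.0, 1.0, 1.0]
        ).values
        eps = 2.0 * mc_run.medium.k0**2 * mc_run.medium.Db0
        untouched = mc_run.Y_region[:, 0] == 0.0
        expected = (
            np.exp(-eps * np.outer(mc_run.Y[untouched], tau_grid[1:])).sum(axis=0)
            / mc_run.n_detected
        )
        np.testing.assert_allclose(g1[1:], expected, atol=1e-10)

    def test_wrong_region_count_rejected(self, mc_run, tau_grid):
        with pytest.raises(ValueError):
            mc.g1_from_histories(mc_run, tau_grid, region_rdb=[2.0])

    def test_tau_grid_must_start_at_zero(self, mc_run):
        with pytest.raises(ValueError):
            mc.g1_from_histories(mc_run, np.array([1e-7, 1e-6]))


class TestPerturbedVsRytov:
    def test_small_signal_slopes_agree(self, mc_run, mc_regions, phantom, tau_grid):
        """First-order sensitivity of MC and the analytic Born kernel match.

        Compared at rDb - 1 = 0.1 on the large inclusion; the analytic
        kernel tracks the transport truth to a few percent.
        """
        from scotkit.medium import FlowPerturbation

        s = 0.1
        g0 = mc.g1_from_histories(mc_run, tau_grid)
        K20 = speckle.contrast_from_g1(g0, 2e-3).K2
        g1p = mc.g1_from_histories(mc_run, tau_grid, region_rdb=[1 + s, 1, 1, 1])
        sig_mc = K20 / speckle.contrast_from_g1(g1p, 2e-3).K2 - 1.0

        box = mc_regions[0]
        grid = VoxelGrid.from_bounds(box.lo, box.hi, 1.0)
        pert = FlowPerturbation.from_boxes(
            grid, [BoxInclusion(box.center, box.size, 1 + s)]
        )
        phis = cde.phi_s(phantom, pert, np.zeros(3), np.array([30.0, 0.0, 0.0]), tau_grid)
        g10 = cde.baseline_curve(phantom, 30.0, tau_grid).normalized().values
        sig_ry = speckle.signals_from_g1_matrix(tau_grid, g10, g10 * np.exp(phis), 2e-3)
        assert sig_ry == pytest.approx(sig_mc, rel=0.08)


class TestFluenceMode:
    def test_effective_mua_at_tau_zero_is_mua(self):
        grid = VoxelGrid((0, 0, 0), (2, 2, 2), (4, 4, 4))
        vm = mc.VoxelMedium.homogeneous(grid, OpticalMedium(mua=0.013, musp=0.86))
        np.testing.assert_array_equal(mc.effective_mua(vm, 0.0), vm.mua)

    def test_gray_matter_effective_mua_hand_value(self):
        # GM row: mua=0.0186/mm, musp=1.0989/mm, alpha*Db=6e-6 mm^2/s, 852 nm
        grid = VoxelGrid((0, 0, 0), (2, 2, 2), (1, 1, 1))
        vm = mc.VoxelMedium(
            grid,
            np.full(grid.shape, 0.0186),
            np.full(grid.shape, 1.0989),
            np.full(grid.shape, 6e-6),
            wavelength_nm=852.0,
        )
        k0 = 2 * np.pi / 8.52e-4
        expected = 0.0186 + 2 * 1.0989 * k0**2 * 6e-6 * 1e-5
        got = mc.effective_mua(vm, 1e-5)[0, 0, 0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0186 + 0.007172, rel=1e-3)

    def test_shape_mismatch_rejected(self):
        grid = VoxelGrid((0, 0, 0), (2, 2, 2), (4, 4, 4))
        with pytest.raises(ValueError):
            mc.VoxelMedium(grid, np.zeros((2, 2, 2)), np.ones(grid.shape), np.ones(grid.shape))

    def test_homogeneous_surface_g1_matches_analytic(self, phantom):
        """Effective-absorption fluence ratios reproduce the analytic decay."""
        grid = VoxelGrid((-30.0, -30.0, 0.0), (2.0, 2.0, 2.0), (30, 30, 15))
        vm = mc.VoxelMedium.homogeneous(grid, phantom)
        tau = np.array([0.0, 1e-6, 4e-6, 1.6e-5])
        res = mc.fluence_effective_absorption(vm, (0.0, 0.0, 0.0), tau, n_photons=150_000, seed=5)
        # voxel centered at (11, 1, 1) mm: 11.2 mm from the source
        idx = (20, 15, 0)
        got = res.g1_at(idx).values
        center = grid.centers().reshape(*grid.shape, 3)[idx]
        Gan = cde.g1_point_interior(phantom, phantom.Db0, np.zeros(3), center, tau)
        np.testing.assert_allclose(got[1:], (Gan / Gan[0])[1:], rtol=0.1)

    def test_extinguished_lags_give_zero_not_nan(self, phantom):
        grid = VoxelGrid((-10.0, -10.0, 0.0), (2.0, 2.0, 2.0), (10, 10, 5))
        vm = mc.VoxelMedium.homogeneous(grid, phantom)
        res = mc.fluence_effective_absorption(
            vm, (0.0, 0.0, 0.0), np.array([0.0, 10.0]), n_photons=2_000, seed=1
        )
        assert np.all(np.isfinite(res.volumes))
        far = res.volumes[1][8:, 8:, :]
        assert np.all(far == 0.0)

    def test_layered_medium_assigns_rows_by_depth(self):
        from scotkit.fixtures import HEAD_SLAB_LAYERS, layered_slab_medium

        vm = layered_slab_medium()
        zc = vm.grid.origin[2] + (np.arange(vm.grid.shape[2]) + 0.5) * vm.grid.spacing[2]
        # gray matter occupies depths [14, 18) mm
        gm = (zc >= 14.0) & (zc < 18.0)
        assert np.all(vm.musp[:, :, gm] == pytest.approx(1.0989))
        assert np.all(vm.alphaDb[:, :, gm] == pytest.approx(6e-6))
        # skin at the top
        assert vm.mua[0, 0, 0] == pytest.approx(HEAD_SLAB_LAYERS[0][2])
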