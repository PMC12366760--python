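"""Correlation-diffusion forward model: Green's functions and perturbations."""

import numpy as np
import pytest

from scotkit import cde
from scotkit.medium import BoxInclusion, FlowPerturbation, OpticalMedium, VoxelGrid


class TestDecayConstant:
    def test_zero_absorption_static_limit(self, phantom):
        assert cde.decay_constant(phantom, Db=1e-6, tau=0.0) == 0.0

    def test_hand_computed_value(self, phantom):
        # independent scalar arithmetic: C = sqrt(6 musp^2 k0^2 Db tau)
        k0 = 2.0 * np.pi / 8e-4
        expected = np.sqrt(6.0 * 1.0 * k0**2 * 1e-6 * 1e-5)
        assert cde.decay_constant(phantom, 1e-6, 1e-5) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.0608367, rel=1e-5)

    def test_linearity_in_Db_tau(self):
        med = OpticalMedium(mua=0.02, musp=1.3)
        base = 3.0 * med.musp * med.mua
        c1 = cde.decay_constant(med, 1e-6, 2e-6) ** 2 - base
        c2 = cde.decay_constant(med, 2e-6, 2e-6) ** 2 - base
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_negative_tau_rejected(self, phantom):
        with pytest.raises(ValueError):
            cde.decay_constant(phantom, 1e-6, -1e-9)


def _g1_semiinf_transcribed(med, Db, rho, tau):
    """Second independent transcription of the semi-infinite solution."""
    z0 = 1.0 / med.musp
    zb = (5.0 / 3.0) / med.musp
    msd = 6.0 * Db * np.asarray(tau)
    C = np.sqrt(3.0 * med.musp * (med.mua + med.musp * med.k0**2 * msd / 3.0))
    r1 = np.sqrt(rho**2 + z0**2)
    r2 = np.sqrt(rho**2 + (z0 + 2 * zb) ** 2)
    return 3 * med.musp / (4 * np.pi) * (np.exp(-C * r1) / r1 - np.exp(-C * r2) / r2)


class TestG1Semiinf:
    def test_static_zero_absorption_form(self, phantom):
        rho = 30.0
        r1 = np.hypot(rho, phantom.z0)
        r2 = np.hypot(rho, phantom.z0 + 2 * phantom.zb)
        expected = 3 * phantom.musp / (4 * np.pi) * (1 / r1 - 1 / r2)
        assert cde.g1_semiinf(phantom, 1e-6, rho, 0.0) == pytest.approx(expected)

    def test_matches_independent_transcription(self, phantom, tau_grid):
        ours = cde.g1_semiinf(phantom, phantom.Db0, 30.0, tau_grid)
        oracle = _g1_semiinf_transcribed(phantom, phantom.Db0, 30.0, tau_grid)
        np.testing.assert_allclose(ours, oracle, rtol=1e-12)

    def test_monotone_nonincreasing_and_positive(self, phantom, tau_grid):
        g = cde.g1_semiinf(phantom, phantom.Db0, 30.0, tau_grid)
        assert np.all(g > 0)
        assert np.all(np.diff(g) <= 0)

    def test_on_axis_rejected(self, phantom):
        with pytest.raises(ValueError):
            cde.g1_semiinf(phantom, 1e-6, 0.0, 1e-6)


class TestG1PointInterior:
    def test_surface_pair_reduces_to_semiinf(self, phantom):
        tau = np.array([0.0, 1e-6, 1e-5])
        a = np.zeros(3)
        b = np.array([25.0, 5.0, 0.0])
        rho = np.linalg.norm(b - a)
        np.testing.assert_allclose(
            cde.g1_point_interior(phantom, phantom.Db0, a, b, tau),
            cde.g1_semiinf(phantom, phantom.Db0, rho, tau),
            rtol=1e-12,
        )

    @pytest.mark.parametrize(
        "a,b",
        [
            ((0.0, 0.0, 0.0), (12.0, -4.0, 22.0)),
            ((5.0, 1.0, 8.0), (12.0, -4.0, 22.0)),
        ],
    )
    def test_reciprocity(self, phantom, a, b):
        tau = np.array([0.0, 3e-6])
        fwd = cde.g1_point_interior(phantom, phantom.Db0, np.array(a), np.array(b), tau)
        rev = cde.g1_point_interior(phantom, phantom.Db0, np.array(b), np.array(a), tau)
        np.testing.assert_allclose(fwd, rev, rtol=1e-12)

    def test_deep_point_matches_independent_image_oracle(self, phantom):
        # brute-force method of images typed independently of the library
        tau = 2e-6
        C = np.sqrt(6 * phantom.musp**2 * phantom.k0**2 * phantom.Db0 * tau)
        src = np.array([0.0, 0.0, 1.0])  # optode -> isotropic source at z0
        field = np.array([18.0, 6.0, 27.0])
        img = np.array([0.0, 0.0, -2 * (5 / 3) - 1.0])
        d1 = np.linalg.norm(field - src)
        d2 = np.linalg.norm(field - img)
        oracle = 3 / (4 * np.pi) * (np.exp(-C * d1) / d1 - np.exp(-C * d2) / d2)
        ours = cde.g1_point_interior(
            phantom, phantom.Db0, np.zeros(3), field, tau
        )
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_negative_z_rejected(self, phantom):
        with pytest.raises(ValueError):
            cde.g1_point_interior(
                phantom, 1e-6, np.zeros(3), np.array([0, 0, -1.0]), 1e-6
            )


@pytest.fixture
def channel():
    return np.zeros(3), np.array([30.0, 0.0, 0.0])


class TestPhiS:
    def test_null_perturbation_gives_zero(self, phantom, channel):
        grid = VoxelGrid((0, -5, 20), (2, 2, 2), (5, 5, 5))
        pert = FlowPerturbation(grid)  # rDb = 1 everywhere
        tau = np.array([0.0, 1e-6, 1e-4])
        np.testing.assert_array_equal(
            cde.phi_s(phantom, pert, *channel, tau), np.zeros(3)
        )

    def test_zero_at_tau_zero_and_negative_for_flow_increase(self, phantom, channel):
        grid = VoxelGrid.from_bounds([10, -5, 25], [20, 5, 35], 1.0)
        pert = FlowPerturbation.from_boxes(
            grid, [BoxInclusion((15, 0, 30), (10, 10, 10), rDb=2.0)]
        )
        phis = cde.phi_s(phantom, pert, *channel, np.array([0.0, 1e-6, 1e-4]))
        assert phis[0] == 0.0
        assert np.all(phis[1:] < 0)

    def test_additive_over_disjoint_regions(self, phantom, channel):
        tau = np.array([0.0, 2e-6, 5e-5])
        grid = VoxelGrid.from_bounds([-15, -25, 10], [45, 25, 50], 2.0)
        r1 = BoxInclusion((0, 0, 30), (30, 50, 40), rDb=2.0)
        r2 = BoxInclusion((30, 0, 30), (30, 50, 40), rDb=2.0)
        p1 = cde.phi_s(phantom, FlowPerturbation.from_boxes(grid, [r1]), *channel, tau)
        p2 = cde.phi_s(phantom, FlowPerturbation.from_boxes(grid, [r2]), *channel, tau)
        p12 = cde.phi_s(
            phantom, FlowPerturbation.from_boxes(grid, [r1, r2]), *channel, tau
        )
        np.testing.assert_allclose(p1 + p2, p12, rtol=1e-13, atol=1e-300)

    def test_single_voxel_matches_hand_composed_product(self, phantom, channel):
        # one 1 mm^3 voxel: compose the integrand factors by hand
        tau = 3e-6
        center = np.array([10.0, 2.0, 18.0])
        grid = VoxelGrid(tuple(center - 0.5), (1, 1, 1), (1, 1, 1))
        pert = FlowPerturbation(grid, np.array([1.5]))
        ours = cde.phi_s(phantom, pert, *channel, tau)
        C = np.sqrt(6 * phantom.musp**2 * phantom.k0**2 * phantom.Db0 * tau)

        def img_pair(src, fld):
            im = src.copy()
            im[2] = -2 * phantom.zb - src[2]
            d1, d2 = np.linalg.norm(fld - src), np.linalg.norm(fld - im)
            pref = 3 * phantom.musp / (4 * np.pi)
            return pref * (np.exp(-C * d1) / d1 - np.exp(-C * d2) / d2)

        Gs = img_pair(np.array([0.0, 0.0, phantom.z0]), center)
        Gd = img_pair(np.array([30.0, 0.0, 0.0]), center)
        G0 = cde.g1_semiinf(phantom, phantom.Db0, 30.0, tau)
        dDb = 0.5 * phantom.Db0
        expected = -1.0 * 2 * phantom.musp * phantom.k0**2 * tau * dDb * Gs * Gd / G0
        assert ours == pytest.approx(expected, rel=1e-12)

    def test_linear_in_delta_Db(self, phantom, channel):
        tau = np.array([0.0, 1e-5])
        grid = VoxelGrid.from_bounds([10, -5, 25], [20, 5, 35], 2.0)
        p1 = cde.phi_s(
            phantom,
            FlowPerturbation.from_boxes(grid, [BoxInclusion((15, 0, 30), (10, 10, 10), 1.5)]),
            *channel,
            tau,
        )
        p2 = cde.phi_s(
            phantom,
            FlowPerturbation.from_boxes(grid, [BoxInclusion((15, 0, 30), (10, 10, 10), 2.0)]),
            *channel,
            tau,
        )
        np.testing.assert_allclose(2.0 * p1, p2, rtol=1e-12)


class TestBornRytov:
    def test_identity_for_zero_phi(self, phantom, tau_grid):
        base = cde.baseline_curve(phantom, 30.0, tau_grid)
        zero = np.zeros_like(tau_grid)
        np.testing.assert_array_equal(cde.g1_born(base, zero).values, base.values)
        np.testing.assert_array_equal(cde.g1_rytov(base, zero).values, base.values)

    def test_direct_substitution(self, phantom, tau_grid):
        base = cde.baseline_curve(phantom, 30.0, tau_grid)
        phis = np.full_like(tau_grid, -0.5)
        phis[0] = 0.0
        born = cde.g1_born(base, phis)
        assert born.values[5] == pytest.approx(0.5 * base.values[5])

    def test_rytov_bounds_born_from_above(self, phantom, tau_grid):
        # exp(phi) >= 1 + phi pointwise
        rng = np.random.default_rng(0)
        phis = -2.0 * rng.random(tau_grid.size)
        base = cde.baseline_curve(phantom, 30.0, tau_grid)
        born = cde.g1_born(base, phis).values
        rytov = cde.g1_rytov(base, phis).values
        assert np.all(rytov >= born)
        assert np.all(rytov > 0)

    def test_born_is_first_order_taylor_of_rytov(self, phantom, tau_grid, channel=None):
        grid = VoxelGrid.from_bounds([10, -5, 25], [20, 5, 35], 1.0)
        pert = FlowPerturbation.from_boxes(
            grid, [BoxInclusion((15, 0, 30), (10, 10, 10), 2.0)]
        )
        phi1 = cde.phi_s(
            phantom, pert, np.zeros(3), np.array([30.0, 0.0, 0.0]), tau_grid
        )
        base = cde.baseline_curve(phantom, 30.0, tau_grid)
        ratios = []
        for eps in (0.5, 0.25, 0.125):
            diff = np.max(
                np.abs(
                    cde.g1_born(base, eps * phi1).values
                    - cde.g1_rytov(base, eps * phi1).values
                )
            )
            ratios.append(diff / eps**2)
        # residual is O(eps^2): the ratio approaches a constant
        assert ratios[2] == pytest.approx(ratios[1], rel=0.2)
        assert ratios[1] == pytest.approx(ratios[0], rel=0.4)

    def test_mismatched_grid_rejected(self, phantom, tau_grid):
        base = cde.baseline_curve(phantom, 30.0, tau_grid)
        with pytest.raises(ValueError):
            cde.g1_born(base, np.zeros(3))
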