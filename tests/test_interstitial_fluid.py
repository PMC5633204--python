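"""Tests for conductivity switching, the IFP solve and the radial oracle."""

import numpy as np
import pytest

from angionorm.grid_core import Grid, ScalarField, dirichlet, no_flux
from angionorm.interstitial_fluid import (
    ConductivityFields,
    FluidParams,
    analytic_ifp_radial,
    boundary_outflux,
    darcy_velocity,
    effective_conductivities,
    lymph_sink,
    solve_ifp,
    starling_source,
)


@pytest.fixture
def fp() -> FluidParams:
    return FluidParams()


@pytest.fixture
def grid() -> Grid:
    return Grid(31, 31, 0.05)


def disc_conductivities(grid: Grid, fp: FluidParams, R: float) -> ConductivityFields:
    """Piecewise-uniform disc: tumor column inside, normal outside (m = 1)."""
    r = grid.radius_from_center()
    frac = np.clip(0.5 + (R - r) / grid.h, 0.0, 1.0)  # sub-cell area fraction
    return ConductivityFields(
        lambda_b=ScalarField(
            grid, fp.lambda_b_normal + frac * (fp.lambda_b_tumor - fp.lambda_b_normal), "1/s"
        ),
        lambda_l=ScalarField(grid, fp.lambda_l_normal * (1.0 - frac), "1/s"),
        osmotic_term=ScalarField(
            grid,
            fp.osmotic_term_normal + frac * (fp.osmotic_term_tumor - fp.osmotic_term_normal),
            "mmHg",
        ),
        leakiness=ScalarField(grid, frac, "dimensionless"),
    )


class TestFluidParams:
    def test_derived_lambda_b(self, fp):
        # Table-1 derived row: lambda_b = L_p * SV
        assert fp.lambda_b_tumor == pytest.approx(3.72e-4)
        assert fp.lambda_b_normal == pytest.approx(2.52e-6)

    def test_derived_p_eff(self, fp):
        assert fp.p_eff_normal == pytest.approx(5.9)
        assert fp.p_eff_tumor == pytest.approx(14.9998, abs=5e-5)

    def test_normal_equilibrium_pressure(self, fp):
        lb, ll = fp.lambda_b_normal, fp.lambda_l_normal
        assert fp.normal_equilibrium_pressure == pytest.approx(lb * 5.9 / (lb + ll))
        assert fp.normal_equilibrium_pressure == pytest.approx(0.022, abs=2e-3)

    def test_negative_conductivity_rejected(self):
        with pytest.raises(ValueError):
            FluidParams(K=-1.0)


class TestEffectiveConductivities:
    def test_normal_column(self, grid, fp):
        n = ScalarField.zeros(grid)
        m = ScalarField.full(grid, 0.5)
        cf = effective_conductivities(n, m, fp)
        np.testing.assert_allclose(cf.lambda_b.values, 2.52e-6)
        np.testing.assert_allclose(cf.lambda_l.values, 6.66e-4)

    def test_tumor_column(self, grid, fp):
        n = ScalarField.full(grid, 1.0)
        m = ScalarField.full(grid, 1.5)
        cf = effective_conductivities(n, m, fp)
        np.testing.assert_allclose(cf.lambda_b.values, 3.72e-4)
        np.testing.assert_allclose(cf.lambda_l.values, 0.0)

    def test_ramp_midpoint(self, grid, fp):
        n = ScalarField.zeros(grid)
        m = ScalarField.full(grid, 1.0 + fp.ramp_delta / 2)
        cf = effective_conductivities(n, m, fp)
        mid_Lp = 0.5 * (fp.L_p_tumor + fp.L_p_normal)
        mid_SV = 0.5 * (fp.SV_tumor + fp.SV_normal)
        np.testing.assert_allclose(cf.lambda_b.values, mid_Lp * mid_SV)

    def test_negative_density_rejected(self, grid, fp):
        bad = ScalarField.full(grid, -0.1)
        with pytest.raises(ValueError):
            effective_conductivities(bad, bad, fp)


class TestStarlingAndLymph:
    def test_equilibrium_zero(self, grid, fp):
        n = ScalarField.full(grid, 1.0)
        m = ScalarField.full(grid, 1.5)
        cf = effective_conductivities(n, m, fp)
        P = ScalarField(grid, fp.P_v - cf.osmotic_term.values, "mmHg")
        out = starling_source(m, P, cf, fp)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-18)

    def test_no_vessels_zero(self, grid, fp):
        n = ScalarField.zeros(grid)
        m = ScalarField.zeros(grid)
        cf = effective_conductivities(n, m, fp)
        P = ScalarField.full(grid, 7.0, "mmHg")
        np.testing.assert_allclose(starling_source(m, P, cf, fp).values, 0.0)

    def test_tumor_column_rate(self, grid, fp):
        # m = 1, P = 0, tumor parameters: 3.72e-4 * (15 - 2.2e-4) /s
        n = ScalarField.full(grid, 1.0)
        m_ramp = ScalarField.full(grid, 1.5)
        cf = effective_conductivities(n, m_ramp, fp)
        m = ScalarField.full(grid, 1.0)
        P = ScalarField.zeros(grid, "mmHg")
        out = starling_source(m, P, cf, fp)
        np.testing.assert_allclose(out.values, 3.72e-4 * (15 - 2.2e-4), rtol=1e-12)
        assert out.values[0, 0] == pytest.approx(5.58e-3, rel=1e-3)

    def test_lymph_sink(self, grid, fp):
        cf = effective_conductivities(ScalarField.zeros(grid), ScalarField.zeros(grid), fp)
        P = ScalarField.full(grid, 10.0, "mmHg")
        np.testing.assert_allclose(lymph_sink(P, cf).values, 6.66e-3, rtol=1e-12)

    def test_lymph_suppressed_in_tumor(self, grid, fp):
        n = ScalarField.full(grid, 0.5)
        cf = effective_conductivities(n, ScalarField.zeros(grid), fp)
        P = ScalarField.full(grid, 10.0, "mmHg")
        np.testing.assert_allclose(lymph_sink(P, cf).values, 0.0)


class TestSolveIFP:
    def test_uniform_tumor_constant_solution(self, grid, fp):
        # m = 1, no lymph, dirichlet at P_eff: the constant solves exactly
        n = ScalarField.full(grid, 1.0)
        m = ScalarField.full(grid, 1.5)
        cf = effective_conductivities(n, m, fp)
        m1 = ScalarField.full(grid, 1.0)
        P = solve_ifp(m1, cf, fp, dirichlet(fp.p_eff_tumor))
        np.testing.assert_allclose(P.values, fp.p_eff_tumor, rtol=1e-10)

    def test_lymph_only_zero(self, grid, fp):
        n = ScalarField.zeros(grid)
        m = ScalarField.zeros(grid)
        cf = effective_conductivities(n, m, fp)
        P = solve_ifp(m, cf, fp, dirichlet(0.0))
        np.testing.assert_allclose(P.values, 0.0, atol=1e-12)

    def test_singular_all_zero_no_flux(self, grid, fp):
        zero = ScalarField.zeros(grid)
        cf = ConductivityFields(
            lambda_b=zero.copy(), lambda_l=zero.copy(),
            osmotic_term=zero.copy(), leakiness=zero.copy(),
        )
        with pytest.raises(ValueError, match="null space"):
            solve_ifp(zero, cf, fp, no_flux())

    def test_maximum_principle(self, fp, rng):
        grid = Grid(41, 41, 0.03)
        n = ScalarField(grid, rng.random(grid.shape))
        m = ScalarField(grid, 1.5 * rng.random(grid.shape))
        cf = effective_conductivities(n, m, fp)
        bval = fp.normal_equilibrium_pressure
        P = solve_ifp(m, cf, fp, dirichlet(bval))
        assert P.values.min() >= min(bval, 0.0) - 1e-9
        assert P.values.max() <= fp.p_eff_tumor + 1e-9

    def test_discrete_conservation(self, fp, rng):
        # interior Starling/lymph balance equals the boundary Darcy outflux
        grid = Grid(41, 41, 0.03)
        n = ScalarField(grid, rng.random(grid.shape))
        m = ScalarField(grid, 1.5 * rng.random(grid.shape))
        cf = effective_conductivities(n, m, fp)
        P = solve_ifp(m, cf, fp, dirichlet(fp.normal_equilibrium_pressure))
        gamma = starling_source(m, P, cf, fp).values - lymph_sink(P, cf).values
        interior_sum = gamma[1:-1, 1:-1].sum() * grid.h ** 2
        outflux = boundary_outflux(P, fp)
        assert outflux == pytest.approx(interior_sum, rel=1e-8)

    def test_radial_oracle_agreement(self, fp):
        # piecewise-uniform disc vs modified-Bessel closed form
        R = 0.5
        grid = Grid(151, 151, 1.2 / 150)
        cf = disc_conductivities(grid, fp, R)
        m = ScalarField(grid, np.ones(grid.shape))
        P = solve_ifp(m, cf, fp, dirichlet(fp.normal_equilibrium_pressure))
        r = grid.radius_from_center()
        exact = analytic_ifp_radial(R, fp, r.ravel()).reshape(grid.shape)
        rel = np.linalg.norm(P.values - exact) / np.linalg.norm(exact)
        assert rel < 0.01  # interface-limited accuracy; see acceptance test


class TestAnalyticOracle:
    def test_symmetry_flat_center(self, fp):
        rs = np.array([0.0, 1e-4, 2e-4])
        P = analytic_ifp_radial(0.5, fp, rs)
        # dP/dr(0) = 0: quadratic near the center, essentially flat
        assert abs(P[1] - P[0]) < 1e-8
        assert P[0] < fp.p_eff_tumor

    def test_perfect_equilibration_limit(self, fp):
        fast = FluidParams(L_p_tumor=fp.L_p_tumor * 1e4)
        P = analytic_ifp_radial(0.5, fast, [0.0])
        assert P[0] == pytest.approx(fast.p_eff_tumor, rel=1e-6)

    def test_center_plateau_near_p_eff(self, fp):
        # Table-1 values, R = 0.5 cm: the center plateau is within 5% of 15
        P0 = analytic_ifp_radial(0.5, fp, [0.0])[0]
        assert abs(P0 - fp.p_eff_tumor) / fp.p_eff_tumor < 0.05

    def test_far_field_equilibrium(self, fp):
        P = analytic_ifp_radial(0.5, fp, [5.0])[0]
        assert P == pytest.approx(fp.normal_equilibrium_pressure, rel=1e-6)

    def test_invalid_radius(self, fp):
        with pytest.raises(ValueError):
            analytic_ifp_radial(-1.0, fp, [0.1])

    def test_continuity_at_interface(self, fp):
        R = 0.5
        P = analytic_ifp_radial(R, fp, [R - 1e-9, R + 1e-9])
        assert P[0] == pytest.approx(P[1], abs=1e-5)


class TestDarcyVelocity:
    def test_constant_pressure_no_flow(self, grid, fp):
        ux, uy = darcy_velocity(ScalarField.full(grid, 5.0, "mmHg"), fp)
        np.testing.assert_allclose(ux.values[1:-1, 1:-1], 0.0, atol=1e-15)
        np.testing.assert_allclose(uy.values[1:-1, 1:-1], 0.0, atol=1e-15)

    def test_linear_pressure(self, grid, fp):
        P = ScalarField.from_function(grid, lambda x, y: 2.0 * x, unit="mmHg")
        ux, uy = darcy_velocity(P, fp)
        np.testing.assert_allclose(ux.values[1:-1, 1:-1], -2.0 * fp.K, rtol=1e-12)
        np.testing.assert_allclose(uy.values[1:-1, 1:-1], 0.0, atol=1e-15)

    def test_outward_flow_at_tumor_rim(self, fp):
        # radial analytic profile: dP/dr < 0 at the rim, so u points outward
        grid = Grid(101, 101, 0.015)
        r = grid.radius_from_center()
        P = ScalarField(grid, analytic_ifp_radial(0.5, fp, r.ravel()).reshape(grid.shape), "mmHg")
        ux, uy = darcy_velocity(P, fp)
        X, Y = grid.coords()
        cx, cy = grid.center
        rim = (np.abs(r - 0.5) < 0.03) & (r > 1e-9)
        radial = (ux.values * (X - cx) + uy.values * (Y - cy)) / np.maximum(r, 1e-12)
        assert (radial[rim] > 0).all()


class TestGridConvergence:
    def test_solver_error_decreases(self, fp):
        R = 0.5
        errs = []
        for nn in (61, 121):
            grid = Grid(nn, nn, 1.2 / (nn - 1))
            cf = disc_conductivities(grid, fp, R)
            m = ScalarField(grid, np.ones(grid.shape))
            P = solve_ifp(m, cf, fp, dirichlet(fp.normal_equilibrium_pressure))
            r = grid.radius_from_center()
            exact = analytic_ifp_radial(R, fp, r.ravel()).reshape(grid.shape)
            errs.append(np.linalg.norm(P.values - exact) / np.linalg.norm(exact))
        assert errs[1] < 0.7 * errs[0]
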