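"""Unit and property tests for the domain types and PDE right-hand sides."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from virorad import (
    NO_FLUX,
    BoundaryCondition,
    FieldState,
    ModelParameters,
    RadialGrid,
    RadiationSchedule,
    fixed_value,
    radial_laplacian,
    rhs_phase1,
    rhs_phase2,
)
from virorad.testing import perturbed_parameters, uniform_state


class TestModelParameters:
    def test_defaults_match_published_rates(self):
        p = ModelParameters()
        assert p.D1 == 1e-8 and p.D2 == 5e-7
        assert p.r1 == 0.02 and p.beta == 7e-10 and p.delta == 1 / 18
        assert p.b == 50 and p.kappa == 1 and p.alpha == 0.008
        assert p.a1 == p.a2 == p.gamma == 0.01
        assert p.r_b == 0.01 and p.BVF == 0.05
        assert p.v0 == 0.5e6 and p.x0 == 0.5e6 and p.t_r == 120.0
        assert p.r_outer == pytest.approx(0.2)

    @pytest.mark.parametrize(
        "bad", [{"BVF": 1.5}, {"BVF": 0.0}, {"r_b": -0.01}, {"x0": 0.0},
                {"kappa": -1.0}, {"r1": -0.02}, {"delta": np.nan}],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    def test_zero_rates_allowed_for_limits(self):
        ModelParameters(D1=0.0, D2=0.0, r1=0.0, beta=0.0, delta=0.0, alpha=0.0, v0=0.0)

    def test_with_overrides_rejects_unknown_name(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ModelParameters().with_overrides(burst=2.0)


class TestRadialGrid:
    def test_nodes_span_annulus_uniformly(self, params):
        g = RadialGrid.from_parameters(params, 191)
        assert g.nodes[0] == params.r_b
        assert g.nodes[-1] == pytest.approx(params.r_outer)
        assert np.allclose(np.diff(g.nodes), g.dr)
        assert g.dr == pytest.approx(0.001, rel=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            RadialGrid(0.01, 0.2, 4)


class TestRadialLaplacian:
    def test_constant_field_maps_to_zero(self, grid):
        assert radial_laplacian(np.full(len(grid), 3.7), grid) == pytest.approx(0.0)

    def test_quadratic_field_interior_value(self, grid):
        # (1/r) d/dr (r * 2r) = 4 exactly for f = r^2
        lap = radial_laplacian(grid.nodes**2, grid)
        assert lap[1:-1] == pytest.approx(4.0, rel=1e-8)

    def test_log_r_is_discrete_harmonic_at_second_order(self):
        # ln r solves (1/r)(r f')' = 0; the residual must shrink ~dr^2.
        # measure away from the inner rim where the truncation constant
        # (~1/r^4) varies rapidly between refinement levels
        errors = []
        for n in (81, 161, 321):
            g = RadialGrid(0.01, 0.2, n)
            lap = radial_laplacian(np.log(g.nodes), g,
                                   inner_bc=fixed_value(np.log(0.01)),
                                   outer_bc=fixed_value(np.log(0.2)))
            window = (g.nodes >= 0.05) & (g.nodes <= 0.19)
            errors.append(np.max(np.abs(lap[window])))
        order = np.log2(errors[0] / errors[1]), np.log2(errors[1] / errors[2])
        assert min(order) > 1.8

    def test_clamped_boundary_nodes_report_zero(self, grid):
        lap = radial_laplacian(grid.nodes**2, grid,
                               inner_bc=fixed_value(1.0), outer_bc=fixed_value(2.0))
        assert lap[0] == 0.0 and lap[-1] == 0.0

    @given(seed=st.integers(0, 2**31 - 1), a=st.floats(-5, 5), b=st.floats(-5, 5))
    @hsettings(max_examples=25, deadline=None)
    def test_linearity_under_no_flux(self, seed, a, b):
        g = RadialGrid(0.01, 0.2, 21)
        r = np.random.default_rng(seed)
        f, h = r.normal(size=21), r.normal(size=21)
        left = radial_laplacian(a * f + b * h, g)
        right = a * radial_laplacian(f, g) + b * radial_laplacian(h, g)
        np.testing.assert_allclose(left, right, rtol=1e-9, atol=1e-9)

    def test_length_mismatch_rejected(self, grid):
        with pytest.raises(ValueError, match="length"):
            radial_laplacian(np.zeros(len(grid) + 1), grid)

    def test_unknown_bc_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown boundary-condition"):
            BoundaryCondition("periodic")


class TestRhsPhase1:
    def test_uniform_uninfected_state_grows_at_r1(self, params, grid):
        # no virus anywhere: only exponential growth of x remains
        state = uniform_state(grid, x=params.x0, y=0.0, v=0.0)
        d = rhs_phase1(state, params, grid, v_inner_bc=fixed_value(0.0))
        assert d.x == pytest.approx(params.r1 * params.x0, rel=1e-12)  # = 1e4
        assert d.y == pytest.approx(0.0)
        assert d.v == pytest.approx(0.0)

    def test_pure_infected_decay_and_burst(self, params, grid):
        y_star = 1.234e5
        state = uniform_state(grid, x=0.0, y=y_star, v=0.0)
        d = rhs_phase1(state, params, grid, v_inner_bc=fixed_value(0.0))
        assert d.y == pytest.approx(-params.delta * y_star, rel=1e-12)
        # wall node is Dirichlet-clamped, so its derivative is suppressed
        assert d.v[0] == 0.0
        assert d.v[1:] == pytest.approx(params.b * params.delta * y_star, rel=1e-12)

    def test_reaction_arithmetic_without_diffusion(self, grid):
        # dx/dt = r1 x - beta x v = 0.02e6 - 7e2 at x = v = 1e6
        p = ModelParameters(D1=0.0, D2=0.0)
        state = uniform_state(grid, x=1e6, y=0.0, v=1e6)
        d = rhs_phase1(state, p, grid, v_inner_bc=NO_FLUX)
        assert d.x == pytest.approx(0.02e6 - 7e2, rel=1e-12)

    def test_dirichlet_node_derivative_suppressed(self, params, grid):
        state = uniform_state(grid, x=params.x0, y=0.0, v=params.v0)
        d = rhs_phase1(state, params, grid)
        assert d.v[0] == 0.0

    def test_state_with_damage_field_rejected(self, params, grid):
        state = uniform_state(grid, x=1.0, y=0.0, v=0.0, with_damage=True)
        with pytest.raises(ValueError, match="without"):
            rhs_phase1(state, params, grid)

    def test_purity_and_input_preservation(self, params, grid):
        state = uniform_state(grid, x=params.x0, y=10.0, v=params.v0)
        before = {k: v.copy() for k, v in state.arrays().items()}
        d1 = rhs_phase1(state, params, grid)
        d2 = rhs_phase1(state, params, grid)
        for k in ("x", "y", "v"):
            np.testing.assert_array_equal(getattr(d1, k), getattr(d2, k))
            np.testing.assert_array_equal(state.arrays()[k], before[k])


class TestRhsPhase2:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_radiation_reduces_to_virotherapy_model(self, grid, seed, rng):
        p = perturbed_parameters(seed)
        fields = {k: rng.uniform(0.0, 1e6, len(grid)) for k in "xyvu"}
        s3 = FieldState(5.0, fields["x"], fields["y"], fields["v"])
        s4 = FieldState(5.0, fields["x"], fields["y"], fields["v"], fields["u"])
        off = RadiationSchedule(mode="off", t0=0.0)
        d3 = rhs_phase1(s3, p, grid)
        d4 = rhs_phase2(s4, p, grid, off)
        np.testing.assert_array_equal(d4.x, d3.x)
        np.testing.assert_array_equal(d4.y, d3.y)
        np.testing.assert_array_equal(d4.v, d3.v)
        np.testing.assert_array_equal(d4.u, -p.gamma * fields["u"])

    def test_damage_equilibrium_closed_form(self, params, grid):
        # du/dt = a1 R x + a2 R y - gamma u vanishes at u* = R(a1 x + a2 y)/gamma
        R = 2.0
        xbar, ybar = 1e4, 0.0
        u_star = R * (params.a1 * xbar + params.a2 * ybar) / params.gamma
        assert u_star == pytest.approx(2e4)
        sched = RadiationSchedule(mode="constant", R_const=R, t0=0.0)
        state = FieldState(
            10.0,
            np.full(len(grid), xbar), np.full(len(grid), ybar),
            np.zeros(len(grid)), np.full(len(grid), u_star),
        )
        d = rhs_phase2(state, params, grid, sched)
        assert d.u == pytest.approx(0.0, abs=1e-9)

    def test_damage_relaxation_matches_exponential_solution(self, params, grid):
        # with frozen x, y the u-equation integrates to u* (1 - e^{-gamma t})
        R, xbar, ybar = 1.5, 2e4, 5e3
        u_star = R * (params.a1 * xbar + params.a2 * ybar) / params.gamma
        sched = RadiationSchedule(mode="constant", R_const=R, t0=0.0)
        u, dt = 0.0, 0.05
        state = FieldState(
            0.0, np.full(len(grid), xbar), np.full(len(grid), ybar),
            np.zeros(len(grid)), np.zeros(len(grid)),
        )
        for _ in range(int(200 / dt)):
            du = rhs_phase2(state, params, grid, sched).u[0]
            u += dt * du
            state.u[:] = u
        expected = u_star * (1.0 - np.exp(-params.gamma * 200.0))
        assert u == pytest.approx(expected, rel=1e-3)

    def test_missing_damage_field_rejected(self, params, grid):
        state = uniform_state(grid, x=1.0, y=0.0, v=0.0)
        with pytest.raises(ValueError, match="damaged-cell"):
            rhs_phase2(state, params, grid, RadiationSchedule(t0=0.0))

    def test_schedule_undefined_before_start_rejected(self, params, grid):
        state = uniform_state(grid, x=1.0, y=0.0, v=0.0, with_damage=True)
        with pytest.raises(ValueError, match="starts at"):
            rhs_phase2(state, params, grid, RadiationSchedule(t0=100.0))
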