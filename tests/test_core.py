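"""Wound PDE core: initial conditions, discrete operators, solver behaviour."""

import numpy as np
import pytest

from woundangio import (
    InjectionEvent,
    MRNAParameters,
    RadialGrid,
    ScaleSet,
    WoundModelParameters,
)
from woundangio.core import (
    SimulationResult,
    initial_conditions,
    open_wound_fraction,
    rhs,
    solve,
    step,
    time_to_closure,
)


def pure_diffusion_params(**kw):
    """All kinetics off; sealed edges (zero Dirichlet/Robin rates)."""
    base = dict(lambda0=0.0, lambda1=0.0, lambda2=0.0, mu_n=0.0, chi=0.0,
                n_hat=0.0, alpha=0.0, lambda4=0.0, lambda5=0.0, lambda7=0.0,
                mu_b=0.0, b_hat=0.0, b_tilde=0.0)
    base.update(kw)
    return WoundModelParameters(**base)


class TestScales:
    def test_time_scale_matches_printed_conversion(self):
        # R^2/D_a with R = 5 mm, D_a = 1e-6 cm^2/s
        assert ScaleSet().time_scale_days == pytest.approx(2.894, abs=5e-3)

    def test_cell_volumes_partition_the_unit_disc(self):
        for n in (11, 101, 201):
            vols = RadialGrid(n_nodes=n).cell_volumes
            assert vols.sum() == pytest.approx(1.0, abs=1e-14)
            assert (vols > 0).all()


class TestInitialConditions:
    def test_chemoattractant_and_mrna_start_at_zero(self, grid101):
        state = initial_conditions(WoundModelParameters(), grid101)
        assert not state.a.any()
        assert not state.m.any()

    def test_tip_density_zero_inside_margin(self, grid101):
        state = initial_conditions(WoundModelParameters(), grid101)
        r = grid101.r
        assert not state.n[r <= 0.95].any()

    def test_margin_polynomial_value(self):
        # n_hat = 2, r_tilde = 0.95 evaluated at r = 0.975
        grid = RadialGrid(n_nodes=41)  # 0.975 is a node of this grid
        state = initial_conditions(WoundModelParameters(n_hat=2.0), grid)
        j = int(np.argmin(np.abs(grid.r - 0.975)))
        assert state.n[j] == pytest.approx(0.00423, abs=5e-6)

    def test_edge_nodes_carry_boundary_values(self, grid101):
        p = WoundModelParameters()
        state = initial_conditions(p, grid101)
        assert state.n[-1] == p.n_hat
        assert state.b[-1] == p.b_hat

    def test_invalid_r_tilde_rejected(self):
        with pytest.raises(ValueError, match="r_tilde"):
            WoundModelParameters(r_tilde=1.2)


class TestRHS:
    def test_uniform_avascular_state_sources_chemoattractant(self, grid101):
        """n=0, a=0, b=1, m=0: da/dt = lambda4/2 everywhere (tanh switch at
        its midpoint), dn/dt = db/dt = dm/dt = 0 in the interior."""
        p = WoundModelParameters(b_hat=1.0)
        state = initial_conditions(p, grid101)
        state.n[:] = 0.0
        state.b[:] = 1.0
        dn, da, db, dm = rhs(state, p, grid=grid101)
        assert np.allclose(da, p.lambda4 / 2.0, rtol=0, atol=1e-9)
        assert np.allclose(dn, 0.0) and np.allclose(db, 0.0)
        assert np.allclose(dm, 0.0)

    def test_production_switch_saturates_off(self, grid101):
        p = WoundModelParameters(b_hat=1.0 + 10.0 * 0.01)
        state = initial_conditions(p, grid101)
        state.n[:] = 0.0
        state.b[:] = 1.0 + 10.0 * p.delta
        _, da, _, _ = rhs(state, p, grid=grid101)
        # tanh(-10) leaves ~2e-9 of the production rate
        assert np.abs(da).max() < p.lambda4 * 1e-8 + 1e-9

    def test_mrna_decouples_when_kgen_zero(self, grid101):
        p = WoundModelParameters()
        mr0 = MRNAParameters(k_gen=0.0)
        state = initial_conditions(p, grid101)
        state.m[:] = 0.7
        _, da_m, _, _ = rhs(state, p, mr0, grid101)
        state.m[:] = 0.0
        _, da_0, _, _ = rhs(state, p, mr0, grid101)
        assert np.allclose(da_m, da_0)

    def test_radial_operator_matches_analytic_laplacian(self):
        """FV divergence approximates u'' + u'/r on a smooth profile,
        including the symmetric limit 2 u'' at the axis."""
        grid = RadialGrid(n_nodes=401)
        r = grid.r
        p = pure_diffusion_params(lambda4=0.0)
        state = initial_conditions(p, grid)
        state.a[:] = np.cos(np.pi * r)  # even at r=0, zero-flux-compatible
        _, da, _, _ = rhs(state, p, grid=grid)
        # u'' + u'/r with u = cos(pi r); the ratio tends to u''(0) at the axis
        with np.errstate(divide="ignore", invalid="ignore"):
            exact = -np.pi**2 * np.cos(np.pi * r) \
                - np.pi * np.sin(np.pi * r) / r
        exact[0] = -2.0 * np.pi**2
        assert np.allclose(da[:-1], exact[:-1], rtol=0, atol=0.02)


class TestStep:
    def test_zero_dt_is_identity(self, grid101, fitted_params):
        state = initial_conditions(fitted_params, grid101)
        new, info = step(state, fitted_params, grid=grid101, dt=0.0)
        for f in ("n", "a", "b", "m"):
            assert np.array_equal(getattr(new, f), getattr(state, f))

    def test_one_default_step_is_finite_without_clipping(self, grid101,
                                                         fitted_params):
        state = initial_conditions(fitted_params, grid101)
        new, info = step(state, fitted_params, grid=grid101)
        for f in ("n", "a", "b", "m"):
            assert np.isfinite(getattr(new, f)).all()
        assert all(v == 0.0 for v in info["clipped_mass"].values())

    def test_pure_diffusion_conserves_discrete_mass(self, grid101):
        """Sealed, reaction-free configuration: the a-mass drifts by less
        than 1e-10 of itself per step."""
        p = pure_diffusion_params()
        state = initial_conditions(p, grid101)
        rng = np.random.default_rng(0)
        state.a[:] = rng.uniform(0.5, 2.0, grid101.n_nodes)
        vols = grid101.cell_volumes
        m0 = float(vols @ state.a)
        n_steps = 200
        new = state
        for _ in range(n_steps):
            new, _ = step(new, p, grid=grid101)
        drift = abs(float(vols @ new.a) - m0)
        assert drift < 1e-10 * m0 * n_steps


class TestOpenWoundFraction:
    def test_fully_open_and_fully_vascularized(self):
        assert open_wound_fraction(np.zeros(101)) == 1.0
        assert open_wound_fraction(np.ones(101)) == 0.0

    def test_linear_profile_crossing(self):
        r = np.linspace(0.0, 1.0, 201)
        assert open_wound_fraction(r) == pytest.approx(0.01, abs=1e-6)

    def test_interior_island_counts_as_closed(self):
        """A vascularised annulus inside the wound reduces the open area by
        its own measure (the open region is a set, not a disc)."""
        r = np.linspace(0.0, 1.0, 2001)
        b = np.where((r > 0.4) & (r < 0.6), 1.0, 0.0)
        b[-1] = 1.5
        expected = 1.0 - (0.6**2 - 0.4**2) - (1.0 - 0.9995**2)
        assert open_wound_fraction(b) == pytest.approx(expected, abs=1e-3)


class TestTimeToClosure:
    def _result(self, days, fracs):
        return SimulationResult(np.asarray(days, float),
                                np.asarray(fracs, float))

    def test_linear_decay_interpolates(self):
        res = self._result([0, 10], [1.0, 0.0])
        assert time_to_closure(res, 0.5) == pytest.approx(5.0)

    def test_target_one_is_time_zero(self):
        res = self._result([0, 1, 2], [0.9, 0.8, 0.7])
        assert time_to_closure(res, 1.0) == 0.0

    def test_never_crossing_returns_nan_sentinel(self):
        res = self._result([0, 1, 2], [1.0, 0.9, 0.8])
        assert np.isnan(time_to_closure(res, 0.5))

    def test_relative_to_initial_fraction(self):
        res = self._result([0, 4], [0.8, 0.0])
        # target is 0.5 * 0.8 = 0.4, crossed at t = 2
        assert time_to_closure(res, 0.5) == pytest.approx(2.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            time_to_closure(self._result([0], [1.0]), 0.0)


class TestVehicleRun:
    """Properties of the production-resolution 36-day vehicle simulation."""

    def test_open_area_decreases_monotonically_after_day_one(
            self, vehicle_result):
        f = vehicle_result.open_area_fraction
        t = vehicle_result.times_days
        late = t >= 1.0
        assert np.all(np.diff(f[late]) <= 1e-12)

    def test_negligible_clipping_over_full_run(self, vehicle_result):
        total = sum(vehicle_result.clipped_mass.values())
        assert total < 1e-4

    def test_front_radius_nonincreasing_after_transient(self, vehicle_result,
                                                        fitted_params):
        radii = []
        for day in range(2, 37, 2):
            b = vehicle_result.snapshots[float(day)].b
            open_nodes = np.nonzero(b < fitted_params.closure_threshold)[0]
            radii.append(open_nodes[-1] if open_nodes.size else -1)
        assert all(r1 <= r0 for r0, r1 in zip(radii, radii[1:]))

    def test_late_time_crowding_near_centre(self, vehicle_result):
        """Cylindrical focusing concentrates capillary tips near r = 0 as
        the front converges, and the closure rate slows in the final phase.

        (The deposition flux vanishes at the axis by symmetry, so vessels
        fill the centre without overshooting the mid-wound plateau; the
        crowding signature lives in the tip field.)"""
        snap = vehicle_result.snapshots[35.0]
        N = snap.n.size
        centre = slice(0, N // 10)
        mid = slice(int(0.45 * N), int(0.55 * N))
        assert snap.n[centre].mean() > 10.0 * snap.n[mid].mean()
        t = vehicle_result.times_days
        f = vehicle_result.open_area_fraction
        rate_mid = (np.interp(4.0, t, f) - np.interp(10.0, t, f)) / 6.0
        rate_late = (np.interp(14.0, t, f) - np.interp(20.0, t, f)) / 6.0
        assert rate_late < rate_mid

    def test_solver_settings_do_not_move_t50(self, fitted_params, grid201,
                                             scales):
        """Doubling the output cadence and halving the stability safety
        factor changes t50 by < 0.1 day."""
        ref = solve(fitted_params, t_end_days=16.0, output_dt_days=0.1,
                    grid=grid201, scales=scales, stop_open_frac=0.45)
        fine = solve(fitted_params, t_end_days=16.0, output_dt_days=0.05,
                     grid=RadialGrid(n_nodes=201, safety=0.1),
                     scales=scales, stop_open_frac=0.45)
        assert abs(time_to_closure(ref, 0.5) -
                   time_to_closure(fine, 0.5)) < 0.1

    def test_injection_list_empty_ignores_kgen(self, fitted_params, grid61,
                                               scales):
        """Without injections m stays 0, so k_gen is irrelevant."""
        a = solve(fitted_params, MRNAParameters(k_gen=7e7), (),
                  t_end_days=4.0, output_dt_days=0.5, grid=grid61,
                  scales=scales)
        b = solve(fitted_params, MRNAParameters(k_gen=0.0), (),
                  t_end_days=4.0, output_dt_days=0.5, grid=grid61,
                  scales=scales)
        assert np.array_equal(a.open_area_fraction, b.open_area_fraction)
        assert not a.m_total.any()

    def test_injection_beyond_horizon_rejected(self, fitted_params, grid61):
        with pytest.raises(ValueError, match="beyond"):
            solve(fitted_params, MRNAParameters(),
                  [InjectionEvent(10.0)], t_end_days=5.0, grid=grid61)
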