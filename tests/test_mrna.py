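"""mRNA deposition, transport invariants and the generation-rate fit."""

import numpy as np
import pytest

from woundangio import (
    InjectionEvent,
    MRNAParameters,
    ScaleSet,
    WoundModelParameters,
)
from woundangio.core import initial_conditions, solve
from woundangio.mrna import (
    deposit_dose,
    dimensionless_dose_mass,
    fit_kgen,
    healed_state,
    net_generation_curve,
    nondim_degradation,
    uniform_dose,
)
from woundangio.pk import DoseEvent, PKParameters, PKTimecourse, simulate_pk


def transport_only_params(**kw):
    """Wound model with every kinetic pathway off (m evolves alone)."""
    base = dict(lambda0=0.0, lambda1=0.0, lambda2=0.0, mu_n=0.0, chi=0.0,
                n_hat=0.0, alpha=0.0, lambda4=0.0, lambda5=0.0, lambda7=0.0,
                mu_b=0.0, b_hat=0.0, b_tilde=0.0)
    base.update(kw)
    return WoundModelParameters(**base)


class TestNondimensionalization:
    def test_degradation_rate_scale(self, scales):
        # (R^2/D_a) * k1 = 69.44 h * 0.055 / h
        assert nondim_degradation(0.055, scales) == pytest.approx(3.82,
                                                                  abs=0.005)

    def test_zero_rate(self, scales):
        assert nondim_degradation(0.0, scales) == 0.0

    def test_quadratic_in_radius(self):
        s1, s2 = ScaleSet(R_mm=5.0), ScaleSet(R_mm=10.0)
        assert nondim_degradation(0.055, s2) == pytest.approx(
            4.0 * nondim_degradation(0.055, s1))


class TestDeposit:
    def test_zero_dose_is_identity(self, grid101, scales, fitted_params):
        state = initial_conditions(fitted_params, grid101)
        deposit_dose(state, InjectionEvent(0.0, dose_ug=0.0), scales, grid101)
        assert not state.m.any()

    @pytest.mark.parametrize("radius_mm", [5.0, 4.0, 2.5, 0.5])
    def test_discrete_mass_matches_dose(self, grid101, scales, fitted_params,
                                        radius_mm):
        state = initial_conditions(fitted_params, grid101)
        deposit_dose(state, InjectionEvent(0.0, radius_mm=radius_mm),
                     scales, grid101)
        target = dimensionless_dose_mass(100.0, scales)
        got = float(grid101.cell_volumes @ state.m)
        assert got == pytest.approx(target, rel=5e-3)

    def test_two_half_doses_equal_one_full(self, grid101, scales,
                                           fitted_params):
        s1 = initial_conditions(fitted_params, grid101)
        deposit_dose(s1, InjectionEvent(0.0, dose_ug=100.0), scales, grid101)
        s2 = initial_conditions(fitted_params, grid101)
        for _ in range(2):
            deposit_dose(s2, InjectionEvent(0.0, dose_ug=50.0), scales,
                         grid101)
        assert np.allclose(s1.m, s2.m, rtol=0, atol=1e-15)

    def test_radius_outside_domain_rejected(self, grid101, scales,
                                            fitted_params):
        state = initial_conditions(fitted_params, grid101)
        with pytest.raises(ValueError, match="radius"):
            deposit_dose(state, InjectionEvent(0.0, radius_mm=6.0), scales,
                         grid101)

    def test_uniform_dose_constant_and_mass_equivalent(self, grid101, scales,
                                                       fitted_params):
        state = initial_conditions(fitted_params, grid101)
        uniform_dose(state, 100.0, scales, grid101)
        assert np.allclose(state.m, state.m[0])
        got = float(grid101.cell_volumes @ state.m)
        assert got == pytest.approx(dimensionless_dose_mass(100.0, scales),
                                    rel=5e-3)


class TestTransportInvariants:
    def test_sealed_mass_decays_at_the_degradation_rate(self, grid101,
                                                        scales):
        """With lambda8 = 0 (sealed edge) total mRNA follows
        exp(-(R^2/D_a) k1 t) to < 1e-3 relative over 6 days."""
        p = transport_only_params()
        mr = MRNAParameters(D_m_cm2_s=3e-9, lambda8=0.0, k_gen=0.0)
        res = solve(p, mr, [InjectionEvent(0.0, radius_mm=4.0)],
                    t_end_days=6.0, output_dt_days=0.5, grid=grid101,
                    scales=scales)
        k1_nd = mr.k1_dimless(scales)
        t_nd = res.times_days / scales.time_scale_days
        expected = res.m_total[0] * np.exp(-k1_nd * t_nd)
        rel = np.abs(res.m_total - expected) / res.m_total[0]
        assert rel.max() < 1e-3

    def test_immobile_mrna_keeps_its_support(self, grid101, scales):
        """D_m = 0: the deposit never spreads to new nodes."""
        p = transport_only_params()
        mr = MRNAParameters(D_m_cm2_s=0.0, k_gen=0.0)
        res = solve(p, mr, [InjectionEvent(0.0, radius_mm=3.0)],
                    t_end_days=2.0, output_dt_days=1.0, grid=grid101,
                    scales=scales, snapshot_days=(0.0, 2.0))
        m0 = res.snapshots[0.0].m
        m2 = res.snapshots[2.0].m
        assert np.array_equal(m0 > 0, m2 > 0)

    def test_edge_loss_monotone_in_diffusivity(self, grid101, scales):
        """Cumulative border loss of a border deposit grows with D_m: after
        correcting for bulk degradation, less mass remains at higher
        diffusivity (the fast-diffusion scenarios lose drug to surrounding
        tissue). The edge clearance is proportional to the edge vessel
        density, so the border must stay vascularized here."""
        p = transport_only_params(b_hat=1.5)
        remaining = []
        for dm in (3e-9, 1e-7, 1e-5):
            mr = MRNAParameters(D_m_cm2_s=dm, k_gen=0.0)  # lambda8 = 20
            res = solve(p, mr, [InjectionEvent(0.0, radius_mm=5.0)],
                        t_end_days=2.0, output_dt_days=1.0, grid=grid101,
                        scales=scales)
            k1_nd = mr.k1_dimless(scales)
            t_nd = res.times_days[-1] / scales.time_scale_days
            remaining.append(res.m_total[-1] * np.exp(k1_nd * t_nd))
        assert remaining[0] > remaining[1] > remaining[2]


@pytest.fixture(scope="module")
def healed101(fitted_params, grid101, scales):
    return healed_state(fitted_params, grid101, scales)


class TestFitKgen:
    def test_healed_wound_is_closed_and_stationary(self, healed101,
                                                   fitted_params):
        assert (healed101.b >= fitted_params.closure_threshold).all()
        assert healed101.n.max() < 0.05

    def test_zero_target_curve_gives_zero_rate(self, healed101,
                                               fitted_params, grid101,
                                               scales):
        pk_curve = PKTimecourse(np.array([6.0, 24.0]), np.zeros(2),
                                np.zeros(2))
        assert fit_kgen(pk_curve, fitted_params, MRNAParameters(), scales,
                        grid101, healed=healed101) == 0.0

    def test_round_trip_recovers_known_rate(self, healed101, fitted_params,
                                            grid101, scales):
        """Fit a synthetic target generated at a known k_gen*: recovery
        within 1%."""
        times = np.array([6.0, 24.0, 48.0, 72.0, 144.0])
        mr = MRNAParameters()
        G = net_generation_curve(healed101, 100.0, times, fitted_params,
                                 mr, grid101, scales, k_gen=1.0)
        k_true = 4.2e4
        conversion = 0.7
        target = PKTimecourse(times, np.zeros_like(times),
                              conversion * k_true * G)
        k_fit = fit_kgen(target, fitted_params, mr, scales, grid101,
                         conversion=conversion, healed=healed101)
        assert k_fit == pytest.approx(k_true, rel=1e-2)

    def test_default_fit_reproduces_published_rate(self, healed101,
                                                   fitted_params, grid101,
                                                   scales):
        """Under the package calibration the 100 ug uniform-dose fit lands
        on the published dimensionless generation rate."""
        times = np.array([6.0, 24.0, 48.0, 72.0, 144.0])
        pk_curve = simulate_pk(PKParameters(), [DoseEvent(0.0, 100.0)],
                               times)
        k_fit = fit_kgen(pk_curve, fitted_params, MRNAParameters(), scales,
                         grid101, healed=healed101)
        assert k_fit == pytest.approx(1.53e5, rel=0.02)
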