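import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from sdglu.constants import MM_UM3_TO_FMOL, amount_from_molecules
from sdglu.glutamate import (
    GlutamatePools,
    ParameterError,
    ReceptorParams,
    ReleaseParams,
    StateValidityError,
    UptakeParams,
    calibrate_release_rate,
    cleft_to_glia_factor,
    diffusion_flux,
    effective_vmaxes,
    envelope_volume_for_increment,
    glutamate_rhs,
    michaelis_km,
    nmda_mg_block,
    receptor_currents,
    receptor_density_bounds,
    receptor_gate_fixed_point,
    receptor_gate_rhs,
    release_flux,
    total_glutamate,
    uptake_velocity,
)

RELEASE = ReleaseParams(R_max=1e-5, V_cr=-20.0, V_hi=30.0, N_max=2e-3, k_rec=1e-4)


class TestRelease:
    def test_zero_below_critical_potential(self):
        assert release_flux(RELEASE.V_cr - 10.0, RELEASE.N_max, RELEASE) == 0.0

    def test_continuous_at_critical_potential(self):
        eps = 1e-9
        below = release_flux(RELEASE.V_cr - eps, RELEASE.N_max, RELEASE)
        above = release_flux(RELEASE.V_cr + eps, RELEASE.N_max, RELEASE)
        assert below == 0.0
        assert above == pytest.approx(0.0, abs=1e-20)

    def test_midpoint_gives_quarter_of_maximum(self):
        v_mid = 0.5 * (RELEASE.V_cr + RELEASE.V_hi)
        assert release_flux(v_mid, RELEASE.N_max, RELEASE) == pytest.approx(
            RELEASE.R_max / 4.0, rel=1e-12
        )

    @given(frac=st.floats(0.0, 1.0), v=st.floats(-19.9, 60.0))
    def test_scales_linearly_with_releasable_pool(self, frac, v):
        full = release_flux(v, RELEASE.N_max, RELEASE)
        part = release_flux(v, frac * RELEASE.N_max, RELEASE)
        assert part == pytest.approx(frac * full, rel=1e-9, abs=1e-30)

    def test_unclamped_by_default_and_clamp_option(self):
        v = RELEASE.V_hi + 50.0  # quadratic factor 2.56
        unclamped = release_flux(v, RELEASE.N_max, RELEASE)
        assert unclamped > RELEASE.R_max
        clamped = ReleaseParams(
            R_max=RELEASE.R_max, V_cr=-20.0, V_hi=30.0, N_max=2e-3,
            clamp_quadratic=True,
        )
        assert release_flux(v, RELEASE.N_max, clamped) == pytest.approx(RELEASE.R_max)

    def test_invalid_potential_ordering_rejected(self):
        with pytest.raises(ParameterError):
            ReleaseParams(R_max=1.0, V_cr=0.0, V_hi=-10.0)

    def test_calibration_hits_target_amount(self):
        """R_max from a synthetic one-spike waveform makes the integral of
        the release flux equal 3,000 molecules."""
        t = np.linspace(0.0, 10.0, 4001)
        V = -70.0 + 110.0 * np.exp(-((t - 2.0) ** 2) / 0.5)
        r_max = calibrate_release_rate(t, V, RELEASE)
        p = ReleaseParams(R_max=r_max, V_cr=-20.0, V_hi=30.0, N_max=2e-3)
        flux = [release_flux(v, p.N_max, p) for v in V]
        released = np.trapezoid(flux, t)
        assert released == pytest.approx(amount_from_molecules(3000.0), rel=1e-9)

    def test_calibration_requires_suprathreshold_waveform(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(ParameterError):
            calibrate_release_rate(t, np.full_like(t, -70.0), RELEASE)


class TestReceptorGates:
    def test_absorbing_and_closing_limits(self):
        assert receptor_gate_rhs(0.0, 0.0, 1.1, 0.19) == 0.0
        assert receptor_gate_rhs(0.0, 1.0, 1.1, 0.19) == pytest.approx(-0.19)

    @given(gc=st.floats(1e-6, 50.0), alpha=st.floats(1e-3, 5.0), beta=st.floats(1e-4, 1.0))
    def test_fixed_point_formula(self, gc, alpha, beta):
        r_inf = receptor_gate_fixed_point(gc, alpha, beta)
        assert receptor_gate_rhs(gc, r_inf, alpha, beta) == pytest.approx(0.0, abs=1e-12)
        assert 0.0 < r_inf < 1.0

    def test_balance_point_at_half(self):
        assert receptor_gate_fixed_point(0.19 / 1.1, 1.1, 0.19) == pytest.approx(0.5)

    @given(gc=st.floats(0.0, 30.0), r0=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_gate_stays_in_unit_interval_under_integration(self, gc, r0):
        sol = solve_ivp(
            lambda t, r: [receptor_gate_rhs(gc, r[0], 1.1, 0.19)],
            (0.0, 100.0), [r0], rtol=1e-9, atol=1e-12,
        )
        assert np.all(sol.y >= -1e-9)
        assert np.all(sol.y <= 1.0 + 1e-9)


class TestReceptorCurrents:
    P = ReceptorParams()

    def test_closed_gates_carry_no_current(self):
        assert receptor_currents(-20.0, 0.0, 0.0, 55.0, -90.0, self.P) == (0, 0, 0, 0)

    def test_sodium_reversal_potential(self):
        i_na_a, _, i_na_n, _ = receptor_currents(55.0, 0.5, 0.5, 55.0, -90.0, self.P)
        assert i_na_a == 0.0
        assert i_na_n == 0.0

    def test_mg_block_denominator_at_zero_potential(self):
        # 1 + 0.33 * e^-0.7 for 1 mM Mg2+ at V = 0
        assert 1.0 / nmda_mg_block(0.0, 1.0) == pytest.approx(1.1639, abs=2e-4)

    def test_mg_block_relieved_by_depolarization(self):
        assert nmda_mg_block(40.0, 1.0) > nmda_mg_block(-80.0, 1.0)

    def test_ampa_current_is_ohmic_in_gate(self):
        i1 = receptor_currents(-20.0, 0.0, 0.3, 55.0, -90.0, self.P)
        i2 = receptor_currents(-20.0, 0.0, 0.6, 55.0, -90.0, self.P)
        assert i2[0] == pytest.approx(2.0 * i1[0])
        assert i2[1] == pytest.approx(2.0 * i1[1])


class TestDiffusion:
    U = UptakeParams()

    def test_no_gradient_no_flux(self, morph):
        assert diffusion_flux(3.0, 3.0, morph, self.U) == 0.0

    def test_antisymmetric_and_linear(self, morph):
        j1 = diffusion_flux(2.0, 1.0, morph, self.U)
        j2 = diffusion_flux(1.0, 2.0, morph, self.U)
        j3 = diffusion_flux(3.0, 1.0, morph, self.U)
        assert j1 == pytest.approx(-j2, rel=1e-14)
        assert j3 == pytest.approx(2.0 * j1, rel=1e-14)

    def test_efflux_is_negative(self, morph):
        assert diffusion_flux(10.0, 0.1, morph, self.U) < 0.0

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ParameterError):
            UptakeParams(dx=0.0)


class TestUptakeVelocity:
    def test_zero_at_zero(self):
        assert uptake_velocity(0.0, 0.03, 0.02) == 0.0

    def test_half_saturation(self):
        assert uptake_velocity(0.02, 0.03, 0.02) == pytest.approx(0.015)

    def test_saturates_at_vmax(self):
        v = uptake_velocity(1e4 * 0.02, 0.03, 0.02)
        assert v == pytest.approx(0.03, rel=1e-4)

    @given(
        k1=st.floats(0.1, 10.0),
        km1=st.floats(0.01, 5.0),
        kr=st.floats(0.01, 5.0),
        g=st.floats(1e-4, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_quasi_steady_state_of_transporter_scheme(self, k1, km1, kr, g):
        """Independent oracle: find the stationary occupancy of the
        binding-site scheme G + B <-> GB -> G_up + B (fixed G, total
        transporter B_tot) by bisection on its balance condition and
        compare the transport velocity kr*[GB] with the Michaelis-Menten
        form."""
        from scipy.optimize import brentq

        b_tot = 1.0
        gb = brentq(
            lambda x: k1 * g * (b_tot - x) - (km1 + kr) * x,
            0.0, b_tot, xtol=1e-16, rtol=1e-15,
        )
        v_oracle = kr * gb
        km = michaelis_km(k1, km1, kr)
        v = uptake_velocity(g, kr * b_tot, km)
        assert v == pytest.approx(v_oracle, rel=1e-10, abs=1e-10)

    def test_quasi_steady_state_holds_under_time_integration(self):
        """One direct check that the stationary occupancy is the attractor
        of the transporter kinetics, not just the algebraic balance."""
        k1, km1, kr, g, b_tot = 1.3, 0.4, 0.7, 0.25, 1.0
        sol = solve_ivp(
            lambda t, y: [k1 * g * (b_tot - y[0]) - (km1 + kr) * y[0]],
            (0.0, 200.0), [0.0], rtol=1e-12, atol=1e-14,
        )
        v_dyn = kr * sol.y[0, -1]
        v = uptake_velocity(g, kr * b_tot, michaelis_km(k1, km1, kr))
        assert v == pytest.approx(v_dyn, rel=1e-8)

    def test_negative_concentration_rejected(self):
        with pytest.raises(StateValidityError):
            uptake_velocity(-1.0, 0.03, 0.02)


class TestEffectiveVmaxes:
    def test_glial_cleft_velocity_is_four_times_neuronal(self, morph):
        v_cn, v_cg, _, _ = effective_vmaxes(0.03, morph.omega_e0, morph)
        assert v_cg == pytest.approx(4.0 * v_cn)

    def test_factor_four_derives_from_densities_and_areas(self, morph):
        """8x glial binding-site density on half the contact area."""
        assert cleft_to_glia_factor(morph, rho_ratio=8.0) == pytest.approx(4.0)

    def test_ecs_velocities_at_resting_volume(self, morph):
        v_cn, v_cg, v_en, v_eg = effective_vmaxes(0.03, morph.omega_e0, morph)
        assert v_en == pytest.approx(0.12 * v_cn)
        assert v_eg == pytest.approx(0.24 * v_cg)

    def test_ecs_velocities_double_when_ecs_halves(self, morph):
        _, _, v_en0, v_eg0 = effective_vmaxes(0.03, morph.omega_e0, morph)
        _, _, v_en1, v_eg1 = effective_vmaxes(0.03, morph.omega_e0 / 2, morph)
        assert v_en1 == pytest.approx(2.0 * v_en0)
        assert v_eg1 == pytest.approx(2.0 * v_eg0)

    def test_collapsed_ecs_rejected(self, morph):
        with pytest.raises(StateValidityError):
            effective_vmaxes(0.03, 0.0, morph)


class TestPoolDynamics:
    U = UptakeParams()

    def test_empty_quiescent_system_is_stationary(self, morph):
        pools = GlutamatePools(0.0, 0.0, 0.0, 0.0)
        d = glutamate_rhs(pools, RELEASE.V_cr - 30.0, morph.omega_e0, morph,
                          RELEASE, self.U)
        assert d == (0.0, 0.0, 0.0, 0.0)

    @given(
        ni=st.floats(0.0, 2e-3),
        gc=st.floats(0.0, 20.0),
        ge=st.floats(0.0, 5.0),
        nup=st.floats(0.0, 10.0),
        v=st.floats(-80.0, 40.0),
        shrink=st.floats(0.3, 1.0),
        scale=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_glutamate_conserved_by_pool_dynamics(
        self, morph, ni, gc, ge, nup, v, shrink, scale
    ):
        """d/dt[(N_syn/2)(N_i+N_c) + N_e + N_up] = 0 to machine precision
        with conservative recycling, over random valid states."""
        omega_e = morph.omega_e0 * shrink
        pools = GlutamatePools(
            N_i=ni,
            N_c=gc * morph.omega_en * MM_UM3_TO_FMOL,
            N_e=ge * omega_e * MM_UM3_TO_FMOL,
            N_up=nup,
        )
        d_ni, d_nc, d_ne, d_nup = glutamate_rhs(
            pools, v, omega_e, morph, RELEASE, self.U, uptake_scale=scale
        )
        total_rate = 0.5 * morph.N_syn * (d_ni + d_nc) + d_ne + d_nup
        scale_ref = max(abs(d_ni), abs(d_nc), abs(d_ne), abs(d_nup), 1e-12)
        assert abs(total_rate) < 1e-9 * morph.N_syn * scale_ref

    def test_literal_recycling_breaks_conservation(self, morph):
        pools = GlutamatePools(N_i=1e-3, N_c=0.0, N_e=0.0, N_up=5.0)
        d = glutamate_rhs(pools, -70.0, morph.omega_e0, morph, RELEASE, self.U,
                          literal_recycling=True)
        total_rate = 0.5 * morph.N_syn * (d[0] + d[1]) + d[2] + d[3]
        assert abs(total_rate) > 1e-6

    def test_zero_uptake_freezes_buffered_pool(self, morph):
        """With clearance disabled (OGD core) and no prior uptake, the
        buffered pool cannot change while release and diffusion still act."""
        pools = GlutamatePools(N_i=1e-3, N_c=5e-5, N_e=1e-2, N_up=0.0)
        d = glutamate_rhs(pools, -5.0, morph.omega_e0, morph, RELEASE, self.U,
                          uptake_scale=0.0)
        assert d[3] == 0.0
        assert d[1] != 0.0 and d[2] != 0.0

    def test_cleft_efflux_raises_ecs_pool(self, morph):
        pools = GlutamatePools(N_i=0.0, N_c=10.0 * morph.omega_en * MM_UM3_TO_FMOL,
                               N_e=0.0, N_up=0.0)
        d = glutamate_rhs(pools, -70.0, morph.omega_e0, morph, RELEASE, self.U,
                          uptake_scale=0.0)
        assert d[1] < 0.0 and d[2] > 0.0

    def test_negative_pool_rejected(self, morph):
        with pytest.raises(StateValidityError):
            glutamate_rhs(GlutamatePools(-1e-6, 0, 0, 0), -70.0, morph.omega_e0,
                          morph, RELEASE, self.U)


class TestConductanceBounds:
    def test_nmda_upper_bound(self):
        _, hi = receptor_density_bounds(1e-8, 6e-7)
        assert hi == pytest.approx(16.7, abs=0.05)

    def test_nmda_lower_bound(self):
        lo, _ = receptor_density_bounds(1e-8, 6e-7)
        assert lo == pytest.approx(0.3, abs=0.03)

    def test_ampa_bounds(self):
        lo, hi = receptor_density_bounds(3.5e-7, 1e-6)
        assert lo == pytest.approx(9.7, abs=0.05)
        assert hi == pytest.approx(27.8, abs=0.05)

    def test_identity_scaling(self):
        lo, hi = receptor_density_bounds(2.0, 3.0, n_post=20, A_m=1.0, n_syn_ap=20)
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(3.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ParameterError):
            receptor_density_bounds(2.0, 1.0)


class TestEnvelopeCalibration:
    def test_3000_molecules_raise_cleft_concentration_by_1_3_mm(self, morph):
        assert envelope_volume_for_increment(3000.0, 1.3) == pytest.approx(
            3.83e-3, rel=2e-3
        )
        pools = GlutamatePools(
            N_i=0.0, N_c=amount_from_molecules(3000.0), N_e=0.0, N_up=0.0
        )
        assert pools.G_c(morph) == pytest.approx(1.3, rel=1e-6)

    def test_ecs_concentration_increments(self, morph):
        """3,000 molecules in 10,000 synapses shared by two neurons:
        ~0.0033 mM in a 7,500 um^3 ECS per synchronous event, ~0.066 mM
        after 20, ~0.266 mM after 75% ECS shrinkage."""
        released = amount_from_molecules(3000.0) * morph.N_syn / 2.0
        inc1 = released / (morph.omega_e0 * MM_UM3_TO_FMOL)
        assert inc1 == pytest.approx(0.0033, abs=2e-4)
        assert 20 * inc1 == pytest.approx(0.066, abs=4e-3)
        assert 20 * inc1 / 0.25 == pytest.approx(0.266, abs=0.02)
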