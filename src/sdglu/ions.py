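"""Membrane, pump, glial-buffering, bath-exchange, and volume dynamics.

Functional forms follow the standard lineage of Hodgkin-Huxley-based ion
homeostasis models of spreading depolarization: HH spiking currents with
instantaneous Na+ activation, ohmic leaks, a Na+/K+-ATPase modelled as a
product of sigmoids in intracellular Na+ and extracellular K+ (3 Na+ out /
2 K+ in per cycle), first-order glial K+ buffering with a saturable
capacity, linear diffusive K+ exchange with a bath, and osmotically driven
water fluxes.  KCl moves as a pair into glia and across the bath boundary,
which keeps every compartment electroneutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import RTF_MV


def _exp(x: float) -> float:
    """Exponential clamped against overflow for far-out-of-range states."""
    return math.exp(x if x < 50.0 else 50.0)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley gating
# ---------------------------------------------------------------------------


def _linoverexp(x: float, scale: float) -> float:
    """Evaluate ``x / (1 - exp(-x/scale))`` with its removable singularity."""
    if abs(x) < 1e-7:
        return scale
    return x / (1.0 - _exp(-x / scale))


def alpha_n(V: float) -> float:
    return 0.01 * _linoverexp(V + 34.0, 10.0)


def beta_n(V: float) -> float:
    return 0.125 * _exp(-(V + 44.0) / 80.0)


def alpha_m(V: float) -> float:
    return 0.1 * _linoverexp(V + 30.0, 10.0)


def beta_m(V: float) -> float:
    return 4.0 * _exp(-(V + 55.0) / 18.0)


def alpha_h(V: float) -> float:
    return 0.07 * _exp(-(V + 44.0) / 20.0)


def beta_h(V: float) -> float:
    return 1.0 / (1.0 + _exp(-(V + 14.0) / 10.0))


def m_inf(V: float) -> float:
    """Instantaneous Na+ activation (adiabatically eliminated)."""
    a = alpha_m(V)
    return a / (a + beta_m(V))


def gate_inf(alpha: float, beta: float) -> float:
    return alpha / (alpha + beta)


def s_inf(V: float, v_half: float = -20.0, slope: float = 8.0) -> float:
    """Steady state of the slow Na+ window-current inactivation gate.

    Near 1 at rest and strongly reduced during sustained depolarization;
    this caps the persistent Na+ current available to hold a depolarized
    state.
    """
    return 1.0 / (1.0 + _exp((V - v_half) / slope))


# ---------------------------------------------------------------------------
# pump / glia / bath
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PumpGliaParams:
    """Na+/K+ pump, glial buffering, bath coupling, and water permeability.

    ``rho_p`` is the maximal pump current density; the pump activates
    sigmoidally in intracellular Na+ (half ``pump_na_half``, slope
    ``pump_na_slope``) and extracellular K+.  Glial buffering is first
    order with forward rate ``k_f_glia`` per mM of K_e onto the free
    capacity ``W_max - W`` and a backward rate fixed by requiring
    equilibrium at rest (load ``W0`` at resting K_e).  Bath exchange is
    linear diffusive in ``K_bath - K_e`` with rate ``lambda_bath`` and is
    referenced to the resting ECS volume.  ``P_water_*`` convert osmotic
    imbalance (mM) to volume flux (um^3/ms).
    """

    rho_p: float = 5.25  # uA/cm^2
    pump_na_half: float = 25.0  # mM
    pump_na_slope: float = 3.0  # mM
    pump_k_half: float = 5.5  # mM
    pump_k_slope: float = 1.0  # mM
    lambda_bath: float = 2.0e-5  # 1/ms
    k_f_glia: float = 3.0e-6  # 1/ms
    k_glia_thr: float = 18.0  # mM: K_e at half-maximal glial uptake
    k_glia_width: float = 2.5  # mM: steepness of the uptake activation
    W_max: float = 800.0  # fmol glial K+ capacity
    W0: float = 150.0  # fmol glial K+ load at rest
    P_water_n: float = 1.0e-3  # um^3/(ms mM)
    P_water_g: float = 1.0e-3  # um^3/(ms mM)
    #: counter-ion handling of the bath K+ exchange: "na_swap" exchanges K+
    #: against Na+ one-for-one (electro- and osmotically neutral, like the
    #: equimolar NaCl/KCl replacement of a perfusion bath and the Na+/K+
    #: exchange of vascular clearance); "kcl" exports KCl (osmotically
    #: active)
    bath_mode: str = "na_swap"
    #: K_e-gated amplification of the bath exchange rate (vascular K+
    #: clearance is strongly recruited at SD-level extracellular K+,
    #: the functional-hyperemia response); 0 disables it
    bath_hyper_amp: float = 0.0
    bath_hyper_thr: float = 22.0  # mM
    bath_hyper_width: float = 3.0  # mM

    def __post_init__(self) -> None:
        if self.bath_mode not in ("kcl", "na_swap"):
            raise ValueError(f"bath_mode must be 'kcl' or 'na_swap', got {self.bath_mode!r}")

    def glia_activation(self, k_e: float) -> float:
        """Sigmoidal K_e-dependence of glial uptake (threshold-like)."""
        return 1.0 / (1.0 + _exp((self.k_glia_thr - k_e) / self.k_glia_width))

    @property
    def k_b_glia(self) -> float:
        """Backward buffering rate making ``W0`` the equilibrium at rest K_e."""
        k_e0 = 4.0
        return self.k_f_glia * self.glia_activation(k_e0) * (self.W_max - self.W0) / self.W0


def pump_current(na_n: float, k_e: float, scale: float, p: PumpGliaParams) -> float:
    """Electrogenic Na+/K+-ATPase current density (uA/cm^2).

    Product of sigmoids in intracellular Na+ and extracellular K+, scaled
    by the protocol's pump-activity factor (0 = complete pump failure).
    """
    f = 1.0 / (1.0 + _exp((p.pump_na_half - na_n) / p.pump_na_slope))
    g = 1.0 / (1.0 + _exp((p.pump_k_half - k_e) / p.pump_k_slope))
    return scale * p.rho_p * f * g


def glial_buffering_flux(k_e: float, W: float, scale: float, p: PumpGliaParams) -> float:
    """K+ flux from ECS into the glial buffer (fmol/ms).

    Forward uptake onto the free capacity, gated by a sigmoidal K_e
    activation (glia engage strongly only at SD-level K+); backward
    release proportional to the load.  Zero at the resting equilibrium.
    """
    act = p.glia_activation(k_e)
    return scale * (p.k_f_glia * act * (p.W_max - W) - p.k_b_glia * W)


def bath_flux(k_e: float, k_bath: float, omega_e0: float, scale: float, p: PumpGliaParams) -> float:
    """K+ flux from the bath into the ECS (fmol/ms); positive raises K_e.

    Diffusive in ``K_bath - K_e``; the exchange-rate coefficient is
    amplified sigmoidally at SD-level K_e (vascular clearance recruitment),
    so the flux remains proportional to the concentration difference with
    a state-dependent conductance.
    """
    lam = p.lambda_bath * (
        1.0 + p.bath_hyper_amp / (1.0 + _exp((p.bath_hyper_thr - k_e) / p.bath_hyper_width))
    )
    return scale * lam * (k_bath - k_e) * omega_e0 * 1e-3


def volume_rhs(
    osm_n: float,
    osm_g: float,
    osm_e: float,
    p: PumpGliaParams,
) -> tuple[float, float]:
    """Osmotic volume rates ``(domega_n/dt, domega_g/dt)`` (um^3/ms).

    Each cell swells in proportion to its transmembrane osmolarity excess;
    the ECS takes up exactly the opposite of the summed cell volume change
    (closed box).
    """
    return (p.P_water_n * (osm_n - osm_e), p.P_water_g * (osm_g - osm_e))


def leak_balance_potential(
    g_k: float,
    g_na: float,
    g_cl: float,
    e_k: float,
    e_na: float,
    e_cl: float,
    i_pump: float,
) -> float:
    """Closed-form fixed point of the leak-and-pump membrane balance.

    Solves ``g_K(V-E_K) + g_Na(V-E_Na) + g_Cl(V-E_Cl) = -I_p`` for V: the
    conductance-weighted mean of the Nernst potentials offset by the pump
    current.  With a large pump current and collapsed conductances this
    potential lies below E_K (hyperpolarization).
    """
    g_tot = g_k + g_na + g_cl
    return (g_k * e_k + g_na * e_na + g_cl * e_cl - i_pump) / g_tot
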