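"""Assembly of the full single-unit SD model.

The state vector couples the Hodgkin-Huxley gating variables,
per-compartment ion amounts (neuron, ECS, glia), the two slow K+ pools
(glial buffer and cumulative bath export), osmotic volumes, and the four
glutamate pools.  The membrane potential is not a separate dynamical
variable: it is the capacitor voltage implied by the neuron's net charge,
``V = (F / C_m A_m) * (N_Na + N_K - N_Cl + z_A A_n)``, so the rate
equation ``C dV/dt = -sum(I)`` holds identically and charge bookkeeping
can never drift from the potential.

The resting state is constructed to be an exact fixed point: leak
conductances are solved from the resting flux balance, intracellular Cl-
is placed at its Nernst equilibrium, and impermeant intracellular anions
enforce simultaneous osmotic and electroneutral rest.

State layout (:class:`S`): amounts in fmol, volumes in um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import ions
from .constants import CURRENT_TO_FMOL_PER_MS, FARADAY, MM_UM3_TO_FMOL, RTF_MV
from .glutamate import (
    GlutamatePools,
    ReceptorParams,
    ReleaseParams,
    UptakeParams,
    glutamate_rhs,
    receptor_currents,
    receptor_gate_rhs,
    total_glutamate,
    uptake_rates,
)
from .morphology import Morphology, cleft_geometry


class NumericalStateError(RuntimeError):
    """Raised when a derivative evaluation produces NaN/Inf."""


class InitializationError(ValueError):
    """Raised when no physical resting state exists for the parameters."""


class S:
    """Indices into the full state vector."""

    N = 0  # K+ activation gate
    H = 1  # fast Na+ inactivation gate
    SNA = 2  # slow Na+ window-current inactivation gate
    R_NMDA = 3
    R_AMPA = 4
    NA_N = 5
    K_N = 6
    CL_N = 7
    NA_E = 8
    K_E = 9
    CL_E = 10
    W_GLIA = 11  # glial K+ (and paired Cl-) buffer load, absolute, fmol
    N_BATH = 12  # cumulative K+ (and paired Cl-) exported to bath, fmol
    OMEGA_N = 13
    OMEGA_G = 14
    GLU_I = 15  # per synapse
    GLU_C = 16  # per synapse
    GLU_E = 17  # total
    GLU_UP = 18  # total
    DIM = 19

    NAMES = (
        "n", "h", "s_na", "r_nmda", "r_ampa",
        "N_Na_n", "N_K_n", "N_Cl_n", "N_Na_e", "N_K_e", "N_Cl_e",
        "W_glia_K", "N_bath_K", "omega_n", "omega_g",
        "N_glu_i", "N_glu_c", "N_glu_e", "N_glu_up",
    )


#: fast-subsystem coordinates: (V, n, h, r_NMDA, r_AMPA, N_Na_n, omega_n,
#: omega_g).  N_K_n is eliminated through the charge-potential relation;
#: the slow K+ pools, neuronal Cl-, the slow Na+ inactivation gate, and
#: the glutamate pools are clamped parameters (all slow variables).
FAST_DIM = 8


@dataclass(frozen=True)
class MembraneParams:
    """Gated/leak conductances and membrane capacitance of the neuron."""

    C_m: float = 1.0  # uF/cm^2
    g_na_gated: float = 100.0  # mS/cm^2
    g_k_gated: float = 40.0  # mS/cm^2
    g_cl_leak: float = 0.005  # mS/cm^2
    phi: float = 3.0  # gating timescale factor
    # slow inactivation of the Na+ window current: caps the persistent
    # current that can hold a sustained depolarization.  The time constant
    # puts s among the slow variables (same tier as the K+ pools)
    tau_s_ms: float = 30000.0
    s_v_half: float = -40.0  # mV
    s_slope: float = 5.0  # mV


@dataclass(frozen=True)
class RestingComposition:
    """Target resting potential and compartment concentrations (mV, mM).

    ECS Cl- is fixed by electroneutrality (Na_e + K_e); neuronal Cl- sits
    at its Nernst equilibrium at ``V0``; impermeant anion amounts are
    derived so each compartment is isotonic with the ECS at rest.
    """

    V0: float = -67.0
    na_n: float = 25.0
    k_n: float = 130.0
    na_e: float = 125.0
    k_e: float = 4.0
    na_g: float = 15.0
    k_g: float = 120.0
    cl_g: float = 20.0

    @property
    def cl_e(self) -> float:
        return self.na_e + self.k_e

    @property
    def cl_n(self) -> float:
        return self.cl_e * math.exp(self.V0 / RTF_MV)


def _safe_conc(amount: float, volume: float) -> float:
    c = amount / (volume * MM_UM3_TO_FMOL)
    return c if c > 1e-9 else 1e-9


class SDModel:
    """The full neuron-glia-ECS model with glutamate homeostasis.

    Parameters
    ----------
    morph : Morphology
    membrane : MembraneParams
    pumpglia : ions.PumpGliaParams
    release, receptors, uptake
        Glutamate subsystem parameters.
    rest : RestingComposition
    literal_recycling : bool
        Reproduce the non-conservative literal recycling bookkeeping
        (whole recycled amount credited per synapse) instead of the
        default mass-conserving form.
    cotransport : bool
        Carry 3 Na+ into the neuron per glutamate taken up neuronally.
    """

    def __init__(
        self,
        morph: Morphology | None = None,
        membrane: MembraneParams | None = None,
        pumpglia: ions.PumpGliaParams | None = None,
        release: ReleaseParams | None = None,
        receptors: ReceptorParams | None = None,
        uptake: UptakeParams | None = None,
        rest: RestingComposition | None = None,
        literal_recycling: bool = False,
        cotransport: bool = True,
    ) -> None:
        from .config import default_release  # avoid cycle at import time

        self.morph = morph if morph is not None else default_morphology()
        self.membrane = membrane if membrane is not None else MembraneParams()
        self.pumpglia = pumpglia if pumpglia is not None else ions.PumpGliaParams()
        self.release = release if release is not None else default_release()
        self.receptors = receptors if receptors is not None else ReceptorParams()
        self.uptake = uptake if uptake is not None else UptakeParams()
        self.rest = rest if rest is not None else RestingComposition()
        self.literal_recycling = literal_recycling
        self.cotransport = cotransport
        self._init_rest()

    # ------------------------------------------------------------------
    # resting-state construction
    # ------------------------------------------------------------------

    def _init_rest(self) -> None:
        m, r = self.morph, self.rest
        mm = MM_UM3_TO_FMOL
        #: mV of membrane potential per fmol of net neuronal charge
        self.gamma_q = FARADAY * 1e-6 / (self.membrane.C_m * m.A_m_n)
        mb = self.membrane
        self.n0 = ions.gate_inf(ions.alpha_n(r.V0), ions.beta_n(r.V0))
        self.h0 = ions.gate_inf(ions.alpha_h(r.V0), ions.beta_h(r.V0))
        self.s0 = ions.s_inf(r.V0, mb.s_v_half, mb.s_slope)
        e_na = RTF_MV * math.log(r.na_e / r.na_n)
        e_k = RTF_MV * math.log(r.k_e / r.k_n)
        ip0 = ions.pump_current(r.na_n, r.k_e, 1.0, self.pumpglia)
        i_na_gated = (
            mb.g_na_gated * ions.m_inf(r.V0) ** 3 * self.h0 * self.s0 * (r.V0 - e_na)
        )
        i_k_gated = mb.g_k_gated * self.n0**4 * (r.V0 - e_k)
        self.g_na_leak = -(i_na_gated + 3.0 * ip0) / (r.V0 - e_na)
        self.g_k_leak = (2.0 * ip0 - i_k_gated) / (r.V0 - e_k)
        if self.g_na_leak <= 0.0 or self.g_k_leak <= 0.0:
            raise InitializationError(
                "resting composition requires negative leak conductances "
                f"(g_na_leak={self.g_na_leak:.4g}, g_k_leak={self.g_k_leak:.4g})"
            )
        # impermeant anions: isotonic with ECS at rest
        osm_e = r.na_e + r.k_e + r.cl_e
        a_n_conc = osm_e - (r.na_n + r.k_n + r.cl_n)
        a_g_conc = osm_e - (r.na_g + r.k_g + r.cl_g)
        if a_n_conc <= 0.0 or a_g_conc <= 0.0:
            raise InitializationError("resting composition is hypertonic to the ECS")
        self.anion_n = a_n_conc * m.omega_n0 * mm
        self.anion_g = a_g_conc * m.omega_g0 * mm
        # charge offset: net neuronal charge minus V0's capacitor charge.
        # The bulk of it is impermeant anion charge; the residual fixes the
        # potential-charge gauge exactly at V0.
        mobile0 = (r.na_n + r.k_n - r.cl_n) * m.omega_n0 * mm
        self.q_offset = mobile0 - r.V0 / self.gamma_q
        # mean impermeant charge (for the electroneutrality audit)
        self.z_anion_n = -(r.na_n + r.k_n - r.cl_n) / a_n_conc
        self.z_anion_g = -(r.na_g + r.k_g - r.cl_g) / a_g_conc
        # fixed glial backbone amounts (W carries the mobile KCl on top)
        pg = self.pumpglia
        # The buffer load W rides on top of these backbone amounts; only
        # the excess over the resting load W0 moves KCl physically, so the
        # bases may be negative without implying negative concentrations.
        self.na_g_amt = r.na_g * m.omega_g0 * mm
        self.k_g_base = r.k_g * m.omega_g0 * mm - pg.W0
        self.cl_g_base = r.cl_g * m.omega_g0 * mm - pg.W0
        # closed-system totals over neuron+ECS (for clamped fast subsystem)
        self.tot_na_ne = (r.na_n * m.omega_n0 + r.na_e * m.omega_e0) * mm
        self.tot_k_ne = (r.k_n * m.omega_n0 + r.k_e * m.omega_e0) * mm
        self.tot_cl_ne = (r.cl_n * m.omega_n0 + r.cl_e * m.omega_e0) * mm

    def resting_state(self) -> np.ndarray:
        """Full state vector at the constructed resting fixed point."""
        m, r = self.morph, self.rest
        mm = MM_UM3_TO_FMOL
        y = np.zeros(S.DIM)
        y[S.N] = self.n0
        y[S.H] = self.h0
        y[S.SNA] = self.s0
        y[S.NA_N] = r.na_n * m.omega_n0 * mm
        y[S.K_N] = r.k_n * m.omega_n0 * mm
        y[S.CL_N] = r.cl_n * m.omega_n0 * mm
        y[S.NA_E] = r.na_e * m.omega_e0 * mm
        y[S.K_E] = r.k_e * m.omega_e0 * mm
        y[S.CL_E] = r.cl_e * m.omega_e0 * mm
        y[S.W_GLIA] = self.pumpglia.W0
        y[S.OMEGA_N] = m.omega_n0
        y[S.OMEGA_G] = m.omega_g0
        y[S.GLU_I] = self.release.N_max
        return y

    # ------------------------------------------------------------------
    # membrane potential from net charge
    # ------------------------------------------------------------------

    def voltage(self, y: np.ndarray) -> float:
        """Membrane potential (mV) implied by the neuron's net charge."""
        return self.gamma_q * (y[S.NA_N] + y[S.K_N] - y[S.CL_N] - self.q_offset)

    def voltage_series(self, Y: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`voltage` over an (n_samples, DIM) array."""
        return self.gamma_q * (
            Y[..., S.NA_N] + Y[..., S.K_N] - Y[..., S.CL_N] - self.q_offset
        )

    def charge_for_voltage(self, v: float) -> float:
        """Net mobile-ion charge (fmol) that puts the membrane at ``v`` mV."""
        return v / self.gamma_q + self.q_offset

    # ------------------------------------------------------------------
    # derivatives
    # ------------------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, protocol) -> np.ndarray:
        """Full right-hand side under a time-dependent protocol."""
        return self._rhs(
            y,
            k_bath=protocol.k_bath(t),
            pump_scale=protocol.pump_scale(t),
            glia_scale=protocol.glia_scale(t),
            uptake_scale=protocol.uptake_scale(t) * protocol.uptake_fraction,
        )

    def _rhs(
        self,
        y: np.ndarray,
        k_bath: float,
        pump_scale: float,
        glia_scale: float,
        uptake_scale: float,
        glu_dynamics: bool = True,
        slow_dynamics: bool = True,
        gc_clamp: float | None = None,
        check: bool = True,
    ) -> np.ndarray:
        m = self.morph
        mb = self.membrane
        pg = self.pumpglia
        mm = MM_UM3_TO_FMOL

        V = self.voltage(y)
        n = y[S.N]
        h = y[S.H]
        s_na = y[S.SNA]
        r_nmda = y[S.R_NMDA]
        r_ampa = y[S.R_AMPA]
        omega_n = y[S.OMEGA_N]
        omega_g = y[S.OMEGA_G]
        omega_e = m.omega_tot - omega_n - omega_g
        if omega_e < 1e-3 * m.omega_tot:
            omega_e = 1e-3 * m.omega_tot

        na_n = _safe_conc(y[S.NA_N], omega_n)
        k_n = _safe_conc(y[S.K_N], omega_n)
        cl_n = _safe_conc(y[S.CL_N], omega_n)
        na_e = _safe_conc(y[S.NA_E], omega_e)
        k_e = _safe_conc(y[S.K_E], omega_e)
        cl_e = _safe_conc(y[S.CL_E], omega_e)

        pools = GlutamatePools(
            N_i=max(y[S.GLU_I], 0.0), N_c=max(y[S.GLU_C], 0.0),
            N_e=max(y[S.GLU_E], 0.0), N_up=max(y[S.GLU_UP], 0.0),
        )
        g_c = pools.G_c(m) if gc_clamp is None else gc_clamp

        e_na = RTF_MV * math.log(na_e / na_n)
        e_k = RTF_MV * math.log(k_e / k_n)
        e_cl = -RTF_MV * math.log(cl_e / cl_n)

        dy = np.zeros(S.DIM)
        dy[S.N] = mb.phi * (ions.alpha_n(V) * (1.0 - n) - ions.beta_n(V) * n)
        dy[S.H] = mb.phi * (ions.alpha_h(V) * (1.0 - h) - ions.beta_h(V) * h)
        dy[S.SNA] = (ions.s_inf(V, mb.s_v_half, mb.s_slope) - s_na) / mb.tau_s_ms
        rc = self.receptors
        dy[S.R_NMDA] = receptor_gate_rhs(g_c, r_nmda, rc.alpha_nmda, rc.beta_nmda)
        dy[S.R_AMPA] = receptor_gate_rhs(g_c, r_ampa, rc.alpha_ampa, rc.beta_ampa)

        i_p = ions.pump_current(na_n, k_e, pump_scale, pg)
        i_na_ampa, i_k_ampa, i_na_nmda, i_k_nmda = receptor_currents(
            V, r_nmda, r_ampa, e_na, e_k, rc
        )

        # glutamate uptake and Na+ cotransport (3 Na+ in per glutamate)
        conv = m.A_m_n * CURRENT_TO_FMOL_PER_MS
        i_co = 0.0
        if glu_dynamics and uptake_scale > 0.0 and self.cotransport:
            q_cn, _, q_en, _ = uptake_rates(pools, omega_e, m, self.uptake, uptake_scale)
            i_co = -3.0 * (q_cn + q_en) / conv

        m3h = ions.m_inf(V) ** 3 * h * s_na
        i_na = (
            (mb.g_na_gated * m3h + self.g_na_leak) * (V - e_na)
            + 3.0 * i_p + i_na_ampa + i_na_nmda + i_co
        )
        i_k = (
            (mb.g_k_gated * n**4 + self.g_k_leak) * (V - e_k)
            - 2.0 * i_p + i_k_ampa + i_k_nmda
        )
        i_cl = mb.g_cl_leak * (V - e_cl)

        dy[S.NA_N] = -i_na * conv
        dy[S.K_N] = -i_k * conv
        dy[S.CL_N] = i_cl * conv
        dy[S.NA_E] = i_na * conv
        dy[S.K_E] = i_k * conv
        dy[S.CL_E] = -i_cl * conv

        if slow_dynamics:
            j_glia = ions.glial_buffering_flux(k_e, y[S.W_GLIA], glia_scale, pg)
            j_bath = ions.bath_flux(k_e, k_bath, m.omega_e0, glia_scale, pg)
            dy[S.W_GLIA] = j_glia
            dy[S.N_BATH] = -j_bath
            dy[S.K_E] += j_bath - j_glia
            dy[S.CL_E] -= j_glia  # glia take KCl as a pair
            if pg.bath_mode == "kcl":
                dy[S.CL_E] += j_bath  # bath K+ travels with Cl-
            else:
                dy[S.NA_E] -= j_bath  # bath swaps K+ against Na+ (equimolar)

        # osmotic volume dynamics
        w = y[S.W_GLIA]
        osm_n = na_n + k_n + cl_n + self.anion_n / (omega_n * mm)
        osm_g = (
            self.na_g_amt + self.k_g_base + self.cl_g_base + 2.0 * w + self.anion_g
        ) / (omega_g * mm)
        osm_e = na_e + k_e + cl_e
        dy[S.OMEGA_N], dy[S.OMEGA_G] = ions.volume_rhs(osm_n, osm_g, osm_e, pg)

        if glu_dynamics:
            d_ni, d_nc, d_ne, d_nup = glutamate_rhs(
                pools, V, omega_e, m, self.release, self.uptake,
                uptake_scale=uptake_scale,
                literal_recycling=self.literal_recycling,
            )
            dy[S.GLU_I] = d_ni
            dy[S.GLU_C] = d_nc
            dy[S.GLU_E] = d_ne
            dy[S.GLU_UP] = d_nup

        if check and not np.isfinite(dy).all():
            bad = [S.NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
            raise NumericalStateError(f"non-finite derivative for state component(s): {bad}")
        return dy

    # ------------------------------------------------------------------
    # derived quantities and audits
    # ------------------------------------------------------------------

    def omega_e(self, y: np.ndarray) -> float:
        return self.morph.omega_tot - y[S.OMEGA_N] - y[S.OMEGA_G]

    def delta_n_glia_k(self, y: np.ndarray) -> float:
        return y[S.W_GLIA] - self.pumpglia.W0

    def delta_n_k(self, y: np.ndarray) -> float:
        """Slow variable: total K+ removed from neuron+ECS by glia and bath."""
        return self.delta_n_glia_k(y) + y[S.N_BATH]

    def pools(self, y: np.ndarray) -> GlutamatePools:
        return GlutamatePools(y[S.GLU_I], y[S.GLU_C], y[S.GLU_E], y[S.GLU_UP])

    def concentrations(self, y: np.ndarray) -> dict[str, float]:
        """Named compartment concentrations (mM) for one state vector."""
        m = self.morph
        mm = MM_UM3_TO_FMOL
        omega_n, omega_g = y[S.OMEGA_N], y[S.OMEGA_G]
        omega_e = self.omega_e(y)
        w = y[S.W_GLIA]
        return {
            "na_n": y[S.NA_N] / (omega_n * mm),
            "k_n": y[S.K_N] / (omega_n * mm),
            "cl_n": y[S.CL_N] / (omega_n * mm),
            "na_e": y[S.NA_E] / (omega_e * mm),
            "k_e": y[S.K_E] / (omega_e * mm),
            "cl_e": y[S.CL_E] / (omega_e * mm),
            "na_g": self.na_g_amt / (omega_g * mm),
            "k_g": (self.k_g_base + w) / (omega_g * mm),
            "cl_g": (self.cl_g_base + w) / (omega_g * mm),
            "G_c": self.pools(y).G_c(m),
            "G_e": self.pools(y).G_e(omega_e),
        }

    def ion_config(self, y: np.ndarray) -> dict[str, float]:
        """Neuron/ECS concentrations as a membrane-model parameter set."""
        c = self.concentrations(y)
        return {k: c[k] for k in ("na_n", "k_n", "cl_n", "na_e", "k_e", "cl_e")}

    def audit(self, y: np.ndarray) -> dict[str, float]:
        """Conserved totals: per-ion closed-system amounts, glutamate, volume."""
        w = y[S.W_GLIA]
        b = y[S.N_BATH]
        kcl = self.pumpglia.bath_mode == "kcl"
        # b counts K+ exported to the bath; in swap mode each exported K+
        # was replaced by one Na+, so the ECS Na pool carries +b
        return {
            "total_na": y[S.NA_N] + y[S.NA_E] + self.na_g_amt - (0.0 if kcl else b),
            "total_k": y[S.K_N] + y[S.K_E] + self.k_g_base + w + b,
            "total_cl": y[S.CL_N] + y[S.CL_E] + self.cl_g_base + w + (b if kcl else 0.0),
            "total_glutamate": total_glutamate(self.pools(y), self.morph.N_syn),
            "total_volume": y[S.OMEGA_N] + y[S.OMEGA_G] + self.omega_e(y),
        }

    def electroneutrality(self, y: np.ndarray) -> dict[str, float]:
        """Net charge concentration (mM) per compartment, impermeants included."""
        c = self.concentrations(y)
        return {
            "neuron": c["na_n"] + c["k_n"] - c["cl_n"]
            + self.z_anion_n * self.anion_n / (y[S.OMEGA_N] * MM_UM3_TO_FMOL),
            "glia": c["na_g"] + c["k_g"] - c["cl_g"]
            + self.z_anion_g * self.anion_g / (y[S.OMEGA_G] * MM_UM3_TO_FMOL),
            "ecs": c["na_e"] + c["k_e"] - c["cl_e"],
        }

    # ------------------------------------------------------------------
    # fast subsystem (slow K+ pools and glutamate clamped)
    # ------------------------------------------------------------------

    def full_from_fast(
        self,
        fast: np.ndarray,
        delta_n_k: float,
        delta_n_glia_k: float,
        g_c: float,
        n_cl_n: float | None = None,
        s_na: float | None = None,
    ) -> np.ndarray:
        """Embed a fast-subsystem state into a full state vector.

        The neuronal K+ amount follows from the membrane potential via
        the charge-potential relation; neuronal Cl- is clamped at
        ``n_cl_n`` (resting amount by default; Cl- is itself slow); ECS
        amounts follow from the clamped slow pools and the conserved
        neuron+ECS totals (K+ and its paired Cl- reduced by
        ``delta_n_k``); glutamate pools are frozen at the clamped cleft
        concentration with an empty ECS pool.
        """
        v, n, h, r_nmda, r_ampa, na_n, omega_n, omega_g = fast
        if s_na is None:
            s_na = self.s0
        cl_n = (
            self.rest.cl_n * self.morph.omega_n0 * MM_UM3_TO_FMOL
            if n_cl_n is None
            else n_cl_n
        )
        y = np.zeros(S.DIM)
        y[S.N] = n
        y[S.H] = h
        y[S.SNA] = s_na
        y[S.R_NMDA] = r_nmda
        y[S.R_AMPA] = r_ampa
        y[S.NA_N] = na_n
        y[S.CL_N] = cl_n
        y[S.K_N] = self.charge_for_voltage(v) - na_n + cl_n
        y[S.OMEGA_N] = omega_n
        y[S.OMEGA_G] = omega_g
        y[S.W_GLIA] = self.pumpglia.W0 + delta_n_glia_k
        y[S.N_BATH] = delta_n_k - delta_n_glia_k
        y[S.K_E] = self.tot_k_ne - y[S.K_N] - delta_n_k
        if self.pumpglia.bath_mode == "kcl":
            # glia and bath both took Cl- along with the removed K+
            y[S.NA_E] = self.tot_na_ne - y[S.NA_N]
            y[S.CL_E] = self.tot_cl_ne - y[S.CL_N] - delta_n_k
        else:
            # bath-removed K+ was swapped for Na+; only glia took Cl-
            y[S.NA_E] = self.tot_na_ne - y[S.NA_N] + (delta_n_k - delta_n_glia_k)
            y[S.CL_E] = self.tot_cl_ne - y[S.CL_N] - delta_n_glia_k
        y[S.GLU_I] = self.release.N_max
        y[S.GLU_C] = g_c * self.morph.omega_en * MM_UM3_TO_FMOL
        return y

    def fast_state_from_full(self, y: np.ndarray) -> np.ndarray:
        return np.array([
            self.voltage(y), y[S.N], y[S.H], y[S.R_NMDA], y[S.R_AMPA],
            y[S.NA_N], y[S.OMEGA_N], y[S.OMEGA_G],
        ])

    def fast_rhs(
        self,
        fast: np.ndarray,
        delta_n_k: float,
        delta_n_glia_k: float,
        g_c: float,
        pump_scale: float = 1.0,
        n_cl_n: float | None = None,
        s_na: float | None = None,
    ) -> np.ndarray:
        """Derivatives of the fast subsystem at clamped slow variables.

        Identical to the full right-hand side with glial buffering, bath
        exchange, glutamate pool dynamics, and neuronal Cl- frozen and
        the cleft glutamate concentration held at ``g_c``; ``dV/dt`` is
        the charge flux over the membrane capacitance (Cl- current
        included).
        """
        y = self.full_from_fast(fast, delta_n_k, delta_n_glia_k, g_c, n_cl_n, s_na)
        dy = self._rhs(
            y, k_bath=self.rest.k_e, pump_scale=pump_scale, glia_scale=0.0,
            uptake_scale=0.0, glu_dynamics=False, slow_dynamics=False,
            gc_clamp=g_c, check=False,
        )
        dv = self.gamma_q * (dy[S.NA_N] + dy[S.K_N] - dy[S.CL_N])
        return np.array([
            dv, dy[S.N], dy[S.H], dy[S.R_NMDA], dy[S.R_AMPA],
            dy[S.NA_N], dy[S.OMEGA_N], dy[S.OMEGA_G],
        ])

    def fast_voltage(self, fast: np.ndarray) -> float:
        """Membrane potential of a fast-subsystem state."""
        return float(fast[0])

    # ------------------------------------------------------------------
    # membrane-only subsystem (ion concentrations as parameters)
    # ------------------------------------------------------------------

    def membrane_rhs(
        self,
        V: float,
        n: float,
        h: float,
        ion_config: dict[str, float],
        g_c: float,
        pump_scale: float = 1.0,
        s_na: float | None = None,
    ) -> tuple[float, float, float]:
        """Membrane model at frozen ion concentrations and cleft glutamate.

        In this reduced model V is dynamical (there is no ion bookkeeping
        left to derive it from).  Receptor gates sit at their
        glutamate-determined equilibria, since their kinetics are voltage
        independent.  ``ion_config`` supplies the six neuron/ECS
        concentrations (mM).
        """
        from .glutamate import receptor_gate_fixed_point

        mb = self.membrane
        rc = self.receptors
        if s_na is None:
            s_na = self.s0
        e_na = RTF_MV * math.log(ion_config["na_e"] / ion_config["na_n"])
        e_k = RTF_MV * math.log(ion_config["k_e"] / ion_config["k_n"])
        e_cl = -RTF_MV * math.log(ion_config["cl_e"] / ion_config["cl_n"])
        i_p = ions.pump_current(ion_config["na_n"], ion_config["k_e"], pump_scale, self.pumpglia)
        r_n = receptor_gate_fixed_point(g_c, rc.alpha_nmda, rc.beta_nmda)
        r_a = receptor_gate_fixed_point(g_c, rc.alpha_ampa, rc.beta_ampa)
        i_na_ampa, i_k_ampa, i_na_nmda, i_k_nmda = receptor_currents(
            V, r_n, r_a, e_na, e_k, rc
        )
        i_na = (
            (mb.g_na_gated * ions.m_inf(V) ** 3 * h * s_na + self.g_na_leak) * (V - e_na)
            + 3.0 * i_p + i_na_ampa + i_na_nmda
        )
        i_k = (
            (mb.g_k_gated * n**4 + self.g_k_leak) * (V - e_k)
            - 2.0 * i_p + i_k_ampa + i_k_nmda
        )
        i_cl = mb.g_cl_leak * (V - e_cl)
        dV = -(i_na + i_k + i_cl) / mb.C_m
        dn = mb.phi * (ions.alpha_n(V) * (1.0 - n) - ions.beta_n(V) * n)
        dh = mb.phi * (ions.alpha_h(V) * (1.0 - h) - ions.beta_h(V) * h)
        return dV, dn, dh


def default_morphology() -> Morphology:
    """Default geometry: envelope calibrated so 3,000 molecules raise
    the cleft concentration by 1.3 mM (r = 0.2 um, h ~= 5.1 nm)."""
    from .glutamate import envelope_volume_for_increment, height_for_envelope

    r = 0.2
    h = height_for_envelope(envelope_volume_for_increment(), r)
    return cleft_geometry(r, h)
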