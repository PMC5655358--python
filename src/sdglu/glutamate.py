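"""Glutamate release, receptor gating, diffusion, uptake, and pool bookkeeping.

Four pools are tracked: per-synapse releasable glutamate ``N_i`` in the
presynaptic terminal, per-synapse cleft glutamate ``N_c``, total ECS
glutamate ``N_e``, and total buffered (taken-up, not yet recycled)
glutamate ``N_up``.  Released glutamate equilibrates instantly over the
glial envelope, so the cleft concentration is ``G_c = N_c / omega_en``.
Because every synapse is shared between two neurons, only half of the
glutamate leaving the clefts (and of cellular re-uptake) is attributed to
the modelled unit, hence the ``N_syn/2`` aggregation factor.

All amounts are in fmol, concentrations in mM, times in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import MM_UM3_TO_FMOL, amount_from_molecules
from .morphology import Morphology


class StateValidityError(ValueError):
    """Raised when a glutamate pool state is physically invalid."""


class ParameterError(ValueError):
    """Raised for invalid kinetic parameters."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReleaseParams:
    """Continuous (non-quantal) release-function parameters.

    ``J_rel = R_max * ((V - V_cr)/(V_hi - V_cr))^2 * N_i/N_max`` for
    ``V >= V_cr`` and zero below: release grows with a power law beyond the
    critical potential ``V_cr`` and scales with the remaining releasable
    glutamate.  ``R_max`` is calibrated so one action potential releases
    about 3,000 molecules per synapse (:func:`calibrate_release_rate`).
    """

    R_max: float  # fmol/ms per synapse
    V_cr: float = -40.0  # mV
    V_hi: float = 30.0  # mV
    N_max: float = 8.0e-3  # fmol per synapse (~4.8e6 molecules reserve)
    k_rec: float = 1.0e-4  # 1/ms recycling of buffered glutamate
    clamp_quadratic: bool = False  # optionally cap the quadratic factor at 1

    def __post_init__(self) -> None:
        if self.V_hi <= self.V_cr:
            raise ParameterError("release requires V_hi > V_cr")
        if min(self.R_max, self.N_max) <= 0 or self.k_rec < 0:
            raise ParameterError("R_max, N_max must be positive and k_rec >= 0")


@dataclass(frozen=True)
class ReceptorParams:
    """First-order NMDA/AMPA kinetics and conductance densities.

    Rate constants follow the first-order receptor models fitted by
    Destexhe and co-workers; conductance densities are the SD-scale values
    implied by per-event conductances of 1e-7 mS (NMDA) and 3.5e-7 mS
    (AMPA) spread over all active synapses
    (:func:`sd_conductance_density`).
    """

    g_nmda: float = 0.1389  # mS/cm^2
    g_ampa: float = 0.4861  # mS/cm^2
    alpha_nmda: float = 0.072  # 1/(mM ms)
    beta_nmda: float = 0.0066  # 1/ms
    alpha_ampa: float = 1.1  # 1/(mM ms)
    beta_ampa: float = 0.19  # 1/ms
    mg: float = 1.0  # mM extracellular Mg2+

    def __post_init__(self) -> None:
        for name in ("g_nmda", "g_ampa", "alpha_nmda", "beta_nmda", "alpha_ampa", "beta_ampa", "mg"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"receptor parameter {name} must be positive")


@dataclass(frozen=True)
class UptakeParams:
    """Michaelis-Menten transporter kinetics and cleft-ECS diffusion.

    Only the base cleft-to-neuron maximal velocity ``v_cn_max`` is free;
    the other three pathways follow from binding-site density (glia have
    8x the neuronal density), contact areas, and compartment volumes:
    ``v_cg_max = 4 v_cn_max``, ``v_en_max = 0.12 v_cn_max * omega_e0/omega_e``,
    ``v_eg_max = 0.24 v_cg_max * omega_e0/omega_e``.
    """

    v_cn_max: float = 0.03  # mM/ms
    k_m: float = 0.02  # mM half-saturation
    D_G: float = 0.4  # um^2/ms glutamate diffusion coefficient
    dx: float = 40.0  # um cutoff distance to steady-state ECS concentration

    def __post_init__(self) -> None:
        if self.v_cn_max < 0 or self.k_m <= 0:
            raise ParameterError("v_cn_max must be >= 0 and k_m > 0")
        if self.dx <= 0 or self.D_G <= 0:
            raise ParameterError("diffusion requires positive D_G and dx")


@dataclass(frozen=True)
class GlutamatePools:
    """The four glutamate state variables (amounts in fmol)."""

    N_i: float  # per synapse, presynaptic releasable
    N_c: float  # per synapse, cleft/envelope
    N_e: float  # total, ECS
    N_up: float  # total, buffered (taken up, unrecycled)

    def validate(self) -> "GlutamatePools":
        if min(self.N_i, self.N_c, self.N_e, self.N_up) < 0.0:
            raise StateValidityError(f"negative glutamate pool in {self}")
        return self

    def G_c(self, morph: Morphology) -> float:
        """Cleft/envelope concentration (mM)."""
        return self.N_c / (morph.omega_en * MM_UM3_TO_FMOL)

    def G_e(self, omega_e: float) -> float:
        """ECS concentration (mM)."""
        return self.N_e / (omega_e * MM_UM3_TO_FMOL)


def total_glutamate(pools: GlutamatePools, n_syn: int) -> float:
    """Conserved weighted total ``(N_syn/2)(N_i + N_c) + N_e + N_up`` (fmol)."""
    return 0.5 * n_syn * (pools.N_i + pools.N_c) + pools.N_e + pools.N_up


# ---------------------------------------------------------------------------
# elementary fluxes
# ---------------------------------------------------------------------------


def release_flux(V: float, N_i: float, p: ReleaseParams) -> float:
    """Continuous glutamate release (fmol/ms per synapse).

    Zero below ``V_cr``; quadratic in the normalized depolarization above it
    and proportional to the remaining releasable pool.
    """
    if V < p.V_cr:
        return 0.0
    x = (V - p.V_cr) / (p.V_hi - p.V_cr)
    q = x * x
    if p.clamp_quadratic and q > 1.0:
        q = 1.0
    return p.R_max * q * (N_i / p.N_max)


def receptor_gate_rhs(G_c: float, r_gate: float, alpha: float, beta: float) -> float:
    """First-order receptor gate kinetics ``G_c*alpha*(1-r) - beta*r`` (1/ms)."""
    return G_c * alpha * (1.0 - r_gate) - beta * r_gate


def receptor_gate_fixed_point(G_c: float, alpha: float, beta: float) -> float:
    """Equilibrium open probability ``G_c*alpha / (G_c*alpha + beta)``."""
    ga = G_c * alpha
    return ga / (ga + beta)


def nmda_mg_block(V: float, mg: float) -> float:
    """Voltage-dependent magnesium unblock factor of the NMDA receptor."""
    x = -0.07 * V - 0.7
    return 1.0 / (1.0 + 0.33 * mg * math.exp(x if x < 50.0 else 50.0))


def receptor_currents(
    V: float,
    r_nmda: float,
    r_ampa: float,
    E_Na: float,
    E_K: float,
    p: ReceptorParams,
) -> tuple[float, float, float, float]:
    """Receptor current densities (uA/cm^2).

    Returns ``(I_Na_ampa, I_K_ampa, I_Na_nmda, I_K_nmda)``.  AMPA currents
    are ohmic; NMDA currents carry the voltage-dependent Mg2+ block.
    """
    g_a = p.g_ampa * r_ampa
    block = nmda_mg_block(V, p.mg)
    g_n = p.g_nmda * r_nmda * block
    return (g_a * (V - E_Na), g_a * (V - E_K), g_n * (V - E_Na), g_n * (V - E_K))


def diffusion_flux(G_c: float, G_e: float, m: Morphology, p: UptakeParams) -> float:
    """Glutamate flux out of one cleft into the ECS (fmol/ms, signed).

    ``J_diff = -(A_sigma * D_G / dx) * (G_c - G_e)``: negative when the
    cleft concentration exceeds the ECS concentration (efflux).
    """
    return -(m.A_sigma * p.D_G / p.dx) * (G_c - G_e) * MM_UM3_TO_FMOL


def uptake_velocity(G: float, v_max: float, k_m: float) -> float:
    """Michaelis-Menten uptake velocity ``v_max * G/(G + k_m)`` (mM/ms)."""
    if G < 0.0:
        raise StateValidityError(f"negative glutamate concentration G={G}")
    return v_max * G / (G + k_m)


def michaelis_km(k_plus1: float, k_minus1: float, k_r: float) -> float:
    """Half-saturation constant ``(k_-1 + k_r)/k_+1`` of the transporter scheme."""
    return (k_minus1 + k_r) / k_plus1


def effective_vmaxes(
    v_cn_max: float, omega_e: float, m: Morphology
) -> tuple[float, float, float, float]:
    """Maximal velocities of the four uptake pathways (mM/ms).

    Returns ``(v_cn, v_cg, v_en, v_eg)``.  The cleft-to-glia velocity is
    four times the neuronal one (8x binding-site density on half the
    contact area); ECS velocities scale inversely with the current ECS
    volume because uptake velocity is a concentration rate.
    """
    if omega_e <= 0.0:
        raise StateValidityError(f"non-positive ECS volume omega_e={omega_e}")
    v_cg = 4.0 * v_cn_max
    shrink = m.omega_e0 / omega_e
    return (v_cn_max, v_cg, 0.12 * v_cn_max * shrink, 0.24 * v_cg * shrink)


def cleft_to_glia_factor(m: Morphology, rho_ratio: float = 8.0) -> float:
    """Derive ``v_cg_max / v_cn_max`` from areas and binding-site densities.

    Glia have ``rho_ratio`` times the neuronal transporter density but only
    half the cleft contact area (``A_up_cg = A_up_cn / 2``), so the ratio is
    ``rho_ratio * A_up_cg / A_up_cn = 4`` for the default morphology.
    """
    return rho_ratio * m.A_up_cg / m.A_up_cn


# ---------------------------------------------------------------------------
# pool dynamics
# ---------------------------------------------------------------------------


def uptake_rates(
    pools: GlutamatePools,
    omega_e: float,
    m: Morphology,
    p: UptakeParams,
    uptake_scale: float = 1.0,
) -> tuple[float, float, float, float]:
    """Instantaneous whole-cell uptake rates by pathway (fmol/ms).

    Returns ``(Q_cn, Q_cg, Q_en, Q_eg)``: cleft->neuron, cleft->glia,
    ECS->neuron, ECS->glia, already aggregated over synapses (factor
    ``N_syn/2`` on the cleft pathways).
    """
    v_cn, v_cg, v_en, v_eg = effective_vmaxes(p.v_cn_max * uptake_scale, omega_e, m)
    G_c = pools.G_c(m)
    G_e = pools.G_e(omega_e)
    sat_c = G_c / (G_c + p.k_m)
    sat_e = G_e / (G_e + p.k_m)
    env = m.n_syn_pre * m.omega_en * MM_UM3_TO_FMOL
    ecs = omega_e * MM_UM3_TO_FMOL
    return (
        env * v_cn * sat_c,
        env * v_cg * sat_c,
        ecs * v_en * sat_e,
        ecs * v_eg * sat_e,
    )


def glutamate_rhs(
    pools: GlutamatePools,
    V: float,
    omega_e: float,
    m: Morphology,
    release: ReleaseParams,
    uptake: UptakeParams,
    uptake_scale: float = 1.0,
    literal_recycling: bool = False,
) -> tuple[float, float, float, float]:
    """Time derivatives of the four glutamate pools (fmol/ms).

    With the default conservative recycling each synapse receives the
    fraction ``2/N_syn`` of the recycled buffered glutamate, so the weighted
    total :func:`total_glutamate` is exactly conserved.
    ``literal_recycling=True`` instead credits the whole of
    ``k_rec * N_up`` to every synapse's releasable pool.
    """
    pools.validate()
    if not 0.0 <= uptake_scale <= 1.0:
        raise ParameterError(f"uptake_scale must be in [0, 1], got {uptake_scale}")
    half = m.n_syn_pre
    j_rel = release_flux(V, pools.N_i, release)
    j_diff = diffusion_flux(pools.G_c(m), pools.G_e(omega_e), m, uptake)
    q_cn, q_cg, q_en, q_eg = uptake_rates(pools, omega_e, m, uptake, uptake_scale)
    recycle = release.k_rec * pools.N_up
    d_Ni = -j_rel + (recycle if literal_recycling else recycle / half)
    d_Nc = j_rel + j_diff - (q_cn + q_cg) / half
    d_Ne = -half * j_diff - (q_en + q_eg)
    d_Nup = q_cn + q_cg + q_en + q_eg - recycle
    return (d_Ni, d_Nc, d_Ne, d_Nup)


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------


def receptor_density_bounds(
    g_lo: float,
    g_hi: float,
    n_post: int = 5_000,
    A_m: float = 1.8e-4,
    n_syn_ap: int = 1,
) -> tuple[float, float]:
    """Receptor conductance-density range implied by per-event conductances.

    A per-event conductance ``g`` (mS) measured for an action potential
    recruiting ``n_syn_ap`` synapses translates to a whole-cell density of
    ``g * n_post / (n_syn_ap * A_m)`` (mS/cm^2) when all ``n_post``
    postsynaptic synapses are active, as during SD.  With ``n_syn_ap=1``
    this returns the coefficient of ``1/N_syn_AP`` as usually quoted.
    """
    if not g_lo < g_hi:
        raise ParameterError("receptor bounds require g_lo < g_hi")
    if min(g_lo, n_post, A_m, n_syn_ap) <= 0:
        raise ParameterError("receptor bound inputs must be positive")
    scale = n_post / (n_syn_ap * A_m)
    return (g_lo * scale, g_hi * scale)


def sd_conductance_density(
    g_per_event: float,
    n_post: int = 5_000,
    A_m: float = 1.8e-4,
    n_syn_ap: int = 20,
) -> float:
    """SD-scale conductance density (mS/cm^2) from one per-event conductance."""
    return g_per_event * n_post / (n_syn_ap * A_m)


def envelope_volume_for_increment(
    n_molecules: float = 3_000.0, delta_conc: float = 1.3
) -> float:
    """Envelope volume (um^3) at which ``n_molecules`` raise G_c by ``delta_conc`` mM."""
    return amount_from_molecules(n_molecules) / (delta_conc * MM_UM3_TO_FMOL)


def height_for_envelope(omega_en: float, r: float) -> float:
    """Cleft height (um) giving envelope volume ``omega_en`` at radius ``r``."""
    return omega_en / (6.0 * math.pi * r * r)


def calibrate_release_rate(
    t: np.ndarray,
    V: np.ndarray,
    p: ReleaseParams,
    target_molecules: float = 3_000.0,
) -> float:
    """Fix ``R_max`` so one action-potential waveform releases ``target_molecules``.

    Integrates the voltage-dependent factor of the release function over the
    waveform (with a full releasable pool) and scales ``R_max`` so the
    time-integral of the release flux equals the target amount per synapse.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    x = np.clip((V - p.V_cr) / (p.V_hi - p.V_cr), 0.0, None)
    q = x * x
    if p.clamp_quadratic:
        q = np.minimum(q, 1.0)
    integral = float(np.trapezoid(q, t))  # ms
    if integral <= 0.0:
        raise ParameterError("waveform never exceeds V_cr; cannot calibrate R_max")
    return amount_from_molecules(target_molecules) / integral
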