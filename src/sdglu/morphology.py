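"""Synapse and compartment geometry.

The synaptic cleft is idealized as a thin half-spherical shell of radius
``r`` and height ``h``; glia wrap the cleft in an envelope three times its
volume, into which released glutamate equilibrates instantly.  Only 5% of
the outer spherical surface is open for diffusion into the ECS, the rest is
covered by the glial envelope.  The neural uptake contact area (one full
spherical surface from the envelope side plus two half-spherical surfaces
above and below the cleft) is twice the glial one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class MorphologyError(ValueError):
    """Raised for geometrically invalid morphology parameters."""


@dataclass(frozen=True)
class Morphology:
    """Geometric constants of the single-unit model.

    Attributes
    ----------
    r, h : float
        Synapse radius and cleft height (um).
    omega_c, omega_en : float
        Cleft and glial-envelope volumes (um^3); ``omega_en = 3 * omega_c``.
    A_sigma : float
        Diffusion cross-section from envelope to ECS (um^2).
    A_up_cn, A_up_cg : float
        Cleft-uptake contact areas for neuron and glia (um^2).
    A_m_n, A_m_g : float
        Whole-cell membrane areas of neuron and glia (cm^2).
    N_syn : int
        Total number of synapses of the model neuron.
    N_syn_AP : int
        Synapses taking part in one normal action potential.
    omega_e0 : float
        Resting ECS volume (um^3).
    omega_n0, omega_g0 : float
        Resting neuron / glia volumes (um^3).
    """

    r: float
    h: float
    omega_c: float
    omega_en: float
    A_sigma: float
    A_up_cn: float
    A_up_cg: float
    A_m_n: float = 1.8e-4
    A_m_g: float = 1.8e-4
    N_syn: int = 10_000
    N_syn_AP: int = 20
    omega_e0: float = 7_500.0
    omega_n0: float = 15_000.0
    omega_g0: float = 15_000.0
    omega_tot: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.omega_tot == 0.0:
            object.__setattr__(
                self, "omega_tot", self.omega_e0 + self.omega_n0 + self.omega_g0
            )

    @property
    def n_syn_pre(self) -> int:
        """Presynaptic (= postsynaptic) synapse count: half of all synapses."""
        return self.N_syn // 2


def cleft_geometry(r: float, h: float, **kwargs) -> Morphology:
    """Build a :class:`Morphology` from synapse radius and cleft height.

    The cleft volume is the thin half-spherical shell
    ``0.5 * (4/3) * pi * ((r+h)^3 - r^3) ~= 2 pi r^2 h`` (terms of order h^2
    dropped, valid for h << r); the envelope is exactly three times the cleft.

    Parameters
    ----------
    r : float
        Synapse radius (um); must be positive.
    h : float
        Cleft height (um); must be non-negative.
    kwargs
        Forwarded to :class:`Morphology` (membrane areas, synapse counts,
        resting volumes).
    """
    if r <= 0.0:
        raise MorphologyError(f"synapse radius must be positive, got r={r}")
    if h < 0.0:
        raise MorphologyError(f"cleft height must be non-negative, got h={h}")
    omega_c = 2.0 * math.pi * r * r * h
    return Morphology(
        r=r,
        h=h,
        omega_c=omega_c,
        omega_en=3.0 * omega_c,
        A_sigma=0.05 * 4.0 * math.pi * r * r,
        A_up_cn=8.0 * math.pi * r * r,
        A_up_cg=4.0 * math.pi * r * r,
        **kwargs,
    )


def exact_shell_volume(r: float, h: float) -> float:
    """Exact half-spherical shell volume, without the h << r truncation."""
    return 0.5 * (4.0 / 3.0) * math.pi * ((r + h) ** 3 - r**3)
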