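"""Physical constants and the package's internal unit system.

Internal units
--------------
potential        mV
time             ms
concentration    mM
volume           um^3
amount           fmol          (1 mM * 1 um^3 = 1e-3 fmol)
current density  uA/cm^2
membrane area    cm^2
conductance      mS/cm^2

All unit conversions in the package go through this table; no other module
hard-codes Avogadro's number or the Faraday constant.
"""

from __future__ import annotations

import math

#: Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23

#: Faraday constant (C/mol)
FARADAY = 96485.33212

#: Gas constant (J/(mol K))
GAS_CONSTANT = 8.31446262

#: Body temperature used throughout (K)
TEMPERATURE = 310.0

#: RT/F at 310 K in mV
RTF_MV = GAS_CONSTANT * TEMPERATURE / FARADAY * 1e3  # ~26.71 mV

#: Amount (fmol) moved per ms by a current density of 1 uA/cm^2 through 1 cm^2.
#: 1 uA * 1 ms = 1e-9 C; divide by F (mol) and express in fmol (1e15).
CURRENT_TO_FMOL_PER_MS = 1e-9 / FARADAY * 1e15  # ~0.010364 fmol/(ms * uA)

#: fmol per (mM * um^3): 1 mM = 1e-18 mol/um^3 -> 1 mM*um^3 = 1e-3 fmol.
MM_UM3_TO_FMOL = 1e-3

#: fmol in one molecule
MOLECULES_TO_FMOL = 1e15 / N_AVOGADRO


def amount_from_molecules(n_molecules: float) -> float:
    """Convert a molecule count to an amount in fmol."""
    return n_molecules * MOLECULES_TO_FMOL


def concentration(amount_fmol: float, volume_um3: float) -> float:
    """Concentration (mM) of ``amount_fmol`` dissolved in ``volume_um3``."""
    return amount_fmol / (volume_um3 * MM_UM3_TO_FMOL)


def amount(concentration_mm: float, volume_um3: float) -> float:
    """Amount (fmol) of a solute at ``concentration_mm`` in ``volume_um3``."""
    return concentration_mm * volume_um3 * MM_UM3_TO_FMOL


def nernst(z: int, c_in: float, c_out: float, temperature: float = TEMPERATURE) -> float:
    """Nernst reversal potential (mV) for valence ``z``.

    Parameters
    ----------
    z : int
        Ion valence (+1 for Na/K, -1 for Cl).
    c_in, c_out : float
        Intra-/extracellular concentrations (mM); must be positive.
    temperature : float
        Absolute temperature (K).
    """
    if c_in <= 0.0 or c_out <= 0.0:
        raise ValueError(
            f"Nernst potential requires positive concentrations, got c_in={c_in}, c_out={c_out}"
        )
    rtf = GAS_CONSTANT * temperature / FARADAY * 1e3
    return rtf / z * math.log(c_out / c_in)
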