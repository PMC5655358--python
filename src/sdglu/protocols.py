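"""Time-dependent experimental protocols.

A :class:`Protocol` bundles the bath K+ concentration and three activity
scales (pump, glia/bath regulation, glutamate uptake), each a pure
function of time, plus a constant uptake fraction multiplying the base
transporter velocity.  Two canonical conditions are provided: high-K+
perfusion (bath K+ step) and oxygen-glucose deprivation (all regulatory
functions ramp off, hold at zero, and ramp back on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable


@dataclass(frozen=True)
class Protocol:
    """Time-dependent modulation of bath K+ and regulatory activity.

    All scale functions map time (ms) to [0, 1]; ``uptake_fraction`` is a
    constant multiplier on the base uptake velocity (the impaired-uptake
    perturbation parameter).
    """

    k_bath: Callable[[float], float]
    pump_scale: Callable[[float], float] = field(default=lambda t: 1.0)
    glia_scale: Callable[[float], float] = field(default=lambda t: 1.0)
    uptake_scale: Callable[[float], float] = field(default=lambda t: 1.0)
    uptake_fraction: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.uptake_fraction <= 1.0:
            raise ValueError(
                f"uptake_fraction must be in [0, 1], got {self.uptake_fraction}"
            )


def baseline_protocol(k_bath: float = 4.0) -> Protocol:
    """Constant physiological bath, all regulation intact."""
    return Protocol(k_bath=lambda t: k_bath, name="baseline")


def perfusion_protocol(k_high: float = 15.0, t_on: float = 0.0, k_rest: float = 4.0) -> Protocol:
    """High-K+ perfusion: bath K+ steps from ``k_rest`` to ``k_high`` at ``t_on``.

    All regulatory activity remains intact; only the bath concentration
    changes (discontinuously at ``t_on``).
    """
    if k_high <= 0.0:
        raise ValueError(f"bath K+ must be positive, got {k_high}")

    def k_bath(t: float) -> float:
        return k_high if t >= t_on else k_rest

    return Protocol(k_bath=k_bath, name="perfusion")


def _ramp(t: float, t0: float, t1: float, start: float, end: float, shape: str) -> float:
    """Monotone continuous ramp from ``start`` to ``end`` over [t0, t1]."""
    if t <= t0:
        return start
    if t >= t1:
        return end
    x = (t - t0) / (t1 - t0)
    if shape == "cosine":
        x = 0.5 * (1.0 - math.cos(math.pi * x))
    return start + (end - start) * x


def ogd_protocol(
    t_start: float = 10_000.0,
    ramp: float = 15_000.0,
    hold: float = 40_000.0,
    k_bath: float = 4.0,
    shape: str = "linear",
) -> Protocol:
    """Oxygen-glucose deprivation: regulation ceases, holds at zero, recovers.

    Pump, glial/bath, and uptake activity ramp 1 -> 0 over
    [t_start, t_start + ramp], stay 0 for ``hold`` ms, and ramp back
    0 -> 1 over the final ``ramp`` ms.  Bath K+ stays at its
    physiological value.  Ramps are linear by default (``shape='cosine'``
    for smooth de-/reactivation).
    """
    if ramp <= 0.0 or hold <= 0.0:
        raise ValueError("OGD ramp and hold durations must be positive")
    if shape not in ("linear", "cosine"):
        raise ValueError(f"unknown ramp shape {shape!r}")
    t1 = t_start + ramp
    t2 = t1 + hold
    t3 = t2 + ramp

    def scale(t: float) -> float:
        if t < t1:
            return _ramp(t, t_start, t1, 1.0, 0.0, shape)
        if t < t2:
            return 0.0
        return _ramp(t, t2, t3, 0.0, 1.0, shape)

    return Protocol(
        k_bath=lambda t: k_bath,
        pump_scale=scale,
        glia_scale=scale,
        uptake_scale=scale,
        name="ogd",
    )


def impaired_uptake(base: Protocol, fraction: float) -> Protocol:
    """Scale the base transporter velocity; all four pathways follow.

    ``fraction=1`` returns an identical protocol; ``fraction=0`` disables
    glutamate clearance entirely.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"uptake fraction must be in [0, 1], got {fraction}")
    return replace(base, uptake_fraction=base.uptake_fraction * fraction)
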