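"""Deterministic synthetic inputs for testing.

Three generator families: voltage traces with known event times (to
validate SD event detection), a planar normal form with an analytic Hopf
bifurcation (to validate continuation markers), and batches of random but
physically valid model states (for conservation audits).  All randomness
is seeded; identical arguments give identical outputs.
"""

from __future__ import annotations

import numpy as np

from .constants import MM_UM3_TO_FMOL
from .model import S, SDModel


def trapezoid_trace(
    plateau_ms: float = 80_000.0,
    baseline_mv: float = -70.0,
    plateau_mv: float = -10.0,
    t_onset_ms: float = 30_000.0,
    ramp_ms: float = 500.0,
    t_end_ms: float | None = None,
    dt_ms: float = 10.0,
    noise_mv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voltage trace with a trapezoidal depolarization of known timing.

    The plateau spans ``[t_onset, t_onset + plateau]`` with linear ramps
    of width ``ramp_ms`` on each side; optional Gaussian noise.
    Returns ``(t, V)``.
    """
    if t_end_ms is None:
        t_end_ms = t_onset_ms + plateau_ms + 60_000.0
    t = np.arange(0.0, t_end_ms, dt_ms)
    V = np.full_like(t, baseline_mv)
    up0, up1 = t_onset_ms - ramp_ms, t_onset_ms
    dn0, dn1 = t_onset_ms + plateau_ms, t_onset_ms + plateau_ms + ramp_ms
    rising = (t >= up0) & (t < up1)
    V[rising] = baseline_mv + (plateau_mv - baseline_mv) * (t[rising] - up0) / ramp_ms
    V[(t >= up1) & (t < dn0)] = plateau_mv
    falling = (t >= dn0) & (t < dn1)
    V[falling] = plateau_mv + (baseline_mv - plateau_mv) * (t[falling] - dn0) / ramp_ms
    if noise_mv > 0.0:
        V = V + np.random.default_rng(seed).normal(0.0, noise_mv, size=len(t))
    return t, V


class ToyHopfSystem:
    """Planar Hopf normal form ``dz/dt = (mu + i omega) z - |z|^2 z``.

    The origin is a fixed point for every ``mu`` with eigenvalues
    ``mu +- i omega``: it loses stability in a Hopf bifurcation exactly
    at ``mu = 0``.  Packaged with the same call signature the fast
    subsystem exposes (state, parameter) so continuation code can be
    exercised against an analytic ground truth.
    """

    def __init__(self, omega: float = 1.0):
        self.omega = omega

    def rhs(self, x: np.ndarray, mu: float) -> np.ndarray:
        u, v = x
        r2 = u * u + v * v
        return np.array([
            mu * u - self.omega * v - r2 * u,
            self.omega * u + mu * v - r2 * v,
        ])

    def fixed_point(self, mu: float) -> np.ndarray:
        return np.zeros(2)

    def eigenvalues(self, mu: float) -> np.ndarray:
        return np.array([mu + 1j * self.omega, mu - 1j * self.omega])


def random_states(
    model: SDModel, n: int = 100, seed: int = 1, spread: float = 0.5
) -> np.ndarray:
    """Batch of valid random full states around rest (shape ``(n, DIM)``).

    Amount-type components are jittered multiplicatively (staying
    positive), gates uniformly in [0, 1], volumes within +-30% of rest
    with the ECS kept above 10% of the box; the slow pools stay within
    physically meaningful ranges.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    rest = model.resting_state()
    out = np.empty((n, S.DIM))
    w_max = model.pumpglia.W_max
    for i in range(n):
        y = rest.copy()
        for idx in (S.NA_N, S.K_N, S.CL_N, S.NA_E, S.K_E, S.CL_E):
            y[idx] = rest[idx] * rng.uniform(1.0 - spread, 1.0 + spread)
        for idx in (S.N, S.H, S.R_NMDA, S.R_AMPA):
            y[idx] = rng.uniform(0.0, 1.0)
        y[S.W_GLIA] = rng.uniform(0.2, 0.95) * w_max
        y[S.N_BATH] = rng.uniform(-100.0, 300.0)
        while True:
            on = rest[S.OMEGA_N] * rng.uniform(0.7, 1.3)
            og = rest[S.OMEGA_G] * rng.uniform(0.7, 1.3)
            if model.morph.omega_tot - on - og > 0.1 * model.morph.omega_tot:
                break
        y[S.OMEGA_N], y[S.OMEGA_G] = on, og
        n_max = model.release.N_max
        y[S.GLU_I] = rng.uniform(0.0, n_max)
        y[S.GLU_C] = rng.uniform(0.0, 20.0) * model.morph.omega_en * MM_UM3_TO_FMOL
        y[S.GLU_E] = rng.uniform(0.0, 5.0) * model.morph.omega_e0 * MM_UM3_TO_FMOL
        y[S.GLU_UP] = rng.uniform(0.0, 0.5 * n_max * model.morph.N_syn)
        out[i] = y
    return out


def make_fixtures(kind: str, **kwargs):
    """Dispatch by fixture kind: trapezoid_trace | toy_hopf_system | random_states."""
    if kind == "trapezoid_trace":
        return trapezoid_trace(**kwargs)
    if kind == "toy_hopf_system":
        return ToyHopfSystem(**kwargs)
    if kind == "random_states":
        return random_states(**kwargs)
    raise ValueError(f"unknown fixture kind {kind!r}")
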