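"""Stiff integration of the full model, SD event detection, and scans.

The model couples millisecond spiking to minute-scale ion redistribution,
so trajectories are integrated with an adaptive implicit-capable solver
(LSODA by default) at tight tolerances, with dense output sampled on a
regular grid that is decoupled from the solver steps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .constants import MM_UM3_TO_FMOL
from .glutamate import ReleaseParams, calibrate_release_rate, uptake_rates
from .model import S, SDModel
from .protocols import Protocol, baseline_protocol


class SimulationError(RuntimeError):
    """Solver failure or volume collapse; carries the last valid state."""

    def __init__(self, message: str, t_last: float | None = None, y_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


#: typical magnitude of each state component, used for absolute tolerances
STATE_SCALE = np.array([
    1.0, 1.0, 1.0, 1.0, 1.0,                 # gates
    1000.0, 1000.0, 1000.0,                  # neuron amounts (fmol)
    1000.0, 1000.0, 1000.0,                  # ECS amounts
    1000.0, 1000.0,                          # W_glia, N_bath
    1e4, 1e4,                                # volumes (um^3)
    1e-3, 1e-3, 1.0, 10.0,                   # glutamate pools
])


@dataclass
class Trajectory:
    """Sampled model trajectory with derived-series accessors."""

    t: np.ndarray  # ms
    y: np.ndarray  # (n_samples, S.DIM)
    model: SDModel
    protocol: Protocol

    @property
    def V(self) -> np.ndarray:
        return self.model.voltage_series(self.y)

    @property
    def omega_e(self) -> np.ndarray:
        return self.model.morph.omega_tot - self.y[:, S.OMEGA_N] - self.y[:, S.OMEGA_G]

    @property
    def G_c(self) -> np.ndarray:
        return self.y[:, S.GLU_C] / (self.model.morph.omega_en * MM_UM3_TO_FMOL)

    @property
    def G_e(self) -> np.ndarray:
        return self.y[:, S.GLU_E] / (self.omega_e * MM_UM3_TO_FMOL)

    @property
    def delta_n_glia_k(self) -> np.ndarray:
        return self.y[:, S.W_GLIA] - self.model.pumpglia.W0

    @property
    def delta_n_bath_k(self) -> np.ndarray:
        return self.y[:, S.N_BATH]

    @property
    def delta_n_k(self) -> np.ndarray:
        """Slow variable: K+ removed from neuron+ECS by glia and bath (fmol)."""
        return self.delta_n_glia_k + self.delta_n_bath_k

    def concentration(self, name: str) -> np.ndarray:
        """Concentration series (mM); name like 'k_e', 'na_n', 'cl_n'."""
        idx = {"na_n": S.NA_N, "k_n": S.K_N, "cl_n": S.CL_N,
               "na_e": S.NA_E, "k_e": S.K_E, "cl_e": S.CL_E}[name]
        vol = (self.y[:, S.OMEGA_N] if name.endswith("_n") else self.omega_e)
        return self.y[:, idx] / (vol * MM_UM3_TO_FMOL)

    def to_frame(self) -> pd.DataFrame:
        """Documented tabular export (one row per sample)."""
        df = pd.DataFrame({"t_ms": self.t, "V_mV": self.V})
        for name in ("na_n", "k_n", "cl_n", "na_e", "k_e", "cl_e"):
            df[f"{name}_mM"] = self.concentration(name)
        df["G_c_mM"] = self.G_c
        df["G_e_mM"] = self.G_e
        df["omega_n_um3"] = self.y[:, S.OMEGA_N]
        df["omega_g_um3"] = self.y[:, S.OMEGA_G]
        df["omega_e_um3"] = self.omega_e
        df["dNK_glia_fmol"] = self.delta_n_glia_k
        df["dNK_bath_fmol"] = self.delta_n_bath_k
        df["dNK_fmol"] = self.delta_n_k
        return df

    def state_hash(self) -> str:
        """Deterministic digest of the sampled trajectory."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.t).tobytes())
        h.update(np.ascontiguousarray(self.y).tobytes())
        return h.hexdigest()

    def conservation_drift(self) -> dict[str, float]:
        """Max relative drift of each conserved total along the trajectory."""
        first = self.model.audit(self.y[0])
        out = {}
        for key, ref in first.items():
            series = np.array([self.model.audit(row)[key] for row in self.y[:: max(1, len(self.t) // 200)]])
            denom = abs(ref) if ref != 0 else 1.0
            out[key] = float(np.max(np.abs(series - ref)) / denom)
        return out


def simulate(
    model: SDModel,
    protocol: Protocol,
    t_end: float,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol_scale: float = 1e-10,
    sample_dt: float = 10.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full model under a protocol.

    Deterministic: repeated calls with identical arguments produce
    bit-identical trajectories.  Integration aborts with a diagnostic if
    the ECS collapses below 5% of the total volume.

    Parameters
    ----------
    t_end : float
        End time (ms); sampling starts at 0 with spacing ``sample_dt``.
    rtol, atol_scale : float
        Relative tolerance and the factor converting per-variable typical
        scales into absolute tolerances.
    """
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    if y0 is None:
        y0 = model.resting_state()
    collapse_level = 0.05 * model.morph.omega_tot

    def volume_collapse(t, y, *_args):
        return (model.morph.omega_tot - y[S.OMEGA_N] - y[S.OMEGA_G]) - collapse_level

    volume_collapse.terminal = True
    volume_collapse.direction = -1

    t_eval = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(
        model.rhs,
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=STATE_SCALE * atol_scale,
        events=[volume_collapse],
        args=(protocol,),
        dense_output=False,
    )
    if sol.status == 1:  # terminated by the collapse event
        raise SimulationError(
            f"ECS volume collapsed below 5% of total at t={sol.t_events[0][0]:.1f} ms",
            t_last=sol.t[-1] if len(sol.t) else None,
            y_last=sol.y[:, -1] if len(sol.t) else None,
        )
    if not sol.success:
        raise SimulationError(
            f"solver failure: {sol.message}",
            t_last=sol.t[-1] if len(sol.t) else None,
            y_last=sol.y[:, -1] if len(sol.t) else None,
        )
    return Trajectory(t=sol.t, y=sol.y.T, model=model, protocol=protocol)


# ---------------------------------------------------------------------------
# SD event detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SDEvents:
    """Onset/offset of sustained depolarization in one trace."""

    t_depol: float | None
    t_repol: float | None
    recovered: bool
    baseline: float

    @property
    def duration(self) -> float | None:
        if self.t_depol is None or self.t_repol is None:
            return None
        return self.t_repol - self.t_depol


def detect_sd_events(
    t: np.ndarray,
    V: np.ndarray,
    baseline_window: float = 5_000.0,
    depol_threshold: float = -30.0,
    persistence: float = 5_000.0,
    repol_tolerance: float = 2.0,
) -> SDEvents:
    """Locate sustained depolarization and the return to baseline.

    ``t_depol`` is the first time V exceeds ``depol_threshold`` and stays
    above it for at least ``persistence`` ms (this skips transient
    spikes); ``t_repol`` is the first subsequent time V falls back to
    within ``repol_tolerance`` mV of the pre-SD baseline (the mean over
    the initial ``baseline_window``).  ``recovered`` is False when no such
    return occurs before the end of the trace.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t[-1] - t[0] <= baseline_window:
        raise ValueError("trajectory shorter than the baseline window")
    baseline = float(V[t <= t[0] + baseline_window].mean())

    above = V > depol_threshold
    t_depol = None
    i = 0
    n = len(t)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            # segment [i, j): above threshold (open-ended counts if long enough)
            seg_len = (t[min(j, n - 1)] if j < n else t[-1]) - t[i]
            if seg_len >= persistence:
                t_depol = float(t[i])
                break
            i = j
        else:
            i += 1
    if t_depol is None:
        return SDEvents(None, None, True, baseline)

    after = t > t_depol + persistence
    back = after & (V <= baseline + repol_tolerance)
    if not back.any():
        return SDEvents(t_depol, None, False, baseline)
    t_repol = float(t[np.argmax(back)])
    return SDEvents(t_depol, t_repol, True, baseline)


def detect_events(traj: Trajectory, **kwargs) -> SDEvents:
    """Event detection on a simulated trajectory."""
    return detect_sd_events(traj.t, traj.V, **kwargs)


# ---------------------------------------------------------------------------
# scans and decompositions
# ---------------------------------------------------------------------------


def scan_uptake(
    model: SDModel,
    fractions,
    base_protocol: Protocol,
    t_end: float,
    rtol: float = 1e-8,
    **event_kwargs,
) -> pd.DataFrame:
    """SD duration versus glutamate-uptake fraction.

    One simulation per fraction; per-run failures are recorded (NaN
    duration, ``recovered=False``) without aborting the scan.
    """
    from .protocols import impaired_uptake

    rows = []
    for frac in fractions:
        row = {"fraction": float(frac), "t_depol": np.nan, "t_repol": np.nan,
               "duration": np.nan, "recovered": False, "error": ""}
        try:
            traj = simulate(model, impaired_uptake(base_protocol, frac), t_end, rtol=rtol)
            ev = detect_events(traj, **event_kwargs)
            row.update(
                t_depol=np.nan if ev.t_depol is None else ev.t_depol,
                t_repol=np.nan if ev.t_repol is None else ev.t_repol,
                duration=np.nan if ev.duration is None else ev.duration,
                recovered=bool(ev.recovered and ev.t_depol is not None),
            )
        except SimulationError as err:  # propagate per-run errors as data
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def uptake_decomposition(traj: Trajectory) -> pd.DataFrame:
    """Cumulative glutamate clearance by pathway (fmol).

    Columns ``cleft_to_neuron``, ``cleft_to_glia``, ``ecs_to_neuron``,
    ``ecs_to_glia`` are non-decreasing; their sum minus the recycled
    amount reproduces the buffered pool at every sample.
    """
    model, proto = traj.model, traj.protocol
    n = len(traj.t)
    rates = np.zeros((n, 4))
    recycle = np.zeros(n)
    for i in range(n):
        y = traj.y[i]
        scale = proto.uptake_scale(traj.t[i]) * proto.uptake_fraction
        pools = model.pools(y)
        omega_e = model.omega_e(y)
        if scale > 0.0:
            rates[i] = uptake_rates(pools, omega_e, model.morph, model.uptake, scale)
        recycle[i] = model.release.k_rec * pools.N_up
    out = {}
    for j, name in enumerate(("cleft_to_neuron", "cleft_to_glia", "ecs_to_neuron", "ecs_to_glia")):
        out[name] = np.concatenate([[0.0], cumulative_trapezoid(rates[:, j], traj.t)])
    out["recycled"] = np.concatenate([[0.0], cumulative_trapezoid(recycle, traj.t)])
    df = pd.DataFrame(out, index=pd.Index(traj.t, name="t_ms"))
    df["buffered"] = traj.y[:, S.GLU_UP]
    return df


# ---------------------------------------------------------------------------
# action-potential waveform and release calibration
# ---------------------------------------------------------------------------


def action_potential_waveform(
    model: SDModel, v_kick: float = 15.0, t_end: float = 25.0, dt: float = 0.005
) -> tuple[np.ndarray, np.ndarray]:
    """One spike of the membrane subsystem at resting ion concentrations.

    The membrane is released from a super-threshold displacement
    ``v_kick`` above rest and integrated at fixed ion concentrations; the
    returned (t, V) waveform contains a single action potential.
    """
    rest = model.rest
    ion_config = {
        "na_n": rest.na_n, "k_n": rest.k_n, "cl_n": rest.cl_n,
        "na_e": rest.na_e, "k_e": rest.k_e, "cl_e": rest.cl_e,
    }

    def rhs(t, x):
        return model.membrane_rhs(x[0], x[1], x[2], ion_config, g_c=0.0)

    t_eval = np.arange(0.0, t_end, dt)
    sol = solve_ivp(
        rhs, (0.0, t_end), [rest.V0 + v_kick, model.n0, model.h0],
        method="LSODA", t_eval=t_eval, rtol=1e-9, atol=1e-10,
    )
    return sol.t, sol.y[0]


def calibrated_release(model: SDModel, **release_kwargs) -> ReleaseParams:
    """Release parameters with ``R_max`` fixed by the one-AP calibration.

    ``R_max`` is chosen so the integral of the release flux over one
    simulated action potential equals 3,000 molecules per synapse.
    """
    base = ReleaseParams(R_max=1.0, **release_kwargs)
    t, V = action_potential_waveform(model)
    r_max = calibrate_release_rate(t, V, base)
    return ReleaseParams(R_max=r_max, **release_kwargs)
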