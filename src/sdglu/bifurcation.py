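"""Slow-fast phase-space analysis of SD recovery.

The two slow variables (glial-buffer and bath K+ pools) are combined into
the single slow variable ``Delta_N_K`` and treated as a bifurcation
parameter of the fast subsystem (membrane, receptor gates, transmembrane
ion amounts, volumes).  Cleft glutamate is clamped as a second parameter.
Fixed points are located by damped Newton iteration, followed by
pseudo-arclength continuation with eigenvalue-based stability flags and
bisection-refined Hopf/fold markers.  Scanning the Hopf locations of the
depolarized and polarized branches over the cleft glutamate concentration
yields the critical glutamate level beyond which the branches no longer
overlap and recovery fails; the reduced membrane-only model (ion
concentrations as parameters) provides an independent estimate via the
disappearance of its stable hyperpolarized state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import S, SDModel

#: typical magnitudes of the fast-subsystem components, for scaling
FAST_SCALE = np.array([100.0, 1.0, 1.0, 1.0, 1.0, 1000.0, 1e4, 1e4])


class ContinuationError(RuntimeError):
    """Continuation step collapse; carries the truncated branch."""

    def __init__(self, message: str, branch: "Branch | None" = None):
        super().__init__(message)
        self.branch = branch


# ---------------------------------------------------------------------------
# numerical Jacobian
# ---------------------------------------------------------------------------


def numerical_jacobian(f, x: np.ndarray, scale: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with per-variable scaled steps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    f0 = np.asarray(f(x))
    jac = np.empty((len(f0), n))
    for j in range(n):
        step = rel_step * scale[j]
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        jac[:, j] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2.0 * step)
    return jac


def damped_newton(
    f,
    x0: np.ndarray,
    scale: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 60,
) -> np.ndarray | None:
    """Damped Newton root of ``f``; residual measured in scaled units.

    Returns None when the iteration does not converge.
    """
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        r = np.asarray(f(x))
        rn = float(np.max(np.abs(r / scale)))
        if rn < tol:
            return x
        jac = numerical_jacobian(f, x, scale)
        try:
            dx = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * dx
            try:
                r_new = np.asarray(f(x_new))
            except (ValueError, FloatingPointError):
                lam *= 0.5
                continue
            if not np.isfinite(r_new).all():
                lam *= 0.5
                continue
            if np.max(np.abs(r_new / scale)) < rn or lam < 1e-4:
                break
            lam *= 0.5
        x = x + lam * dx
    r = np.asarray(f(x))
    if float(np.max(np.abs(r / scale))) < tol:
        return x
    return None


# ---------------------------------------------------------------------------
# fixed points of the fast subsystem
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedPoint:
    """One fixed point of a clamped subsystem."""

    param: float  # Delta_N_K (fmol) or other continuation parameter
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    V: float

    @property
    def max_re(self) -> float:
        return float(np.max(self.eigenvalues.real))


def _classify(f, x: np.ndarray, param: float, scale: np.ndarray, volt) -> FixedPoint:
    jac = numerical_jacobian(f, x, scale)
    eig = np.linalg.eigvals(jac)
    return FixedPoint(param=param, state=x.copy(), eigenvalues=eig,
                      stable=bool(np.max(eig.real) < 0.0), V=float(volt(x)))


def default_seed_grid(model: SDModel) -> list[np.ndarray]:
    """Seed states spanning polarized and depolarized voltage ranges.

    The target seed voltage is imposed through the neuron's net charge
    (a sub-fmol Na+ adjustment); larger Na+/K+ exchanges mimic graded
    transmembrane gradient rundown.
    """
    from .ions import alpha_h, alpha_n, beta_h, beta_n, gate_inf

    rest = model.resting_state()
    base = model.fast_state_from_full(rest)
    seeds = []
    for v in (-90.0, -75.0, -60.0, -45.0, -30.0, -15.0, -5.0, 5.0):
        for na_shift in (0.0, 0.35, 0.7):
            x = base.copy()
            x[0] = v
            x[1] = gate_inf(alpha_n(v), beta_n(v))
            x[2] = gate_inf(alpha_h(v), beta_h(v))
            # shift Na into the neuron to mimic graded gradient rundown
            x[5] = base[5] + na_shift * rest[S.NA_E]
            seeds.append(x)
    return seeds


def find_fixed_points(
    model: SDModel,
    delta_n_k: float,
    delta_n_glia_k: float,
    g_c: float,
    seeds: list[np.ndarray] | None = None,
    pump_scale: float = 1.0,
    n_cl_n: float | None = None,
    s_na: float | None = None,
    tol: float = 1e-11,
) -> list[FixedPoint]:
    """Damped-Newton fixed points of the clamped fast subsystem, deduplicated.

    The seed grid spans polarized and depolarized membrane states; receptor
    gates in every seed are set to their clamped-glutamate equilibria.
    Returns an empty list when no seed converges.
    """
    from .glutamate import receptor_gate_fixed_point

    if seeds is None:
        seeds = default_seed_grid(model)

    def f(x):
        return model.fast_rhs(x, delta_n_k, delta_n_glia_k, g_c, pump_scale, n_cl_n, s_na)

    rc = model.receptors
    found: list[np.ndarray] = []
    for seed in seeds:
        x0 = np.asarray(seed, dtype=float).copy()
        x0[3] = receptor_gate_fixed_point(g_c, rc.alpha_nmda, rc.beta_nmda)
        x0[4] = receptor_gate_fixed_point(g_c, rc.alpha_ampa, rc.beta_ampa)
        x = damped_newton(f, x0, FAST_SCALE, tol=tol)
        if x is None:
            continue
        if any(np.max(np.abs((x - y) / FAST_SCALE)) < 1e-6 for y in found):
            continue
        found.append(x)
    return sorted(
        (_classify(f, x, delta_n_k, FAST_SCALE, model.fast_voltage) for x in found),
        key=lambda fp: fp.V,
    )


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    """Ordered fixed points along one continuation run with markers."""

    params: np.ndarray
    states: np.ndarray
    V: np.ndarray
    max_re: np.ndarray
    stable: np.ndarray
    markers: list[dict] = field(default_factory=list)

    def marker_params(self, kind: str) -> list[float]:
        return [m["param"] for m in self.markers if m["type"] == kind]


def _eig_info(f_ext, z: np.ndarray, scale_ext: np.ndarray):
    jac = numerical_jacobian(f_ext, z, scale_ext)[:, :-1]
    eig = np.linalg.eigvals(jac)
    return eig


def continue_fixed_point(
    rhs,
    x0: np.ndarray,
    p0: float,
    scale: np.ndarray,
    param_range: tuple[float, float],
    step: float = 5.0,
    max_step: float = 25.0,
    min_step: float = 1e-3,
    max_points: int = 2000,
    direction: float = 1.0,
    param_scale: float | None = None,
) -> Branch:
    """Pseudo-arclength continuation of a fixed point of ``rhs(x, p)``.

    Follows the branch while the parameter varies in ``param_range``,
    with adaptive step control.  A Hopf marker is recorded where the
    leading eigenvalue pair crosses the imaginary axis with nonzero
    imaginary part (sign change of the maximal real part), a fold marker
    where a real eigenvalue crosses zero; both are refined by bisection
    in arclength.  ``Branch.V`` carries the first state coordinate (the
    membrane potential for the fast subsystem).
    """
    lo, hi = min(param_range), max(param_range)
    nx = len(x0)
    if param_scale is None:
        param_scale = max(abs(lo), abs(hi), 1.0)
    scale_ext = np.concatenate([scale, [param_scale]])

    def rhs_ext(z):
        return np.asarray(rhs(z[:nx], float(z[nx])))

    # refine the starting point at fixed parameter before following it
    x_start = damped_newton(lambda x: np.asarray(rhs(x, p0)),
                            np.asarray(x0, dtype=float), scale, tol=1e-10)
    if x_start is None:
        x_start = np.asarray(x0, dtype=float)
    z = np.concatenate([x_start, [p0]])
    eig = _eig_info(rhs_ext, z, scale_ext)
    params = [float(z[-1])]
    states = [z[:nx].copy()]
    res = [float(np.max(eig.real))]
    stab = [bool(np.max(eig.real) < 0.0)]
    markers: list[dict] = []

    # initial tangent: predictor along the parameter axis
    tangent = np.zeros(nx + 1)
    tangent[-1] = math.copysign(1.0, direction)
    ds = step / param_scale

    def corrector(z_pred, tang, ds_local, z_prev):
        """Newton for [rhs(z)=0, tang . (z - z_prev)/scale = ds]."""
        def f(z):
            r = rhs_ext(z)
            arc = float(np.dot(tang, (z - z_prev) / scale_ext) - ds_local)
            return np.concatenate([r, [arc]])

        return damped_newton(f, z_pred, scale_ext, tol=1e-10, max_iter=30)

    max_ds = max_step / param_scale
    min_ds = min_step / param_scale
    prev_eig = eig
    while len(params) < max_points:
        z_pred = z + tangent * ds * scale_ext
        z_new = corrector(z_pred, tangent, ds, z)
        if z_new is None:
            ds *= 0.5
            if ds < min_ds:
                branch = Branch(
                    np.array(params), np.array(states),
                    np.array(states)[:, 0].copy(),
                    np.array(res), np.array(stab), markers,
                )
                raise ContinuationError(
                    f"continuation step collapsed at parameter {z[-1]:.4g}", branch
                )
            continue
        eig_new = _eig_info(rhs_ext, z_new, scale_ext)
        re_prev = float(np.max(prev_eig.real))
        re_new = float(np.max(eig_new.real))
        if re_prev * re_new < 0.0:
            marker = _refine_crossing(rhs_ext, corrector, z, z_new, tangent,
                                      prev_eig, eig_new, scale_ext)
            if marker is not None:
                markers.append(marker)
        # accept the step; next tangent from the secant
        secant = (z_new - z) / scale_ext
        norm = float(np.linalg.norm(secant))
        if norm > 0:
            tangent = secant / norm
        z = z_new
        prev_eig = eig_new
        params.append(float(z[-1]))
        states.append(z[:nx].copy())
        res.append(re_new)
        stab.append(re_new < 0.0)
        ds = min(ds * 1.3, max_ds)
        if not (lo - 1e-9 <= z[-1] <= hi + 1e-9):
            break
    st = np.array(states)
    return Branch(np.array(params), st, st[:, 0].copy(),
                  np.array(res), np.array(stab), markers)


def continue_branch(
    model: SDModel,
    start: FixedPoint,
    delta_n_glia_k: float,
    g_c: float,
    param_range: tuple[float, float],
    step: float = 5.0,
    max_step: float = 25.0,
    min_step: float = 1e-3,
    max_points: int = 2000,
    pump_scale: float = 1.0,
    n_cl_n: float | None = None,
    s_na: float | None = None,
    direction: float = 1.0,
) -> Branch:
    """Continuation of a fast-subsystem fixed point in ``Delta_N_K``.

    Wraps :func:`continue_fixed_point` around the clamped fast subsystem;
    see there for marker semantics.
    """

    def rhs(x, p):
        return model.fast_rhs(x, p, delta_n_glia_k, g_c, pump_scale, n_cl_n, s_na)

    return continue_fixed_point(
        rhs, start.state, start.param, FAST_SCALE, param_range,
        step=step, max_step=max_step, min_step=min_step,
        max_points=max_points, direction=direction,
        param_scale=max(abs(param_range[0]), abs(param_range[1]), 100.0),
    )


def _refine_crossing(rhs_ext, corrector, z_a, z_b, tangent, eig_a, eig_b, scale_ext):
    """Bisect in arclength between two accepted points to locate the marker."""
    nfast = len(scale_ext) - 1

    def leading_im(eig):
        i = int(np.argmax(eig.real))
        return abs(float(eig[i].imag))

    za, zb = z_a.copy(), z_b.copy()
    ea, eb = eig_a, eig_b
    for _ in range(48):
        ds_half = float(np.dot(tangent, (zb - za) / scale_ext)) / 2.0
        if abs(ds_half) < 1e-14:
            break
        z_mid = corrector(0.5 * (za + zb), tangent, ds_half, za)
        if z_mid is None:
            break
        e_mid = _eig_info(lambda w: rhs_ext(w), z_mid, scale_ext)
        if float(np.max(ea.real)) * float(np.max(e_mid.real)) <= 0.0:
            zb, eb = z_mid, e_mid
        else:
            za, ea = z_mid, e_mid
        if abs(float(np.max(eb.real)) - float(np.max(ea.real))) < 1e-10:
            break
    z_star = 0.5 * (za + zb)
    e_star = ea if abs(np.max(ea.real)) < abs(np.max(eb.real)) else eb
    kind = "hopf" if leading_im(e_star) > 1e-9 else "fold"
    return {
        "type": kind,
        "param": float(z_star[-1]),
        "state": z_star[:nfast].copy(),
        "imag": leading_im(e_star),
    }


# ---------------------------------------------------------------------------
# two-parameter Hopf loci and critical glutamate level
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchEnds:
    """Stability boundaries of the two branches at one cleft-glutamate level."""

    g_c: float
    depol_end: float | None  # Delta_N_K where the depolarized branch destabilizes
    polar_start: float | None  # Delta_N_K where the polarized branch stabilizes

    @property
    def overlap(self) -> float | None:
        if self.depol_end is None or self.polar_start is None:
            return None
        return self.depol_end - self.polar_start  # -inf when the polarized branch is absent


def _stability_boundary(branch: Branch, from_stable: bool) -> float | None:
    """Parameter of the first stability change along a branch.

    ``from_stable=True``: last parameter before the branch destabilizes
    (depolarized-branch end).  ``from_stable=False``: first parameter at
    which the branch is stable (polarized-branch start).
    """
    hopfs = branch.marker_params("hopf") + branch.marker_params("fold")
    if hopfs:
        return float(hopfs[0])
    # fall back to the sign change on the sampled grid
    flips = np.flatnonzero(np.diff(branch.stable.astype(int)) != 0)
    if len(flips):
        return float(0.5 * (branch.params[flips[0]] + branch.params[flips[0] + 1]))
    return None


def branch_ends(
    model: SDModel,
    g_c: float,
    delta_n_glia_k: float,
    depol_seed_dnk: float,
    polar_seed_dnk: float,
    dnk_range: tuple[float, float],
    pump_scale: float = 1.0,
    n_cl_n: float | None = None,
    s_na: float | None = None,
) -> BranchEnds:
    """Locate the depolarized-branch end and polarized-branch start.

    Starts one continuation on the stable depolarized fixed point at
    ``depol_seed_dnk`` (following increasing ``Delta_N_K``) and one on
    the polarized fixed point at ``polar_seed_dnk`` (following decreasing
    ``Delta_N_K``); each boundary is the branch's first stability change.
    """
    depol_end = polar_start = None
    fps = find_fixed_points(model, depol_seed_dnk, delta_n_glia_k, g_c,
                            n_cl_n=n_cl_n, s_na=s_na)
    dep = [fp for fp in fps if fp.stable and fp.V > -45.0]
    if dep:
        try:
            br = continue_branch(
                model, dep[-1], delta_n_glia_k, g_c, dnk_range, direction=+1.0,
                pump_scale=pump_scale, n_cl_n=n_cl_n, s_na=s_na,
            )
        except ContinuationError as err:
            br = err.branch
        if br is not None:
            depol_end = _stability_boundary(br, from_stable=True)
    fps = find_fixed_points(model, polar_seed_dnk, delta_n_glia_k, g_c,
                            n_cl_n=n_cl_n, s_na=s_na)
    pol = [fp for fp in fps if fp.stable and fp.V < -55.0]
    if pol:
        try:
            br = continue_branch(
                model, pol[0], delta_n_glia_k, g_c, dnk_range, direction=-1.0,
                pump_scale=pump_scale, n_cl_n=n_cl_n, s_na=s_na,
            )
        except ContinuationError as err:
            br = err.branch
        if br is not None:
            polar_start = _stability_boundary(br, from_stable=True)
    return BranchEnds(g_c=g_c, depol_end=depol_end, polar_start=polar_start)


def hopf_loci(
    model: SDModel,
    g_c_grid,
    delta_n_glia_k: float,
    depol_seed_dnk: float,
    polar_seed_dnk: float,
    dnk_range: tuple[float, float],
    n_cl_n: float | None = None,
    s_na: float | None = None,
) -> list[BranchEnds]:
    """Branch-stability boundaries in the (G_c, Delta_N_K) plane.

    Missing branches at some G_c are flagged with ``None`` entries rather
    than aborting the scan.
    """
    return [
        branch_ends(model, float(gc), delta_n_glia_k, depol_seed_dnk,
                    polar_seed_dnk, dnk_range, n_cl_n=n_cl_n, s_na=s_na)
        for gc in g_c_grid
    ]


def critical_g_c(loci: list[BranchEnds]) -> float:
    """Cleft-glutamate level where the branch overlap vanishes.

    Located by a root of the overlap (depolarized end minus polarized
    start) versus G_c, interpolated between the bracketing grid points.
    Raises if the scan never brackets a sign change.
    """
    pts = [(be.g_c, be.overlap) for be in loci if be.overlap is not None]
    if len(pts) < 2:
        raise ValueError("not enough branch overlaps to locate the critical level")
    pts.sort()
    for (g0, f0), (g1, f1) in zip(pts[:-1], pts[1:]):
        if f0 > 0.0 >= f1:
            if math.isinf(f1):
                # overlap vanished because the polarized branch disappeared
                return 0.5 * (g0 + g1)
            # secant interpolation within the bracketing interval
            return g0 + (g1 - g0) * f0 / (f0 - f1)
    raise ValueError("branch overlap does not change sign on the scanned G_c grid")


# ---------------------------------------------------------------------------
# membrane-only subsystem (Fig-7-style analysis)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembraneFixedPoint:
    V: float
    n: float
    h: float
    stable: bool
    eigenvalues: np.ndarray


MEMBRANE_SCALE = np.array([100.0, 1.0, 1.0])


def membrane_fixed_points(
    model: SDModel,
    ion_config: dict[str, float],
    g_c: float,
    pump_scale: float = 1.0,
    s_na: float | None = None,
    v_seeds=None,
) -> list[MembraneFixedPoint]:
    """Fixed points of the membrane-only model (ion concentrations frozen).

    Seeds Newton iterations from gate-equilibrated states over a voltage
    grid; deduplicates and classifies stability from the 3x3 Jacobian.
    """
    from .ions import alpha_h, alpha_n, beta_h, beta_n, gate_inf

    if v_seeds is None:
        v_seeds = np.arange(-110.0, 20.1, 5.0)

    def f(x):
        return np.array(
            model.membrane_rhs(x[0], x[1], x[2], ion_config, g_c, pump_scale, s_na)
        )

    out: list[np.ndarray] = []
    for v in v_seeds:
        x0 = np.array([v, gate_inf(alpha_n(v), beta_n(v)), gate_inf(alpha_h(v), beta_h(v))])
        x = damped_newton(f, x0, MEMBRANE_SCALE, tol=1e-12)
        if x is None:
            continue
        if any(abs(x[0] - y[0]) < 1e-6 for y in out):
            continue
        out.append(x)
    fps = []
    for x in sorted(out, key=lambda w: w[0]):
        eig = np.linalg.eigvals(numerical_jacobian(f, x, MEMBRANE_SCALE))
        fps.append(MembraneFixedPoint(V=float(x[0]), n=float(x[1]), h=float(x[2]),
                                      stable=bool(np.max(eig.real) < 0.0),
                                      eigenvalues=eig))
    return fps


def hyperpolarized_state(
    model: SDModel,
    ion_config: dict[str, float],
    g_c: float,
    pump_scale: float = 1.0,
    s_na: float | None = None,
) -> MembraneFixedPoint | None:
    """The stable low-voltage membrane state, if it exists.

    During recovery this state lies below the K+ Nernst potential: the
    pump current pushes the potential beyond E_K while all conductances
    are collapsed.
    """
    fps = membrane_fixed_points(model, ion_config, g_c, pump_scale, s_na)
    low = [fp for fp in fps if fp.stable and fp.V < -50.0]
    return low[0] if low else None


def critical_g_c_membrane(
    model: SDModel,
    ion_config: dict[str, float],
    g_lo: float = 0.0,
    g_hi: float = 0.4,
    tol: float = 1e-4,
    pump_scale: float = 1.0,
    s_na: float | None = None,
) -> float:
    """Glutamate level at which the stable hyperpolarized state disappears.

    Bisection on existence of the state between ``g_lo`` (must exist) and
    ``g_hi`` (must not).
    """
    if hyperpolarized_state(model, ion_config, g_lo, pump_scale, s_na) is None:
        raise ValueError("no hyperpolarized state even at the low glutamate bound")
    if hyperpolarized_state(model, ion_config, g_hi, pump_scale, s_na) is not None:
        raise ValueError("hyperpolarized state persists at the high glutamate bound")
    lo, hi = g_lo, g_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if hyperpolarized_state(model, ion_config, mid, pump_scale, s_na) is None:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# slow-variable diagnostics on full trajectories
# ---------------------------------------------------------------------------


def transition_clamps(traj, t_ms: float) -> dict[str, float]:
    """Clamp values for the fast subsystem taken from one trajectory time.

    Returns the slow variables (``delta_n_k``, ``delta_n_glia_k``), the
    neuronal Cl- amount, the slow Na+ inactivation gate, and the cleft
    glutamate concentration at ``t_ms`` — everything needed to anchor the
    fixed-point analysis at a de- or repolarization point.
    """
    i = int(np.searchsorted(traj.t, t_ms))
    y = traj.y[i]
    model = traj.model
    return {
        "delta_n_k": float(model.delta_n_k(y)),
        "delta_n_glia_k": float(model.delta_n_glia_k(y)),
        "n_cl_n": float(y[S.CL_N]),
        "s_na": float(y[S.SNA]),
        "g_c": float(max(traj.G_c[i], 1e-4)),
        "fast_state": model.fast_state_from_full(y),
    }


def two_parameter_analysis(
    traj,
    events,
    g_c_grid,
    back_ms: float = 8_000.0,
    forward_ms: float = 30_000.0,
) -> list[BranchEnds]:
    """Branch-overlap analysis in the (G_c, Delta_N_K) plane.

    Anchored on one simulated SD cycle: the depolarized branch is seeded
    from the trajectory shortly before repolarization, the polarized
    branch from the recovered state after it; slow clamps (glial pool,
    neuronal Cl-, slow Na+ inactivation) are taken at the repolarization
    point.  For each clamped cleft-glutamate level the depolarized-branch
    end and polarized-branch start are located by continuation; an absent
    polarized branch is recorded as ``polar_start = inf`` (no overlap at
    any Delta_N_K).
    """
    if events.t_repol is None:
        raise ValueError("two-parameter analysis requires a recovered SD cycle")
    model = traj.model
    dep = transition_clamps(traj, events.t_repol - back_ms)
    pol = transition_clamps(traj, events.t_repol + forward_ms)
    dnk_lo = dep["delta_n_k"] - 450.0
    dnk_hi = dep["delta_n_k"] + 700.0
    out = []
    for g_c in g_c_grid:
        g_c = float(g_c)
        depol_end = polar_start = None

        def rhs(x, p_, gc=g_c):
            return model.fast_rhs(x, p_, dep["delta_n_glia_k"], gc, 1.0,
                                  dep["n_cl_n"], dep["s_na"])

        def f_at(x, dnk, gc=g_c):
            return model.fast_rhs(x, dnk, dep["delta_n_glia_k"], gc, 1.0,
                                  dep["n_cl_n"], dep["s_na"])

        x_dep = damped_newton(lambda x: f_at(x, dep["delta_n_k"]),
                              dep["fast_state"], FAST_SCALE, tol=1e-10)
        if x_dep is not None and model.fast_voltage(x_dep) > -45.0:
            try:
                br = continue_fixed_point(rhs, x_dep, dep["delta_n_k"], FAST_SCALE,
                                          (dnk_lo, dnk_hi), step=5.0, max_step=20.0,
                                          param_scale=500.0, direction=+1.0)
                depol_end = _stability_boundary(br, from_stable=True)
                if depol_end is None and len(br.params):
                    depol_end = float(br.params[-1])  # fold: corrector collapse
            except ContinuationError as err:
                if err.branch is not None and len(err.branch.params):
                    depol_end = _stability_boundary(err.branch, from_stable=True)
                    if depol_end is None:
                        depol_end = float(err.branch.params[-1])
        x_pol = damped_newton(lambda x: f_at(x, pol["delta_n_k"]),
                              pol["fast_state"], FAST_SCALE, tol=1e-10)
        if x_pol is None or model.fast_voltage(x_pol) > -50.0:
            polar_start = math.inf  # polarized state absent at this G_c
        else:
            try:
                br = continue_fixed_point(rhs, x_pol, pol["delta_n_k"], FAST_SCALE,
                                          (dnk_lo, dnk_hi), step=5.0, max_step=20.0,
                                          param_scale=500.0, direction=-1.0)
                polar_start = _stability_boundary(br, from_stable=True)
                if polar_start is None and len(br.params):
                    polar_start = float(br.params.min())
            except ContinuationError as err:
                if err.branch is not None and len(err.branch.params):
                    polar_start = _stability_boundary(err.branch, from_stable=True)
                    if polar_start is None:
                        polar_start = float(err.branch.params[-1])
        out.append(BranchEnds(g_c=g_c, depol_end=depol_end, polar_start=polar_start))
    return out


def slow_variable_series(traj, events) -> dict[str, float]:
    """Slow variable at the SD transition times versus its cycle extrema.

    Returns ``Delta_N_K`` at depolarization and repolarization together
    with the minimum/maximum over the SD cycle (from shortly before
    depolarization to repolarization).  The identity
    ``Delta_N_K = Delta_N_glia_K + Delta_N_bath_K`` holds pointwise by
    construction.
    """
    if events.t_depol is None or events.t_repol is None:
        raise ValueError("slow-variable analysis requires a detected SD cycle")
    dnk = traj.delta_n_k
    t = traj.t
    i_dep = int(np.searchsorted(t, events.t_depol))
    i_rep = int(np.searchsorted(t, events.t_repol))
    lo = max(0, int(np.searchsorted(t, events.t_depol - 20_000.0)))
    cycle = dnk[lo : i_rep + 1]
    return {
        "dnk_at_depol": float(dnk[i_dep]),
        "dnk_at_repol": float(dnk[i_rep]),
        "dnk_cycle_min": float(cycle.min()),
        "dnk_cycle_max": float(cycle.max()),
        "dnk_glia_at_depol": float(traj.delta_n_glia_k[i_dep]),
        "dnk_glia_at_repol": float(traj.delta_n_glia_k[i_rep]),
    }
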