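"""Time stepping: segregated fixed-point solver, monolithic reference
solver, and full simulation runs.

Each time step solves the coupled force-balance/transport system on the
current mesh by fixed-point iteration (force balance with the previous
iterate's myosin, then one linearized backward-Euler transport solve
anchored at the previous *time step*), checks the sup-norm difference of
consecutive iterates against the tolerance, and only after convergence
moves the boundary: protrusion speed from the converged area and myosin,
boundary actin flow by bilinear extrapolation (ZS) or zero (ZV), front
advance, mesh rebuild, conservative mass transfer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from . import analysis
from .discretization import (MovingDomainMesh, apply_stencils, build_mesh,
                             transfer_mass)
from .force_balance import ForceBalanceOperator
from .front_tracking import (BoundaryCurve, TopologyError, advance_front,
                             aspect_ratio, assemble_boundary_velocity,
                             centroid, enclosed_area, protrusion_rate_zs,
                             protrusion_rate_zv, unit_circle)
from .model_core import DimensionlessParameters, DomainError
from .myosin_transport import total_mass, transport_solve

logger = logging.getLogger("actomotion")


class StagnationError(RuntimeError):
    """Fixed-point iterations hit the cap without converging."""


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings.  dt = c*h, additionally capped so the front
    moves at most half a background cell per step."""

    h: float = 0.16
    c: float = 0.01
    fp_tol: float = 1e-10
    max_iters: int = 35
    t_end: float = 10.0
    snapshot_stride: int = 0
    n_markers: int = 256
    cfl: float = 0.5
    stop_when_steady: bool = False
    steady_margin: float = 2.0   # extra time simulated beyond detection

    def __post_init__(self):
        if not (0.01 <= self.h <= 0.5):
            raise DomainError(f"h={self.h} outside [0.01, 0.5]")
        if self.c <= 0 or self.fp_tol <= 0 or self.max_iters < 1:
            raise DomainError("c, fp_tol must be positive; max_iters >= 1")


@dataclass
class SimulationState:
    t: float
    curve: BoundaryCurve
    mesh: MovingDomainMesh
    m: np.ndarray                 # myosin per group
    u: np.ndarray                 # actin velocity per group, (G, 2)
    fp_iterations: int = 0
    max_boundary_speed: float = 0.0
    dt_hint: float = np.inf       # step-size limit carried from the last step

    @property
    def area(self) -> float:
        return enclosed_area(self.curve)

    @property
    def centroid(self) -> np.ndarray:
        return centroid(self.curve)

    @property
    def total_myosin(self) -> float:
        return total_mass(self.mesh, self.m)

    def diagnostics(self) -> dict:
        return dict(t=self.t, area=self.area,
                    centroid=self.centroid, total_myosin=self.total_myosin,
                    fp_iterations=self.fp_iterations,
                    max_m=float(self.m.max()),
                    aspect_ratio=aspect_ratio(self.curve))


def initial_condition(p: DimensionlessParameters,
                      settings: SolverSettings) -> SimulationState:
    """Unit circle, resting actin, and a linear myosin gradient.

    m(x, 0) = (mu_tot / a) (1 - g x): the uniform stationary profile of the
    ZV model plus a horizontal nudge of steepness g that seeds symmetry
    breaking.  The discrete total is rescaled to mu_tot exactly.
    """
    curve = unit_circle(settings.n_markers)
    mesh = build_mesh(curve, settings.h)
    a = mesh.total_volume
    m = (p.mu_tot / a) * (1.0 - p.g * mesh.group_pt[:, 0])
    m = np.maximum(m, 0.0)
    m *= p.mu_tot / total_mass(mesh, m)
    u = np.zeros((mesh.n_groups, 2))
    return SimulationState(t=0.0, curve=curve, mesh=mesh, m=m, u=u)


# ---------------------------------------------------------------------------

def _fixed_point(state: SimulationState, settings: SolverSettings,
                 p: DimensionlessParameters, dt: float):
    """The segregated fixed-point loop: returns (m, u, iterations used)."""
    mesh = state.mesh
    fb = ForceBalanceOperator(mesh, p)
    m_k = state.m
    m_n, u_n = m_k, state.u
    for n in range(1, settings.max_iters + 1):
        u_next = fb.solve(m_n)
        m_next = transport_solve(mesh, m_k, m_n, u_next, dt, p)
        err_u = float(np.abs(u_next - u_n).max()) if u_n.size else 0.0
        err_m = float(np.abs(m_next - m_n).max())
        m_n, u_n = m_next, u_next
        if err_u < settings.fp_tol and err_m < settings.fp_tol:
            return m_n, u_n, n
    raise StagnationError(
        f"iterations are stagnant: after {settings.max_iters} iterations "
        f"|du|={err_u:.3e}, |dm|={err_m:.3e} (tol {settings.fp_tol:.0e})")


def _boundary_velocity(curve, mesh, m, u, p):
    # the curve was validated when the front advanced; skip the re-check
    from .front_tracking import shoelace_area
    a = shoelace_area(curve.markers)
    if p.variant == "ZV":
        m_b = np.maximum(apply_stencils(m, mesh.mk_sten_idx, mesh.mk_sten_w), 0.0)
        v_p = protrusion_rate_zv(a, m_b, p)
        u_b = None
    else:
        v_p = protrusion_rate_zs(a, p)
        u_b = apply_stencils(u, mesh.mk_sten_idx, mesh.mk_sten_w)
    return assemble_boundary_velocity(curve, v_p, u_b, p.variant)


def _remap_velocity(u_old, mesh_old, mesh_new):
    tree = cKDTree(mesh_old.group_pt)
    _, idx = tree.query(mesh_new.group_pt)
    return u_old[idx]


def _dt_limit(bv, curve: BoundaryCurve, settings: SolverSettings) -> float:
    """Kinematic step-size limits: the front may move at most ``cfl``
    background cells per step, and neighbouring markers may not shear past
    each other (velocity *differences* times dt stay below half a marker
    spacing)."""
    lim = settings.c * settings.h
    vmax = bv.max_speed()
    if vmax > 0:
        lim = min(lim, settings.cfl * settings.h / vmax)
    dv = np.diff(bv.v_f, axis=0, append=bv.v_f[:1])
    dvmax = float(np.hypot(dv[:, 0], dv[:, 1]).max())
    if dvmax > 0:
        lim = min(lim, 0.5 * curve.target_spacing / dvmax)
    return lim


def _advance(state, settings, p, m, u, bv, n_iters, dt, dt_hint):
    curve_new = advance_front(state.curve, bv, dt)
    mesh_new = build_mesh(curve_new, settings.h)
    m_new = transfer_mass(m, state.mesh, mesh_new)
    u_new = _remap_velocity(u, state.mesh, mesh_new)
    return SimulationState(t=state.t + dt, curve=curve_new, mesh=mesh_new,
                           m=m_new, u=u_new, fp_iterations=n_iters,
                           max_boundary_speed=bv.max_speed(), dt_hint=dt_hint)


def segregated_step(state: SimulationState, settings: SolverSettings,
                    p: DimensionlessParameters,
                    dt: float | None = None) -> Tuple[SimulationState, int]:
    """One full time step of the segregated solver.

    If no dt is forced, the nominal dt = c*h is reduced when the boundary
    velocity of the converged solution violates the kinematic limits (the
    inner solve is redone at the smaller dt); a trial front move that would
    self-intersect is likewise rejected and retried with dt halved.
    """
    forced = dt is not None
    if not forced:
        dt = min(settings.c * settings.h, state.dt_hint)
    last_exc = None
    for _attempt in range(10):
        m, u, n = _fixed_point(state, settings, p, dt)
        bv = _boundary_velocity(state.curve, state.mesh, m, u, p)
        lim = _dt_limit(bv, state.curve, settings)
        if not forced and dt > 1.2 * lim:
            dt = lim
            continue
        try:
            return _advance(state, settings, p, m, u, bv, n, dt, lim), n
        except TopologyError as exc:
            if forced:
                raise
            last_exc = exc
            dt *= 0.5
    raise TopologyError(
        f"front advance kept self-intersecting down to dt={dt:.3e}"
    ) from last_exc


# ---------------------------------------------------------------------------
# monolithic reference solver

MONO_TOL = 1e-12
MONO_MAX_ITERS = 500


def _monolithic_system(mesh, p, m_bar, m_k, dt):
    """Fully coupled linear system for (u_x, u_y, m) with the crowding and
    upwind coefficients frozen at the iterate ``m_bar``.

    Unlike the segregated solver, the force-balance/advection coupling is
    solved *simultaneously*: the myosin unknown enters the force-balance
    rows through the contraction term, and the velocity unknowns enter the
    transport rows through the (frozen-myosin) advective fluxes.
    """
    from .model_core import effective_advection_factor, effective_diffusivity

    G = mesh.n_groups
    fb = ForceBalanceOperator(mesh, p)
    H = fb.matrix  # alpha Lap - vol, shared by both components

    gA, gB = mesh.f_gA, mesh.f_gB
    # contraction term beta * oint m n ds, moved to the LHS (acts on m)
    rows_c, cols_c, vals_x, vals_y = [], [], [], []
    coef = p.beta * mesh.f_area
    for (g_of, sgn) in ((gA, 1.0), (gB, -1.0)):
        for g_m in (gA, gB):
            rows_c.append(g_of)
            cols_c.append(g_m)
            vals_x.append(sgn * 0.5 * coef * mesh.f_nrm[:, 0])
            vals_y.append(sgn * 0.5 * coef * mesh.f_nrm[:, 1])
    if p.variant == "ZV":
        sgl = p.beta * mesh.seg_len
        for kk in range(4):
            rows_c.append(mesh.seg_group)
            cols_c.append(mesh.seg_sten_idx[:, kk])
            vals_x.append(sgl * mesh.seg_sten_w[:, kk] * mesh.seg_nrm[:, 0])
            vals_y.append(sgl * mesh.seg_sten_w[:, kk] * mesh.seg_nrm[:, 1])
    rows_c = np.concatenate(rows_c)
    cols_c = np.concatenate(cols_c)
    Bx = sp.csc_matrix((np.concatenate(vals_x), (rows_c, cols_c)), shape=(G, G))
    By = sp.csc_matrix((np.concatenate(vals_y), (rows_c, cols_c)), shape=(G, G))

    # transport rows: (vol/dt + Diff) m + C . u = vol/dt m_k
    mb = np.maximum(m_bar, 0.0)
    d_cell = np.asarray(effective_diffusivity(mb, p.mmax_d))
    fac = np.asarray(effective_advection_factor(mb, p.mmax_u))
    d_face = 0.5 * (d_cell[gA] + d_cell[gB])
    cdiff = d_face * mesh.f_area / mesh.f_dist
    rows_d = np.concatenate([gA, gA, gB, gB, np.arange(G)])
    cols_d = np.concatenate([gB, gA, gA, gB, np.arange(G)])
    vals_d = np.concatenate([-cdiff, cdiff, -cdiff, cdiff, mesh.group_vol / dt])
    T = sp.csc_matrix((vals_d, (rows_d, cols_d)), shape=(G, G))

    return fb, H, Bx, By, T, cdiff, fac


def monolithic_step(state: SimulationState, settings: SolverSettings,
                    p: DimensionlessParameters,
                    dt: float | None = None) -> Tuple[SimulationState, int]:
    """Reference solver: the same one-step nonlinear system solved by a
    fully coupled (3G x 3G) linearization, iterated to residual 1e-12."""
    if dt is None:
        dt = min(settings.c * settings.h, state.dt_hint)
    mesh = state.mesh
    G = mesh.n_groups
    gA, gB = mesh.f_gA, mesh.f_gB
    m_k = state.m
    m_bar = state.m.copy()
    u_bar = state.u.copy()

    for it in range(1, MONO_MAX_ITERS + 1):
        fb, H, Bx, By, T, cdiff, fac = _monolithic_system(mesh, p, m_bar, m_k, dt)
        # upwind concentrations frozen at m_bar, velocity sign from u_bar
        un_bar = 0.5 * np.sum((u_bar[gA] * fac[gA, None]
                               + u_bar[gB] * fac[gB, None]) * mesh.f_nrm, axis=1)
        m_up = np.where(un_bar > 0, m_bar[gA], m_bar[gB])
        # flux = f_area * 0.5*(fac_A u_A + fac_B u_B).n * m_up, linear in u
        cA = 0.5 * mesh.f_area * fac[gA] * m_up
        cB = 0.5 * mesh.f_area * fac[gB] * m_up
        rows = np.concatenate([gA, gA, gB, gB])
        valx = np.concatenate([cA * mesh.f_nrm[:, 0], cB * mesh.f_nrm[:, 0],
                               -cA * mesh.f_nrm[:, 0], -cB * mesh.f_nrm[:, 0]])
        valy = np.concatenate([cA * mesh.f_nrm[:, 1], cB * mesh.f_nrm[:, 1],
                               -cA * mesh.f_nrm[:, 1], -cB * mesh.f_nrm[:, 1]])
        cols = np.concatenate([gA, gB, gA, gB])
        Cx = sp.csc_matrix((valx, (rows, cols)), shape=(G, G))
        Cy = sp.csc_matrix((valy, (rows, cols)), shape=(G, G))

        Z = sp.csc_matrix((G, G))
        A = sp.bmat([[H, Z, Bx],
                     [Z, H, By],
                     [Cx, Cy, T]], format="csc")
        b = np.concatenate([np.zeros(2 * G), mesh.group_vol / dt * m_k])
        z = spla.spsolve(A, b)
        u_new = np.column_stack([z[:G], z[G:2 * G]])
        m_new = z[2 * G:]
        delta = max(float(np.abs(m_new - m_bar).max()),
                    float(np.abs(u_new - u_bar).max()) if u_new.size else 0.0)
        m_bar, u_bar = m_new, u_new
        if delta < MONO_TOL:
            break
    else:
        raise StagnationError("monolithic solver failed to reach residual "
                              f"{MONO_TOL:.0e} in {MONO_MAX_ITERS} iterations")
    bv = _boundary_velocity(state.curve, state.mesh, m_bar, u_bar, p)
    lim = _dt_limit(bv, state.curve, settings)
    return _advance(state, settings, p, m_bar, u_bar, bv, it, dt, lim), it


# ---------------------------------------------------------------------------

def run_simulation(p: DimensionlessParameters, settings: SolverSettings,
                   snapshot_callback=None
                   ) -> Tuple[analysis.TrajectoryRecord, SimulationState]:
    """Run from t=0 to t_end (or until steadiness, if requested).

    The pipeline is deterministic: identical configurations give identical
    trajectories.  Returns the per-step record and the final state.
    """
    state = initial_condition(p, settings)

    def quick_diag(st):
        # centroid + aspect ratio in one pass (no validity re-checks)
        x, y = st.curve.markers[:, 0], st.curve.markers[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a2 = 0.5 * np.sum(cross)
        cen = np.array([np.sum((x + xn) * cross), np.sum((y + yn) * cross)]) / (6 * a2)
        r = np.hypot(x - cen[0], y - cen[1])
        return cen, float(r.max() / r.min())

    cen0, asp0 = quick_diag(state)
    ts = [0.0]
    cents = [cen0]
    areas = [state.mesh.total_volume]
    aspects = [asp0]
    totals = [state.total_myosin]
    iters = [0]
    maxm = [float(state.m.max())]

    step = 0
    check_every = max(1, int(round(0.5 / (settings.c * settings.h))))
    while state.t < settings.t_end - 1e-12:
        state, n = segregated_step(state, settings, p)
        step += 1
        cen, asp = quick_diag(state)
        ts.append(state.t)
        cents.append(cen)
        areas.append(state.mesh.total_volume)
        aspects.append(asp)
        totals.append(state.total_myosin)
        iters.append(n)
        maxm.append(float(state.m.max()))
        if snapshot_callback is not None and settings.snapshot_stride > 0 \
                and step % settings.snapshot_stride == 0:
            snapshot_callback(state)
        if settings.stop_when_steady and step % check_every == 0 \
                and state.t > analysis.STEADY_WINDOW:
            rec = _make_record(ts, cents, areas, aspects, totals, iters, maxm)
            t_st = analysis.detect_steadiness(rec)
            if t_st is not None and \
                    state.t >= t_st + analysis.STEADY_WINDOW + settings.steady_margin:
                logger.info("steady since t=%.3f; stopping at t=%.3f",
                            t_st, state.t)
                break
    record = _make_record(ts, cents, areas, aspects, totals, iters, maxm)
    return record, state


def _make_record(ts, cents, areas, aspects, totals, iters, maxm):
    return analysis.TrajectoryRecord(
        times=np.array(ts), centroid=np.array(cents), area=np.array(areas),
        aspect=np.array(aspects), total_myosin=np.array(totals),
        fp_iters=np.array(iters), max_m=np.array(maxm))
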