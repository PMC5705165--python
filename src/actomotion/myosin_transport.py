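"""Implicit finite-volume transport of myosin on the cut-cell mesh.

One backward-Euler step of the conservative advection-diffusion equation

    dm/dt = div( d_eff grad m - u_eff m )

with crowding-limited coefficients evaluated per control volume from the
previous fixed-point iterate (which keeps the within-step system linear).
Face diffusion uses two-point fluxes between collocation points; advection
is first-order upwind, so together with the implicit diffusion the system
matrix is an M-matrix and myosin stays non-negative for any dt.

The no-flux Rankine-Hugoniot condition on the moving edge is enforced by
construction: boundary segments carry identically zero flux, and the
sweeping of myosin by the moving boundary is realized geometrically by the
conservative mesh-to-mesh mass transfer.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .discretization import MovingDomainMesh, transfer_mass
from .model_core import (DimensionlessParameters, effective_advection_factor,
                         effective_diffusivity)

NEGATIVITY_TOL = 1e-12


class PositivityError(RuntimeError):
    pass


DENSE_LIMIT = 600  # below this many unknowns a dense LAPACK solve is faster


def _transport_entries(mesh: MovingDomainMesh, m_coef: np.ndarray,
                       u: np.ndarray, dt: float, p: DimensionlessParameters):
    """COO entries of one implicit transport step.

    ``m_coef`` is the iterate used to evaluate the crowding coefficients;
    ``u`` is the actin velocity per group.
    """
    G = mesh.n_groups
    gA, gB = mesh.f_gA, mesh.f_gB

    d_cell = np.asarray(effective_diffusivity(np.maximum(m_coef, 0.0), p.mmax_d))
    fac = np.asarray(effective_advection_factor(np.maximum(m_coef, 0.0), p.mmax_u))
    u_eff = u * fac[:, None]

    d_face = 0.5 * (d_cell[gA] + d_cell[gB])
    cdiff = d_face * mesh.f_area / mesh.f_dist
    un = 0.5 * np.sum((u_eff[gA] + u_eff[gB]) * mesh.f_nrm, axis=1)  # A -> B
    flux = mesh.f_area * un
    pos = np.maximum(flux, 0.0)     # leaves A (upwinds on A)
    neg = np.minimum(flux, 0.0)     # enters A (upwinds on B)

    # row A: vol_A/dt m_A - [cdiff (m_B - m_A) - pos m_A - neg m_B] = ...
    rows = np.concatenate([gA, gA, gB, gB, np.arange(G)])
    cols = np.concatenate([gB, gA, gA, gB, np.arange(G)])
    vals = np.concatenate([
        -cdiff + neg,               # A row, B col
        cdiff + pos,                # A row, A col
        -cdiff - pos,               # B row, A col
        cdiff - neg,                # B row, B col
        mesh.group_vol / dt,
    ])
    return rows, cols, vals


def assemble_transport(mesh: MovingDomainMesh, m_coef: np.ndarray,
                       u: np.ndarray, dt: float,
                       p: DimensionlessParameters) -> sp.csc_matrix:
    """Sparse matrix of one implicit transport step."""
    G = mesh.n_groups
    rows, cols, vals = _transport_entries(mesh, m_coef, u, dt, p)
    return sp.csc_matrix((vals, (rows, cols)), shape=(G, G))


def transport_solve(mesh: MovingDomainMesh, m_anchor: np.ndarray,
                    m_coef: np.ndarray, u: np.ndarray, dt: float,
                    p: DimensionlessParameters,
                    source: np.ndarray | None = None) -> np.ndarray:
    """Solve one backward-Euler step on a fixed mesh.

    ``m_anchor`` is the previous *time step* (the anchor of the discrete
    time derivative), ``m_coef`` the previous *fixed-point iterate*.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    G = mesh.n_groups
    b = mesh.group_vol / dt * m_anchor
    if source is not None:
        b = b + mesh.group_vol * source
    rows, cols, vals = _transport_entries(mesh, m_coef, u, dt, p)
    if G <= DENSE_LIMIT:
        A = np.zeros((G, G))
        np.add.at(A, (rows, cols), vals)
        m_new = np.linalg.solve(A, b)
    else:
        A = sp.csc_matrix((vals, (rows, cols)), shape=(G, G))
        m_new = spla.spsolve(A, b)
    if not np.all(np.isfinite(m_new)):
        raise RuntimeError("transport solve produced non-finite values")
    if m_new.min() < -NEGATIVITY_TOL and (source is None):
        raise PositivityError(
            f"myosin went negative: min m = {m_new.min():.3e}")
    return m_new


def transport_step(mesh_prev: MovingDomainMesh,
                   mesh_next: MovingDomainMesh | None,
                   m_prev: np.ndarray, u: np.ndarray, dt: float,
                   p: DimensionlessParameters,
                   source: np.ndarray | None = None) -> np.ndarray:
    """Backward-Euler step followed by conservative transfer to the moved
    mesh (identity when ``mesh_next`` is None or the same mesh)."""
    m_new = transport_solve(mesh_prev, m_prev, m_prev, u, dt, p, source=source)
    if mesh_next is not None and mesh_next is not mesh_prev:
        m_new = transfer_mass(m_new, mesh_prev, mesh_next)
    return m_new


def total_mass(mesh: MovingDomainMesh, m: np.ndarray) -> float:
    return float(np.dot(mesh.group_vol, m))
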