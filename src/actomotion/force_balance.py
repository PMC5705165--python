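"""Elliptic force balance for the actin flow: alpha*Lap(u) + beta*grad(m) - u = 0.

Each velocity component satisfies a Helmholtz-type equation (the viscous
term is the componentwise Laplacian, not a full Stokes stress); the
components couple only through the boundary condition of the ZS variant.
Finite-volume form over a control volume V:

    alpha * oint du/dn ds  +  beta * oint m n ds  -  int u dV  =  0.

ZV: u = 0 on the boundary, imposed through a ghost/penalty flux on each
boundary segment; the myosin boundary term uses extrapolated m.
ZS: the zero-stress condition n.(alpha*grad u + beta*m*I) = 0 makes the
*combined* boundary contribution vanish, so boundary segments simply drop
out of the surface integrals (natural weak imposition).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .discretization import MovingDomainMesh, apply_stencils
from .model_core import DimensionlessParameters

RESIDUAL_TOL = 1e-10


class SolverError(RuntimeError):
    pass


class ForceBalanceOperator:
    """Factorized force-balance operator for one mesh.

    The matrix depends on the mesh and alpha only, so within a time step it
    is factorized once and reused across fixed-point iterations (the myosin
    field enters through the right-hand side, which is linear in m).
    """

    def __init__(self, mesh: MovingDomainMesh, p: DimensionlessParameters):
        self.mesh = mesh
        self.p = p
        G = mesh.n_groups
        a = p.alpha

        cf = a * mesh.f_area / mesh.f_dist
        gA, gB = mesh.f_gA, mesh.f_gB
        rows = np.concatenate([gA, gA, gB, gB])
        cols = np.concatenate([gB, gA, gA, gB])
        vals = np.concatenate([cf, -cf, cf, -cf])
        diag_extra = np.zeros(G)
        if p.variant == "ZV":
            # Dirichlet ghost flux alpha * (0 - u_g) / d_g per segment, with
            # d_g the collocation-to-wall distance along the segment normal
            dv = mesh.seg_mid - mesh.group_pt[mesh.seg_group]
            d = np.maximum(np.sum(dv * mesh.seg_nrm, axis=1), 0.25 * mesh.h)
            np.add.at(diag_extra, mesh.seg_group, -a * mesh.seg_len / d)
        diag = diag_extra - mesh.group_vol
        rows = np.concatenate([rows, np.arange(G)])
        cols = np.concatenate([cols, np.arange(G)])
        vals = np.concatenate([vals, diag])
        self.matrix = sp.csc_matrix((vals, (rows, cols)), shape=(G, G))
        self._solve = spla.factorized(self.matrix)

    def rhs(self, m: np.ndarray) -> np.ndarray:
        """-beta * (oint m n ds) per group, assembled per component."""
        mesh, p = self.mesh, self.p
        G = mesh.n_groups
        b = np.zeros((G, 2))
        m_face = 0.5 * (m[mesh.f_gA] + m[mesh.f_gB])
        contrib = p.beta * (mesh.f_area * m_face)[:, None] * mesh.f_nrm
        np.subtract.at(b, mesh.f_gA, contrib)   # outward normal of A is +n
        np.add.at(b, mesh.f_gB, contrib)        # outward normal of B is -n
        if p.variant == "ZV":
            m_b = np.maximum(
                apply_stencils(m, mesh.seg_sten_idx, mesh.seg_sten_w), 0.0)
            seg = p.beta * (mesh.seg_len * m_b)[:, None] * mesh.seg_nrm
            np.subtract.at(b, mesh.seg_group, seg)
        # ZS: boundary terms cancel against alpha*du/dn by the zero-stress BC
        return b

    def solve(self, m: np.ndarray) -> np.ndarray:
        b = self.rhs(m)
        u = np.column_stack([self._solve(b[:, 0]), self._solve(b[:, 1])])
        res = self.matrix @ u - b
        scale = max(1.0, float(np.abs(b).max()))
        if np.abs(res).max() > RESIDUAL_TOL * scale:
            raise SolverError(
                f"force-balance residual {np.abs(res).max():.3e} exceeds "
                f"{RESIDUAL_TOL:.0e} (scale {scale:.3e})")
        return u


def solve_force_balance(mesh: MovingDomainMesh, m: np.ndarray,
                        p: DimensionlessParameters) -> np.ndarray:
    """One-shot force-balance solve; see ForceBalanceOperator for reuse."""
    return ForceBalanceOperator(mesh, p).solve(np.asarray(m, dtype=float))
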