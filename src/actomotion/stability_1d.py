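"""1D ZV model on a fixed segment and its linear stability analysis.

On x in (0, 1) with clamped actin (u(0) = u(1) = 0), no myosin flux through
the ends, and crowding cutoffs disabled, the model reduces to

    alpha u_xx + beta m_x - u = 0,      m_t = m_xx - (u m)_x.

The uniform state (u = 0, m = mu_tot) destabilizes through long-wavelength
modes.  A perturbation ~ exp(lambda t + i q x) with q in {pi, 2 pi, ...}
grows at

    lambda(q) = q^2 ( beta mu_tot / (1 + alpha q^2) - 1 ),

so the symmetric state is unstable iff beta mu_tot > 1 + pi^2 alpha, and the
fastest-growing admissible mode is q = pi except at extreme contractility.
Because varying beta only rescales beta*m, (beta, mu_tot) -> (beta/c,
c mu_tot) leaves the dynamics of beta*m invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class NonlinearRegimeError(RuntimeError):
    """The perturbation left the linear regime (amplitude blow-up)."""


@dataclass(frozen=True)
class PerturbationMode:
    q: float
    lam: float
    delta_u0: complex = 0.0
    delta_m0: complex = 0.0

    def __post_init__(self):
        k = self.q / math.pi
        if not (k >= 1 and abs(k - round(k)) < 1e-9):
            raise ValueError("admissible wavenumbers are pi, 2 pi, ...")


def dispersion_rate(q: float, alpha: float, beta: float,
                    mu_tot: float) -> float:
    """Growth rate lambda(q) of the uniform 1D ZV state."""
    if q <= 0 or alpha <= 0 or beta * mu_tot < 0:
        raise ValueError("require q > 0, alpha > 0, beta*mu_tot >= 0")
    return q ** 2 * (beta * mu_tot / (1.0 + alpha * q ** 2) - 1.0)


def critical_mu_tot(alpha: float, beta: float) -> float:
    """Contractility threshold: instability iff mu_tot > (1 + pi^2 alpha)/beta."""
    if alpha < 0 or beta <= 0:
        raise ValueError("require alpha >= 0, beta > 0")
    return (1.0 + math.pi ** 2 * alpha) / beta


def fastest_mode(alpha: float, beta: float, mu_tot: float,
                 q_max_index: int = 16) -> float:
    """Admissible wavenumber with the largest growth rate."""
    if mu_tot <= critical_mu_tot(alpha, beta):
        raise ValueError("no growing mode below the critical contractility")
    qs = math.pi * np.arange(1, q_max_index + 1)
    lams = [dispersion_rate(q, alpha, beta, mu_tot) for q in qs]
    return float(qs[int(np.argmax(lams))])


# ---------------------------------------------------------------------------
# nonlinear 1D solver

def _velocity_matrix(alpha: float, n: int, h: float) -> sp.csc_matrix:
    """Cell-centered alpha u'' - u with u = 0 at both walls (linear ghost)."""
    main = np.full(n, -2.0 * alpha / h ** 2 - 1.0)
    main[0] = main[-1] = -3.0 * alpha / h ** 2 - 1.0  # ghost u = -u_first
    off = np.full(n - 1, alpha / h ** 2)
    return sp.diags([off, main, off], [-1, 0, 1], format="csc")


def _solve_velocity(alpha, beta, m, h, solver):
    mx = np.zeros_like(m)
    mx[1:-1] = (m[2:] - m[:-2]) / (2 * h)
    mx[0] = (m[1] - m[0]) / h
    mx[-1] = (m[-1] - m[-2]) / h
    return solver(-beta * mx)


def simulate_1d_zv(alpha: float, beta: float, mu_tot: float,
                   n: int = 200, dt: float = 1e-3, t_end: float = 1.0,
                   perturbation: float = 1e-4, q: float = math.pi,
                   fp_tol: float = 1e-10, max_iters: int = 50):
    """Integrate the 1D ZV model from a cosine-perturbed uniform state.

    Returns (x, m, u, times, amplitude) where ``amplitude`` is the time
    series of the cosine projection of m onto the probed mode,
    A(t) = 2 \\int (m - mean) cos(qx) dx.
    """
    h = 1.0 / n
    x = (np.arange(n) + 0.5) * h
    m = mu_tot * (1.0 + perturbation * np.cos(q * x))
    m *= mu_tot / (m.sum() * h)
    u = np.zeros(n)
    vel_solver = spla.factorized(_velocity_matrix(alpha, n, h))

    times = [0.0]
    amps = [2 * h * float(np.sum((m - m.mean()) * np.cos(q * x)))]
    nsteps = int(round(t_end / dt))
    for _ in range(nsteps):
        m_k = m
        m_n, u_n = m, u
        for _it in range(max_iters):
            u_next = _solve_velocity(alpha, beta, m_n, h, vel_solver)
            m_next = _transport_1d(m_k, m_n, u_next, dt, h, n)
            err = max(np.abs(m_next - m_n).max(), np.abs(u_next - u_n).max())
            m_n, u_n = m_next, u_next
            if err < fp_tol:
                break
        m, u = m_n, u_n
        times.append(times[-1] + dt)
        amp = 2 * h * float(np.sum((m - m.mean()) * np.cos(q * x)))
        amps.append(amp)
        if abs(amp) > 1e6:
            raise NonlinearRegimeError(
                "mode amplitude exceeded 1e6: nonlinear regime")
    return x, m, u, np.array(times), np.array(amps)


def _transport_1d(m_k, m_coef, u, dt, h, n):
    """Backward-Euler FV step: diffusion (two-point) + upwind advection,
    zero-flux walls."""
    uf = 0.5 * (u[:-1] + u[1:])                 # interior face velocities
    pos = np.maximum(uf, 0.0)
    neg = np.minimum(uf, 0.0)
    idx = np.arange(n)
    rows = np.concatenate([idx[:-1], idx[:-1], idx[1:], idx[1:], idx])
    cols = np.concatenate([idx[1:], idx[:-1], idx[:-1], idx[1:], idx])
    cdiff = 1.0 / h
    vals = np.concatenate([
        np.full(n - 1, -cdiff) + neg,
        np.full(n - 1, cdiff) + pos,
        np.full(n - 1, -cdiff) - pos,
        np.full(n - 1, cdiff) - neg,
        np.full(n, h / dt),
    ])
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return spla.spsolve(A, h / dt * m_k)


def fitted_growth_rate(times: np.ndarray, amps: np.ndarray,
                       skip: float = 0.05) -> float:
    """Log-linear fit of the mode amplitude, skipping an initial transient."""
    sel = times >= skip
    a = np.abs(amps[sel])
    if np.any(a <= 0):
        raise ValueError("amplitude crossed zero; cannot fit a rate")
    coef = np.polyfit(times[sel], np.log(a), 1)
    return float(coef[0])
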