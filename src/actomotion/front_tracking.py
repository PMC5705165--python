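"""Marker representation and evolution of the free cell boundary.

The boundary is a closed, counterclockwise polyline of markers.  Each time
step the markers move with the boundary velocity

    v_f = v_p n + u|_boundary,

where ``v_p`` is the normal protrusion speed powered by actin growth and
``u|_boundary`` the actin flow at the edge (zero in the ZV variant), and the
curve is then reparameterized to uniform arclength with a periodic cubic
spline so marker spacing stays tied to the mesh resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import CubicSpline

from .model_core import DimensionlessParameters, DomainError


class GeometryError(ValueError):
    """Degenerate or self-intersecting boundary geometry."""


class TopologyError(GeometryError):
    """The advancing front self-intersected; the simulation cannot continue."""


@dataclass
class BoundaryCurve:
    """Closed counterclockwise marker polygon for the cell edge."""

    markers: np.ndarray              # (N, 2), first point NOT repeated
    target_spacing: float

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float)
        if self.markers.ndim != 2 or self.markers.shape[1] != 2 or len(self.markers) < 4:
            raise GeometryError("markers must be an (N>=4, 2) array")
        seg = np.diff(np.vstack([self.markers, self.markers[:1]]), axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) < 1e-14):
            raise GeometryError("duplicate consecutive markers")

    # -- geometry queries ---------------------------------------------------

    @property
    def closed(self) -> np.ndarray:
        """Markers with the first point repeated at the end."""
        return np.vstack([self.markers, self.markers[:1]])

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.markers)

    def is_simple(self) -> bool:
        return shapely.LinearRing(self.markers).is_simple

    def segment_lengths(self) -> np.ndarray:
        d = np.diff(self.closed, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def perimeter(self) -> float:
        return float(self.segment_lengths().sum())


def unit_circle(n_markers: int = 256, radius: float = 1.0,
                center=(0.0, 0.0)) -> BoundaryCurve:
    """Counterclockwise circle of markers; the standard initial shape."""
    th = 2 * np.pi * np.arange(n_markers) / n_markers
    pts = np.column_stack([center[0] + radius * np.cos(th),
                           center[1] + radius * np.sin(th)])
    return BoundaryCurve(pts, target_spacing=2 * np.pi * radius / n_markers)


def shoelace_area(markers: np.ndarray) -> float:
    """Signed polygon area without validity checks (hot-path helper)."""
    x, y = markers[:, 0], markers[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def enclosed_area(curve: BoundaryCurve) -> float:
    """Shoelace area of the marker polygon (positive for CCW curves)."""
    if not curve.is_simple():
        raise GeometryError("curve is self-intersecting")
    a = shoelace_area(curve.markers)
    if a <= 0:
        raise GeometryError("curve must be counterclockwise (positive area)")
    return a


def centroid(curve: BoundaryCurve) -> np.ndarray:
    """Area-weighted polygon centroid."""
    x, y = curve.markers[:, 0], curve.markers[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6 * a)
    cy = np.sum((y + yn) * cross) / (6 * a)
    return np.array([cx, cy])


def aspect_ratio(curve: BoundaryCurve) -> float:
    """Longest over shortest centroid-to-boundary distance (>= 1)."""
    r = np.hypot(*(curve.markers - centroid(curve)).T)
    return float(r.max() / r.min())


def outward_normals(curve: BoundaryCurve) -> np.ndarray:
    """Per-marker outward unit normals.

    Tangents are central differences over neighbouring markers; for a
    counterclockwise curve the outward normal is the tangent rotated by
    -90 degrees.  Outwardness is verified by probing a point offset along
    the normal (works for non-convex shapes where the centroid test fails).
    """
    pts = curve.markers
    tan = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    ln = np.hypot(tan[:, 0], tan[:, 1])
    if np.any(ln < 1e-14):
        raise GeometryError("degenerate markers: zero-length tangent")
    tan /= ln[:, None]
    normals = np.column_stack([tan[:, 1], -tan[:, 0]])
    # in/out probe on a small sample of markers
    eps = 0.1 * curve.target_spacing
    idx = np.linspace(0, len(pts) - 1, min(8, len(pts)), dtype=int)
    probes = pts[idx] + eps * normals[idx]
    inside = shapely.contains_xy(curve.polygon(), probes[:, 0], probes[:, 1])
    if np.count_nonzero(inside) > len(idx) // 2:
        normals = -normals  # curve was clockwise-oriented locally
    return normals


# -- protrusion laws --------------------------------------------------------

def protrusion_rate_zs(a: float, p: DimensionlessParameters) -> float:
    """ZS protrusion speed, uniform along the boundary.

    v_p = v0 a0/a - k (a - a0 (a0/a)^2).  The (a0/a)^2 term is the
    cytoplasmic resistance that prevents collapse at small v0.
    """
    if a <= 0:
        raise DomainError(f"area must be positive, got {a}")
    return p.v0 * p.a0 / a - p.k * (a - p.a0 * (p.a0 / a) ** 2)


def protrusion_rate_zv(a: float, m_b, p: DimensionlessParameters):
    """ZV protrusion speed per marker; local myosin inhibits actin growth.

    v_p = v0 a0 / (a (1 + m_b)) - k (a - a0).
    """
    if a <= 0:
        raise DomainError(f"area must be positive, got {a}")
    m_b = np.asarray(m_b, dtype=float)
    if np.any(m_b < 0):
        raise DomainError("boundary myosin must be non-negative")
    out = p.v0 * p.a0 / (a * (1.0 + m_b)) - p.k * (a - p.a0)
    return out if out.ndim else float(out)


@dataclass
class BoundaryVelocity:
    """Per-marker decomposition of the boundary velocity v_f = v_p n + u_b."""

    v_p: np.ndarray       # (N,) normal protrusion speed
    u_b: np.ndarray       # (N, 2) actin velocity at the boundary
    normals: np.ndarray   # (N, 2) outward unit normals
    v_f: np.ndarray       # (N, 2) total boundary velocity

    def max_speed(self) -> float:
        return float(np.hypot(self.v_f[:, 0], self.v_f[:, 1]).max())


def assemble_boundary_velocity(curve: BoundaryCurve, v_p, u_b,
                               variant: str) -> BoundaryVelocity:
    """Superpose normal protrusion and boundary actin flow.

    The ZV variant pins the actin network at the edge (u|_boundary = 0): a
    nonzero ``u_b`` there is a contract violation, not data to be ignored.
    """
    n = outward_normals(curve)
    v_p = np.broadcast_to(np.asarray(v_p, dtype=float), (len(curve.markers),)).copy()
    if u_b is None:
        u_b = np.zeros((len(curve.markers), 2))
    u_b = np.asarray(u_b, dtype=float)
    if u_b.shape != (len(curve.markers), 2):
        raise ValueError("u_b must be (N, 2) aligned with markers")
    if variant == "ZV" and np.any(u_b != 0.0):
        raise DomainError("ZV variant requires zero boundary actin velocity")
    v_f = v_p[:, None] * n + u_b
    return BoundaryVelocity(v_p=v_p, u_b=u_b, normals=n, v_f=v_f)


# -- front advance ----------------------------------------------------------

def resample(curve: BoundaryCurve) -> BoundaryCurve:
    """Arclength reparameterization by a periodic cubic spline.

    The marker count is chosen so spacing stays within [0.5, 1.5] of the
    target; on an already equispaced curve the operation reproduces the
    markers to round-off (the spline interpolates them).
    """
    closed = curve.closed
    seg = np.diff(closed, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total = s[-1]
    n_new = max(16, int(round(total / curve.target_spacing)))
    spline = CubicSpline(s, closed, bc_type="periodic")
    s_new = total * np.arange(n_new) / n_new
    pts = spline(s_new)
    return BoundaryCurve(pts, target_spacing=curve.target_spacing)


MAX_TURN_ANGLE = np.radians(45.0)   # fold-suppression trigger


def _suppress_folds(pts: np.ndarray, max_turn: float = MAX_TURN_ANGLE,
                    max_passes: int = 12) -> np.ndarray:
    """Damp marker-scale sawteeth in the polyline.

    Normal-speed protrusion amplifies zigzags at the marker spacing (well
    below the mesh scale) into folds the continuous model does not have.
    Markers whose turning angle exceeds ``max_turn`` — far above anything a
    resolved shape produces — are locally averaged with their neighbours;
    smooth stretches of the curve are never touched, so no cumulative
    diffusion of the resolved shape occurs.
    """
    out = pts
    for _ in range(max_passes):
        d = np.roll(out, -1, axis=0) - out
        ang = np.arctan2(d[:, 1], d[:, 0])
        turn = np.abs((np.roll(ang, -1) - ang + np.pi) % (2 * np.pi) - np.pi)
        bad = turn > max_turn          # turn[i] is the angle at marker i+1
        if not bad.any():
            return out
        mask = np.roll(bad, 1) | bad | np.roll(bad, 2)  # offender +- 1
        sm = 0.25 * np.roll(out, 1, axis=0) + 0.5 * out \
            + 0.25 * np.roll(out, -1, axis=0)
        out = np.where(mask[:, None], sm, out)
    return out


def advance_front(curve: BoundaryCurve, bv: BoundaryVelocity,
                  dt: float) -> BoundaryCurve:
    """Move markers by dt * v_f, suppress marker-scale folds, resample.

    Self-intersection after the move is a hard topology error: the model
    has no splitting/merging rule, so the simulation aborts.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    moved = BoundaryCurve(_suppress_folds(curve.markers + dt * bv.v_f),
                          target_spacing=curve.target_spacing)
    if not moved.is_simple():
        raise TopologyError("front self-intersected during advance")
    new = resample(moved)
    if not new.is_simple():
        raise TopologyError("front self-intersected after resampling")
    return new
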