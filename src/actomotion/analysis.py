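"""Trajectory metrics, steadiness detection, and motility-state
classification.

The simulator produces a per-step record of centroid, area and aspect
ratio.  A run is *steady* from the earliest time after which the centroid
speed and the aspect ratio each stay within a small relative band of their
trailing-window means for a full window (5 time units by default).  Steady
runs are classified as

* ``stationary``  -- trailing speed negligible relative to the fastest
  speed seen and net displacement below a tenth of the cell radius;
* ``rotation``    -- the trailing centroid track is fitted better by a
  circle whose radius is comparable to (<= 1.5x) the cell's linear size
  sqrt(a/pi), following the operational rule used to read the phase
  diagrams;
* ``translation`` -- everything else; near-threshold radii are flagged
  ambiguous because slow turning and straight motion are hard to separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

STEADY_WINDOW = 5.0          # time units
STEADY_REL_TOL = 0.02
SPEED_NOISE_FLOOR = 5e-3     # absolute speed resolution (cell radii per time
                             # unit): centroid creep below this is treated as
                             # rest — it covers marker-resampling jitter and
                             # the exponentially slow settling of stationary
                             # cells, and sits two orders below motile speeds
ROTATION_RADIUS_FACTOR = 1.5  # "comparable to the cell size"
AMBIGUOUS_RADIUS_FACTOR = 3.0
SPEED_SAMPLE_DT = 0.1        # resample interval for speed estimates


class UnresolvedStateError(RuntimeError):
    """The record never reached steadiness; classification refused."""


@dataclass
class TrajectoryRecord:
    """Per-step diagnostics of a simulation run."""

    times: np.ndarray            # (T,)
    centroid: np.ndarray         # (T, 2)
    area: np.ndarray             # (T,)
    aspect: np.ndarray           # (T,)
    total_myosin: np.ndarray     # (T,)
    fp_iters: np.ndarray         # (T,)
    max_m: np.ndarray            # (T,)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        n = len(self.times)
        for name in ("centroid", "area", "aspect", "total_myosin",
                     "fp_iters", "max_m"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times,
            "centroid_x": self.centroid[:, 0],
            "centroid_y": self.centroid[:, 1],
            "area": self.area,
            "aspect_ratio": self.aspect,
            "total_myosin": self.total_myosin,
            "fp_iterations": self.fp_iters,
            "max_m": self.max_m,
        })


@dataclass
class StateLabel:
    state: str                               # stationary | translation | rotation
    time_to_steady: float
    speed: float = 0.0
    aspect_ratio: float = 1.0
    area: float = 0.0
    radius: Optional[float] = None           # rotation only
    angular_velocity: Optional[float] = None  # rotation only
    ambiguous: bool = False


def _resample_track(record: TrajectoryRecord, dt_s: float = SPEED_SAMPLE_DT):
    """Downsample the centroid track to suppress marker-resampling jitter."""
    t = record.times
    if t[-1] - t[0] < 2 * dt_s:
        return t, record.centroid, None
    ts = np.arange(t[0], t[-1] + 1e-12, dt_s)
    cx = np.interp(ts, t, record.centroid[:, 0])
    cy = np.interp(ts, t, record.centroid[:, 1])
    pts = np.column_stack([cx, cy])
    d = np.diff(pts, axis=0)
    speed = np.hypot(d[:, 0], d[:, 1]) / np.diff(ts)
    return ts, pts, speed


def detect_steadiness(record: TrajectoryRecord,
                      window: float = STEADY_WINDOW,
                      rel_tol: float = STEADY_REL_TOL) -> Optional[float]:
    """Earliest time after which speed and aspect ratio hold steady.

    Steadiness is judged on trailing-window *means*: the 5-unit trailing
    means of speed and aspect ratio must sit within ``rel_tol`` of their
    final (end-of-record) values, continuously, from the detected time to
    the end.  Window means rather than pointwise values are compared
    because steadily rotating cells carry a few-percent periodic speed
    wobble as their shape re-discretizes on the fixed background grid; the
    means average it out while still catching genuine reorganisation.  An
    absolute speed floor lets stationary cells (speed -> 0) qualify.  The
    returned time is the start of the earliest window of the final steady
    stretch, or None if the record does not end steady — a transiently
    quiet phase that later destabilizes does not count.
    """
    ts, pts, speed = _resample_track(record)
    if speed is None or ts[-1] - ts[0] < 2 * window:
        return None
    tm = 0.5 * (ts[:-1] + ts[1:])
    aspect = np.interp(tm, record.times, record.aspect)
    v_ref = max(float(speed.max()), 1e-12)
    nwin = max(2, int(round(window / (tm[1] - tm[0]))))
    if len(tm) < nwin + 1:
        return None
    cs = np.concatenate([[0.0], np.cumsum(speed)])
    ca = np.concatenate([[0.0], np.cumsum(aspect)])
    mean_s = (cs[nwin:] - cs[:-nwin]) / nwin    # trailing means
    mean_a = (ca[nwin:] - ca[:-nwin]) / nwin
    stol = rel_tol * mean_s[-1] + max(1e-3 * v_ref, SPEED_NOISE_FLOOR)
    atol = rel_tol * mean_a[-1]
    ok = (np.abs(mean_s - mean_s[-1]) <= stol) & \
         (np.abs(mean_a - mean_a[-1]) <= atol)
    bad = np.nonzero(~ok)[0]
    first = 0 if len(bad) == 0 else int(bad[-1]) + 1
    if first >= len(ok):
        return None
    t0 = float(tm[first])      # start of the earliest steady window
    # the final window alone is trivially consistent with itself; demand
    # that steadiness persists for at least half a window beyond one full
    # window before calling the record steady
    if tm[-1] - t0 < 1.5 * window:
        return None
    return t0


def fit_rotation_circle(points: np.ndarray):
    """Algebraic (Kasa) least-squares circle through a centroid track.

    Returns (center, radius, rms).  If an orthogonal straight-line fit has
    a smaller rms residual the track is treated as straight: center None,
    radius inf, and the line's rms is returned.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 points for a circle fit")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    bb = x ** 2 + y ** 2
    (cx, cy, c), *_ = np.linalg.lstsq(A, bb, rcond=None)
    r2 = c + cx ** 2 + cy ** 2
    if r2 <= 0:
        circle_rms = np.inf
        radius = np.inf
    else:
        radius = float(np.sqrt(r2))
        circle_rms = float(np.sqrt(np.mean(
            (np.hypot(x - cx, y - cy) - radius) ** 2)))
    # orthogonal line fit via PCA
    mu = pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(pts - mu, full_matrices=False)
    line_rms = float(np.sqrt(np.mean(((pts - mu) @ vt[1]) ** 2)))
    if line_rms < circle_rms:
        return None, np.inf, line_rms
    return np.array([cx, cy]), radius, circle_rms


def _trailing(ts, values, t_from):
    sel = ts >= t_from
    return values[sel]


def classify_state(record: TrajectoryRecord,
                   window: float = STEADY_WINDOW,
                   rotation_factor: float = ROTATION_RADIUS_FACTOR) -> StateLabel:
    """Label the asymptotic mechanical state of a steady run."""
    t_steady = detect_steadiness(record, window=window)
    if t_steady is None:
        raise UnresolvedStateError("record never reached steadiness; "
                                   "run longer or refine the criterion")
    ts, pts, speed = _resample_track(record)
    tm = 0.5 * (ts[:-1] + ts[1:])
    t_tail = ts[-1] - window
    v_tail = float(_trailing(tm, speed, t_tail).mean())
    v_ref = max(float(speed.max()), 1e-12)
    tail_pts = pts[ts >= t_tail]
    net_disp = float(np.hypot(*(tail_pts[-1] - tail_pts[0])))
    aspect = float(_trailing(record.times, record.aspect, t_tail).mean())
    area = float(_trailing(record.times, record.area, t_tail).mean())
    size = float(np.sqrt(area / np.pi))

    common = dict(time_to_steady=t_steady, aspect_ratio=aspect, area=area)
    if v_tail < max(1e-2 * v_ref, 2 * SPEED_NOISE_FLOOR) and net_disp < 0.1:
        return StateLabel(state="stationary", speed=v_tail, **common)

    # use a longer trailing arc for the circle fit so large radii resolve
    fit_pts = pts[ts >= ts[-1] - max(2 * window, window)]
    _, radius, _ = fit_rotation_circle(fit_pts)
    if radius <= rotation_factor * size:
        return StateLabel(state="rotation", speed=v_tail, radius=float(radius),
                          angular_velocity=v_tail / float(radius), **common)
    ambiguous = radius <= AMBIGUOUS_RADIUS_FACTOR * size
    return StateLabel(state="translation", speed=v_tail,
                      ambiguous=bool(ambiguous), **common)


@dataclass
class SteadyMetrics:
    speed: float
    angular_velocity: float
    aspect_ratio: float
    area: float
    time_to_steady: float


def steady_metrics(record: TrajectoryRecord,
                   window: float = STEADY_WINDOW) -> SteadyMetrics:
    """Trailing-window means of the steady state's observables."""
    label = classify_state(record, window=window)
    omega = label.angular_velocity if label.state == "rotation" else 0.0
    return SteadyMetrics(speed=label.speed, angular_velocity=float(omega),
                         aspect_ratio=label.aspect_ratio, area=label.area,
                         time_to_steady=label.time_to_steady)


def phase_scan(variant: str, v0_values, mu_tot_values, alphas,
               settings, base_params=None) -> pd.DataFrame:
    """Classify the asymptotic state over a (v0, mu_tot) x alpha grid.

    Returns a tidy table (variant, alpha, v0, mu_tot, state, speed, radius,
    omega, aspect_ratio, area, ambiguous).  Runs that never steady or abort
    are reported with state 'unresolved'.
    """
    from .coupler import run_simulation  # local import avoids a cycle
    from .model_core import DimensionlessParameters

    combos = []
    seen = set()
    for alpha in alphas:
        for v0 in v0_values:
            for mu in mu_tot_values:
                key = (float(alpha), float(v0), float(mu))
                if key not in seen:
                    seen.add(key)
                    combos.append(key)
    rows = []
    for alpha, v0, mu in combos:
        base = base_params or {}
        p = DimensionlessParameters(variant=variant, alpha=alpha, v0=v0,
                                    mu_tot=mu, **base)
        row = dict(variant=variant, alpha=alpha, v0=v0, mu_tot=mu,
                   state="unresolved", speed=np.nan, radius=np.nan,
                   omega=np.nan, aspect_ratio=np.nan, area=np.nan,
                   ambiguous=False)
        try:
            record, _ = run_simulation(p, settings)
            label = classify_state(record)
            row.update(state=label.state, speed=label.speed,
                       radius=label.radius if label.radius is not None else np.nan,
                       omega=(label.angular_velocity
                              if label.angular_velocity is not None else np.nan),
                       aspect_ratio=label.aspect_ratio, area=label.area,
                       ambiguous=label.ambiguous)
        except Exception as exc:  # noqa: BLE001 - scans report, not raise
            row["state"] = f"unresolved ({type(exc).__name__})"
        rows.append(row)
    return pd.DataFrame(rows)


_STATE_MARKERS = {"stationary": ("o", "tab:gray"),
                  "translation": ("^", "tab:blue"),
                  "rotation": ("s", "tab:red")}


def plot_phase_diagram(df: pd.DataFrame, path) -> None:
    """One (v0, mu_tot/pi) panel per alpha, marker-coded by state."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    alphas = sorted(df["alpha"].unique())
    fig, axes = plt.subplots(1, max(len(alphas), 1),
                             figsize=(4 * max(len(alphas), 1), 3.5),
                             squeeze=False)
    for ax, alpha in zip(axes[0], alphas):
        sub = df[df["alpha"] == alpha]
        for state, (mark, color) in _STATE_MARKERS.items():
            sel = sub[sub["state"] == state]
            ax.scatter(sel["v0"], sel["mu_tot"] / np.pi, marker=mark,
                       c=color, label=state, s=60)
        other = sub[~sub["state"].isin(_STATE_MARKERS)]
        if len(other):
            ax.scatter(other["v0"], other["mu_tot"] / np.pi, marker="x",
                       c="k", label="unresolved", s=40)
        ax.set_xlabel("v0")
        ax.set_ylabel(r"$\mu_{tot}/\pi$")
        ax.set_title(rf"$\alpha$ = {alpha}")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
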