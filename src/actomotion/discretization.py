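"""Cut-cell finite-volume mesh of the moving cell on a fixed Cartesian grid.

The lab frame is covered by an implicit global grid with spacing ``h`` and
lines at integer multiples of ``h``; each mesh instance stores a window of
that grid around the current boundary curve.  Background cells are exterior,
interior, or cut by the boundary; cut cells carry exact clipped volume
fractions and face apertures.

The geometry is computed from the marker polygon itself: the polyline is
split at grid lines, apertures follow from the crossing points (walking each
face between crossings, with node in/out parity), and cut-cell areas and
centroids come from Green's theorem over the pieces plus the face portions.
Because areas, apertures and boundary segments all derive from the same
polygon, the discrete divergence theorem holds cell by cell to round-off —
a uniform field exerts exactly zero net contraction force.  Degenerate
crossings (curve through a grid node) are caught by parity/closure checks
and the affected cells fall back to robust polygon clipping.

Unknowns live on *groups*: cut cells with volume fraction below
``MERGE_THRESHOLD`` are merged into their best-covered active neighbour so
implicit solves do not see arbitrarily small control volumes.  Collocation
points are volume-weighted centroids of the clipped cell regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .front_tracking import BoundaryCurve, shoelace_area

logger = logging.getLogger("actomotion")

MERGE_THRESHOLD = 0.3      # volume fraction below which cut cells are merged
ACTIVE_TOL = 1e-12         # fraction below which a cell is exterior
STENCIL_REACH = 3.0        # max distance (in h) for the 2x2 extrapolation block


class MeshError(RuntimeError):
    pass


class ResolutionError(MeshError):
    """Curve too small (or h too large) for the requested resolution."""


class CFLError(MeshError):
    """Boundary moved more than one background cell in a single step."""


@dataclass
class MovingDomainMesh:
    """Cut-cell mesh of one boundary snapshot.  See module docstring."""

    h: float
    i0: int                      # window origin, global cell indices
    j0: int
    nx: int
    ny: int
    frac: np.ndarray             # (nx, ny) clipped volume fraction in [0, 1]
    crossed: np.ndarray          # (nx, ny) bool, boundary passes through cell
    active: np.ndarray           # (nx, ny) bool, frac > ACTIVE_TOL
    interior: np.ndarray         # (nx, ny) bool, active and not crossed
    cell_group: np.ndarray       # (nx, ny) int32 group id, -1 if inactive
    n_groups: int
    group_vol: np.ndarray        # (G,) control-volume measure
    group_pt: np.ndarray         # (G, 2) collocation points
    # internal faces between distinct groups
    f_gA: np.ndarray             # (F,) int32
    f_gB: np.ndarray             # (F,) int32
    f_area: np.ndarray           # (F,) aperture * h ... in 2D: aperture length
    f_nrm: np.ndarray            # (F, 2) unit normal pointing A -> B
    f_dist: np.ndarray           # (F,) collocation distance
    # boundary segments (marker polyline split at grid lines)
    seg_group: np.ndarray        # (S,) int32 owning group
    seg_len: np.ndarray          # (S,)
    seg_mid: np.ndarray          # (S, 2)
    seg_nrm: np.ndarray          # (S, 2) outward unit normal
    seg_sten_idx: np.ndarray     # (S, 4) int32 group ids for bilinear extrapolation
    seg_sten_w: np.ndarray       # (S, 4) weights
    # per-marker extrapolation stencils for the curve the mesh was built on
    mk_sten_idx: np.ndarray      # (N, 4)
    mk_sten_w: np.ndarray        # (N, 4)

    @property
    def total_volume(self) -> float:
        return float(self.group_vol.sum())

    def cell_center(self, ii, jj):
        return np.stack([(self.i0 + np.asarray(ii) + 0.5) * self.h,
                         (self.j0 + np.asarray(jj) + 0.5) * self.h], axis=-1)


# ---------------------------------------------------------------------------
# polyline splitting with crossing bookkeeping

def _split_polyline(closed: np.ndarray, h: float):
    """Split the closed marker polyline at grid lines.

    Returns (pa, pb, cells, crossings): piece endpoints (S, 2), the global
    cell index of each piece (S, 2), and crossing records (axis, line,
    coord) -- a crossing of the vertical line x = line*h at y = coord for
    axis 0, of the horizontal line y = line*h at x = coord for axis 1.
    """
    a, b = closed[:-1], closed[1:]
    ia = np.floor(a / h).astype(np.int64)
    ib = np.floor(b / h).astype(np.int64)
    dcount = np.abs(ia - ib)
    ncross = dcount.sum(axis=1)

    pa_parts, pb_parts, cell_parts = [], [], []
    cross_axis, cross_line, cross_coord = [], [], []

    m0 = ncross == 0
    if np.any(m0):
        pa_parts.append(a[m0])
        pb_parts.append(b[m0])
        cell_parts.append(ia[m0])

    m1 = ncross == 1
    if np.any(m1):
        a1, b1, ia1, ib1 = a[m1], b[m1], ia[m1], ib[m1]
        k = np.arange(len(a1))
        ax = np.where(dcount[m1, 0] == 1, 0, 1)
        line = np.maximum(ia1[k, ax], ib1[k, ax])
        t = (line * h - a1[k, ax]) / (b1[k, ax] - a1[k, ax])
        c = a1 + t[:, None] * (b1 - a1)
        pa_parts.extend([a1, c])
        pb_parts.extend([c, b1])
        cell_parts.extend([ia1, ib1])
        cross_axis.append(ax)
        cross_line.append(line)
        cross_coord.append(c[k, 1 - ax])

    for s in np.nonzero(ncross >= 2)[0]:
        p, q = a[s], b[s]
        events = [0.0, 1.0]
        for axx in range(2):
            lo, hi = sorted((ia[s, axx], ib[s, axx]))
            for line in range(lo + 1, hi + 1):
                denom = q[axx] - p[axx]
                if abs(denom) > 1e-300:
                    t = (line * h - p[axx]) / denom
                    if 0.0 < t < 1.0:
                        events.append(t)
                        pt = p + t * (q - p)
                        cross_axis.append(np.array([axx]))
                        cross_line.append(np.array([line]))
                        cross_coord.append(np.array([pt[1 - axx]]))
        events.sort()
        for t0, t1 in zip(events[:-1], events[1:]):
            if t1 - t0 < 1e-14:
                continue
            p0 = p + t0 * (q - p)
            p1 = p + t1 * (q - p)
            mid = 0.5 * (p0 + p1)
            pa_parts.append(p0[None])
            pb_parts.append(p1[None])
            cell_parts.append(np.floor(mid / h).astype(np.int64)[None])

    pa = np.concatenate(pa_parts, axis=0)
    pb = np.concatenate(pb_parts, axis=0)
    cells = np.concatenate(cell_parts, axis=0)
    if cross_axis:
        crossings = (np.concatenate(cross_axis),
                     np.concatenate(cross_line),
                     np.concatenate(cross_coord))
    else:
        crossings = (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0))
    d = pb - pa
    ln = np.hypot(d[:, 0], d[:, 1])
    keep = ln > 1e-14
    return pa[keep], pb[keep], cells[keep], crossings


def _face_apertures(node_in, crossings, h, i0, j0, nx, ny):
    """Face apertures from curve crossings plus node in/out parity.

    ap_x[i, j]: vertical face at x=(i0+i)h along cell row j (i in 0..nx);
    ap_y[i, j]: horizontal face at y=(j0+j)h along cell column i.
    Returns (ap_x, ap_y, bad): ``bad`` collects window cells adjacent to a
    face whose crossing parity contradicts the node classification
    (degenerate geometry, resolved by polygon clipping).
    """
    cax, cline, ccoord = crossings
    ap_x = np.where(node_in[:, :-1] & node_in[:, 1:], h, 0.0)
    ap_y = np.where(node_in[:-1, :] & node_in[1:, :], h, 0.0)

    per_face: dict[tuple, list] = {}
    for axis, line, coord in zip(cax, cline, ccoord):
        if axis == 0:
            fi = int(line) - i0
            fj = int(np.floor(coord / h)) - j0
            if 0 <= fi <= nx and 0 <= fj < ny:
                per_face.setdefault((0, fi, fj), []).append(float(coord))
        else:
            fj = int(line) - j0
            fi = int(np.floor(coord / h)) - i0
            if 0 <= fi < nx and 0 <= fj <= ny:
                per_face.setdefault((1, fi, fj), []).append(float(coord))

    bad = set()
    for (axis, fi, fj), coords in per_face.items():
        coords.sort()
        if axis == 0:
            lo = (j0 + fj) * h
            st = bool(node_in[fi, fj])
            end_state = bool(node_in[fi, fj + 1])
        else:
            lo = (i0 + fi) * h
            st = bool(node_in[fi, fj])
            end_state = bool(node_in[fi + 1, fj])
        ap = 0.0
        prev = lo
        for cc in coords:
            if st:
                ap += cc - prev
            prev = cc
            st = not st
        if st:
            ap += lo + h - prev
        if st != end_state:
            if axis == 0:
                for ii in (fi - 1, fi):
                    if 0 <= ii < nx:
                        bad.add((ii, fj))
            else:
                for jj in (fj - 1, fj):
                    if 0 <= jj < ny:
                        bad.add((fi, jj))
            continue
        if axis == 0:
            ap_x[fi, fj] = ap
        else:
            ap_y[fi, fj] = ap
    return ap_x, ap_y, bad


# ---------------------------------------------------------------------------
# mesh construction

_NBR4 = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])
_NBR8 = np.array([[1, 0], [-1, 0], [0, 1], [0, -1],
                  [1, 1], [1, -1], [-1, 1], [-1, -1]])


def build_mesh(curve: BoundaryCurve, h: float) -> MovingDomainMesh:
    if not (0.01 <= h <= 0.5):
        raise MeshError(f"h={h} outside the supported range [0.01, 0.5]")
    pts = curve.markers
    ext_x = pts[:, 0].max() - pts[:, 0].min()
    ext_y = pts[:, 1].max() - pts[:, 1].min()
    if min(ext_x, ext_y) < 2 * h:
        raise ResolutionError(
            f"curve extent {min(ext_x, ext_y):.3g} is below 2h={2 * h:.3g}")

    poly = curve.polygon()
    shapely.prepare(poly)
    i0 = int(np.floor(pts[:, 0].min() / h)) - 2
    i1 = int(np.floor(pts[:, 0].max() / h)) + 2
    j0 = int(np.floor(pts[:, 1].min() / h)) - 2
    j1 = int(np.floor(pts[:, 1].max() / h)) + 2
    nx, ny = i1 - i0 + 1, j1 - j0 + 1

    pa, pb, pcell, crossings = _split_polyline(curve.closed, h)
    pii = pcell[:, 0] - i0
    pjj = pcell[:, 1] - j0
    if np.any((pii < 0) | (pii >= nx) | (pjj < 0) | (pjj >= ny)):
        raise MeshError("boundary piece outside the mesh window")
    crossed = np.zeros((nx, ny), dtype=bool)
    crossed[pii, pjj] = True

    # node classification (one vectorized point-in-polygon query)
    gx = (i0 + np.arange(nx + 1)) * h
    gy = (j0 + np.arange(ny + 1)) * h
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    node_in = shapely.contains_xy(poly, GX.ravel(), GY.ravel()).reshape(nx + 1, ny + 1)

    ap_x, ap_y, bad = _face_apertures(node_in, crossings, h, i0, j0, nx, ny)

    # piece length / midpoint / outward normal (CCW curve)
    d = pb - pa
    plen = np.hypot(d[:, 0], d[:, 1])
    pmid = 0.5 * (pa + pb)
    pnrm = np.column_stack([d[:, 1], -d[:, 0]]) / plen[:, None]

    # Green's theorem per crossed cell:
    #   A = oint x n_x ds,  Cx A = oint (x^2/2) n_x ds,  Cy A = oint (y^2/2) n_y ds
    S0 = np.zeros((nx, ny))   # oint n_x ds over the pieces (closure check)
    S1 = np.zeros((nx, ny))
    S2 = np.zeros((nx, ny))
    S3 = np.zeros((nx, ny))
    np.add.at(S0, (pii, pjj), pnrm[:, 0] * plen)
    np.add.at(S1, (pii, pjj), pnrm[:, 0] * plen * 0.5 * (pa[:, 0] + pb[:, 0]))
    np.add.at(S2, (pii, pjj), pnrm[:, 0] * plen
              * (pa[:, 0] ** 2 + pa[:, 0] * pb[:, 0] + pb[:, 0] ** 2) / 6.0)
    np.add.at(S3, (pii, pjj), pnrm[:, 1] * plen
              * (pa[:, 1] ** 2 + pa[:, 1] * pb[:, 1] + pb[:, 1] ** 2) / 6.0)

    cx_cells = (i0 + np.arange(nx) + 0.5) * h
    cy_cells = (j0 + np.arange(ny) + 0.5) * h
    CX, CY = np.meshgrid(cx_cells, cy_cells, indexing="ij")
    frac = np.where(~crossed & node_in[:-1, :-1], 1.0, 0.0)
    cent_x = CX.copy()
    cent_y = CY.copy()

    ci, cj = np.nonzero(crossed)
    xl = (i0 + ci) * h
    xr = xl + h
    yb = (j0 + cj) * h
    yt = yb + h
    apL = ap_x[ci, cj]
    apR = ap_x[ci + 1, cj]
    apB = ap_y[ci, cj]
    apT = ap_y[ci, cj + 1]
    area_c = S1[ci, cj] + xr * apR - xl * apL
    closure = S0[ci, cj] + apR - apL
    bad |= {(int(ii), int(jj)) for ii, jj in
            zip(ci[np.abs(closure) > 1e-9 * h], cj[np.abs(closure) > 1e-9 * h])}
    bad |= {(int(ii), int(jj)) for ii, jj in
            zip(ci[(area_c < -1e-12) | (area_c > h * h * (1 + 1e-9))],
                cj[(area_c < -1e-12) | (area_c > h * h * (1 + 1e-9))])}
    area_c = np.clip(area_c, 0.0, h * h)
    frac[ci, cj] = area_c / h ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        cxa = (S2[ci, cj] + 0.5 * (xr ** 2 * apR - xl ** 2 * apL)) / area_c
        cya = (S3[ci, cj] + 0.5 * (yt ** 2 * apT - yb ** 2 * apB)) / area_c
    okc = area_c > ACTIVE_TOL * h ** 2
    cent_x[ci[okc], cj[okc]] = cxa[okc]
    cent_y[ci[okc], cj[okc]] = cya[okc]

    if bad:  # degenerate geometry: robust polygon clipping for these cells
        logger.debug("mesh build: %d cells fall back to polygon clipping", len(bad))
        for ii, jj in bad:
            x0c, y0c = (i0 + ii) * h, (j0 + jj) * h
            box = shapely.box(x0c, y0c, x0c + h, y0c + h)
            inter = shapely.intersection(box, poly)
            aa = shapely.area(inter)
            frac[ii, jj] = aa / h ** 2
            if aa > 0:
                cpt = shapely.centroid(inter)
                cent_x[ii, jj] = shapely.get_x(cpt)
                cent_y[ii, jj] = shapely.get_y(cpt)
            for axis, fi, fj, xa, ya, xbb, ybb in (
                    (0, ii, jj, x0c, y0c, x0c, y0c + h),
                    (0, ii + 1, jj, x0c + h, y0c, x0c + h, y0c + h),
                    (1, ii, jj, x0c, y0c, x0c + h, y0c),
                    (1, ii, jj + 1, x0c, y0c + h, x0c + h, y0c + h)):
                ls = shapely.LineString([(xa, ya), (xbb, ybb)])
                ln2 = shapely.length(shapely.intersection(ls, poly))
                if axis == 0:
                    ap_x[fi, fj] = ln2
                else:
                    ap_y[fi, fj] = ln2

    active = frac > ACTIVE_TOL
    interior = active & ~crossed

    # reassign boundary pieces sitting in (near-)inactive cells
    inactive_piece = ~active[pii, pjj]
    for s in np.nonzero(inactive_piece)[0]:
        best, bestf = None, 0.0
        for di, dj in _NBR8:
            ii, jj = pii[s] + di, pjj[s] + dj
            if 0 <= ii < nx and 0 <= jj < ny and active[ii, jj] and frac[ii, jj] > bestf:
                best, bestf = (ii, jj), frac[ii, jj]
        if best is None:
            raise MeshError("boundary piece with no active cell nearby")
        pii[s], pjj[s] = best

    # merge small cut cells (union-find on window cells)
    parent = np.arange(nx * ny)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    small_i, small_j = np.nonzero(active & crossed & (frac < MERGE_THRESHOLD))
    order = np.argsort(frac[small_i, small_j], kind="stable")
    for s in order:
        ii, jj = small_i[s], small_j[s]
        best, bestf = None, -1.0
        for di, dj in _NBR4:
            ni, nj = ii + di, jj + dj
            if 0 <= ni < nx and 0 <= nj < ny and active[ni, nj] and frac[ni, nj] > bestf:
                best, bestf = ni * ny + nj, frac[ni, nj]
        if best is not None:
            parent[find(ii * ny + jj)] = find(best)

    cell_group = np.full((nx, ny), -1, dtype=np.int32)
    act_i, act_j = np.nonzero(active)
    roots = np.array([find(ii * ny + jj) for ii, jj in zip(act_i, act_j)])
    uniq, inv = np.unique(roots, return_inverse=True)
    n_groups = len(uniq)
    cell_group[act_i, act_j] = inv.astype(np.int32)

    vol_cell = frac * h ** 2
    group_vol = np.bincount(inv, weights=vol_cell[act_i, act_j], minlength=n_groups)
    gpx = np.bincount(inv, weights=(vol_cell * cent_x)[act_i, act_j], minlength=n_groups)
    gpy = np.bincount(inv, weights=(vol_cell * cent_y)[act_i, act_j], minlength=n_groups)
    group_pt = np.column_stack([gpx, gpy]) / group_vol[:, None]

    # internal faces ------------------------------------------------------
    fgA, fgB, farea, fnrm = [], [], [], []

    def add_faces(axis):
        if axis == 0:
            ok = active[:-1, :] & active[1:, :]
            gA = cell_group[:-1, :]
            gB = cell_group[1:, :]
            ap = ap_x[1:-1, :] if nx > 1 else ap_x[1:0, :]
        else:
            ok = active[:, :-1] & active[:, 1:]
            gA = cell_group[:, :-1]
            gB = cell_group[:, 1:]
            ap = ap_y[:, 1:-1]
        fi, fj = np.nonzero(ok & (gA != gB) & (ap > ACTIVE_TOL * h))
        if len(fi) == 0:
            return
        fgA.append(gA[fi, fj])
        fgB.append(gB[fi, fj])
        farea.append(ap[fi, fj])
        nv = np.zeros((len(fi), 2))
        nv[:, axis] = 1.0
        fnrm.append(nv)

    add_faces(0)
    add_faces(1)
    if fgA:
        f_gA = np.concatenate(fgA).astype(np.int32)
        f_gB = np.concatenate(fgB).astype(np.int32)
        f_area = np.concatenate(farea)
        f_nrm = np.concatenate(fnrm, axis=0)
    else:  # pragma: no cover - single-group degenerate mesh
        f_gA = np.zeros(0, np.int32)
        f_gB = np.zeros(0, np.int32)
        f_area = np.zeros(0)
        f_nrm = np.zeros((0, 2))
    dvec = group_pt[f_gB] - group_pt[f_gA]
    f_dist = np.maximum(np.hypot(dvec[:, 0], dvec[:, 1]), 0.25 * h)

    seg_group = cell_group[pii, pjj].astype(np.int32)

    mesh = MovingDomainMesh(
        h=h, i0=i0, j0=j0, nx=nx, ny=ny, frac=frac, crossed=crossed,
        active=active, interior=interior, cell_group=cell_group,
        n_groups=n_groups, group_vol=group_vol, group_pt=group_pt,
        f_gA=f_gA, f_gB=f_gB, f_area=f_area, f_nrm=f_nrm, f_dist=f_dist,
        seg_group=seg_group, seg_len=plen, seg_mid=pmid, seg_nrm=pnrm,
        seg_sten_idx=None, seg_sten_w=None, mk_sten_idx=None, mk_sten_w=None,
    )
    sten_idx, sten_w = boundary_stencils(
        mesh, np.concatenate([pmid, curve.markers], axis=0))
    mesh.seg_sten_idx = sten_idx[:len(pmid)]
    mesh.seg_sten_w = sten_w[:len(pmid)]
    mesh.mk_sten_idx = sten_idx[len(pmid):]
    mesh.mk_sten_w = sten_w[len(pmid):]

    area = shoelace_area(curve.markers)
    if abs(mesh.total_volume - area) > 1e-6 * max(area, 1.0):
        raise MeshError(
            f"clipped volume {mesh.total_volume:.12g} does not match "
            f"polygon area {area:.12g}")
    return mesh


# ---------------------------------------------------------------------------
# boundary extrapolation

_OFFS = np.stack(np.meshgrid(np.arange(-3, 3), np.arange(-3, 3),
                             indexing="ij"), axis=-1).reshape(-1, 2)


def boundary_stencils(mesh: MovingDomainMesh, points: np.ndarray):
    """Second-order bilinear extrapolation stencils for boundary points.

    For each point, picks the nearest 2x2 block of fully interior cells
    within STENCIL_REACH * h and returns the four group indices plus the
    bilinear weights of the (possibly extrapolating) fit.  Points with no
    complete block nearby fall back to the nearest active cell (weight 1)
    with a logged warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    P = len(points)
    h, i0, j0, nx, ny = mesh.h, mesh.i0, mesh.j0, mesh.nx, mesh.ny

    inter = mesh.interior
    block = np.zeros((nx, ny), dtype=bool)
    block[:-1, :-1] = (inter[:-1, :-1] & inter[1:, :-1]
                       & inter[:-1, 1:] & inter[1:, 1:])

    base_i = np.floor(points[:, 0] / h - 0.5).astype(int) - i0
    base_j = np.floor(points[:, 1] / h - 0.5).astype(int) - j0
    ci = base_i[:, None] + _OFFS[None, :, 0]           # (P, K)
    cj = base_j[:, None] + _OFFS[None, :, 1]
    inb = (ci >= 0) & (ci < nx - 1) & (cj >= 0) & (cj < ny - 1)
    cis = np.clip(ci, 0, nx - 1)
    cjs = np.clip(cj, 0, ny - 1)
    valid = inb & block[cis, cjs]
    # block center = shared node of the 2x2 cells
    bx = (i0 + cis + 1) * h
    by = (j0 + cjs + 1) * h
    d2 = (bx - points[:, 0:1]) ** 2 + (by - points[:, 1:2]) ** 2
    d2[~valid] = np.inf
    best = np.argmin(d2, axis=1)
    bestd = d2[np.arange(P), best]
    ok = bestd <= (STENCIL_REACH * h) ** 2

    idx = np.zeros((P, 4), dtype=np.int32)
    w = np.zeros((P, 4))
    if np.any(ok):
        bi = cis[np.arange(P), best][ok]
        bj = cjs[np.arange(P), best][ok]
        cg = mesh.cell_group
        idx[ok] = np.column_stack([cg[bi, bj], cg[bi + 1, bj],
                                   cg[bi, bj + 1], cg[bi + 1, bj + 1]])
        # bilinear fit through the stencil's *collocation points* (groups
        # that absorbed cut slivers have shifted centroids), evaluated at
        # the boundary point: exact for affine and bilinear fields
        rel = (mesh.group_pt[idx[ok]] - points[ok, None, :]) / h   # (Q,4,2)
        A = np.empty((rel.shape[0], 4, 4))
        A[:, :, 0] = 1.0
        A[:, :, 1] = rel[:, :, 0]
        A[:, :, 2] = rel[:, :, 1]
        A[:, :, 3] = rel[:, :, 0] * rel[:, :, 1]
        rhs = np.zeros((rel.shape[0], 4))
        rhs[:, 0] = 1.0
        try:
            w[ok] = np.linalg.solve(np.swapaxes(A, 1, 2), rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate block
            ws = np.empty((rel.shape[0], 4))
            for q in range(rel.shape[0]):
                ws[q] = np.linalg.lstsq(A[q].T, rhs[q], rcond=None)[0]
            w[ok] = ws
    if np.any(~ok):
        logger.warning("%d boundary points lack an interior 2x2 stencil; "
                       "falling back to nearest cell value", int((~ok).sum()))
        tree = cKDTree(mesh.group_pt)
        _, gg = tree.query(points[~ok])
        idx[~ok, 0] = gg
        w[~ok, 0] = 1.0
    return idx, w


def extrapolate_to_boundary(values: np.ndarray, mesh: MovingDomainMesh,
                            point) -> float:
    """Extrapolate a cell-group field to a single boundary point."""
    idx, w = boundary_stencils(mesh, np.asarray(point, dtype=float)[None, :])
    return float(np.sum(np.asarray(values)[idx[0]] * w[0]))


def apply_stencils(values: np.ndarray, idx: np.ndarray, w: np.ndarray):
    """Evaluate precomputed extrapolation stencils (vectorized)."""
    values = np.asarray(values)
    if values.ndim == 1:
        return np.sum(values[idx] * w, axis=1)
    return np.einsum("pkc,pk->pc", values[idx], w)


# ---------------------------------------------------------------------------
# conservative mass transfer between meshes

def transfer_mass(m_old: np.ndarray, mesh_old: MovingDomainMesh,
                  mesh_new: MovingDomainMesh) -> np.ndarray:
    """Move cell masses from one mesh to the next, conserving the total
    exactly.

    Cells active on both meshes keep their mass (their concentration
    changes with the clipped volume, which realizes the Rankine-Hugoniot
    sweeping of myosin by the moving edge).  Dried cells donate all mass to
    neighbouring wet cells, weighted by the receivers' volume; newly wetted
    cells draw mass from their best-covered previously-wet neighbour at
    that donor's concentration (capped at half the donor's mass so
    positivity is preserved).
    """
    if mesh_old.h != mesh_new.h:
        raise MeshError("meshes must share the background grid")
    h = mesh_new.h
    m_old = np.asarray(m_old, dtype=float)

    di = mesh_old.i0 - mesh_new.i0
    dj = mesh_old.j0 - mesh_new.j0

    conc_old = np.zeros((mesh_old.nx, mesh_old.ny))
    oa = mesh_old.active
    conc_old[oa] = m_old[mesh_old.cell_group[oa]]
    mass_old = conc_old * mesh_old.frac * h ** 2

    mass = np.zeros((mesh_new.nx, mesh_new.ny))
    act_old_on_new = np.zeros((mesh_new.nx, mesh_new.ny), dtype=bool)
    conc_old_on_new = np.zeros((mesh_new.nx, mesh_new.ny))
    oi, oj = np.nonzero(oa)
    ni, nj = oi + di, oj + dj
    inwin = (ni >= 0) & (ni < mesh_new.nx) & (nj >= 0) & (nj < mesh_new.ny)
    if np.any(~inwin) and np.any(mass_old[oi[~inwin], oj[~inwin]] > 0):
        raise CFLError("active old cells fell outside the new mesh window")
    mass[ni[inwin], nj[inwin]] = mass_old[oi[inwin], oj[inwin]]
    act_old_on_new[ni[inwin], nj[inwin]] = True
    conc_old_on_new[ni[inwin], nj[inwin]] = conc_old[oi[inwin], oj[inwin]]

    na = mesh_new.active
    vol_new = mesh_new.frac * h ** 2

    # dried cells: donate everything to adjacent wet cells
    d_i, d_j = np.nonzero(act_old_on_new & ~na)
    for ii, jj in zip(d_i, d_j):
        if mass[ii, jj] == 0.0:
            continue
        nbrs = []
        for ring in (_NBR4, _NBR8[4:]):
            for dii, djj in ring:
                ai, aj = ii + dii, jj + djj
                if 0 <= ai < mesh_new.nx and 0 <= aj < mesh_new.ny and na[ai, aj]:
                    nbrs.append((ai, aj))
            if nbrs:
                break
        if not nbrs:
            raise CFLError("dried cell has no wet neighbour (front moved "
                           "more than one cell per step)")
        wts = np.array([vol_new[ai, aj] for ai, aj in nbrs])
        wts = wts / wts.sum()
        for (ai, aj), wt in zip(nbrs, wts):
            mass[ai, aj] += wt * mass[ii, jj]
        mass[ii, jj] = 0.0

    # newly wetted cells: draw donor-concentration mass from a neighbour
    w_i, w_j = np.nonzero(na & ~act_old_on_new)
    for ii, jj in zip(w_i, w_j):
        best, bestf = None, -1.0
        for ring in (_NBR4, _NBR8[4:]):
            for dii, djj in ring:
                ai, aj = ii + dii, jj + djj
                if (0 <= ai < mesh_new.nx and 0 <= aj < mesh_new.ny
                        and act_old_on_new[ai, aj] and na[ai, aj]):
                    f = conc_old_on_new[ai, aj]
                    if f > bestf:
                        best, bestf = (ai, aj), f
            if best is not None:
                break
        if best is None:
            raise CFLError("newly wetted cell has no previously wet "
                           "neighbour (front moved more than one cell)")
        ai, aj = best
        take = min(conc_old_on_new[ai, aj] * vol_new[ii, jj],
                   0.5 * mass[ai, aj])
        mass[ai, aj] -= take
        mass[ii, jj] += take

    gi, gj = np.nonzero(na)
    g = mesh_new.cell_group[gi, gj]
    gmass = np.bincount(g, weights=mass[gi, gj], minlength=mesh_new.n_groups)
    return gmass / mesh_new.group_vol
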