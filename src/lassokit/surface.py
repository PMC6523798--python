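"""Threading classification by the minimal-surface method.

A spanning surface is stretched on the closed loop: an initial triangle fan
from the loop centroid is midpoint-subdivided towards a target edge length
and then relaxed towards minimal area by monotone per-vertex descent
(boundary vertices stay pinned on the loop).  Tail threading is detected by
counting transversal intersections of tail segments with the relaxed
surface, signed by crossing direction.  The total per-tail piercing count
gives the lasso class: L0 (trivial, no piercings), L_n (one tail, n
piercings, piercing directions merged), or LL_{i,j} (both tails pierce).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from lassokit.generation import LassoConformation, LoopConformation, Polyline3D

__all__ = [
    "SurfaceParams",
    "TriangulatedSurface",
    "PiercingRecord",
    "LassoClassLabel",
    "DegenerateSurfaceError",
    "span_minimal_surface",
    "count_piercings",
    "classify_lasso",
]


class DegenerateSurfaceError(ValueError):
    """Raised when the loop is degenerate (collinear) and spans no surface."""


@dataclass(frozen=True)
class SurfaceParams:
    """Spanning/relaxation settings.

    target_edge_factor : mesh edge target as a multiple of the loop edge
        length; subdivision stops once the longest edge is below it.
    max_triangles : cap on mesh size (overrides the edge target for very
        large loops).
    tol : relative area decrease per sweep below which relaxation stops.
    max_sweeps : relaxation sweep cap per refinement level.
    eps : geometric epsilon (in loop-edge units) for boundary/anchor
        exclusion and degeneracy detection in the piercing test.
    """

    target_edge_factor: float = 1.0
    max_triangles: int = 12000
    tol: float = 1e-4
    max_sweeps: int = 200
    eps: float = 1e-9
    init: str = "earclip"  # "earclip" (tight) or "fan" (centroid cone)


@dataclass
class TriangulatedSurface:
    """Orientable disk mesh whose boundary traces the loop."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (T, 3) int32, consistently oriented
    boundary_loop: np.ndarray  # ordered boundary vertex indices
    edge_length: float  # loop edge length (sets the geometric scale)

    @property
    def area(self) -> float:
        v = self.vertices[self.triangles]
        cr = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return float(0.5 * np.linalg.norm(cr, axis=1).sum())

    def euler_characteristic(self) -> int:
        edges = set()
        for a, b, c in self.triangles:
            for i, j in ((a, b), (b, c), (c, a)):
                edges.add((min(i, j), max(i, j)))
        return self.vertices.shape[0] - len(edges) + self.triangles.shape[0]

    def to_off(self, path) -> None:
        """Write the mesh as an OFF file for external inspection."""
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{self.vertices.shape[0]} {self.triangles.shape[0]} 0\n")
            for x, y, z in self.vertices:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")
            for a, b, c in self.triangles:
                fh.write(f"3 {a} {b} {c}\n")

    def boundary_edge_flags(self) -> np.ndarray:
        """(T, 3) bool; entry e marks local edge (v_e, v_{e+1}) as boundary."""
        tris = self.triangles
        counts: dict = {}
        for a, b, c in tris:
            for i, j in ((a, b), (b, c), (c, a)):
                key = (min(i, j), max(i, j))
                counts[key] = counts.get(key, 0) + 1
        flags = np.zeros(tris.shape, dtype=np.bool_)
        for t, (a, b, c) in enumerate(tris):
            for e, (i, j) in enumerate(((a, b), (b, c), (c, a))):
                if counts[(min(i, j), max(i, j))] == 1:
                    flags[t, e] = True
        return flags


@dataclass
class PiercingRecord:
    """Transversal crossings of one or more tails with the surface."""

    crossings: list  # per tail: (segment, triangle, sign, point) tuples
    totals: list  # per-tail crossing counts
    signed_sums: list  # per-tail signed crossing sums

    @property
    def n_total(self) -> int:
        return int(sum(self.totals))


@dataclass(frozen=True)
class LassoClassLabel:
    label: str
    n_piercings_total: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


# ---------------------------------------------------------------------------
# mesh construction


def _fan_triangulation(loop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = loop.shape[0]
    centroid = loop.mean(axis=0)
    verts = np.vstack([loop, centroid[None, :]])
    tris = np.empty((n, 3), dtype=np.int32)
    tris[:, 0] = np.arange(n)
    tris[:, 1] = (np.arange(n) + 1) % n
    tris[:, 2] = n
    return verts, tris


@njit(cache=False)
def _ear_clip_kernel(pts):
    """Greedy minimal-area ear clipping of a closed 3D polygon.

    Repeatedly removes the boundary vertex whose ear triangle has the
    smallest area, yielding a tight interior-vertex-free triangulation of
    the loop (n - 2 triangles).
    """
    n = pts.shape[0]
    nxt = np.empty(n, np.int64)
    prv = np.empty(n, np.int64)
    alive = np.ones(n, np.bool_)
    for i in range(n):
        nxt[i] = (i + 1) % n
        prv[i] = (i - 1) % n
    area = np.empty(n)

    def ear_area(i):
        a = prv[i]
        c = nxt[i]
        ux = pts[i, 0] - pts[a, 0]
        uy = pts[i, 1] - pts[a, 1]
        uz = pts[i, 2] - pts[a, 2]
        vx = pts[c, 0] - pts[a, 0]
        vy = pts[c, 1] - pts[a, 1]
        vz = pts[c, 2] - pts[a, 2]
        cx = uy * vz - uz * vy
        cy = uz * vx - ux * vz
        cz = ux * vy - uy * vx
        return 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)

    for i in range(n):
        area[i] = ear_area(i)
    tris = np.empty((n - 2, 3), np.int32)
    remaining = n
    k = 0
    while remaining > 3:
        best = -1
        besta = 1e300
        for i in range(n):
            if alive[i] and area[i] < besta:
                besta = area[i]
                best = i
        a = prv[best]
        c = nxt[best]
        tris[k, 0] = a
        tris[k, 1] = best
        tris[k, 2] = c
        k += 1
        alive[best] = False
        nxt[a] = c
        prv[c] = a
        area[a] = ear_area(a)
        area[c] = ear_area(c)
        remaining -= 1
    # final triangle
    start = -1
    for i in range(n):
        if alive[i]:
            start = i
            break
    tris[k, 0] = start
    tris[k, 1] = nxt[start]
    tris[k, 2] = nxt[nxt[start]]
    return tris


def _subdivide(verts: np.ndarray, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint (1-to-4) subdivision; geometry is unchanged."""
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    ekey = np.sort(edges, axis=1)
    uniq, inv = np.unique(ekey, axis=0, return_inverse=True)
    mids = 0.5 * (verts[uniq[:, 0]] + verts[uniq[:, 1]])
    mid_idx = verts.shape[0] + np.arange(uniq.shape[0])
    new_verts = np.vstack([verts, mids])
    t = tris.shape[0]
    m01 = mid_idx[inv[:t]]
    m12 = mid_idx[inv[t : 2 * t]]
    m20 = mid_idx[inv[2 * t :]]
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    new_tris = np.concatenate(
        [
            np.stack([a, m01, m20], axis=1),
            np.stack([m01, b, m12], axis=1),
            np.stack([m20, m12, c], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ]
    ).astype(np.int32)
    return new_verts, new_tris


def _boundary_vertices(tris: np.ndarray) -> np.ndarray:
    """Vertices on edges used by exactly one triangle."""
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    ekey = np.sort(edges, axis=1)
    uniq, counts = np.unique(ekey, axis=0, return_counts=True)
    bnd_edges = uniq[counts == 1]
    nv = int(tris.max()) + 1
    mask = np.zeros(nv, dtype=np.bool_)
    mask[bnd_edges.ravel()] = True
    return mask


def _ordered_boundary(tris: np.ndarray) -> np.ndarray:
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    ekey = np.sort(edges, axis=1)
    uniq, counts = np.unique(ekey, axis=0, return_counts=True)
    bnd = uniq[counts == 1]
    nxt: dict = {}
    for i, j in bnd:
        nxt.setdefault(int(i), []).append(int(j))
        nxt.setdefault(int(j), []).append(int(i))
    start = int(bnd.min())
    order = [start]
    prev = -1
    cur = start
    for _ in range(len(bnd) - 1):
        a, b = nxt[cur]
        cur, prev = (b, cur) if a == prev else (a, cur)
        order.append(cur)
    return np.asarray(order, dtype=np.int64)


@njit(cache=False)
def _total_area(verts, tris):
    s = 0.0
    for t in range(tris.shape[0]):
        a = tris[t, 0]
        b = tris[t, 1]
        c = tris[t, 2]
        e1x = verts[b, 0] - verts[a, 0]
        e1y = verts[b, 1] - verts[a, 1]
        e1z = verts[b, 2] - verts[a, 2]
        e2x = verts[c, 0] - verts[a, 0]
        e2y = verts[c, 1] - verts[a, 1]
        e2z = verts[c, 2] - verts[a, 2]
        cx = e1y * e2z - e1z * e2y
        cy = e1z * e2x - e1x * e2z
        cz = e1x * e2y - e1y * e2x
        s += 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)
    return s


@njit(cache=False)
def _star_area(verts, tris, vt_list, lo, hi, vx, vy, vz, vid):
    s = 0.0
    for k in range(lo, hi):
        t = vt_list[k]
        ia = tris[t, 0]
        ib = tris[t, 1]
        ic = tris[t, 2]
        ax, ay, az = verts[ia, 0], verts[ia, 1], verts[ia, 2]
        bx, by, bz = verts[ib, 0], verts[ib, 1], verts[ib, 2]
        cx_, cy_, cz_ = verts[ic, 0], verts[ic, 1], verts[ic, 2]
        if ia == vid:
            ax, ay, az = vx, vy, vz
        elif ib == vid:
            bx, by, bz = vx, vy, vz
        else:
            cx_, cy_, cz_ = vx, vy, vz
        e1x, e1y, e1z = bx - ax, by - ay, bz - az
        e2x, e2y, e2z = cx_ - ax, cy_ - ay, cz_ - az
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        s += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
    return s


@njit(cache=False)
def _relax_kernel(verts, tris, vt_start, vt_list, interior, tol, max_sweeps):
    """Monotone area descent: per-vertex cotan-average proposals with
    backtracking, accepted only when they lower the vertex-star area."""
    prev = _total_area(verts, tris)
    sweeps = 0
    for sweep in range(max_sweeps):
        for ii in range(interior.shape[0]):
            vid = interior[ii]
            lo = vt_start[vid]
            hi = vt_start[vid + 1]
            # cotan-weighted average of the star neighbours
            numx = 0.0
            numy = 0.0
            numz = 0.0
            den = 0.0
            for k in range(lo, hi):
                t = vt_list[k]
                ia = tris[t, 0]
                ib = tris[t, 1]
                ic = tris[t, 2]
                if ia == vid:
                    p, q = ib, ic
                elif ib == vid:
                    p, q = ic, ia
                else:
                    p, q = ia, ib
                # cot of angle at q weights edge (vid, p); at p weights (vid, q)
                for which in range(2):
                    if which == 0:
                        o, n_ = q, p
                    else:
                        o, n_ = p, q
                    ux = verts[n_, 0] - verts[o, 0]
                    uy = verts[n_, 1] - verts[o, 1]
                    uz = verts[n_, 2] - verts[o, 2]
                    wx = verts[vid, 0] - verts[o, 0]
                    wy = verts[vid, 1] - verts[o, 1]
                    wz = verts[vid, 2] - verts[o, 2]
                    dot = ux * wx + uy * wy + uz * wz
                    cx = uy * wz - uz * wy
                    cy = uz * wx - ux * wz
                    cz = ux * wy - uy * wx
                    cr = np.sqrt(cx * cx + cy * cy + cz * cz)
                    cot = dot / cr if cr > 1e-14 else 1e3
                    if cot < 1e-3:
                        cot = 1e-3
                    numx += cot * verts[n_, 0]
                    numy += cot * verts[n_, 1]
                    numz += cot * verts[n_, 2]
                    den += cot
            if den <= 0.0:
                continue
            px = numx / den
            py = numy / den
            pz = numz / den
            vx0 = verts[vid, 0]
            vy0 = verts[vid, 1]
            vz0 = verts[vid, 2]
            a0 = _star_area(verts, tris, vt_list, lo, hi, vx0, vy0, vz0, vid)
            step = 1.0
            for _try in range(4):
                nx = vx0 + step * (px - vx0)
                ny = vy0 + step * (py - vy0)
                nz = vz0 + step * (pz - vz0)
                a1 = _star_area(verts, tris, vt_list, lo, hi, nx, ny, nz, vid)
                if a1 < a0:
                    verts[vid, 0] = nx
                    verts[vid, 1] = ny
                    verts[vid, 2] = nz
                    break
                step *= 0.5
        cur = _total_area(verts, tris)
        sweeps = sweep + 1
        if prev - cur < tol * max(cur, 1e-300):
            prev = cur
            break
        prev = cur
    return prev, sweeps


def _vertex_triangle_csr(tris: np.ndarray, nv: int) -> tuple[np.ndarray, np.ndarray]:
    flat = tris.ravel()
    order = np.argsort(flat, kind="stable")
    vt_list = (order // 3).astype(np.int64)
    counts = np.bincount(flat, minlength=nv)
    vt_start = np.zeros(nv + 1, dtype=np.int64)
    np.cumsum(counts, out=vt_start[1:])
    return vt_start, vt_list


def span_minimal_surface(
    loop: LoopConformation | np.ndarray, params: SurfaceParams | None = None
) -> TriangulatedSurface:
    """Span a near-minimal triangulated surface on the loop.

    ``loop`` is a LoopConformation or a plain (N, 3) array of closed-loop
    vertices (the closing edge implicit); non-equilateral loops (protein
    backbones closed by a bridge) use their mean edge length as the
    geometric scale.  The initial centroid fan is refined by midpoint
    subdivision until the longest mesh edge is below
    ``target_edge_factor`` loop-edge lengths (or the triangle cap is hit)
    and relaxed at each refinement level; the area is non-increasing
    across relaxation sweeps.
    """
    params = params or SurfaceParams()
    if isinstance(loop, LoopConformation):
        pts = loop.vertices
        edge_length = loop.edge_length
    else:
        pts = np.asarray(loop, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("loop must be an (N, 3) array with N >= 3")
        if not np.all(np.isfinite(pts)):
            raise ValueError("loop coordinates must be finite")
        edge_length = float(
            np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).mean()
        )
        loop = None
    centered = pts - pts.mean(axis=0)
    # collinearity check: second singular value ~ 0
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1.0):
        raise DegenerateSurfaceError("loop is collinear; no surface can be spanned")
    if params.init == "fan":
        verts, tris = _fan_triangulation(pts)
    else:
        verts = pts.copy()
        tris = _ear_clip_kernel(np.ascontiguousarray(pts))
    target = params.target_edge_factor * edge_length

    def max_edge(v, t):
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).max())

    while True:
        bmask = _boundary_vertices(tris)
        interior = np.nonzero(~bmask[: verts.shape[0]])[0].astype(np.int64)
        vt_start, vt_list = _vertex_triangle_csr(tris, verts.shape[0])
        _relax_kernel(
            verts, tris, vt_start, vt_list, interior, params.tol, params.max_sweeps
        )
        if max_edge(verts, tris) <= target or tris.shape[0] * 4 > params.max_triangles:
            break
        verts, tris = _subdivide(verts, tris)
    return TriangulatedSurface(
        vertices=verts,
        triangles=tris,
        boundary_loop=_ordered_boundary(tris),
        edge_length=edge_length,
    )


# ---------------------------------------------------------------------------
# piercing detection


@njit(cache=False)
def _pierce_kernel(verts, tris, tri_bnd, bmin, bmax, tail, anchor, eps, anchor_eps):
    nseg = tail.shape[0] - 1
    ntri = tris.shape[0]
    cap = 64 + 8 * nseg
    seg_out = np.empty(cap, np.int64)
    tri_out = np.empty(cap, np.int64)
    sgn_out = np.empty(cap, np.int64)
    tpar_out = np.empty(cap, np.float64)
    pts_out = np.empty((cap, 3), np.float64)
    nhit = 0
    degen = False
    beps = 1e-12
    for s in range(nseg):
        p0x, p0y, p0z = tail[s, 0], tail[s, 1], tail[s, 2]
        p1x, p1y, p1z = tail[s + 1, 0], tail[s + 1, 1], tail[s + 1, 2]
        dx, dy, dz = p1x - p0x, p1y - p0y, p1z - p0z
        sminx = min(p0x, p1x) - eps
        smaxx = max(p0x, p1x) + eps
        sminy = min(p0y, p1y) - eps
        smaxy = max(p0y, p1y) + eps
        sminz = min(p0z, p1z) - eps
        smaxz = max(p0z, p1z) + eps
        for t in range(ntri):
            if (
                bmin[t, 0] > smaxx
                or bmax[t, 0] < sminx
                or bmin[t, 1] > smaxy
                or bmax[t, 1] < sminy
                or bmin[t, 2] > smaxz
                or bmax[t, 2] < sminz
            ):
                continue
            ia, ib, ic = tris[t, 0], tris[t, 1], tris[t, 2]
            ax, ay, az = verts[ia, 0], verts[ia, 1], verts[ia, 2]
            e1x = verts[ib, 0] - ax
            e1y = verts[ib, 1] - ay
            e1z = verts[ib, 2] - az
            e2x = verts[ic, 0] - ax
            e2y = verts[ic, 1] - ay
            e2z = verts[ic, 2] - az
            hx = dy * e2z - dz * e2y
            hy = dz * e2x - dx * e2z
            hz = dx * e2y - dy * e2x
            det = e1x * hx + e1y * hy + e1z * hz
            if abs(det) < 1e-14:
                continue
            f = 1.0 / det
            svx, svy, svz = p0x - ax, p0y - ay, p0z - az
            u = f * (svx * hx + svy * hy + svz * hz)
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            qx = svy * e1z - svz * e1y
            qy = svz * e1x - svx * e1z
            qz = svx * e1y - svy * e1x
            v = f * (dx * qx + dy * qy + dz * qz)
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            tp = f * (e2x * qx + e2y * qy + e2z * qz)
            if tp < -1e-9 or tp > 1.0 + 1e-9:
                continue
            # flag near-degenerate hits (mesh edge / segment endpoint)
            if (
                u < beps
                or v < beps
                or u + v > 1.0 - beps
                or tp < beps
                or tp > 1.0 - beps
            ):
                degen = True
                continue
            if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0 and u + v <= 1.0):
                continue
            if not (0.0 <= tp < 1.0):
                continue
            ptx = p0x + tp * dx
            pty = p0y + tp * dy
            ptz = p0z + tp * dz
            # anchor exclusion
            da = np.sqrt(
                (ptx - anchor[0]) ** 2 + (pty - anchor[1]) ** 2 + (ptz - anchor[2]) ** 2
            )
            if da < anchor_eps:
                continue
            # boundary-curve exclusion: distance to boundary edges of this tri
            skip = False
            for e in range(3):
                if not tri_bnd[t, e]:
                    continue
                if e == 0:
                    j0, j1 = ia, ib
                elif e == 1:
                    j0, j1 = ib, ic
                else:
                    j0, j1 = ic, ia
                ex = verts[j1, 0] - verts[j0, 0]
                ey = verts[j1, 1] - verts[j0, 1]
                ez = verts[j1, 2] - verts[j0, 2]
                wx = ptx - verts[j0, 0]
                wy = pty - verts[j0, 1]
                wz = ptz - verts[j0, 2]
                ee = ex * ex + ey * ey + ez * ez
                tt = (wx * ex + wy * ey + wz * ez) / ee if ee > 0 else 0.0
                if tt < 0.0:
                    tt = 0.0
                elif tt > 1.0:
                    tt = 1.0
                rx = wx - tt * ex
                ry = wy - tt * ey
                rz = wz - tt * ez
                if np.sqrt(rx * rx + ry * ry + rz * rz) < eps:
                    skip = True
                    break
            if skip:
                continue
            nx = e1y * e2z - e1z * e2y
            ny = e1z * e2x - e1x * e2z
            nz = e1x * e2y - e1y * e2x
            sgn = 1 if (dx * nx + dy * ny + dz * nz) > 0.0 else -1
            if nhit < cap:
                seg_out[nhit] = s
                tri_out[nhit] = t
                sgn_out[nhit] = sgn
                tpar_out[nhit] = s + tp
                pts_out[nhit, 0] = ptx
                pts_out[nhit, 1] = pty
                pts_out[nhit, 2] = ptz
                nhit += 1
            else:
                degen = True
    return seg_out, tri_out, sgn_out, tpar_out, pts_out, nhit, degen


_PERTURB_DIR = np.array([1.0, np.sqrt(2.0), np.sqrt(3.0)])
_PERTURB_DIR = _PERTURB_DIR / np.linalg.norm(_PERTURB_DIR)


def count_piercings(
    surface: TriangulatedSurface,
    tail: Polyline3D,
    anchor_index: int = 0,
    eps: float | None = None,
) -> PiercingRecord:
    """Count signed transversal crossings of one tail with the surface.

    Crossings within ``eps`` of the boundary curve or of the anchor vertex
    are excluded; hits landing exactly on mesh edges are resolved by a
    deterministic tiny perturbation of the tail.
    """
    tail = np.asarray(tail, dtype=np.float64)
    if not np.all(np.isfinite(tail)):
        raise ValueError("tail coordinates must be finite")
    if eps is None:
        eps = 1e-9 * surface.edge_length
    tri_bnd = surface.boundary_edge_flags()
    v = surface.vertices[surface.triangles]
    bmin = v.min(axis=1) - eps
    bmax = v.max(axis=1) + eps
    anchor = surface.vertices[
        surface.boundary_loop[0] if anchor_index is None else anchor_index
    ]
    shift = np.zeros(3)
    for attempt in range(4):
        # the anchor sits on the surface boundary, so a shifted tail can
        # graze the mesh right next to it; widen the anchor exclusion with
        # the perturbation magnitude
        anchor_eps = max(eps, 20.0 * float(np.linalg.norm(shift)))
        res = _pierce_kernel(
            surface.vertices,
            surface.triangles,
            tri_bnd,
            bmin,
            bmax,
            tail + shift,
            anchor,
            eps,
            anchor_eps,
        )
        seg, tri, sgn, tpar, pts, nhit, degen = res
        if not degen:
            break
        shift = (10.0 ** (attempt) * 1e-7 * surface.edge_length) * _PERTURB_DIR
    order = np.argsort(tpar[:nhit], kind="stable")
    crossings = [
        (int(seg[i]), int(tri[i]), int(sgn[i]), pts[i].copy()) for i in order
    ]
    total = len(crossings)
    signed = int(sgn[:nhit].sum())
    return PiercingRecord(crossings=[crossings], totals=[total], signed_sums=[signed])


def classify_lasso(
    lasso: LassoConformation, params: SurfaceParams | None = None
) -> tuple[LassoClassLabel, PiercingRecord]:
    """Assign the lasso class from per-tail piercing totals."""
    params = params or SurfaceParams()
    surface = span_minimal_surface(lasso.loop, params)
    records = [
        count_piercings(surface, tail, anchor_index=a)
        for tail, a in zip(lasso.tails, lasso.anchor_indices)
    ]
    totals = [r.totals[0] for r in records]
    merged = PiercingRecord(
        crossings=[r.crossings[0] for r in records],
        totals=totals,
        signed_sums=[r.signed_sums[0] for r in records],
    )
    n_total = int(sum(totals))
    if n_total == 0:
        label = "L0"
    elif len(totals) >= 2 and all(t > 0 for t in totals):
        label = f"LL{totals[0]},{totals[1]}"
    else:
        label = f"L{n_total}"
    return LassoClassLabel(label=label, n_piercings_total=n_total), merged
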