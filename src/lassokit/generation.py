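"""Phantom lasso generation.

Phantom chains carry no excluded volume or interactions; segments may pass
through each other freely.  Loops are closed equilateral polygons sampled
from the uniform measure on polygon space via the diagonal/dihedral
(action-angle) construction: for a ``k``-gon the lengths of the fan
diagonals from vertex 0 form a sequence ``d_1..d_{k-3}`` whose consecutive
differences are uniform on [-1, 1]; valid sequences (those satisfying the
triangle inequalities of the fan triangles) together with ``k-3`` uniform
dihedral angles about the diagonals parametrize polygon space with the
uniform measure.  Invalid difference sequences are rejected and resampled.
Tails are equilateral random walks (isotropic unit steps) anchored at loop
vertex 0, which plays the role of the bridge.

All phantom chains use unit edge length; the analysis is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from numba import njit

__all__ = [
    "Polyline3D",
    "LoopConformation",
    "LassoConformation",
    "EnsembleSpec",
    "sample_equilateral_polygon",
    "sample_random_walk_tail",
    "build_lasso",
    "generate_ensemble",
    "child_seed",
]

Polyline3D = np.ndarray  # (n, 3) float array of ordered vertices


def _check_polyline(vertices: np.ndarray) -> np.ndarray:
    vertices = np.asarray(vertices, dtype=np.float64)
    if vertices.ndim != 2 or vertices.shape[1] != 3 or vertices.shape[0] < 1:
        raise ValueError("polyline must be an (n, 3) array with n >= 1")
    if not np.all(np.isfinite(vertices)):
        raise ValueError("polyline coordinates must be finite")
    return vertices


@dataclass(frozen=True)
class LoopConformation:
    """A closed equilateral loop.

    ``vertices`` stores the N distinct vertices; the closing edge
    (vertices[-1] -> vertices[0]) is implicit.
    """

    vertices: np.ndarray
    edge_length: float = 1.0

    def __post_init__(self) -> None:
        v = _check_polyline(self.vertices)
        object.__setattr__(self, "vertices", v)
        if self.n_edges < 3:
            raise ValueError("a loop needs at least 3 edges")
        edges = np.roll(v, -1, axis=0) - v
        lengths = np.linalg.norm(edges, axis=1)
        if not np.allclose(lengths, self.edge_length, atol=1e-9, rtol=0.0):
            raise ValueError("loop is not equilateral to 1e-9")

    @property
    def n_edges(self) -> int:
        return self.vertices.shape[0]


@dataclass(frozen=True)
class LassoConformation:
    """A loop plus 0-2 open tails anchored at loop vertices (the bridge)."""

    loop: LoopConformation
    tails: tuple = ()
    anchor_indices: tuple = ()

    def __post_init__(self) -> None:
        tails = tuple(_check_polyline(t) for t in self.tails)
        object.__setattr__(self, "tails", tails)
        if len(tails) > 2:
            raise ValueError("at most 2 tails")
        anchors = tuple(int(a) for a in self.anchor_indices)
        if len(anchors) != len(tails):
            raise ValueError("one anchor index per tail")
        object.__setattr__(self, "anchor_indices", anchors)
        for tail, a in zip(tails, anchors):
            if not np.allclose(tail[0], self.loop.vertices[a], atol=1e-9):
                raise ValueError("tail must start at its anchor loop vertex")


@dataclass(frozen=True)
class EnsembleSpec:
    """Grid specification for a phantom-lasso ensemble."""

    loop_lengths: Sequence[int]
    tail_lengths: Sequence[int]
    samples_per_cell: int
    master_seed: int
    n_tails: int = 1

    def __post_init__(self) -> None:
        if self.samples_per_cell < 1:
            raise ValueError("samples_per_cell must be >= 1")
        if any(n < 3 for n in self.loop_lengths):
            raise ValueError("loop lengths must be >= 3")
        if any(t < 0 for t in self.tail_lengths):
            raise ValueError("tail lengths must be >= 0")
        if self.n_tails not in (0, 1, 2):
            raise ValueError("n_tails must be 0, 1 or 2")


@njit(cache=False)
def _polygon_kernel(k: int, seed: int) -> np.ndarray:
    """Rejection-sample fan diagonals + dihedrals and rebuild the polygon."""
    np.random.seed(seed)
    diag = np.empty(k - 1)  # diag[j] = |v_{j+1} - v_0|, j = 0..k-2
    diag[0] = 1.0
    diag[k - 2] = 1.0
    # rejection loop over difference sequences (early exit on violation)
    while True:
        ok = True
        prev = 1.0
        for i in range(k - 3):
            d = prev + (2.0 * np.random.random() - 1.0)
            if d <= 0.0 or d + prev < 1.0:
                ok = False
                break
            diag[i + 1] = d
            prev = d
        if ok and prev <= 2.0:
            break

    verts = np.zeros((k, 3))
    verts[1, 0] = 1.0
    # previous-plane normal reference: start with the xy-plane
    e2 = np.zeros(3)
    e2[2] = 1.0  # normal to current triangle plane (axis x e1 convention)
    for j in range(1, k - 1):
        r = diag[j - 1]
        s = diag[j]
        u = verts[j] / r
        # component of the new vertex along the diagonal and off it
        a = (r * r + s * s - 1.0) / (2.0 * r)
        b2 = s * s - a * a
        b = np.sqrt(b2) if b2 > 0.0 else 0.0
        # orthonormal frame (u, f1, f2); f1 lies in the previous triangle plane
        f1 = np.cross(e2, u)
        nf = np.sqrt(f1[0] ** 2 + f1[1] ** 2 + f1[2] ** 2)
        if nf < 1e-14:
            # degenerate reference (collinear); pick any perpendicular
            tmp = np.zeros(3)
            if abs(u[0]) < 0.9:
                tmp[0] = 1.0
            else:
                tmp[1] = 1.0
            f1 = np.cross(tmp, u)
            nf = np.sqrt(f1[0] ** 2 + f1[1] ** 2 + f1[2] ** 2)
        f1 /= nf
        f2 = np.cross(u, f1)
        if j == 1:
            phi = 0.0
        else:
            phi = 2.0 * np.pi * np.random.random()
        w = a * u + b * (np.cos(phi) * f1 + np.sin(phi) * f2)
        verts[j + 1] = w
        # normal of the triangle (v0, v_j, v_{j+1}) for the next dihedral
        n = np.cross(verts[j], verts[j + 1])
        nn = np.sqrt(n[0] ** 2 + n[1] ** 2 + n[2] ** 2)
        if nn > 1e-14:
            e2 = n / nn
    return verts


def sample_equilateral_polygon(k: int, rng: np.random.Generator) -> LoopConformation:
    """Sample a closed equilateral ``k``-gon with unit edges, uniformly.

    Parameters
    ----------
    k : int
        Number of edges (>= 3).
    rng : numpy.random.Generator
        Seeded random stream.

    Returns
    -------
    LoopConformation
    """
    if k < 3:
        raise ValueError("polygon needs k >= 3 edges")
    if k == 3:
        # rigid up to motion: the unit equilateral triangle
        verts = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3.0) / 2.0, 0.0]]
        )
        return LoopConformation(verts)
    seed = int(rng.integers(0, 2**31 - 1))
    verts = _polygon_kernel(k, seed)
    # close the tiny numerical drift of the final vertex onto the unit sphere
    return LoopConformation(verts)


def sample_random_walk_tail(
    t: int, origin: np.ndarray, rng: np.random.Generator
) -> Polyline3D:
    """Equilateral random walk of ``t`` unit steps starting at ``origin``."""
    if t < 0:
        raise ValueError("tail length must be >= 0")
    origin = np.asarray(origin, dtype=np.float64)
    if t == 0:
        return origin.reshape(1, 3).copy()
    steps = rng.normal(size=(t, 3))
    steps /= np.linalg.norm(steps, axis=1)[:, None]
    pts = np.empty((t + 1, 3))
    pts[0] = origin
    pts[1:] = origin + np.cumsum(steps, axis=0)
    return pts


def build_lasso(
    loop: LoopConformation,
    tail_lengths: Sequence[int],
    rng: np.random.Generator,
) -> LassoConformation:
    """Attach random-walk tails at the bridge (loop vertex 0).

    The loop is translated so its first vertex sits at the origin; all
    tails start there, mirroring a bridge that joins both termini at one
    point.
    """
    if len(tail_lengths) > 2:
        raise ValueError("at most 2 tails")
    verts = loop.vertices - loop.vertices[0]
    loop0 = LoopConformation(verts, loop.edge_length)
    origin = np.zeros(3)
    tails = tuple(sample_random_walk_tail(t, origin, rng) for t in tail_lengths)
    anchors = tuple(0 for _ in tails)
    return LassoConformation(loop0, tails, anchors)


def child_seed(master_seed: int, n: int, t: int, index: int) -> int:
    """Deterministic per-sample seed from (master_seed, N, t, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(n), int(t), int(index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_ensemble(
    spec: EnsembleSpec,
) -> Iterator[tuple[tuple[int, int, int], LassoConformation]]:
    """Stream ``((N, t, index), lasso)`` over the grid, reproducibly.

    Each (N, t, index) triple maps to a unique child seed derived from the
    master seed so that any cell (or any single sample) can be regenerated
    independently.
    """
    for n in spec.loop_lengths:
        for t in spec.tail_lengths:
            for i in range(spec.samples_per_cell):
                rng = np.random.default_rng(child_seed(spec.master_seed, n, t, i))
                loop = sample_equilateral_polygon(n, rng)
                lasso = build_lasso(loop, [t] * spec.n_tails, rng)
                yield (n, t, i), lasso
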