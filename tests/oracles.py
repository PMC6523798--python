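"""Independent reference implementations used only by the test suite.

Each oracle is deliberately written as straight-line brute force code,
sharing nothing with the package's implementation paths.
"""

from __future__ import annotations

import numpy as np


def polygon_acceptance_rate_bruteforce(k: int, n_trials: int, rng) -> float:
    """Fraction of uniformly drawn diagonal-difference tuples that satisfy
    the fan triangle inequalities of a unit equilateral k-gon."""
    ok = 0
    for _ in range(n_trials):
        u = rng.uniform(-1.0, 1.0, size=k - 3)
        d = 1.0 + np.cumsum(u)
        prev = np.concatenate([[1.0], d[:-1]])
        valid = np.all(d > 0.0) and np.all(d + prev >= 1.0) and d[-1] <= 2.0
        ok += bool(valid)
    return ok / n_trials


def fold_polygon_sampler(n: int, n_samples: int, rng, burn: int = 2000, thin: int = 20):
    """Equilateral polygons via the crankshaft/'polygonal fold' Markov chain.

    Starts from a planar regular n-gon; each move rotates a random arc
    about the chord through its endpoints by a uniform angle.  Folds
    preserve closure and edge lengths and have uniform stationary
    distribution on polygon space; mixing is ensured by burn-in/thinning.
    """
    theta = 2 * np.pi * np.arange(n) / n
    r = 0.5 / np.sin(np.pi / n)
    poly = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n)], axis=1)
    out = []
    steps = burn + n_samples * thin
    for step in range(steps):
        i = rng.integers(0, n)
        m = rng.integers(2, n - 1)
        j = (i + m) % n
        axis = poly[j] - poly[i]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        axis = axis / norm
        ang = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(ang), np.sin(ang)
        idx = [(i + kk) % n for kk in range(1, m)]
        p = poly[idx] - poly[i]
        rot = (
            p * c
            + np.cross(axis, p) * s
            + np.outer(p @ axis, axis) * (1 - c)
        )
        poly[idx] = poly[i] + rot
        if step >= burn and (step - burn) % thin == 0:
            out.append(poly.copy())
    return out


def rg_bruteforce(coords: np.ndarray) -> float:
    """Radius of gyration via the explicit double loop over beads."""
    n = len(coords)
    cm = np.zeros(3)
    for p in coords:
        cm += p
    cm /= n
    s = 0.0
    for p in coords:
        d = p - cm
        s += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
    return np.sqrt(s / n)


def gyration_eigenvalues_charpoly(coords: np.ndarray) -> np.ndarray:
    """Gyration-tensor eigenvalues as roots of the characteristic cubic."""
    c = coords - coords.mean(axis=0)
    g = c.T @ c / len(coords)
    # coefficients of det(G - x I) = -x^3 + tr x^2 - m2 x + det
    tr = np.trace(g)
    m2 = (
        g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
        + g[0, 0] * g[2, 2] - g[0, 2] * g[2, 0]
        + g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1]
    )
    det = np.linalg.det(g)
    roots = np.roots([-1.0, tr, -m2, det])
    return np.sort(roots.real)[::-1]


def triangle_boltzmann_bond_pdf(r_grid, k_bond, r0, beta, n_quad=200):
    """Marginal bond-length density of a 3-bead harmonic ring.

    The joint density of the three side lengths of a triangle of free
    points is proportional to r1*r2*r3 exp(-beta*E) on the triangle-
    inequality domain; the marginal over one side is obtained by 2D
    quadrature over the other two.
    """
    lo, hi = max(r0 - 6 * np.sqrt(1 / (beta * k_bond)), 1e-4), r0 + 6 * np.sqrt(
        1 / (beta * k_bond)
    )
    grid = np.linspace(lo, hi, n_quad)
    dg = grid[1] - grid[0]
    pdf = np.zeros_like(r_grid)
    for a, r1 in enumerate(r_grid):
        tot = 0.0
        for r2 in grid:
            for r3 in grid:
                if r3 > r1 + r2 or r3 < abs(r1 - r2):
                    continue
                e = 0.5 * k_bond * ((r1 - r0) ** 2 + (r2 - r0) ** 2 + (r3 - r0) ** 2)
                tot += r1 * r2 * r3 * np.exp(-beta * e)
        pdf[a] = tot * dg * dg
    pdf /= np.trapezoid(pdf, r_grid)
    return pdf


def winding_number_ray_crossings(coords: np.ndarray) -> int:
    """Winding of the xy projection around the origin, counted as signed
    crossings of the positive x axis."""
    w = 0
    n = len(coords)
    for i in range(n):
        x0, y0 = coords[i][0], coords[i][1]
        x1, y1 = coords[(i + 1) % n][0], coords[(i + 1) % n][1]
        if y0 < 0 <= y1 or y1 < 0 <= y0:
            # x coordinate where the edge crosses y = 0
            t = -y0 / (y1 - y0)
            xc = x0 + t * (x1 - x0)
            if xc > 0:
                w += 1 if y1 > y0 else -1
    return w
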