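"""Size and shape descriptors of polymer loops and their scaling laws.

Descriptors per conformation:

* radius of gyration  Rg = sqrt( (1/N) sum_i |r_i - r_cm|^2 )
* distension          D  = (2 Rg / r0) sin(pi / N), which is 1 for a flat
  regular N-gon with all bonds at the equilibrium length r0
* gyration-ellipsoid semi-axes a >= b >= c: square roots of the gyration
  tensor eigenvalues (principal radii of gyration)
* asphericity         A  = [(a-b)^2 + (b-c)^2 + (c-a)^2] / [2 (a+b+c)^2]
  (0 sphere, 0.25 flat disk, 1 stick)
* prolateness         P  = (2a-b-c)(2b-c-a)(2c-a-b) /
                           [2 (a^2+b^2+c^2-ab-bc-ca)^{3/2}]
  in [-1, 1]; -1 degenerate oblate, +1 degenerate prolate; undefined for a
  sphere.

Scaling laws fitted against loop length N (loops of >= 30 beads by
default, where the rigid small-loop regime is excluded):

* <Rg> = c_r + a_r N^nu           (nu free, or frozen at 0.59)
* <A>  = A_inf + a_A N^mu
* <P>  = P_inf + a_P N^(-0.47)    (exponent frozen; linear fit)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ShapeRecord",
    "ScalingFit",
    "FitFailureError",
    "UndefinedProlatenessError",
    "radius_of_gyration",
    "distension",
    "ellipsoid_semi_axes",
    "asphericity",
    "prolateness",
    "shape_record",
    "fit_rg_scaling",
    "fit_asphericity_scaling",
    "fit_prolateness_scaling",
]


class FitFailureError(RuntimeError):
    """Raised when a scaling fit does not converge from any start."""


class UndefinedProlatenessError(ValueError):
    """Prolateness is undefined for a perfect sphere (a = b = c)."""


@dataclass(frozen=True)
class ShapeRecord:
    rg: float
    distension: float
    semi_axes: tuple  # (a, b, c), a >= b >= c
    asphericity: float
    prolateness: float | None  # None when undefined (sphere)


@dataclass(frozen=True)
class ScalingFit:
    law: str  # "rg" | "asphericity" | "prolateness"
    params: dict
    covariance: np.ndarray
    n_range: tuple


def radius_of_gyration(coords: np.ndarray) -> float:
    """Centroid-centred root-mean-square bead distance."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


def distension(coords: np.ndarray, n: int | None = None, r0: float = 1.0) -> float:
    """Rg normalised by the Rg of a flat regular N-gon with bond length r0.

    A regular N-gon with circumradius R has Rg = R and bond length
    2 R sin(pi/N), so D = (2 Rg / r0) sin(pi/N) equals 1 when every bond
    is exactly at r0.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if n is None:
        n = coords.shape[0]
    if n < 3:
        raise ValueError("a loop needs at least 3 beads")
    rg = 0.0 if coords.shape[0] < 2 else radius_of_gyration(coords)
    if np.allclose(coords, coords[0]):
        return 0.0
    return float(2.0 * rg / r0 * np.sin(np.pi / n))


def ellipsoid_semi_axes(coords: np.ndarray) -> tuple[float, float, float]:
    """Principal radii of gyration a >= b >= c.

    Square roots of the eigenvalues of the centroid-centred second-moment
    (gyration) tensor; degenerate configurations yield zero axes.
    """
    coords = np.asarray(coords, dtype=np.float64)
    c = coords - coords.mean(axis=0)
    gyr = c.T @ c / coords.shape[0]
    ev = np.linalg.eigvalsh(gyr)
    ev = np.clip(ev, 0.0, None)
    a, b, cc = np.sqrt(ev[::-1])
    return float(a), float(b), float(cc)


def asphericity(a: float, b: float, c: float) -> float:
    if not (a >= b >= c >= 0):
        raise ValueError("semi-axes must satisfy a >= b >= c >= 0")
    s = a + b + c
    if s == 0:
        raise ValueError("all-zero semi-axes")
    return float(((a - b) ** 2 + (b - c) ** 2 + (c - a) ** 2) / (2.0 * s * s))


def prolateness(a: float, b: float, c: float) -> float:
    if not (a >= b >= c >= 0):
        raise ValueError("semi-axes must satisfy a >= b >= c >= 0")
    q = a * a + b * b + c * c - a * b - b * c - c * a
    if q <= 0:
        raise UndefinedProlatenessError("prolateness undefined for a sphere")
    num = (2 * a - b - c) * (2 * b - c - a) * (2 * c - a - b)
    # clip round-off at the degenerate prolate/oblate limits
    return float(np.clip(num / (2.0 * q**1.5), -1.0, 1.0))


def shape_record(coords: np.ndarray, r0: float = 1.0) -> ShapeRecord:
    """All descriptors for one loop conformation."""
    rg = radius_of_gyration(coords)
    d = distension(coords, r0=r0)
    axes = ellipsoid_semi_axes(coords)
    a = asphericity(*axes)
    try:
        p = prolateness(*axes)
    except UndefinedProlatenessError:
        p = None
    return ShapeRecord(rg=rg, distension=d, semi_axes=axes, asphericity=a, prolateness=p)


# ---------------------------------------------------------------------------
# scaling fits


def _weights(se: np.ndarray | None, n: int) -> np.ndarray | None:
    if se is None:
        return None
    se = np.asarray(se, dtype=np.float64)
    floor = se[se > 0].min() * 1e-3 if np.any(se > 0) else 1.0
    return np.maximum(se, floor)


def _select(n_values, means, se, min_n):
    n_values = np.asarray(n_values, dtype=np.float64)
    means = np.asarray(means, dtype=np.float64)
    mask = n_values >= min_n
    se_sel = None if se is None else np.asarray(se, dtype=np.float64)[mask]
    return n_values[mask], means[mask], se_sel


def fit_rg_scaling(
    n_values: Sequence[float],
    means: Sequence[float],
    se: Sequence[float] | None = None,
    mode: str = "free",
    nu_fixed: float = 0.59,
    min_n: int = 30,
) -> ScalingFit:
    """Fit <Rg> = c_r + a_r N^nu (nu free, or frozen at ``nu_fixed``)."""
    n, y, w = _select(n_values, means, se, min_n)
    if n.size < (3 if mode == "free" else 2):
        raise FitFailureError("too few points above the minimum loop size")
    sigma = _weights(w, n.size)
    try:
        if mode == "free":
            def f(x, c, a, nu):
                return c + a * x**nu

            p0 = [0.0, y[-1] / n[-1] ** 0.6, 0.6]
            popt, pcov = curve_fit(
                f, n, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
                maxfev=20000,
            )
            params = {"c_r": popt[0], "a_r": popt[1], "nu": popt[2]}
        else:
            def f(x, c, a):
                return c + a * x**nu_fixed

            p0 = [0.0, y[-1] / n[-1] ** nu_fixed]
            popt, pcov = curve_fit(
                f, n, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
                maxfev=20000,
            )
            params = {"c_r": popt[0], "a_r": popt[1], "nu": nu_fixed}
    except RuntimeError as err:  # pragma: no cover - scipy non-convergence
        raise FitFailureError(str(err)) from err
    return ScalingFit("rg", params, pcov, (float(n.min()), float(n.max())))


def fit_asphericity_scaling(
    n_values: Sequence[float],
    means: Sequence[float],
    se: Sequence[float] | None = None,
    min_n: int = 30,
) -> ScalingFit:
    """Fit <A> = A_inf + a_A N^mu (all three parameters free)."""
    n, y, w = _select(n_values, means, se, min_n)
    if n.size < 4:
        raise FitFailureError("need >= 4 points above the minimum loop size")
    sigma = _weights(w, n.size)

    def f(x, ainf, amp, mu):
        return ainf + amp * x**mu

    best = None
    for mu0 in (-0.15, -0.3, -0.8):
        for ainf0 in (y[-1], max(y[-1] - 0.02, 1e-3)):
            amp0 = (y[0] - ainf0) / n[0] ** mu0
            try:
                # A_inf is an asphericity (in [0, 1]); the exponent must be
                # a genuine decay to keep the asymptote identifiable (a
                # power slower than N^-0.1 varies by < ~25% over a decade
                # of N and degenerates with the constant term)
                popt, pcov = curve_fit(
                    f, n, y, p0=[ainf0, amp0, mu0], sigma=sigma,
                    absolute_sigma=sigma is not None, maxfev=20000,
                    bounds=([0.0, -5.0, -3.0], [1.0, 5.0, -0.1]),
                )
            except (RuntimeError, ValueError):
                continue
            resid = f(n, *popt) - y
            if sigma is not None:
                resid = resid / sigma
            cost = float((resid**2).sum())
            if best is None or cost < best[0]:
                best = (cost, popt, pcov)
    if best is None:
        raise FitFailureError("asphericity scaling fit did not converge")
    _, popt, pcov = best
    params = {"A_inf": popt[0], "a_A": popt[1], "mu": popt[2]}
    return ScalingFit("asphericity", params, pcov, (float(n.min()), float(n.max())))


def fit_prolateness_scaling(
    n_values: Sequence[float],
    means: Sequence[float],
    se: Sequence[float] | None = None,
    min_n: int = 30,
    exponent: float = -0.47,
) -> ScalingFit:
    """Fit <P> = P_inf + a_P N^exponent with the exponent frozen.

    Linear in both parameters, solved by (weighted) linear least squares.
    """
    n, y, w = _select(n_values, means, se, min_n)
    if n.size < 2:
        raise FitFailureError("need >= 2 points above the minimum loop size")
    x = n**exponent
    design = np.stack([np.ones_like(x), x], axis=1)
    if w is not None:
        sw = 1.0 / _weights(w, n.size)
        design = design * sw[:, None]
        yw = y * sw
    else:
        yw = y
    coef, *_ = np.linalg.lstsq(design, yw, rcond=None)
    # parameter covariance from the normal equations
    try:
        cov = np.linalg.inv(design.T @ design)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((2, 2), np.nan)
    params = {"P_inf": coef[0], "a_P": coef[1], "exponent": exponent}
    return ScalingFit("prolateness", params, cov, (float(n.min()), float(n.max())))
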