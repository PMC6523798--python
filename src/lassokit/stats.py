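"""Ensemble statistics of lasso classes and their decay laws.

The probability of a trivial (unthreaded) lasso decays with both loop
length N and tail length t towards a non-zero asymptote P_inf: even an
infinite phantom lasso stays unthreaded with finite probability.  Two
exponential rates, one roughly an order of magnitude slower than the
other, capture the short- and long-chain regimes:

    1D:      P(N; L0)   = P_inf + c_a exp(-alpha N) + c_b exp(-beta N)
    surface: P(N, t; L0) = P_inf + c_at exp(-at t) + c_aN exp(-aN N)
                                 + c_bt exp(-bt t) + c_bN exp(-bN N)

The piercing spectrum of non-trivial lassos is summarised by the
domination number d(N, t) = max p such that P(n >= p | n > 0) > 1/2, and
compared against an idealised geometric model in which each piercing
"fails" to be the last with probability 1 - p_success.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "EnsembleTable",
    "DecayFitParams",
    "SurfaceFitParams",
    "DominationResult",
    "FitFailureError",
    "UndefinedDominationError",
    "tabulate_ensemble",
    "fit_decay_1d",
    "fit_probability_surface",
    "domination_number",
    "geometric_piercing_model",
]


class FitFailureError(RuntimeError):
    pass


class UndefinedDominationError(ValueError):
    """No non-trivial lassos in the cell."""


@dataclass
class EnsembleTable:
    """Per-(N, t) lasso class counts with binomial uncertainties.

    ``counts`` maps (N, t) -> {class label: count}; ``table`` is the long
    format DataFrame with columns N, t, label, count, n, p, se.
    """

    counts: dict
    table: pd.DataFrame

    def cell(self, n: int, t: int) -> Mapping[str, int]:
        return self.counts[(n, t)]

    def probability(self, n: int, t: int, label: str) -> tuple[float, float]:
        c = self.counts[(n, t)]
        tot = sum(c.values())
        p = c.get(label, 0) / tot
        return p, float(np.sqrt(p * (1 - p) / tot))

    def trivial_series(self, along: str = "N") -> pd.DataFrame:
        """P(L0) with SE per cell, long format."""
        rows = []
        for (n, t), c in sorted(self.counts.items()):
            tot = sum(c.values())
            p = c.get("L0", 0) / tot
            se = np.sqrt(p * (1 - p) / tot)
            rows.append({"N": n, "t": t, "p_trivial": p, "se": se, "n_samples": tot})
        return pd.DataFrame(rows)

    def piercing_spectrum(self, n: int, t: int) -> dict[int, int]:
        """Total piercing count -> number of samples, for one cell."""
        spectrum: dict[int, int] = {}
        for label, cnt in self.counts[(n, t)].items():
            npier = _label_piercings(label)
            spectrum[npier] = spectrum.get(npier, 0) + cnt
        return spectrum


def _label_piercings(label: str) -> int:
    if label == "L0":
        return 0
    if label.startswith("LL"):
        i, j = label[2:].split(",")
        return int(i) + int(j)
    return int(label[1:])


def tabulate_ensemble(classified: Iterable) -> EnsembleTable:
    """Aggregate a stream of ((N, t, index), class label) into a table."""
    counts: dict = {}
    for cell, label in classified:
        n, t = cell[0], cell[1]
        label = getattr(label, "label", label)
        counts.setdefault((n, t), {})
        counts[(n, t)][label] = counts[(n, t)].get(label, 0) + 1
    rows = []
    for (n, t), c in sorted(counts.items()):
        tot = sum(c.values())
        for label, cnt in sorted(c.items()):
            p = cnt / tot
            rows.append(
                {
                    "N": n,
                    "t": t,
                    "label": label,
                    "count": cnt,
                    "n_samples": tot,
                    "p": p,
                    "se": np.sqrt(p * (1 - p) / tot),
                }
            )
    return EnsembleTable(counts=counts, table=pd.DataFrame(rows))


@dataclass(frozen=True)
class DecayFitParams:
    p_inf: float
    c_alpha: float
    alpha: float
    c_beta: float
    beta: float
    covariance: np.ndarray
    fixed_variable: str | None = None  # which of N or t was held fixed

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return (
            self.p_inf
            + self.c_alpha * np.exp(-self.alpha * x)
            + self.c_beta * np.exp(-self.beta * x)
        )


@dataclass(frozen=True)
class SurfaceFitParams:
    p_inf: float
    c_alpha_t: float
    alpha_t: float
    c_alpha_n: float
    alpha_n: float
    c_beta_t: float
    beta_t: float
    c_beta_n: float
    beta_n: float
    covariance: np.ndarray

    def __call__(self, n: np.ndarray, t: np.ndarray) -> np.ndarray:
        n = np.asarray(n, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        return (
            self.p_inf
            + self.c_alpha_t * np.exp(-self.alpha_t * t)
            + self.c_alpha_n * np.exp(-self.alpha_n * n)
            + self.c_beta_t * np.exp(-self.beta_t * t)
            + self.c_beta_n * np.exp(-self.beta_n * n)
        )


def _floored_se(p: np.ndarray, se: np.ndarray, n_samples: np.ndarray | None) -> np.ndarray:
    se = np.asarray(se, dtype=np.float64).copy()
    if n_samples is not None:
        floor = 1.0 / (2.0 * np.asarray(n_samples, dtype=np.float64))
    else:
        floor = np.full_like(se, max(se[se > 0].min() if np.any(se > 0) else 1e-3, 1e-6))
    return np.where(se <= 0, floor, se)


def fit_decay_1d(
    lengths,
    probabilities,
    se=None,
    n_samples=None,
    fixed_variable: str | None = None,
) -> DecayFitParams:
    """Weighted fit of the double-exponential-plus-constant decay law.

    Multi-start initialisation over fast/slow rate guesses (the two rates
    typically differ by an order of magnitude); the lowest-residual start
    wins.
    """
    x = np.asarray(lengths, dtype=np.float64)
    y = np.asarray(probabilities, dtype=np.float64)
    if x.size < 6:
        raise FitFailureError("need at least 6 points for the 5-parameter fit")
    if se is not None:
        sigma = _floored_se(y, np.asarray(se), n_samples)
    else:
        sigma = None

    def f(x, p_inf, ca, alpha, cb, beta):
        return p_inf + ca * np.exp(-alpha * x) + cb * np.exp(-beta * x)

    p_inf0 = float(y[np.argmax(x)])
    resid0 = float(y[np.argmin(x)] - p_inf0)
    # identifiability floor: a rate slower than 1/span decays by less than
    # a factor e across the fitted range and degenerates with the constant
    rate_floor = 1.0 / float(x.max() - x.min())
    best = None
    best_resid = np.inf
    for alpha0 in (0.3, 0.03):
        for beta0 in (0.05, 0.005):
            p0 = [
                p_inf0,
                0.7 * resid0,
                max(alpha0, 10 * rate_floor),
                0.3 * resid0,
                max(beta0, 1.5 * rate_floor),
            ]
            try:
                # the asymptote is a probability and the amplitudes are
                # bounded by 1; rates are kept positive (decay, not growth)
                popt, pcov = curve_fit(
                    f, x, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
                    bounds=(
                        [0.0, -2.0, rate_floor, -2.0, rate_floor],
                        [1.0, 2.0, 10.0, 2.0, 10.0],
                    ),
                    maxfev=50000,
                )
            except RuntimeError:
                continue
            r = f(x, *popt) - y
            if sigma is not None:
                r = r / sigma
            cost = float((r**2).sum())
            if cost < best_resid:
                best_resid = cost
                best = (popt, pcov)
    if best is None:
        raise FitFailureError(f"decay fit failed; best residual {best_resid}")
    popt, pcov = best
    # order the exponentials so alpha is the faster rate
    p_inf, ca, alpha, cb, beta = popt
    if alpha < beta:
        ca, cb = cb, ca
        alpha, beta = beta, alpha
    return DecayFitParams(
        p_inf=float(p_inf),
        c_alpha=float(ca),
        alpha=float(alpha),
        c_beta=float(cb),
        beta=float(beta),
        covariance=pcov,
        fixed_variable=fixed_variable,
    )


def fit_probability_surface(table: EnsembleTable | pd.DataFrame) -> SurfaceFitParams:
    """Weighted fit of the trivial-lasso probability surface over (N, t)."""
    df = table.trivial_series() if isinstance(table, EnsembleTable) else table
    n_distinct = df["N"].nunique()
    t_distinct = df["t"].nunique()
    if n_distinct < 4 or t_distinct < 4:
        raise FitFailureError("need a grid with >= 4 distinct N and t values")
    n = df["N"].to_numpy(dtype=np.float64)
    t = df["t"].to_numpy(dtype=np.float64)
    y = df["p_trivial"].to_numpy(dtype=np.float64)
    sigma = _floored_se(
        y, df["se"].to_numpy(), df.get("n_samples", pd.Series(np.ones_like(y))).to_numpy()
    )

    def f(xdata, p_inf, cat, at, can, an, cbt, bt, cbn, bn):
        nn, tt = xdata
        return (
            p_inf
            + cat * np.exp(-at * tt)
            + can * np.exp(-an * nn)
            + cbt * np.exp(-bt * tt)
            + cbn * np.exp(-bn * nn)
        )

    p_inf0 = float(y.min())
    amp0 = max(float(y.max() - y.min()), 1e-3)
    best = None
    best_cost = np.inf
    for fast in (0.3, 0.03):
        for slow in (0.05, 0.005):
            p0 = [p_inf0, 0.3 * amp0, fast, 0.3 * amp0, fast, 0.2 * amp0, slow, 0.2 * amp0, slow]
            try:
                popt, pcov = curve_fit(
                    f, (n, t), y, p0=p0, sigma=sigma, absolute_sigma=True,
                    bounds=(
                        [-np.inf] + [-np.inf, 1e-8] * 4,
                        [np.inf] + [np.inf, np.inf] * 4,
                    ),
                    maxfev=100000,
                )
            except RuntimeError:
                continue
            cost = float((((f((n, t), *popt) - y) / sigma) ** 2).sum())
            if cost < best_cost:
                best_cost = cost
                best = (popt, pcov)
    if best is None:
        raise FitFailureError("surface fit did not converge from any start")
    popt, pcov = best
    return SurfaceFitParams(
        p_inf=float(popt[0]),
        c_alpha_t=float(popt[1]),
        alpha_t=float(popt[2]),
        c_alpha_n=float(popt[3]),
        alpha_n=float(popt[4]),
        c_beta_t=float(popt[5]),
        beta_t=float(popt[6]),
        c_beta_n=float(popt[7]),
        beta_n=float(popt[8]),
        covariance=pcov,
    )


@dataclass(frozen=True)
class DominationResult:
    d: int
    tail_probabilities: dict  # p -> P(n >= p | non-trivial)


def domination_number(spectrum: Mapping[int, int]) -> DominationResult:
    """Largest p with P(n >= p | n > 0) > 1/2 (strict inequality).

    ``spectrum`` maps total piercing count -> sample count; the n = 0
    entry (trivial lassos) is ignored.
    """
    nontrivial = {k: v for k, v in spectrum.items() if k > 0 and v > 0}
    if not nontrivial:
        raise UndefinedDominationError("no non-trivial lassos in the spectrum")
    total = sum(nontrivial.values())
    ps = sorted(nontrivial)
    tail_probs = {}
    d = 0
    for p in range(1, max(ps) + 1):
        tail = sum(v for k, v in nontrivial.items() if k >= p) / total
        tail_probs[p] = tail
        if tail > 0.5:
            d = p
    return DominationResult(d=d, tail_probabilities=tail_probs)


def geometric_piercing_model(p_success: float, n_max: int = 50) -> np.ndarray:
    """Idealised asymptotic piercing distribution P(n) = p (1-p)^n.

    ``p_success`` is the probability that the tail drifts away for good
    (the asymptotic trivial-lasso probability); n = 0 is the trivial
    lasso.  Returns P(n) for n = 0..n_max (unnormalised tail beyond n_max
    is negligible for the intended p range).
    """
    if not (0.0 < p_success < 1.0):
        raise ValueError("p_success must lie strictly inside (0, 1)")
    n = np.arange(n_max + 1)
    return p_success * (1.0 - p_success) ** n
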