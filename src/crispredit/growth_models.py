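"""Logistic growth fitting, dose-inhibition fitting, and limiting dilution.

The growth model is P(t) = K*P0 / ((K - P0)*exp(-t/T) + P0) with carrying
capacity K, initial density P0, and time constant T (the source protocol
labels T the "doubling time"; it is the e-folding constant of early
exponential growth). Fitting minimizes the sum of absolute deviations
with a multi-start derivative-free simplex. Limiting-dilution helpers
evaluate Poisson single-founder statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GrowthSeries",
    "LogisticFit",
    "DoseInhibitionFit",
    "DilutionPlan",
    "FounderStats",
    "logistic_density",
    "fit_logistic_lad",
    "fit_dose_inhibition",
    "mean_occupancy",
    "single_founder_probability",
    "founder_stats",
    "read_growth_tsv",
]


class FitWarning(UserWarning):
    """Raised (as a warning) when a fit is degenerate or unreliable."""


@dataclass(frozen=True)
class GrowthSeries:
    """Time-density observations for one replicate culture."""

    times: tuple[float, ...]        # hours
    densities: tuple[float, ...]    # cells/ml
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "densities",
                           tuple(float(d) for d in self.densities))
        if len(self.times) != len(self.densities):
            raise ValueError("times and densities must have equal length")
        if any(t < 0 for t in self.times):
            raise ValueError("times must be non-negative")
        if any(d <= 0 for d in self.densities):
            raise ValueError("densities must be positive")
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters and the L1 residual at the optimum."""

    K: float
    P0: float
    T: float
    l1_residual: float
    n_obs: int
    warnings: tuple[str, ...] = field(default=())
    # T is reported with the upstream label "doubling time"; strictly it
    # is the exponential time constant of the printed model.
    t_label: str = "doubling time (e-folding time constant of early growth)"


def logistic_density(t, K: float, P0: float, T: float):
    """Logistic density K*P0 / ((K - P0)*exp(-t/T) + P0)."""
    if K <= 0 or P0 <= 0 or T <= 0:
        raise ValueError("K, P0, and T must all be positive")
    t = np.asarray(t, dtype=float)
    out = K * P0 / ((K - P0) * np.exp(-t / T) + P0)
    return float(out) if out.ndim == 0 else out


def _pool(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, GrowthSeries):
        series = [series]
    times = np.concatenate([np.asarray(s.times) for s in series])
    dens = np.concatenate([np.asarray(s.densities) for s in series])
    return times, dens


def _heuristic_init(t: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    p0 = float(p[np.argmin(t)])
    k = float(p.max())
    if k <= p0:
        k = p0 * 1.001
    # time to reach K/2, scaled by the log density ratio covered so far
    half = k / 2
    above = np.nonzero(p >= half)[0]
    t_half = float(t[above[0]]) if above.size else float(t.max())
    ratio = max(k / p0, 1.0 + 1e-9)
    T = max(t_half / math.log(ratio), 1e-3)
    return k, p0, T


def fit_logistic_lad(
    series: GrowthSeries | Sequence[GrowthSeries],
    n_restarts: int = 32,
    seed: int | None = 0,
    log_space: bool = False,
) -> LogisticFit:
    """Least-absolute-deviation logistic fit with multi-start simplex.

    Observations from multiple replicates are pooled. Parameters are
    optimized in log space for positivity; ``log_space`` switches the
    *objective* to log densities (off by default: the deviations are
    taken on raw densities).
    """
    t, p = _pool(series)
    if len(t) < 4:
        raise ValueError("need at least 4 observations to fit")
    warn_msgs: list[str] = []
    if np.allclose(p, p[0], rtol=1e-9):
        warn_msgs.append("constant density series; K ~= P0 and T is unidentifiable")
        warnings.warn(warn_msgs[-1], FitWarning)

    target = np.log(p) if log_space else p

    def objective(x: np.ndarray) -> float:
        K, P0, T = np.exp(x)
        pred = K * P0 / ((K - P0) * np.exp(-t / T) + P0)
        if log_space:
            pred = np.log(np.maximum(pred, 1e-300))
        return float(np.abs(pred - target).sum())

    k0, p00, t0 = _heuristic_init(t, p)
    x0 = np.log([k0, p00, t0])
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(scale=0.4, size=3)
                     for _ in range(max(n_restarts - 1, 0))]
    best_x, best_f = x0, objective(x0)
    for start in starts:
        res = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10 * max(best_f, 1.0),
                     "maxiter": 4000, "maxfev": 4000},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    K, P0, T = (float(v) for v in np.exp(best_x))
    if K <= P0:
        warn_msgs.append(f"fitted K ({K:.3g}) does not exceed P0 ({P0:.3g})")
        warnings.warn(warn_msgs[-1], FitWarning)
    return LogisticFit(K=K, P0=P0, T=T, l1_residual=best_f, n_obs=len(t),
                       warnings=tuple(warn_msgs))


@dataclass(frozen=True)
class DoseInhibitionFit:
    """Three-parameter Hill fit: density = top / (1 + (c/IC50)^hill).

    The functional form is a documented substitute; the source analysis
    names a "dose inhibition curve" without printing one.
    """

    top: float
    ic50: float
    hill: float
    rss: float
    warnings: tuple[str, ...] = field(default=())
    functional_form: str = "top / (1 + (c/IC50)^hill)"


def fit_dose_inhibition(
    concentrations: Sequence[float], densities: Sequence[float]
) -> DoseInhibitionFit:
    """Least-squares Hill fit of density vs dose."""
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(densities, dtype=float)
    if len(c) != len(d) or len(c) < 4:
        raise ValueError("need >= 4 matched dose levels")
    warn_msgs: list[str] = []
    order = np.argsort(c)
    if np.allclose(d, d[0]) or d[order][-1] >= d[order][0]:
        warn_msgs.append("densities do not decrease with dose; fit unreliable")
        warnings.warn(warn_msgs[-1], FitWarning)

    def hill(cc, top, ic50, h):
        return top / (1.0 + (cc / ic50) ** h)

    pos = c[c > 0]
    ic50_0 = float(np.exp(np.log(pos).mean())) if pos.size else 1.0
    p0 = [float(d.max()), ic50_0, 1.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = optimize.curve_fit(
            hill, c, d, p0=p0,
            bounds=([1e-12, 1e-12, 0.05], [np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
    rss = float(((hill(c, *popt) - d) ** 2).sum())
    return DoseInhibitionFit(top=float(popt[0]), ic50=float(popt[1]),
                             hill=float(popt[2]), rss=rss,
                             warnings=tuple(warn_msgs))


@dataclass(frozen=True)
class DilutionPlan:
    """A limiting-dilution plating scheme."""

    concentration: float  # cells/ml
    volume_per_well: float  # ml

    @property
    def mean_cells_per_well(self) -> float:
        return self.concentration * self.volume_per_well


def mean_occupancy(plan: DilutionPlan) -> float:
    """Expected cells per well: concentration x volume."""
    lam = plan.mean_cells_per_well
    if lam <= 0:
        warnings.warn("mean occupancy is not positive; every well is empty",
                      FitWarning)
    return lam


@dataclass(frozen=True)
class FounderStats:
    """Poisson statistics for wells seeded at mean occupancy lambda."""

    lam: float
    p_single_given_occupied: float
    p_at_most_one: float
    p_two_or_more: float


def founder_stats(lam: float) -> FounderStats:
    if lam <= 0:
        raise ValueError("lambda must be positive")
    e = math.exp(-lam)
    return FounderStats(
        lam=lam,
        p_single_given_occupied=lam * e / (1.0 - e),
        p_at_most_one=e * (1.0 + lam),
        p_two_or_more=1.0 - e * (1.0 + lam),
    )


def single_founder_probability(lam: float) -> float:
    """P(exactly one founding cell | well occupied) = lam*e^-lam/(1-e^-lam)."""
    return founder_stats(lam).p_single_given_occupied


def read_growth_tsv(path: str | Path) -> list[GrowthSeries]:
    """Read a growth TSV with columns replicate, time_h, density_cells_per_ml."""
    df = pd.read_csv(path, sep="\t")
    required = {"replicate", "time_h", "density_cells_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for rep, group in df.groupby("replicate", sort=False):
        group = group.sort_values("time_h")
        series.append(GrowthSeries(
            times=tuple(group["time_h"]),
            densities=tuple(group["density_cells_per_ml"]),
            replicate=str(rep),
        ))
    return series
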