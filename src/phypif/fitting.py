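"""Fitting the forward model to fold-change time courses.

Each gene has exactly one free parameter, the relative dissociation
constant K_PIF, estimated by weighted least squares against the replicate
means (weights 1/SE^2 when standard errors are available).  phyB-deficient
series are fitted the same way over the PhyB-abundance scaling q with
K_PIF held fixed.  Both problems are 1-D and quasi-convex; a log-spaced
pre-scan brackets the minimum before bounded scalar minimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .expression import GeneParams
from .model import ModelConfig, forward_gene

__all__ = [
    "ExpressionSeries",
    "FitResult",
    "HalflifeFit",
    "KPIF_BOUNDS",
    "fit_kpif",
    "fit_q",
    "fit_exponential_halflife",
]

KPIF_BOUNDS = (1e-4, 10.0)
Q_BOUNDS = (1e-3, 1.0)
_PRESCAN_POINTS = 50
_XATOL = 1e-6


@dataclass
class ExpressionSeries:
    """Fold-change (relative to dark) measurements for one gene.

    Either ``replicates`` (matrix, rows = time points) or ``mean``/``se``/
    ``n_replicates`` summaries are given; summaries are derived from
    replicates when present (SE = sd/sqrt(n)).
    """

    gene_id: str
    times: np.ndarray
    replicates: np.ndarray | None = None
    mean: np.ndarray | None = None
    se: np.ndarray | None = None
    n_replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be sorted, distinct and >= 0")
        if self.replicates is not None:
            rep = np.atleast_2d(np.asarray(self.replicates, dtype=float))
            if rep.shape[0] != self.times.size:
                raise ValueError("replicate rows must match the time grid")
            if np.any(rep <= 0):
                raise ValueError("fold-changes must be > 0")
            self.replicates = rep
            self.mean = rep.mean(axis=1)
            n = rep.shape[1]
            self.n_replicates = np.full(self.times.size, n)
            if n > 1:
                self.se = rep.std(axis=1, ddof=1) / math.sqrt(n)
            else:
                self.se = None
        else:
            if self.mean is None:
                raise ValueError("need replicates or mean values")
            self.mean = np.asarray(self.mean, dtype=float)
            if self.mean.shape != self.times.shape:
                raise ValueError("mean length must match times")
            if np.any(self.mean <= 0):
                raise ValueError("fold-changes must be > 0")
            if self.se is not None:
                self.se = np.asarray(self.se, dtype=float)
                if self.n_replicates is not None:
                    n = np.asarray(self.n_replicates)
                    if np.any((n > 1) & (self.se <= 0)):
                        raise ValueError("SE must be > 0 where n_replicates > 1")
        if self.times.size < 3:
            raise ValueError("at least 3 time points are required for fitting")

    @property
    def weights(self) -> np.ndarray:
        """1/SE^2 where SE is available and positive, else uniform."""
        if self.se is not None and np.all(np.asarray(self.se) > 0):
            return 1.0 / np.asarray(self.se) ** 2
        return np.ones(self.times.size)


@dataclass
class FitResult:
    """Outcome of a 1-D parameter fit."""

    parameter: str
    estimate: float
    loss: float
    converged: bool
    n_evaluations: int
    bounds: tuple[float, float]
    gene_id: str | None = None
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "gene_id": self.gene_id,
            "estimate": self.estimate,
            "loss": self.loss,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "bounds": list(self.bounds),
            "warnings": self.warnings,
            "seed": self.seed,
        }


def _weighted_loss(model_vals, series: ExpressionSeries) -> float:
    w = series.weights
    r = series.mean - model_vals
    return float(np.sum(w * r * r))


def _minimise_1d(loss_fn, bounds, log_scan: bool = True):
    """Log-grid pre-scan (guards against local minima) then bounded Brent."""
    lo, hi = bounds
    grid = (
        np.geomspace(lo, hi, _PRESCAN_POINTS)
        if log_scan
        else np.linspace(lo, hi, _PRESCAN_POINTS)
    )
    scan = np.array([loss_fn(x) for x in grid])
    i = int(np.argmin(scan))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    if b_lo == b_hi:  # degenerate bracket at an edge
        b_lo, b_hi = lo, hi
    res = minimize_scalar(
        loss_fn, bounds=(b_lo, b_hi), method="bounded", options={"xatol": _XATOL}
    )
    n_eval = _PRESCAN_POINTS + int(res.nfev)
    return float(res.x), float(res.fun), bool(res.success), n_eval


def fit_kpif(
    series: ExpressionSeries,
    config: ModelConfig = ModelConfig(),
    bounds: tuple[float, float] = KPIF_BOUNDS,
) -> FitResult:
    """Estimate K_PIF for one gene from its fold-change time course.

    All other parameters are fixed by ``config``; the loss is the weighted
    squared error between the replicate means and the forward model.
    """
    def loss(k):
        gene = GeneParams(series.gene_id, K_PIF=float(k))
        return _weighted_loss(forward_gene(gene, config, series.times), series)

    est, fval, ok, n_eval = _minimise_1d(loss, bounds, log_scan=True)
    warn = []
    spread = series.mean.max() / series.mean.min()
    if spread < 1.05:
        warn.append("series is nearly constant; K_PIF is not identifiable")
    if est > 0.99 * bounds[1]:
        warn.append("estimate at the upper bound (no detectable light response)")
    if not ok:
        raise RuntimeError(f"K_PIF fit did not converge for {series.gene_id}")
    return FitResult(
        parameter="K_PIF",
        estimate=est,
        loss=fval,
        converged=ok,
        n_evaluations=n_eval,
        bounds=bounds,
        gene_id=series.gene_id,
        warnings=warn,
    )


def fit_q(
    series: ExpressionSeries,
    gene: GeneParams,
    config: ModelConfig = ModelConfig(),
    bounds: tuple[float, float] = Q_BOUNDS,
) -> FitResult:
    """Estimate the phyB-mutant PhyB-abundance scaling q, K_PIF fixed."""

    def loss(q):
        return _weighted_loss(
            forward_gene(gene, config.with_q(float(q)), series.times), series
        )

    est, fval, ok, n_eval = _minimise_1d(loss, bounds, log_scan=False)
    if not ok:
        raise RuntimeError(f"q fit did not converge for {series.gene_id}")
    warn = []
    if est > 0.99 * bounds[1]:
        warn.append("estimate at q = 1 (wild-type-like series)")
    return FitResult(
        parameter="q",
        estimate=est,
        loss=fval,
        converged=ok,
        n_evaluations=n_eval,
        bounds=bounds,
        gene_id=series.gene_id,
        warnings=warn,
    )


@dataclass
class HalflifeFit:
    """Exponential-decay fit value(t) = floor + (v0 - floor)*exp(-rate*t)."""

    rate: float  # per day
    half_life_days: float
    v0: float
    floor: float
    floor_fitted: bool


def fit_exponential_halflife(times, values, floor: float | None = None) -> HalflifeFit:
    """Least-squares exponential decay toward a known or co-fitted floor.

    Used to recover the pooled PhyB decay rate Q_Pfr*gamma_Pr (and hence
    the ~8 h half-life) from decay curves.  Raises on non-decaying input.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2 or t.size != v.size:
        raise ValueError("need >= 2 matching (time, value) pairs")
    if np.any(v <= 0):
        raise ValueError("values must be > 0")
    if v[-1] >= v[0]:
        raise ValueError("series does not decay; cannot fit a decay rate")
    if t.size == 2:
        f = floor or 0.0
        rate = math.log((v[0] - f) / (v[1] - f)) / (t[1] - t[0])
        return HalflifeFit(rate, math.log(2.0) / rate, float(v[0]), f, False)

    if floor is None:
        def f_model(t, v0, rate, fl):
            return fl + (v0 - fl) * np.exp(-rate * t)
        p0 = (v[0], math.log(max(v[0] / v[-1], 1.5)) / (t[-1] - t[0] + 1e-12), v[-1] * 0.9)
        popt, _ = curve_fit(f_model, t, v, p0=p0, maxfev=20000)
        v0, rate, fl = popt
        fitted = True
    else:
        fl = floor
        def f_model(t, v0, rate):
            return fl + (v0 - fl) * np.exp(-rate * t)
        p0 = (v[0], math.log(max((v[0] - fl) / max(v[-1] - fl, 1e-12), 1.5)) / (t[-1] - t[0]))
        popt, _ = curve_fit(f_model, t, v, p0=p0, maxfev=20000)
        v0, rate = popt
        fitted = False
    if rate <= 0:
        raise RuntimeError("fitted rate is non-positive")
    return HalflifeFit(float(rate), math.log(2.0) / float(rate), float(v0), float(fl), fitted)
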