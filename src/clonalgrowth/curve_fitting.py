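"""Nonlinear least-squares fitting of trait time series to growth families.

A :class:`TraitSeries` holds one cluster's (or rhizome's) DOY-indexed
cumulative growth increments for a single trait. :func:`fit_series` fits
it to one of the three growth families with data-driven initialisation
and jittered multi-start bounded least squares (scipy's trust-region
reflective solver), reporting adjusted R² as the fit-quality statistic.

The trait-to-family assignment used throughout the pipeline is fixed:
plant height -> logistic, leaf area -> BiHill, rhizome length ->
BiDoseResp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from . import growth_models as gm
from .errors import ContractError, DegenerateSeriesError, NonConvergenceError

__all__ = [
    "TRAITS",
    "TRAIT_FAMILY",
    "REPRODUCTIVE_TYPES",
    "TraitSeries",
    "FitConfig",
    "GrowthFit",
    "initialize_params",
    "default_bounds",
    "fit_series",
    "adjusted_r2",
    "standardize_series",
]

TRAITS = ("plant_height", "leaf_area", "rhizome_length")
REPRODUCTIVE_TYPES = ("asexual", "sexual", "not_applicable")

TRAIT_FAMILY: Dict[str, gm.ModelFamily] = {
    "plant_height": gm.ModelFamily.LOGISTIC,
    "leaf_area": gm.ModelFamily.BIHILL,
    "rhizome_length": gm.ModelFamily.BIDOSERESP,
}


@dataclass(frozen=True)
class TraitSeries:
    """One sample's growth-increment series for one trait.

    Observations are sorted by DOY on construction, so equality of the
    (doy, increment) multiset implies equality of the series.
    """

    series_id: str
    patch_area_m2: float
    trait: str
    reproductive_type: str
    doys: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ContractError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        if self.reproductive_type not in REPRODUCTIVE_TYPES:
            raise ContractError(
                f"unknown reproductive_type {self.reproductive_type!r}"
            )
        if not self.patch_area_m2 > 0:
            raise ContractError("patch_area_m2 must be positive")
        doys = np.asarray(self.doys, dtype=float)
        inc = np.asarray(self.increments, dtype=float)
        if doys.shape != inc.shape or doys.ndim != 1:
            raise ContractError("doys and increments must be 1-D and equal length")
        order = np.argsort(doys)
        doys, inc = doys[order], inc[order]
        if np.any(np.diff(doys) <= 0):
            raise ContractError("duplicate DOY in series")
        if np.any(inc < 0):
            raise ContractError("growth increments must be non-negative")
        object.__setattr__(self, "doys", doys)
        object.__setattr__(self, "increments", inc)

    def __len__(self) -> int:
        return len(self.doys)

    @property
    def span(self) -> float:
        return float(self.increments.max() - self.increments.min())


@dataclass(frozen=True)
class FitConfig:
    """Multi-start least-squares settings; ``seed`` makes reruns exact."""

    n_starts: int = 8
    max_iter: int = 2000
    seed: int = 0
    param_bounds: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self):
        if self.n_starts < 1:
            raise ContractError("n_starts must be >= 1")


@dataclass(frozen=True)
class GrowthFit:
    """A fitted growth family with goodness-of-fit and provenance."""

    family: gm.ModelFamily
    params: object
    adj_r2: float
    rss: float
    n_obs: int
    converged: bool
    season_window: Tuple[float, float]
    series_id: Optional[str] = None
    trait: Optional[str] = None
    seed: Optional[int] = None
    at_bounds: Tuple[str, ...] = field(default=())

    def predict(self, t):
        return gm.evaluate(self.family, self.params, t)


def standardize_series(series: TraitSeries) -> TraitSeries:
    """Scale increments so the maximum equals 1 (display convention)."""
    m = float(series.increments.max())
    if m <= 0:
        raise DegenerateSeriesError("cannot standardize an all-zero series")
    return replace(series, increments=series.increments / m)


def adjusted_r2(rss: float, tss: float, n_obs: int, k_params: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - k - 1); equals 1 iff rss == 0."""
    if rss < 0 or tss <= 0:
        raise ContractError("need rss >= 0 and tss > 0")
    if n_obs <= k_params + 1:
        raise ContractError("adjusted R^2 needs n_obs > k_params + 1")
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - k_params - 1)


def _half_crossing(doys: np.ndarray, inc: np.ndarray, level: float) -> float:
    """First DOY at which the series reaches ``level`` (linear interpolation)."""
    idx = np.nonzero(inc >= level)[0]
    if len(idx) == 0:
        return float(doys[-1])
    i = idx[0]
    if i == 0 or inc[i] == inc[i - 1]:
        return float(doys[i])
    w = (level - inc[i - 1]) / (inc[i] - inc[i - 1])
    return float(doys[i - 1] + w * (doys[i] - doys[i - 1]))


def _smoothed_rate(doys: np.ndarray, inc: np.ndarray) -> np.ndarray:
    r = np.gradient(inc, doys)
    if len(r) >= 5:
        kernel = np.ones(3) / 3.0
        r = np.convolve(r, kernel, mode="same")
    return r


def initialize_params(series: TraitSeries, family: gm.ModelFamily):
    """Data-driven starting parameters for ``fit_series``.

    Raises :class:`DegenerateSeriesError` for constant/all-zero series,
    for which no growth curve is meaningful.
    """
    doys, inc = series.doys, series.increments
    mx = float(inc.max())
    if mx <= 0 or series.span <= 0:
        raise DegenerateSeriesError(
            f"series {series.series_id!r} is constant or all-zero"
        )

    if family is gm.ModelFamily.LOGISTIC:
        a2 = mx
        x0 = _half_crossing(doys, inc, a2 / 2.0)
        # slope of log(y/(A2-y)) against log(t) over mid-range points
        mid = (inc > 0.2 * a2) & (inc < 0.8 * a2)
        p = 8.0
        if mid.sum() >= 2:
            ly = np.log(inc[mid] / (a2 - inc[mid]))
            lx = np.log(doys[mid])
            slope = np.polyfit(lx, ly, 1)[0]
            if np.isfinite(slope) and slope > 0:
                p = float(np.clip(slope, 1.0, 40.0))
        return gm.LogisticParams(A1=0.0, A2=a2, x0=max(x0, 1.0), p=p)

    if family is gm.ModelFamily.BIHILL:
        ka = _half_crossing(doys, inc, mx / 2.0)
        ki = 1.5 * float(doys[int(np.argmax(inc))])
        return gm.BiHillParams(Pm=mx, Ka=max(ka, 1.0), Ha=4.0, Ki=max(ki, ka + 1.0), Hi=4.0)

    if family is gm.ModelFamily.BIDOSERESP:
        r = _smoothed_rate(doys, inc)
        # candidate phase peaks: interior local maxima of the smoothed rate
        peaks = [
            i
            for i in range(1, len(r) - 1)
            if r[i] >= r[i - 1] and r[i] >= r[i + 1] and r[i] > 0
        ]
        split = None
        if len(peaks) >= 2:
            top = sorted(sorted(peaks, key=lambda i: r[i], reverse=True)[:2])
            i1, i2 = top
            if i2 > i1 + 1:
                split = i1 + int(np.argmin(r[i1 : i2 + 1]))
        if split is None:
            split = len(doys) // 2
        rise1 = max(inc[split] - inc[0], 0.0)
        rise2 = max(inc[-1] - inc[split], 0.0)
        total = rise1 + rise2
        prop = 0.5 if total == 0 else float(np.clip(rise1 / total, 0.05, 0.95))
        l1 = _half_crossing(doys[: split + 1], inc[: split + 1], inc[0] + rise1 / 2.0)
        l2 = _half_crossing(doys[split:], inc[split:], inc[split] + rise2 / 2.0)
        if l2 <= l1:
            l2 = l1 + max(1.0, 0.1 * (doys[-1] - doys[0]))
        return gm.BiDoseRespParams(
            A1=float(inc[0]), A2=mx, L1=l1, L2=l2, h1=0.05, h2=0.05, P=prop
        )

    raise ContractError(f"unknown family {family!r}")


def default_bounds(series: TraitSeries, family: gm.ModelFamily):
    """Per-family box bounds keyed to the observed span and season."""
    mx = float(series.increments.max())
    t0, t1 = float(series.doys[0]), float(series.doys[-1])
    if family is gm.ModelFamily.LOGISTIC:
        names = ("A1", "A2", "x0", "p")
        lo = [-0.5 * mx, 0.3 * mx, max(1.0, 0.5 * t0), 0.5]
        hi = [0.5 * mx, 3.0 * mx, 1.5 * t1, 60.0]
    elif family is gm.ModelFamily.BIHILL:
        names = ("Pm", "Ka", "Ha", "Ki", "Hi")
        lo = [0.3 * mx, max(1.0, 0.5 * t0), 0.5, max(1.0, t0), 0.3]
        hi = [10.0 * mx, 1.5 * t1, 40.0, 3.0 * t1, 40.0]
    elif family is gm.ModelFamily.BIDOSERESP:
        names = ("A1", "A2", "L1", "L2", "h1", "h2", "P")
        lo = [-0.5 * mx, 0.3 * mx, t0 - 30.0, t0, 2e-3, 2e-3, 0.0]
        hi = [0.5 * mx, 3.0 * mx, t1, t1 + 60.0, 2.0, 2.0, 1.0]
    else:
        raise ContractError(f"unknown family {family!r}")
    return names, np.array(lo), np.array(hi)


def _canonical_theta(family: gm.ModelFamily, theta: np.ndarray) -> np.ndarray:
    """Map an optimiser iterate to a valid parameter vector (phase order etc.)."""
    th = np.array(theta, dtype=float)
    if family is gm.ModelFamily.BIDOSERESP:
        a1, a2, l1, l2, h1, h2, p = th
        if l1 > l2:  # phases are exchangeable; keep L1 <= L2
            th = np.array([a1, a2, l2, l1, h2, h1, 1.0 - p])
        th[6] = float(np.clip(th[6], 0.0, 1.0))
    return th


def _params_from_theta(family: gm.ModelFamily, theta: np.ndarray):
    return family.param_cls.from_array(_canonical_theta(family, theta))


# bounds a fitted parameter may legitimately sit on (baselines, proportions,
# Hill/sigmoid shape coefficients); location and amplitude parameters pinned
# to their box edge indicate a fit escaping the season window instead
_SOFT_BOUND_PARAMS = {"A1", "P", "Ha", "Hi", "h1", "h2"}


def fit_series(
    series: TraitSeries, family: gm.ModelFamily, config: FitConfig = FitConfig()
) -> GrowthFit:
    """Best-of-``n_starts`` bounded least-squares fit of one series.

    Deterministic given ``config.seed``. Raises
    :class:`NonConvergenceError` (with best-attempt diagnostics) when no
    start converges, and :class:`DegenerateSeriesError` for flat series.
    """
    k = family.n_params
    if len(series) < k + 2:
        raise ContractError(
            f"series of length {len(series)} cannot constrain {k} parameters"
        )
    init = initialize_params(series, family)  # may raise DegenerateSeriesError
    names, lo, hi = default_bounds(series, family)
    if config.param_bounds:
        for i, nm in enumerate(names):
            if nm in config.param_bounds:
                lo[i], hi[i] = config.param_bounds[nm]
    theta0 = np.clip(init.to_array(), lo + 1e-12, hi - 1e-12)

    doys, inc = series.doys, series.increments

    def residuals(theta):
        p = _params_from_theta(family, theta)
        return gm.evaluate(family, p, doys) - inc

    rng = np.random.default_rng(config.seed)
    starts = [theta0]
    for _ in range(config.n_starts - 1):
        jitter = np.where(
            theta0 > 0,
            theta0 * np.exp(rng.uniform(np.log(0.75), np.log(4 / 3), size=len(theta0))),
            theta0 + rng.uniform(-0.1, 0.1, size=len(theta0)) * series.span,
        )
        starts.append(np.clip(jitter, lo + 1e-12, hi - 1e-12))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                max_nfev=config.max_iter,
                x_scale="jac",
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not np.all(np.isfinite(best.x)):
        raise NonConvergenceError(
            f"no optimisation start converged for series {series.series_id!r}"
        )

    params = _params_from_theta(family, best.x)
    rss = float(2.0 * best.cost)
    tss = float(np.sum((inc - inc.mean()) ** 2))
    if tss <= 0:
        raise DegenerateSeriesError("zero total variance in increments")
    adj = adjusted_r2(rss, tss, len(series), k)

    theta = _canonical_theta(family, best.x)
    tol = 1e-6 * np.maximum(1.0, np.abs(hi - lo))
    pinned = [
        nm
        for nm, v, a, b, tl in zip(names, theta, lo, hi, tol)
        if (v - a < tl or b - v < tl)
    ]
    hard_pinned = [nm for nm in pinned if nm not in _SOFT_BOUND_PARAMS]
    converged = bool(best.success) and not hard_pinned

    if not bool(best.success):
        raise NonConvergenceError(
            f"optimiser failed for series {series.series_id!r}",
            best_params=params,
            best_rss=rss,
        )

    return GrowthFit(
        family=family,
        params=params,
        adj_r2=adj,
        rss=rss,
        n_obs=len(series),
        converged=converged,
        season_window=(float(doys[0]), float(doys[-1])),
        series_id=series.series_id,
        trait=series.trait,
        seed=config.seed,
        at_bounds=tuple(pinned),
    )
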