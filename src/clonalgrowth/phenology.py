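"""Growth-characteristic (phenological) parameters from fitted curves.

From a converged :class:`~clonalgrowth.curve_fitting.GrowthFit` the
extractor reads off the standard seasonal descriptors:

=========  ===========================================================
W_max      maximum growth increment of the fitted curve in the window
V_max      maximum growth rate (first derivative peak)
V_mean     mean daily rate, W_max / GD
D_o        onset of growth: earliest DOY with y >= theta_o * W_max
D_r        start of rapid growth: acceleration maximum before D_vmax
D_vmax     DOY of the rate maximum
D_st       start of stable growth: acceleration minimum after D_vmax
D_t        growth termination: earliest DOY with y >= theta_t * W_max
GD_sl      slow growth period,   D_r  - D_o
GD_r       rapid growth period,  D_st - D_r
GD_st      stable growth period, D_t  - D_st  (bimodal: D_t - D_st2)
GD         total growth period,  D_t  - D_o
=========  ===========================================================

Asymptotic curves never literally start or stop, so onset and
termination are fractional thresholds of W_max (defaults 5% and 95%,
configurable). D_r and D_st are the inflections of the rate curve — the
acceleration extrema flanking the rate peak.

Rhizome series fitted with the two-phase family can show two rate
maxima; the season is then split at the interior rate minimum and a
second-phase set (V_max2, D_r2, D_vmax2, D_st2, GD_sl2, GD_r2) is
extracted on the late segment, with GD_sl2 = D_r2 - D_st and
GD_r2 = D_st2 - D_r2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import growth_models as gm
from .curve_fitting import GrowthFit
from .errors import ContractError, ExtractionError

__all__ = [
    "ExtractionConfig",
    "PhenologyParams",
    "extract_phenology",
    "derive_periods",
    "mean_growth_rate",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds and grid resolution for date extraction.

    ``theta_o``/``theta_t`` are the onset/termination fractions of W_max;
    ``grid_step`` (days) controls the bracketing grid; ``season_window``
    of ``None`` means the fit's own data window.
    """

    theta_o: float = 0.05
    theta_t: float = 0.95
    grid_step: float = 0.1
    season_window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if not (0.0 < self.theta_o < self.theta_t < 1.0):
            raise ContractError("need 0 < theta_o < theta_t < 1")
        if self.grid_step <= 0:
            raise ContractError("grid_step must be positive")


@dataclass(frozen=True)
class PhenologyParams:
    """The extracted date/rate/increment set, incl. optional second phase."""

    W_max: float
    V_max: float
    D_o: float
    D_r: float
    D_vmax: float
    D_st: float
    D_t: float
    V_mean: Optional[float] = None
    GD_sl: Optional[float] = None
    GD_r: Optional[float] = None
    GD_st: Optional[float] = None
    GD: Optional[float] = None
    # second rapid phase (bimodal rhizome growth), None for unimodal fits
    V_max2: Optional[float] = None
    D_r2: Optional[float] = None
    D_vmax2: Optional[float] = None
    D_st2: Optional[float] = None
    GD_sl2: Optional[float] = None
    GD_r2: Optional[float] = None

    @property
    def bimodal(self) -> bool:
        return self.D_vmax2 is not None

    def validate_ordering(self):
        """Raise unless the date ordering and duration identities hold."""
        if not (self.D_o < self.D_r < self.D_vmax < self.D_st <= self.D_t):
            raise ContractError(
                f"date ordering violated: D_o={self.D_o}, D_r={self.D_r}, "
                f"D_vmax={self.D_vmax}, D_st={self.D_st}, D_t={self.D_t}"
            )
        if self.bimodal and not (
            self.D_st < self.D_r2 < self.D_vmax2 < self.D_st2 <= self.D_t
        ):
            raise ContractError("second-phase date ordering violated")


def mean_growth_rate(W_max: float, GD: float) -> float:
    """Mean daily growth rate, W_max / GD (trait units per day)."""
    if GD <= 0:
        raise ContractError("GD must be positive")
    return W_max / GD


def derive_periods(params: PhenologyParams) -> PhenologyParams:
    """Populate the growth-period durations from the extracted dates.

    GD_sl = D_r - D_o, GD_r = D_st - D_r, GD = D_t - D_o and
    GD_st = D_t - D_st for unimodal sets (so GD_sl + GD_r + GD_st = GD);
    bimodal sets use GD_st = D_t - D_st2 plus the phase-2 durations.
    """
    for name in ("D_o", "D_r", "D_vmax", "D_st", "D_t"):
        if getattr(params, name) is None:
            raise ContractError(f"cannot derive periods: {name} missing")
    gd = params.D_t - params.D_o
    upd = dict(
        GD_sl=params.D_r - params.D_o,
        GD_r=params.D_st - params.D_r,
        GD=gd,
        V_mean=mean_growth_rate(params.W_max, gd),
    )
    if params.bimodal:
        upd.update(
            GD_st=params.D_t - params.D_st2,
            GD_sl2=params.D_r2 - params.D_st,
            GD_r2=params.D_st2 - params.D_r2,
        )
    else:
        upd.update(GD_st=params.D_t - params.D_st)
    return replace(params, **upd)


def _refine_max(f, a: float, b: float) -> float:
    res = minimize_scalar(
        lambda x: -f(float(x)), bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _grid_argextreme(ts, vals, lo_i, hi_i, sign, f):
    """Refined arg-extreme of f over the grid slice [lo_i, hi_i]."""
    sl = vals[lo_i : hi_i + 1]
    if len(sl) < 1:
        raise ExtractionError("empty segment", parameter="acceleration")
    j = lo_i + int(np.argmax(sign * sl))
    a = ts[max(j - 1, lo_i)]
    b = ts[min(j + 1, hi_i)]
    if b <= a:
        return float(ts[j])
    return _refine_max(lambda x: sign * f(x), a, b)


def _local_extrema(ts, vals):
    """Interior local extrema of a grid-sampled curve: list of (index, kind)."""
    d = np.diff(vals)
    out = []
    for i in range(1, len(d)):
        if d[i - 1] > 0 >= d[i] or d[i - 1] >= 0 > d[i]:
            out.append((i, "max"))
        elif d[i - 1] < 0 <= d[i] or d[i - 1] <= 0 < d[i]:
            out.append((i, "min"))
    return out


def _flanking_inflection(ts, acc, f_acc, pivot, lo_t, hi_t, side):
    """Acceleration inflection flanking the rate peak at ``pivot``.

    ``side='before'`` returns the last acceleration maximum in
    (lo_t, pivot); ``side='after'`` the first acceleration minimum in
    (pivot, hi_t). Falls back to the segment arg-extreme when the grid
    shows no interior local extremum there.
    """
    cand = []
    for i, kind in _local_extrema(ts, acc):
        t = ts[i]
        if side == "before" and kind == "max" and lo_t <= t < pivot:
            cand.append(i)
        elif side == "after" and kind == "min" and pivot < t <= hi_t:
            cand.append(i)
    if cand:
        j = cand[-1] if side == "before" else cand[0]
        a, b = ts[max(j - 1, 0)], ts[min(j + 1, len(ts) - 1)]
        sign = +1.0 if side == "before" else -1.0
        return _refine_max(lambda x: sign * f_acc(x), a, b)
    lo_i = int(np.searchsorted(ts, lo_t))
    hi_i = min(int(np.searchsorted(ts, hi_t)), len(ts) - 1)
    sign = +1.0 if side == "before" else -1.0
    return _grid_argextreme(ts, acc, lo_i, max(hi_i, lo_i + 1), sign, f_acc)


def _threshold_crossing(fit, ts, ys, level, name):
    """Earliest window time with fitted value >= level (brentq-refined)."""
    idx = np.nonzero(ys >= level)[0]
    if len(idx) == 0:
        raise ExtractionError(
            f"fitted curve never reaches the {name} threshold inside the window",
            parameter=name,
        )
    i = idx[0]
    if i == 0:
        return float(ts[0])
    g = lambda x: gm.evaluate(fit.family, fit.params, float(x)) - level
    lo, hi = float(ts[i - 1]), float(ts[i])
    if g(lo) >= 0:
        return lo
    return float(brentq(g, lo, hi, xtol=1e-8))


def extract_phenology(
    fit: GrowthFit, config: ExtractionConfig = ExtractionConfig()
) -> PhenologyParams:
    """Extract the full phenological parameter set from a converged fit.

    Dates are located on a ``grid_step`` bracketing grid and refined with
    bounded scalar optimisation / root finding, so the result is accurate
    to far better than the grid step for smooth curves.
    """
    if not fit.converged:
        raise ContractError("phenology extraction requires a converged fit")
    window = config.season_window or fit.season_window
    lo, hi = float(window[0]), float(window[1])
    if not hi > lo:
        raise ContractError("empty season window")
    if fit.family is gm.ModelFamily.BIHILL:
        lo = max(lo, 1e-6)

    n = max(int(np.ceil((hi - lo) / config.grid_step)) + 1, 32)
    ts = np.linspace(lo, hi, n)
    ys = gm.evaluate(fit.family, fit.params, ts)
    acc = gm.acceleration(fit.family, fit.params, ts)

    # W_max: fitted-curve maximum over the window (refined near the grid argmax)
    j = int(np.argmax(ys))
    a, b = ts[max(j - 1, 0)], ts[min(j + 1, n - 1)]
    if b > a:
        t_wmax = _refine_max(lambda x: gm.evaluate(fit.family, fit.params, x), a, b)
        w_max = float(gm.evaluate(fit.family, fit.params, t_wmax))
    else:
        t_wmax = float(ts[j])
        w_max = float(ys[j])
    if w_max <= 0:
        raise ExtractionError("fitted curve is non-positive in the window", "W_max")

    extrema = gm.rate_extrema(fit.family, fit.params, (lo, hi), config.grid_step)
    maxima = [e for e in extrema if e.kind == "max"]
    if not maxima:
        raise ExtractionError(
            "no interior rate maximum in the window", parameter="D_vmax"
        )
    d_vmax = maxima[0].time
    v_max = maxima[0].value

    bimodal = fit.family is gm.ModelFamily.BIDOSERESP and len(maxima) >= 2
    if fit.family is gm.ModelFamily.BIDOSERESP and len(maxima) == 1:
        warnings.warn(
            "two-phase fit shows a single rate maximum; second-phase "
            "parameters left empty",
            stacklevel=2,
        )
    t_split = hi
    if bimodal:
        interior_min = [
            e for e in extrema if e.kind == "min" and maxima[0].time < e.time < maxima[1].time
        ]
        if interior_min:
            t_split = interior_min[0].time
        else:
            bimodal = False

    f_acc = lambda x: gm.acceleration(fit.family, fit.params, x)
    # stable-growth onset must precede the increment maximum: for a family
    # whose fitted curve peaks and then declines inside the window, the
    # D_st search stops at the peak, not in the post-peak decline
    phase1_end = min(t_split, t_wmax) if t_wmax > d_vmax else t_split

    d_r = _flanking_inflection(ts, acc, f_acc, d_vmax, lo, hi, "before")
    d_st = _flanking_inflection(ts, acc, f_acc, d_vmax, lo, phase1_end, "after")

    d_o = _threshold_crossing(fit, ts, ys, config.theta_o * w_max, "D_o")
    d_t = _threshold_crossing(fit, ts, ys, config.theta_t * w_max, "D_t")

    out = PhenologyParams(
        W_max=w_max, V_max=v_max, D_o=d_o, D_r=d_r,
        D_vmax=d_vmax, D_st=d_st, D_t=d_t,
    )

    if bimodal:
        d_vmax2 = maxima[1].time
        d_r2 = _flanking_inflection(ts, acc, f_acc, d_vmax2, t_split, hi, "before")
        d_st2 = _flanking_inflection(ts, acc, f_acc, d_vmax2, t_split, hi, "after")
        out = replace(
            out,
            V_max2=maxima[1].value,
            D_r2=d_r2,
            D_vmax2=d_vmax2,
            D_st2=d_st2,
        )

    out = derive_periods(out)
    out.validate_ordering()
    return out
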