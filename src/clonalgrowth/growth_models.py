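"""Seasonal growth-curve families and their time derivatives.

Three closed-form families describe the cumulative growth increment of a
trait over a growing season, indexed by day of year (DOY):

* **Logistic** (power-law dose-response form) — unimodal, saturating;
  used for plant height::

      y(t) = A2 + (A1 - A2) / (1 + (t / x0)^p)

* **BiHill** — product of an activating and an inhibitory Hill term;
  rise followed by plateau/decline, used for leaf area::

      y(t) = Pm / [(1 + (Ka/t)^Ha) * (1 + (t/Ki)^Hi)]

* **BiDoseResp** — weighted sum of two base-10 sigmoids; a bimodal growth
  rate with two rapid phases, used for rhizome length::

      y(t) = A1 + (A2 - A1) * [P / (1 + 10^((L1-t) h1))
                               + (1-P) / (1 + 10^((L2-t) h2))]

All first and second derivatives are analytic (written in terms of the
numerically stable logistic function), so downstream phenology can locate
rate maxima and acceleration extrema without finite differencing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import List, Tuple, Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .errors import ContractError, DomainError

__all__ = [
    "ModelFamily",
    "LogisticParams",
    "BiHillParams",
    "BiDoseRespParams",
    "RateExtremum",
    "evaluate",
    "rate",
    "acceleration",
    "rate_extrema",
]

ArrayLike = Union[float, np.ndarray]

LN10 = float(np.log(10.0))


class ModelFamily(enum.Enum):
    """Tag selecting one of the three growth families."""

    LOGISTIC = "logistic"
    BIHILL = "bihill"
    BIDOSERESP = "bidoseresp"

    @property
    def param_cls(self):
        return _PARAM_CLS[self]

    @property
    def n_params(self) -> int:
        return len(fields(self.param_cls))


class _ParamBase:
    """Array round-tripping shared by the parameter dataclasses."""

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "_ParamBase":
        names = [f.name for f in fields(cls)]
        if len(arr) != len(names):
            raise ContractError(
                f"{cls.__name__} expects {len(names)} values, got {len(arr)}"
            )
        return cls(**dict(zip(names, (float(v) for v in arr))))

    @classmethod
    def param_names(cls) -> Tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class LogisticParams(_ParamBase):
    """Power-law logistic: A1 initial value, A2 final value, x0 centre (DOY), p power."""

    A1: float
    A2: float
    x0: float
    p: float

    def __post_init__(self):
        if not (self.x0 > 0 and self.p > 0):
            raise ContractError("logistic requires x0 > 0 and p > 0")


@dataclass(frozen=True)
class BiHillParams(_ParamBase):
    """BiHill: Pm maximum, Ka/Ki half-maximal activating/inhibitory (DOY), Ha/Hi Hill coefficients."""

    Pm: float
    Ka: float
    Ha: float
    Ki: float
    Hi: float

    def __post_init__(self):
        vals = (self.Pm, self.Ka, self.Ha, self.Ki, self.Hi)
        if not all(v > 0 for v in vals):
            raise ContractError("all BiHill parameters must be positive")


@dataclass(frozen=True)
class BiDoseRespParams(_ParamBase):
    """Two-phase sigmoid: A1 bottom, A2 top, L1/L2 half-rise DOYs, h1/h2 slopes, P phase-1 share."""

    A1: float
    A2: float
    L1: float
    L2: float
    h1: float
    h2: float
    P: float

    def __post_init__(self):
        if not (self.h1 > 0 and self.h2 > 0):
            raise ContractError("BiDoseResp slopes h1, h2 must be positive")
        if not (0.0 <= self.P <= 1.0):
            raise ContractError("BiDoseResp proportion P must lie in [0, 1]")
        if not (self.L1 <= self.L2):
            raise ContractError("BiDoseResp requires L1 <= L2")


_PARAM_CLS = {
    ModelFamily.LOGISTIC: LogisticParams,
    ModelFamily.BIHILL: BiHillParams,
    ModelFamily.BIDOSERESP: BiDoseRespParams,
}


def _check(family: ModelFamily, params, t: ArrayLike) -> np.ndarray:
    if not isinstance(family, ModelFamily):
        raise ContractError(f"unknown model family: {family!r}")
    if not isinstance(params, family.param_cls):
        raise ContractError(
            f"{family.value} expects {family.param_cls.__name__}, "
            f"got {type(params).__name__}"
        )
    ts = np.asarray(t, dtype=float)
    if family is ModelFamily.BIHILL:
        if np.any(ts <= 0):
            raise DomainError("BiHill is undefined at t <= 0 ((Ka/t)^Ha diverges)")
    elif family is ModelFamily.LOGISTIC:
        if np.any(ts < 0):
            raise DomainError("logistic power law is undefined for t < 0")
    return ts


# -- logistic -----------------------------------------------------------------
# With z = p*ln(t/x0) and s = expit(z) = u/(1+u), u = (t/x0)^p:
#   y   = A2 + (A1 - A2)(1 - s)
#   y'  = (A2 - A1) (p/t) s (1 - s)
#   y'' = (A2 - A1) (p/t^2) s (1 - s) [(p-1)(1-s) - (p+1) s]


def _logistic_s(q: LogisticParams, t: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        z = q.p * np.log(t / q.x0)
    return expit(z)


def _logistic_eval(q: LogisticParams, t: np.ndarray) -> np.ndarray:
    return q.A2 + (q.A1 - q.A2) * (1.0 - _logistic_s(q, t))


def _logistic_rate(q: LogisticParams, t: np.ndarray) -> np.ndarray:
    s = _logistic_s(q, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (q.A2 - q.A1) * (q.p / t) * s * (1.0 - s)
    return np.where(t == 0.0, 0.0, r)


def _logistic_accel(q: LogisticParams, t: np.ndarray) -> np.ndarray:
    s = _logistic_s(q, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (
            (q.A2 - q.A1)
            * (q.p / t**2)
            * s
            * (1.0 - s)
            * ((q.p - 1.0) * (1.0 - s) - (q.p + 1.0) * s)
        )
    return np.where(t == 0.0, 0.0, a)


# -- bihill -------------------------------------------------------------------
# F = expit(Ha*ln(t/Ka)) is the activating term, G = expit(-Hi*ln(t/Ki)) the
# inhibitory one; y = Pm F G.
#   F'  = (Ha/t) F(1-F)              G'  = -(Hi/t) G(1-G)
#   F'' = (Ha/t^2) F(1-F)[Ha(1-2F)-1]
#   G'' = (Hi/t^2) G(1-G)[1+Hi(1-2G)]


def _bihill_terms(q: BiHillParams, t: np.ndarray):
    F = expit(q.Ha * np.log(t / q.Ka))
    G = expit(-q.Hi * np.log(t / q.Ki))
    return F, G


def _bihill_eval(q: BiHillParams, t: np.ndarray) -> np.ndarray:
    F, G = _bihill_terms(q, t)
    return q.Pm * F * G


def _bihill_rate(q: BiHillParams, t: np.ndarray) -> np.ndarray:
    F, G = _bihill_terms(q, t)
    dF = (q.Ha / t) * F * (1.0 - F)
    dG = -(q.Hi / t) * G * (1.0 - G)
    return q.Pm * (dF * G + F * dG)


def _bihill_accel(q: BiHillParams, t: np.ndarray) -> np.ndarray:
    F, G = _bihill_terms(q, t)
    dF = (q.Ha / t) * F * (1.0 - F)
    dG = -(q.Hi / t) * G * (1.0 - G)
    d2F = (q.Ha / t**2) * F * (1.0 - F) * (q.Ha * (1.0 - 2.0 * F) - 1.0)
    d2G = (q.Hi / t**2) * G * (1.0 - G) * (1.0 + q.Hi * (1.0 - 2.0 * G))
    return q.Pm * (d2F * G + 2.0 * dF * dG + F * d2G)


# -- bidoseresp ---------------------------------------------------------------
# Each phase is s_i = expit(k_i (t - L_i)) with k_i = h_i ln(10), so
#   s'  = k s(1-s),   s'' = k^2 s(1-s)(1-2s)


def _bdr_phase(L: float, h: float, t: np.ndarray):
    k = h * LN10
    s = expit(k * (t - L))
    ds = k * s * (1.0 - s)
    d2s = k * ds * (1.0 - 2.0 * s)
    return s, ds, d2s


def _bdr_eval(q: BiDoseRespParams, t: np.ndarray) -> np.ndarray:
    s1, _, _ = _bdr_phase(q.L1, q.h1, t)
    s2, _, _ = _bdr_phase(q.L2, q.h2, t)
    return q.A1 + (q.A2 - q.A1) * (q.P * s1 + (1.0 - q.P) * s2)


def _bdr_rate(q: BiDoseRespParams, t: np.ndarray) -> np.ndarray:
    _, ds1, _ = _bdr_phase(q.L1, q.h1, t)
    _, ds2, _ = _bdr_phase(q.L2, q.h2, t)
    return (q.A2 - q.A1) * (q.P * ds1 + (1.0 - q.P) * ds2)


def _bdr_accel(q: BiDoseRespParams, t: np.ndarray) -> np.ndarray:
    _, _, d2s1 = _bdr_phase(q.L1, q.h1, t)
    _, _, d2s2 = _bdr_phase(q.L2, q.h2, t)
    return (q.A2 - q.A1) * (q.P * d2s1 + (1.0 - q.P) * d2s2)


_DISPATCH = {
    ModelFamily.LOGISTIC: (_logistic_eval, _logistic_rate, _logistic_accel),
    ModelFamily.BIHILL: (_bihill_eval, _bihill_rate, _bihill_accel),
    ModelFamily.BIDOSERESP: (_bdr_eval, _bdr_rate, _bdr_accel),
}


def _apply(family: ModelFamily, params, t: ArrayLike, which: int) -> ArrayLike:
    ts = _check(family, params, t)
    out = _DISPATCH[family][which](params, ts)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def evaluate(family: ModelFamily, params, t: ArrayLike) -> ArrayLike:
    """Growth increment of the fitted curve at DOY ``t`` (trait units)."""
    return _apply(family, params, t, 0)


def rate(family: ModelFamily, params, t: ArrayLike) -> ArrayLike:
    """Instantaneous growth rate dy/dt at DOY ``t`` (trait units per day)."""
    return _apply(family, params, t, 1)


def acceleration(family: ModelFamily, params, t: ArrayLike) -> ArrayLike:
    """Second time derivative d2y/dt2 at DOY ``t``."""
    return _apply(family, params, t, 2)


@dataclass(frozen=True)
class RateExtremum:
    """An interior local extremum of the growth-rate curve."""

    time: float
    kind: str  # "max" or "min"
    value: float  # rate at the extremum


def rate_extrema(
    family: ModelFamily,
    params,
    window: Tuple[float, float],
    grid_step: float = 0.1,
) -> List[RateExtremum]:
    """Locate interior local maxima/minima of dy/dt within ``window``.

    A coarse grid brackets candidate extrema (sign changes of the discrete
    rate differences), each of which is then refined by bounded scalar
    optimisation of the analytic rate. Times are returned in increasing
    order. A unimodal family yields a single maximum if its rate peak lies
    inside the window; the two-phase family yields two maxima separated by
    one interior minimum when the phases are well separated.
    """
    lo, hi = float(window[0]), float(window[1])
    if not (hi > lo):
        raise ContractError(f"empty rate_extrema window [{lo}, {hi}]")
    _check(family, params, np.array([hi]))

    n = max(int(np.ceil((hi - lo) / grid_step)) + 1, 16)
    grid = np.linspace(lo, hi, n)
    if family is ModelFamily.BIHILL and grid[0] <= 0:
        grid[0] = min(1e-6, grid[1] / 2)
    r = rate(family, params, grid)

    d = np.diff(r)
    out: List[RateExtremum] = []
    for i in range(1, len(d)):
        if d[i - 1] > 0 >= d[i] or d[i - 1] >= 0 > d[i]:
            kind = "max"
        elif d[i - 1] < 0 <= d[i] or d[i - 1] <= 0 < d[i]:
            kind = "min"
        else:
            continue
        a, b = grid[i - 1], grid[i + 1]
        sign = -1.0 if kind == "max" else 1.0
        res = minimize_scalar(
            lambda x: sign * rate(family, params, float(x)),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        t_ext = float(res.x)
        # collapse duplicates from flat stretches of the grid
        if out and abs(out[-1].time - t_ext) < max(grid_step, 1e-6):
            continue
        out.append(RateExtremum(t_ext, kind, float(rate(family, params, t_ext))))
    return out
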