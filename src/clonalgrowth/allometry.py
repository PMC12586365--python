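"""Trait-pair increment ratios and standardized major axis (SMA) allometry.

The allometric growth model y = a x^b is fitted on base-10 logs,
lg y = lg a + b lg x, with SMA (reduced major axis) rather than OLS so
that measurement error in both traits is treated symmetrically:

    b = sign(r) * sd(lg y) / sd(lg x)

The allometric index b is read against isometry (b = 1): b > 1 means the
numerator trait grows proportionally faster. Following the convention in
the "Y-X" pair labels (LA-PH, RL-LA, RL-PH), the first-named trait is
the dependent y.

The slope-vs-B test uses the rotated scores u = y - B x, v = y + B x:
when the sample SMA slope equals B, u and v are uncorrelated, so
r(u, v)^2 converted to an F statistic on (1, n-2) df tests slope != B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ContractError, InsufficientDataError

__all__ = [
    "TRAIT_PAIRS",
    "SMAFit",
    "TraitPairRatio",
    "LogPairs",
    "prepare_log_pairs",
    "sma_fit",
    "test_slope",
    "increment_ratios",
]

# (label, y trait, x trait); the first trait in the label is the dependent y
TRAIT_PAIRS: Tuple[Tuple[str, str, str], ...] = (
    ("LA-PH", "leaf_area", "plant_height"),
    ("RL-LA", "rhizome_length", "leaf_area"),
    ("RL-PH", "rhizome_length", "plant_height"),
)

#: default last survey DOY included in early-season allometry (mid-July)
DEFAULT_CUTOFF_DOY = 196.0


@dataclass(frozen=True)
class SMAFit:
    """SMA slope/intercept on the lg scale with fit and slope-vs-1 tests."""

    slope_b: float
    intercept: float
    r2: float
    p_fit: float
    r2_1: float
    p_1: float
    n: int


@dataclass(frozen=True)
class TraitPairRatio:
    """Ratio of patch-mean maximum growth increments for one trait pair."""

    pair: str
    ratio: float
    patch_area_m2: float

    def __post_init__(self):
        if not self.ratio > 0:
            raise ContractError("trait-pair ratio must be positive")


@dataclass(frozen=True)
class LogPairs:
    """lg-transformed paired observations with the drop count."""

    lg_x: np.ndarray
    lg_y: np.ndarray
    n_dropped: int


def prepare_log_pairs(
    x_series: Sequence[float],
    y_series: Sequence[float],
    doys: Optional[Sequence[float]] = None,
    cutoff_doy: float = DEFAULT_CUTOFF_DOY,
) -> LogPairs:
    """Pairwise base-10 log transform of two matched survey series.

    Surveys after ``cutoff_doy`` (when ``doys`` is given) and pairs where
    either value is <= 0 (early-season zeros, not loggable) are dropped;
    the drop count is reported. Fewer than 3 surviving pairs raises
    :class:`InsufficientDataError`.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x_series and y_series must be 1-D and equal length")
    keep = np.ones(len(x), dtype=bool)
    if doys is not None:
        d = np.asarray(doys, dtype=float)
        if d.shape != x.shape:
            raise ContractError("doys must match the series length")
        keep &= d <= cutoff_doy
    x, y = x[keep], y[keep]
    pos = (x > 0) & (y > 0)
    dropped = int((~pos).sum())
    x, y = x[pos], y[pos]
    if len(x) < 3:
        raise InsufficientDataError(
            f"only {len(x)} positive pairs survive the log transform (need >= 3)"
        )
    return LogPairs(lg_x=np.log10(x), lg_y=np.log10(y), n_dropped=dropped)


def test_slope(log_pairs: LogPairs, B: float = 1.0) -> Tuple[float, float]:
    """Test whether the SMA slope differs from the hypothesised value ``B``.

    Returns ``(r2_1, p_1)`` where r2_1 = corr(y - Bx, y + Bx)^2 and p_1
    comes from F = r2_1 (n-2) / (1 - r2_1) on (1, n-2) df.
    """
    x, y = log_pairs.lg_x, log_pairs.lg_y
    n = len(x)
    if n < 3:
        raise ContractError("slope test needs n >= 3")
    u = y - B * x
    v = y + B * x
    su, sv = u.std(ddof=1), v.std(ddof=1)
    if su == 0 or sv == 0:
        # u (or v) constant: the data lie exactly on the slope +/-B line
        return 0.0, 1.0
    r = float(np.corrcoef(u, v)[0, 1])
    r2_1 = r * r
    if r2_1 >= 1.0:
        return 1.0, 0.0
    F = r2_1 * (n - 2) / (1.0 - r2_1)
    p_1 = float(stats.f.sf(F, 1, n - 2))
    return r2_1, p_1


def sma_fit(log_pairs: LogPairs) -> SMAFit:
    """Standardized major axis fit of lg y on lg x.

    slope = sign(r) sd(y)/sd(x), intercept = mean(y) - slope * mean(x);
    the fit p-value is the correlation t-test on n-2 df, and the
    slope-vs-1 statistics come from :func:`test_slope` with B = 1.
    """
    x, y = log_pairs.lg_x, log_pairs.lg_y
    n = len(x)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ContractError("zero variance in a log-transformed coordinate")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.copysign(sy / sx, r if r != 0 else 1.0))
    intercept = float(y.mean() - slope * x.mean())
    r2 = r * r
    if r2 >= 1.0:
        p_fit = 0.0
    else:
        t = abs(r) * np.sqrt((n - 2) / (1.0 - r2))
        p_fit = float(2.0 * stats.t.sf(t, n - 2))
    r2_1, p_1 = test_slope(log_pairs, B=1.0)
    return SMAFit(
        slope_b=slope, intercept=intercept, r2=r2, p_fit=p_fit,
        r2_1=r2_1, p_1=p_1, n=n,
    )


def increment_ratios(
    patch_wmax_means: Dict[float, Dict[str, float]],
) -> List[TraitPairRatio]:
    """Trait-pair ratios of patch-mean maximum growth increments.

    ``patch_wmax_means`` maps patch area (m^2) to {trait: mean W_max}.
    One record per pair per patch; a patch missing either trait of a pair
    is skipped with a warning.
    """
    import warnings

    out: List[TraitPairRatio] = []
    for area in sorted(patch_wmax_means):
        traits = patch_wmax_means[area]
        for label, y_trait, x_trait in TRAIT_PAIRS:
            if y_trait not in traits or x_trait not in traits:
                warnings.warn(
                    f"patch {area} m^2 missing {y_trait} or {x_trait}; "
                    f"skipping {label}",
                    stacklevel=2,
                )
                continue
            out.append(
                TraitPairRatio(
                    pair=label,
                    ratio=traits[y_trait] / traits[x_trait],
                    patch_area_m2=area,
                )
            )
    return out
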