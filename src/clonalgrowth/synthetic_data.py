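"""Synthetic monitoring campaigns with the structure the analysis assumes.

The generator emulates a one-year field campaign on a rhizomatous clonal
grass: five independent clonal patches spanning four orders of magnitude
in area, aboveground traits (plant height, leaf area) surveyed every 5
days from late March to early November, rhizome length surveyed every 10
days from late February to mid December. Plant height follows a
power-law logistic, leaf area a BiHill rise-and-plateau, rhizome length
a two-phase (bimodal-rate) sigmoid on top of a positive pre-season
baseline. Sexual clusters (largest patch only) carry multiplicatively
larger aboveground amplitudes and earlier centres; measurement noise is
additive Gaussian truncated at zero.

Per-patch mean generator parameters are calibrated numerically, once per
config, so that each trait's maximum increment, rate-peak date and (for
plant height) rapid-growth onset match the per-patch default targets.
All randomness flows from the single campaign seed: each series draws
its parameters and noise from a dedicated child generator keyed by
(patch, trait, reproductive type, series index).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import growth_models as gm
from .errors import ContractError

__all__ = [
    "CampaignConfig",
    "survey_schedule",
    "doy_to_date",
    "draw_cluster_params",
    "series_rng",
    "simulate_campaign",
]

CAMPAIGN_YEAR = 2021  # non-leap study calendar

#: Default per-patch target means used to calibrate generator parameters:
#: (W_max, D_vmax, D_r) for plant height, (W_max, D_vmax) for leaf area,
#: (W_max, D_vmax phase 1, D_vmax phase 2) for rhizome length.
DEFAULT_TARGETS = {
    "plant_height": [
        (76.0, 110.0, 98.0),
        (70.0, 111.0, 100.0),
        (71.0, 106.0, 96.0),
        (76.0, 111.0, 99.0),
        (74.0, 107.0, 97.0),
    ],
    "leaf_area": [
        (249.0, 151.0, 130.0),
        (221.0, 158.0, 131.0),
        (208.0, 147.0, 124.0),
        (229.0, 132.0, 117.0),
        (266.0, 142.0, 122.0),
    ],
    "rhizome_length": [
        (94.0, 171.0, 251.0),
        (153.0, 177.0, 258.0),
        (200.0, 164.0, 259.0),
        (202.0, 156.0, 262.0),
        (173.0, 161.0, 256.0),
    ],
}

_TRAIT_CODE = {"plant_height": 0, "leaf_area": 1, "rhizome_length": 2}
_TYPE_CODE = {"asexual": 0, "sexual": 1, "not_applicable": 2}


def doy_to_date(doy: int, year: int = CAMPAIGN_YEAR) -> _dt.date:
    return _dt.date(year, 1, 1) + _dt.timedelta(days=int(doy) - 1)


def survey_schedule(start: _dt.date, end: _dt.date, step_days: int) -> List[int]:
    """Survey dates start, start+step, ... (last <= end), as DOY (Jan 1 = 1)."""
    if start > end:
        raise ContractError("schedule start must not be after end")
    if step_days < 1:
        raise ContractError("step_days must be >= 1")
    out = []
    d = start
    while d <= end:
        out.append(d.timetuple().tm_yday)
        d += _dt.timedelta(days=step_days)
    return out


@dataclass(frozen=True)
class CampaignConfig:
    """Study-design and noise settings for one simulated campaign."""

    patch_areas_m2: Tuple[float, ...] = (0.51, 2.29, 201.11, 312.93, 36075.0)
    asexual_clusters_per_patch: Tuple[int, ...] = (2, 3, 7, 5, 8)
    sexual_clusters_largest_patch: int = 6
    rhizomes_per_patch: Tuple[int, ...] = (2, 3, 7, 5, 17)
    aboveground_schedule: Tuple[str, str, int] = ("2021-03-25", "2021-11-05", 5)
    rhizome_schedule: Tuple[str, str, int] = ("2021-02-25", "2021-12-15", 10)
    noise_sd_fraction: float = 0.02
    sexual_Wmax_multiplier_leaf: float = 1.8
    sexual_Wmax_multiplier_height: float = 1.7
    sexual_center_shift_days: float = -8.0
    rhizome_baseline_cm: Tuple[float, float] = (30.0, 60.0)
    between_cluster_cv: float = 0.15
    timing_sd_days: float = 4.0
    trait_targets: Optional[Dict[str, list]] = None
    seed: int = 0

    def __post_init__(self):
        npatch = len(self.patch_areas_m2)
        if (
            len(self.asexual_clusters_per_patch) != npatch
            or len(self.rhizomes_per_patch) != npatch
        ):
            raise ContractError("per-patch count lists must match the patch count")
        if self.noise_sd_fraction < 0:
            raise ContractError("noise_sd_fraction must be >= 0")
        if not (
            self.sexual_Wmax_multiplier_leaf > 1
            and self.sexual_Wmax_multiplier_height > 1
        ):
            raise ContractError("sexual multipliers must exceed 1")

    def schedule_doys(self, trait: str) -> List[int]:
        sched = (
            self.rhizome_schedule
            if trait == "rhizome_length"
            else self.aboveground_schedule
        )
        start = _dt.date.fromisoformat(sched[0])
        end = _dt.date.fromisoformat(sched[1])
        return survey_schedule(start, end, sched[2])

    def targets(self) -> Dict[str, list]:
        return self.trait_targets or DEFAULT_TARGETS


# ---------------------------------------------------------------------------
# calibration of per-patch mean parameters from target phenology

_CAL_WINDOW = (40.0, 349.0)


def _d_vmax(family, params) -> float:
    ext = gm.rate_extrema(family, params, _CAL_WINDOW, grid_step=0.25)
    maxima = [e for e in ext if e.kind == "max"]
    if not maxima:
        raise ContractError("calibration: no rate maximum in window")
    return maxima[0].time


def _d_r_logistic(params: gm.LogisticParams) -> float:
    ts = np.arange(_CAL_WINDOW[0], params.x0, 0.05)
    acc = gm.acceleration(gm.ModelFamily.LOGISTIC, params, ts)
    return float(ts[int(np.argmax(acc))])


@lru_cache(maxsize=None)
def _calibrate_logistic(w_max: float, d_vmax: float, d_r: float) -> gm.LogisticParams:
    """Choose (x0, p) so the dy/dt peak and acceleration peak hit the targets."""

    def make(p: float) -> gm.LogisticParams:
        x0 = d_vmax / ((p - 1.0) / (p + 1.0)) ** (1.0 / p)
        return gm.LogisticParams(A1=0.0, A2=w_max, x0=x0, p=p)

    def gap(p: float) -> float:
        return _d_r_logistic(make(p)) - d_r

    p = brentq(gap, 2.5, 39.0, xtol=1e-4)
    return make(p)


@lru_cache(maxsize=None)
def _calibrate_bihill(w_max: float, d_vmax: float, d_r: float) -> gm.BiHillParams:
    """Solve (Ka, Ha) for the rate-peak and rapid-onset dates, scale Pm.

    The activation steepness Ha controls how far the rapid-growth onset
    (last acceleration maximum before the rate peak) precedes the rate
    peak; for each candidate Ha, Ka is solved so the rate peak lands on
    its target. The inhibitory term (decline after the seasonal peak) is
    kept gentle and late: Ki = 2 * D_vmax, Hi = 8.
    """
    hi = 8.0
    ki = 2.0 * d_vmax

    def make(ka: float, ha: float, pm: float = 1.0) -> gm.BiHillParams:
        return gm.BiHillParams(Pm=pm, Ka=ka, Ha=ha, Ki=ki, Hi=hi)

    def solve_ka(ha: float) -> float:
        return brentq(
            lambda ka: _d_vmax(gm.ModelFamily.BIHILL, make(ka, ha)) - d_vmax,
            60.0, 330.0, xtol=1e-3,
        )

    def d_r_of(ha: float) -> float:
        q = make(solve_ka(ha), ha)
        ts = np.arange(_CAL_WINDOW[0], d_vmax, 0.05)
        acc = gm.acceleration(gm.ModelFamily.BIHILL, q, ts)
        return float(ts[int(np.argmax(acc))])

    ha = brentq(lambda h: d_r_of(h) - d_r, 3.0, 30.0, xtol=1e-3)
    ka = solve_ka(ha)
    ts = np.arange(*_CAL_WINDOW, 0.1)
    shape_max = float(gm.evaluate(gm.ModelFamily.BIHILL, make(ka, ha), ts).max())
    return make(ka, ha, pm=w_max / shape_max)


def _calibrate_bidoseresp(
    w_max: float, d_vmax1: float, d_vmax2: float
) -> gm.BiDoseRespParams:
    # well-separated phases: each rate peak sits at its half-rise location
    return gm.BiDoseRespParams(
        A1=0.0, A2=w_max, L1=d_vmax1, L2=d_vmax2, h1=0.05, h2=0.08, P=0.6
    )


def mean_params(config: CampaignConfig, patch_index: int, trait: str):
    """Calibrated per-patch mean generator parameters for one trait."""
    targets = config.targets()[trait][patch_index]
    if trait == "plant_height":
        return _calibrate_logistic(*targets)
    if trait == "leaf_area":
        return _calibrate_bihill(*targets)
    if trait == "rhizome_length":
        return _calibrate_bidoseresp(*targets)
    raise ContractError(f"unknown trait {trait!r}")


# ---------------------------------------------------------------------------
# per-series parameter draws

_AMPLITUDE = {"plant_height": ("A2",), "leaf_area": ("Pm",), "rhizome_length": ("A2",)}
_LOCATION = {
    "plant_height": ("x0",),
    "leaf_area": ("Ka", "Ki"),
    "rhizome_length": ("L1", "L2"),
}
_SHAPE = {
    "plant_height": ("p",),
    "leaf_area": ("Ha", "Hi"),
    "rhizome_length": ("h1", "h2"),
}


def series_rng(
    config: CampaignConfig,
    patch_index: int,
    trait: str,
    reproductive_type: str,
    series_index: int,
) -> np.random.Generator:
    """Deterministic child generator for one series of the campaign."""
    seq = np.random.SeedSequence(
        entropy=config.seed,
        spawn_key=(
            patch_index,
            _TRAIT_CODE[trait],
            _TYPE_CODE[reproductive_type],
            series_index,
        ),
    )
    return np.random.default_rng(seq)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def draw_cluster_params(
    config: CampaignConfig,
    patch_index: int,
    trait: str,
    reproductive_type: str,
    rng: np.random.Generator,
):
    """Draw one series' family parameters around the patch means.

    Amplitudes are lognormal with CV ``between_cluster_cv`` (mean exactly
    the configured value); all location parameters of a series share one
    Gaussian shift (SD ``timing_sd_days``); shape parameters get a mild
    lognormal jitter. Sexual clusters multiply aboveground amplitudes by
    the configured factor and shift their centres earlier.
    """
    if trait not in _TRAIT_CODE:
        raise ContractError(f"unknown trait {trait!r}")
    base = mean_params(config, patch_index, trait)
    vals = {name: getattr(base, name) for name in base.param_names()}

    amp = _lognormal_factor(rng, config.between_cluster_cv)
    shift = float(rng.normal(0.0, config.timing_sd_days))
    for name in _AMPLITUDE[trait]:
        vals[name] *= amp
    for name in _LOCATION[trait]:
        vals[name] += shift
    for name in _SHAPE[trait]:
        vals[name] *= _lognormal_factor(rng, config.between_cluster_cv / 3.0)
    if trait == "rhizome_length":
        vals["P"] = float(np.clip(vals["P"] + rng.normal(0.0, 0.05), 0.05, 0.95))

    if reproductive_type == "sexual":
        mult = (
            config.sexual_Wmax_multiplier_leaf
            if trait == "leaf_area"
            else config.sexual_Wmax_multiplier_height
        )
        for name in _AMPLITUDE[trait]:
            vals[name] *= mult
        for name in _LOCATION[trait]:
            vals[name] += config.sexual_center_shift_days

    return type(base)(**vals)


# ---------------------------------------------------------------------------
# campaign assembly


def _series_plan(config: CampaignConfig):
    """Yield (patch_index, trait, reproductive_type, series_index, series_id)."""
    largest = int(np.argmax(config.patch_areas_m2))
    for pi in range(len(config.patch_areas_m2)):
        for trait in ("plant_height", "leaf_area"):
            for si in range(config.asexual_clusters_per_patch[pi]):
                yield pi, trait, "asexual", si, f"P{pi + 1}-A{si + 1}"
            if pi == largest:
                for si in range(config.sexual_clusters_largest_patch):
                    yield pi, trait, "sexual", si, f"P{pi + 1}-S{si + 1}"
        for si in range(config.rhizomes_per_patch[pi]):
            yield pi, "rhizome_length", "not_applicable", si, f"P{pi + 1}-R{si + 1}"


def simulate_campaign(config: CampaignConfig = CampaignConfig()) -> pd.DataFrame:
    """Simulate one long-format monitoring table.

    One row per (series, survey): calendar date, patch area, series id,
    reproductive type, trait, measured value. Aboveground values start
    near zero at the first survey; rhizome values ride on their positive
    pre-season baseline and are non-decreasing when the noise fraction
    is zero.
    """
    rows = []
    family_of = {
        "plant_height": gm.ModelFamily.LOGISTIC,
        "leaf_area": gm.ModelFamily.BIHILL,
        "rhizome_length": gm.ModelFamily.BIDOSERESP,
    }
    for pi, trait, rtype, si, sid in _series_plan(config):
        rng = series_rng(config, pi, trait, rtype, si)
        params = draw_cluster_params(config, pi, trait, rtype, rng)
        doys = np.array(config.schedule_doys(trait), dtype=float)
        model = gm.evaluate(family_of[trait], params, doys)
        if trait == "rhizome_length":
            baseline = float(rng.uniform(*config.rhizome_baseline_cm))
            model = baseline + model
            span = float(params.A2)
        else:
            span = float(getattr(params, "A2", getattr(params, "Pm", 1.0)))
        if config.noise_sd_fraction > 0:
            noise = rng.normal(0.0, config.noise_sd_fraction * span, size=len(doys))
            values = np.maximum(model + noise, 0.0)
        else:
            values = np.maximum(model, 0.0)
        for doy, val in zip(doys, values):
            rows.append(
                {
                    "date": doy_to_date(int(doy)).isoformat(),
                    "patch_area_m2": config.patch_areas_m2[pi],
                    "series_id": sid,
                    "reproductive_type": rtype,
                    "trait": trait,
                    "value": float(val),
                }
            )
    return pd.DataFrame(rows)
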