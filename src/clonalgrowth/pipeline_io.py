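"""Reading/writing monitoring tables, preprocessing and the full pipeline.

The canonical input is a long (tidy) table with one row per measurement:
``date, patch_area_m2, series_id, reproductive_type, trait, value``.
Dates are converted to day of year (DOY, Jan 1 = 1). Aboveground traits
are recorded as growth increments starting from zero each season;
rhizome length is measured on its pre-season baseline, so rhizome series
are converted to increments by subtracting the first measurement.

:func:`run_pipeline` chains the full analysis — read/simulate, per-series
curve fitting, phenology extraction, population and patch statistics,
trait-pair ratios, SMA allometry, lg-area spline trends — and writes
machine-readable CSV tables plus a run manifest. All randomness is
derived from the single pipeline seed, and the written tables are
byte-identical across reruns with equal configs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline

from . import __version__
from . import allometry as al
from . import group_stats as gs
from . import phenology as ph
from .curve_fitting import (
    TRAIT_FAMILY,
    TRAITS,
    FitConfig,
    GrowthFit,
    TraitSeries,
    fit_series,
)
from .errors import (
    ClonalGrowthError,
    ContractError,
    InsufficientDataError,
    SchemaError,
)
from .synthetic_data import CampaignConfig, simulate_campaign

__all__ = [
    "REQUIRED_COLUMNS",
    "PatchSummary",
    "PipelineConfig",
    "read_monitoring_table",
    "write_monitoring_table",
    "series_from_frame",
    "rhizome_baseline_correct",
    "patch_means",
    "spline_trend",
    "run_pipeline",
]

log = logging.getLogger("clonalgrowth")

REQUIRED_COLUMNS = (
    "date",
    "patch_area_m2",
    "series_id",
    "reproductive_type",
    "trait",
    "value",
)

#: phenology fields reported in tables, in print order
PHENOLOGY_FIELDS = (
    "W_max", "V_max", "V_mean",
    "D_o", "D_r", "D_vmax", "D_st", "D_t",
    "GD_sl", "GD_r", "GD_st", "GD",
    "V_max2", "D_r2", "D_vmax2", "D_st2", "GD_sl2", "GD_r2",
)


def write_monitoring_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _to_doy(dates: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(dates, errors="coerce", format="mixed")
    bad = parsed.isna()
    if bad.any():
        rows = list(dates.index[bad][:5] + 2)  # 1-based incl. header
        raise SchemaError(f"unparseable date(s) at file row(s) {rows}")
    return parsed.dt.dayofyear


def series_from_frame(df: pd.DataFrame) -> List[TraitSeries]:
    """Validate a long-format monitoring frame and split it into series."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if "reproductive_type" in missing and "type" in df.columns:
        df = df.rename(columns={"type": "reproductive_type"})
        missing.remove("reproductive_type")
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["doy"] = _to_doy(df["date"])
    neg = df.index[pd.to_numeric(df["value"], errors="coerce") < 0]
    if len(neg):
        raise SchemaError(f"negative value(s) at file row(s) {list(neg[:5] + 2)}")
    dup = df.duplicated(subset=["series_id", "trait", "doy"])
    if dup.any():
        rows = list(df.index[dup][:5] + 2)
        raise SchemaError(f"duplicate (series, trait, date) row(s) at {rows}")

    out: List[TraitSeries] = []
    for (sid, trait), grp in df.groupby(["series_id", "trait"], sort=True):
        grp = grp.sort_values("doy")
        out.append(
            TraitSeries(
                series_id=str(sid),
                patch_area_m2=float(grp["patch_area_m2"].iloc[0]),
                trait=str(trait),
                reproductive_type=str(grp["reproductive_type"].iloc[0]),
                doys=grp["doy"].to_numpy(dtype=float),
                increments=grp["value"].to_numpy(dtype=float),
            )
        )
    return out


def read_monitoring_table(path, format: Optional[str] = None) -> List[TraitSeries]:
    """Read a long-format monitoring table (CSV or spreadsheet).

    ``format`` is inferred from the extension when omitted. Returns one
    :class:`TraitSeries` per (series_id, trait), sorted rows by DOY.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    fmt = format
    if fmt is None:
        fmt = "spreadsheet" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "spreadsheet":
        df = pd.read_excel(path)
    else:
        raise ContractError(f"unknown format {fmt!r}")
    return series_from_frame(df)


def rhizome_baseline_correct(series: TraitSeries) -> TraitSeries:
    """Convert measured rhizome lengths to increments past the baseline.

    The first measurement is the pre-season baseline; every value has it
    subtracted, so the first increment is exactly zero. Measurement noise
    can push later readings marginally below the baseline; such
    increments are floored at zero.
    """
    if series.trait != "rhizome_length":
        raise ContractError("baseline correction applies to rhizome_length only")
    if len(series) < 1:
        raise ContractError("empty series")
    inc = series.increments - series.increments[0]
    return replace(series, increments=np.maximum(inc, 0.0))


def patch_means(records: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    """Per (patch, trait) mean, SD and count of the given value columns."""
    for c in ("patch_area_m2", "trait"):
        if c not in records.columns:
            raise ContractError(f"records need a {c!r} column")
    agg = {c: ["mean", "std", "count"] for c in value_cols}
    out = records.groupby(["patch_area_m2", "trait"], sort=True).agg(agg)
    out.columns = [f"{c}_{s}" for c, s in out.columns]
    return out.reset_index()


def spline_trend(
    lg_areas: Sequence[float],
    values: Sequence[float],
    n_grid: int = 100,
    degree: int = 3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Interpolating B-spline of a patch-level statistic over lg area.

    Degree falls back (with a warning) when there are fewer than
    ``degree + 1`` points. Returns the evaluation grid and curve.
    """
    import warnings

    x = np.asarray(lg_areas, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 2:
        raise ContractError("need matching 1-D inputs with at least 2 points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        raise ContractError("lg_areas must be distinct")
    k = degree
    if len(x) < degree + 1:
        k = len(x) - 1
        warnings.warn(
            f"only {len(x)} points; spline degree reduced to {k}", stacklevel=2
        )
    spl = make_interp_spline(x, y, k=k)
    grid = np.linspace(x[0], x[-1], n_grid)
    return grid, spl(grid)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings."""

    theta_o: float = 0.05
    theta_t: float = 0.95
    grid_step: float = 0.1
    allometry_cutoff_doy: float = al.DEFAULT_CUTOFF_DOY
    alpha: float = 0.05
    marginal: float = 0.10
    seed: int = 0
    n_starts: int = 8
    out_dir: str = "results"
    campaign: CampaignConfig = field(default_factory=CampaignConfig)

    def fit_config(self) -> FitConfig:
        return FitConfig(n_starts=self.n_starts, seed=self.seed)

    def extraction_config(self) -> ph.ExtractionConfig:
        return ph.ExtractionConfig(
            theta_o=self.theta_o, theta_t=self.theta_t, grid_step=self.grid_step
        )


@dataclass(frozen=True)
class PatchSummary:
    """Per-patch aggregate: lg area, per-trait phenology means, ratios."""

    patch_area_m2: float
    lg_area: float
    trait_means: Dict[str, Dict[str, float]]
    series_counts: Dict[str, int]
    ratios: Dict[str, float]


def _phen_to_dict(p: ph.PhenologyParams) -> Dict[str, float]:
    return {f: getattr(p, f) for f in PHENOLOGY_FIELDS if getattr(p, f) is not None}


def _fit_all(
    series_list: List[TraitSeries], config: PipelineConfig
) -> Tuple[List[Tuple[TraitSeries, GrowthFit, ph.PhenologyParams]], List[dict]]:
    """Fit + extract every series; collect structured per-series failures."""
    done, failures = [], []
    fc = config.fit_config()
    ec = config.extraction_config()
    for s in series_list:
        work = rhizome_baseline_correct(s) if s.trait == "rhizome_length" else s
        try:
            fit = fit_series(work, TRAIT_FAMILY[s.trait], fc)
            if not fit.converged:
                failures.append(
                    {"series_id": s.series_id, "trait": s.trait, "stage": "fit",
                     "error": f"not converged (at bounds: {fit.at_bounds})"}
                )
                continue
            phen = ph.extract_phenology(fit, ec)
        except ClonalGrowthError as exc:
            failures.append(
                {"series_id": s.series_id, "trait": s.trait,
                 "stage": "fit/phenology", "error": str(exc)}
            )
            continue
        done.append((s, fit, phen))
    return done, failures


def _phenology_frame(done) -> pd.DataFrame:
    rows = []
    for s, fit, phen in done:
        row = {
            "series_id": s.series_id,
            "trait": s.trait,
            "patch_area_m2": s.patch_area_m2,
            "reproductive_type": s.reproductive_type,
            "family": fit.family.value,
            "adj_r2": fit.adj_r2,
        }
        row.update(_phen_to_dict(phen))
        rows.append(row)
    return pd.DataFrame(rows)


def _comparison_rows(comparisons: List[gs.GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for g, n, m, sd in zip(c.groups, c.n_per_group, c.means, c.sds):
            rows.append(
                {
                    "parameter": c.parameter,
                    "group": g,
                    "n": n,
                    "mean": m,
                    "sd": sd,
                    "letters": c.letters[g],
                    "method": c.method,
                    "homogeneity_p": c.homogeneity_p,
                    "F": c.F,
                    "p": c.p,
                    "significant": c.p <= 0.05,
                    "marginal": c.marginal,
                    "low_power": c.low_power,
                }
            )
    return pd.DataFrame(rows)


def _group_compare_frame(
    phen: pd.DataFrame, group_col: str, params: Sequence[str]
) -> pd.DataFrame:
    comparisons = []
    for param in params:
        sub = phen.dropna(subset=[param]) if param in phen.columns else phen.iloc[0:0]
        if param not in phen.columns or sub.empty:
            continue
        groups = {
            str(g): grp[param].to_numpy()
            for g, grp in sub.groupby(group_col)
            if len(grp) >= 2
        }
        if len(groups) < 2:
            continue
        comparisons.append(gs.compare_groups(param, groups))
    return _comparison_rows(comparisons)


def _survey_patch_means(
    series_list: List[TraitSeries], trait: str, asexual_only: bool
) -> Dict[float, Dict[float, float]]:
    """patch area -> {DOY: mean increment across that patch's series}."""
    acc: Dict[float, Dict[float, List[float]]] = {}
    for s in series_list:
        if s.trait != trait:
            continue
        if asexual_only and s.reproductive_type == "sexual":
            continue
        work = rhizome_baseline_correct(s) if trait == "rhizome_length" else s
        d = acc.setdefault(s.patch_area_m2, {})
        for doy, v in zip(work.doys, work.increments):
            d.setdefault(float(doy), []).append(float(v))
    return {
        area: {doy: float(np.mean(vals)) for doy, vals in sorted(doys.items())}
        for area, doys in acc.items()
    }


def _match_surveys(
    x_by_doy: Dict[float, float], y_by_doy: Dict[float, float], tol_days: float = 2.0
) -> Tuple[List[float], List[float], List[float]]:
    """Pair y surveys with the nearest x survey within ``tol_days``.

    The field schedule measures belowground traits on every second
    aboveground visit, so a small matching tolerance reconstructs the
    paired surveys when the nominal schedules are offset.
    """
    xs = np.array(sorted(x_by_doy))
    doys, xv, yv = [], [], []
    for dy in sorted(y_by_doy):
        j = int(np.argmin(np.abs(xs - dy)))
        if abs(xs[j] - dy) <= tol_days:
            doys.append(dy)
            xv.append(x_by_doy[float(xs[j])])
            yv.append(y_by_doy[dy])
    return doys, xv, yv


def _sma_table(
    series_list: List[TraitSeries], config: PipelineConfig
) -> Tuple[pd.DataFrame, List[dict]]:
    by_trait = {
        "plant_height": _survey_patch_means(series_list, "plant_height", True),
        "leaf_area": _survey_patch_means(series_list, "leaf_area", True),
        "rhizome_length": _survey_patch_means(series_list, "rhizome_length", False),
    }
    rows, problems = [], []
    areas = sorted({s.patch_area_m2 for s in series_list})
    for label, y_trait, x_trait in al.TRAIT_PAIRS:
        for area in areas:
            xm = by_trait[x_trait].get(area, {})
            ym = by_trait[y_trait].get(area, {})
            doys, xv, yv = _match_surveys(xm, ym)
            try:
                pairs = al.prepare_log_pairs(
                    xv, yv, doys=doys, cutoff_doy=config.allometry_cutoff_doy
                )
                fit = al.sma_fit(pairs)
            except (InsufficientDataError, ContractError) as exc:
                problems.append({"pair": label, "patch_area_m2": area, "error": str(exc)})
                continue
            rows.append(
                {
                    "pair": label,
                    "patch_area_m2": area,
                    "slope": fit.slope_b,
                    "intercept": fit.intercept,
                    "r2": fit.r2,
                    "p": fit.p_fit,
                    "r2_1": fit.r2_1,
                    "p_1": fit.p_1,
                    "n": fit.n,
                    "n_dropped": pairs.n_dropped,
                }
            )
    return pd.DataFrame(rows), problems


def _patch_summaries(
    phen: pd.DataFrame, ratios: List[al.TraitPairRatio]
) -> List[PatchSummary]:
    out = []
    ratio_by_area: Dict[float, Dict[str, float]] = {}
    for r in ratios:
        ratio_by_area.setdefault(r.patch_area_m2, {})[r.pair] = r.ratio
    for area, grp in phen.groupby("patch_area_m2"):
        trait_means, counts = {}, {}
        for trait, tgrp in grp.groupby("trait"):
            cols = [c for c in PHENOLOGY_FIELDS if c in tgrp.columns]
            trait_means[trait] = {
                c: float(tgrp[c].mean()) for c in cols if tgrp[c].notna().any()
            }
            counts[trait] = int(len(tgrp))
        out.append(
            PatchSummary(
                patch_area_m2=float(area),
                lg_area=float(np.log10(area)),
                trait_means=trait_means,
                series_counts=counts,
                ratios=ratio_by_area.get(float(area), {}),
            )
        )
    return out


def _trend_frame(summaries: List[PatchSummary]) -> pd.DataFrame:
    """Spline trends of each patch-mean parameter over lg area."""
    rows = []
    by_trait: Dict[str, Dict[str, List[Tuple[float, float]]]] = {}
    for s in summaries:
        for trait, means in s.trait_means.items():
            for param, val in means.items():
                by_trait.setdefault(trait, {}).setdefault(param, []).append(
                    (s.lg_area, val)
                )
    for trait, params in sorted(by_trait.items()):
        for param, pts in sorted(params.items()):
            if len(pts) < 2:
                continue
            x, y = zip(*sorted(pts))
            grid, curve = spline_trend(x, y)
            for gx, gy in zip(grid, curve):
                rows.append(
                    {"trait": trait, "parameter": param, "lg_area": gx, "value": gy}
                )
    return pd.DataFrame(rows)


def _render_report(out_dir: Path, tables: Dict[str, pd.DataFrame]) -> str:
    lines = ["clonalgrowth analysis report", "=" * 28, ""]
    for name, df in tables.items():
        lines.append(name)
        lines.append("-" * len(name))
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    input_path=None,
    simulate: bool = False,
) -> Dict[str, object]:
    """Execute the full analysis and write the report bundle.

    Either ``input_path`` (long-format CSV/spreadsheet) or
    ``simulate=True`` must be given. Returns a dict with the output
    directory, the tables, patch summaries and the manifest.
    """
    if simulate == (input_path is not None):
        raise ContractError("provide exactly one of input_path or simulate=True")
    t_start = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_log: List[str] = []

    def stage(name):
        log.info("stage %-12s at %7.2fs", name, time.perf_counter() - t_start)

    stage("input")
    if simulate:
        campaign_cfg = dataclasses.replace(config.campaign, seed=config.seed)
        df = simulate_campaign(campaign_cfg)
        write_monitoring_table(df, out_dir / "campaign.csv")
        series_list = series_from_frame(df)
    else:
        series_list = read_monitoring_table(input_path)

    stage("fit")
    done, failures = _fit_all(series_list, config)
    phen = _phenology_frame(done)
    if phen.empty:
        raise ClonalGrowthError("no series could be fitted; nothing to report")

    stage("stats")
    pop_params = [f for f in PHENOLOGY_FIELDS if not f.endswith("2")]
    population = _group_compare_frame(phen, "trait", pop_params)

    largest = phen["patch_area_m2"].max()
    sexual_zone = phen[
        (phen["patch_area_m2"] == largest)
        & (phen["trait"].isin(["plant_height", "leaf_area"]))
    ]
    sexual_rows = []
    for trait, tgrp in sexual_zone.groupby("trait"):
        sub = _group_compare_frame(tgrp, "reproductive_type", pop_params)
        if not sub.empty:
            sub.insert(0, "trait", trait)
            sexual_rows.append(sub)
    sexual = (
        pd.concat(sexual_rows, ignore_index=True) if sexual_rows else pd.DataFrame()
    )

    stage("patches")
    # across-patch tables use asexual clusters only for aboveground traits
    comparable = phen[
        (phen["trait"] == "rhizome_length")
        | (phen["reproductive_type"] != "sexual")
    ]
    patch_table = patch_means(
        comparable, [c for c in PHENOLOGY_FIELDS if c in comparable.columns]
    )
    wmax_means: Dict[float, Dict[str, float]] = {}
    for (area, trait), grp in comparable.groupby(["patch_area_m2", "trait"]):
        wmax_means.setdefault(float(area), {})[trait] = float(grp["W_max"].mean())
    ratios = al.increment_ratios(wmax_means)
    ratio_df = pd.DataFrame(
        [
            {"pair": r.pair, "patch_area_m2": r.patch_area_m2,
             "lg_area": np.log10(r.patch_area_m2), "ratio": r.ratio}
            for r in ratios
        ]
    )

    stage("allometry")
    sma, sma_problems = _sma_table(series_list, config)

    stage("trends")
    summaries = _patch_summaries(comparable, ratios)
    trends = _trend_frame(summaries)

    stage("write")
    tables = {
        "phenology": phen,
        "population_comparison": population,
        "patch_phenology": patch_table,
        "sexual_vs_asexual": sexual,
        "increment_ratios": ratio_df,
        "sma_allometry": sma,
        "trends": trends,
    }
    for name, tab in tables.items():
        tab.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "report.txt").write_text(_render_report(out_dir, tables))

    n_in = len(series_list)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "series_in": n_in,
        "series_converged": len(done),
        "series_failed": len(failures),
        "failures": failures,
        "sma_skipped": sma_problems,
        "warnings": warnings_log,
    }
    assert manifest["series_converged"] + manifest["series_failed"] == n_in
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stage("done")
    return {
        "out_dir": out_dir,
        "tables": tables,
        "summaries": summaries,
        "manifest": manifest,
    }
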