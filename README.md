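# clonalgrowth

Growth-curve phenology and allometric resource-allocation analysis for
season-long monitoring of clonal plants — built around the study design
used for rhizomatous dune grasses such as *Psammochloa villosa*, where
plant height, leaf area and rhizome length are surveyed through a
growing season across clonal patches spanning four orders of magnitude
in area.

## What it computes

**Growth families.** Each trait's cumulative growth increment *y(t)*
(DOY-indexed) is fitted by nonlinear least squares to one of three
families:

| Trait | Family | Form |
|---|---|---|
| plant height | logistic | y = A₂ + (A₁ − A₂) / (1 + (t/x₀)ᵖ) |
| leaf area | BiHill | y = Pₘ / [(1 + (Kₐ/t)^Hₐ)(1 + (t/Kᵢ)^Hᵢ)] |
| rhizome length | BiDoseResp | y = A₁ + (A₂ − A₁)[P/(1+10^((L₁−t)h₁)) + (1−P)/(1+10^((L₂−t)h₂))] |

The two-phase BiDoseResp family captures the bimodal rhizome rate curve
(an early-summer and a September rapid phase).

**Phenology.** From the fitted curve and its analytic derivatives:
W_max (maximum increment), V_max and D_vmax (rate peak), D_o/D_t (5%/95%
of W_max crossings), D_r/D_st (acceleration extrema flanking the rate
peak), the durations GD_sl = D_r − D_o, GD_r = D_st − D_r,
GD_st = D_t − D_st, GD = D_t − D_o, and V_mean = W_max/GD. Bimodal fits
additionally report the second-phase set (V_max2, D_r2, D_vmax2, D_st2,
GD_sl2, GD_r2).

**Allocation across patch sizes.** Trait-pair increment ratios (LA-PH,
RL-LA, RL-PH), standardized major axis (SMA) allometry on base-10 logs
(lg y = lg a + b·lg x, slope b = sign(r)·sd(y)/sd(x)) with the
slope-vs-isometry test (scores u = y − Bx, v = y + Bx; F on corr(u,v)²),
group comparison (Brown–Forsythe homogeneity check, classic/Welch
one-way F, LSD or Games–Howell post hoc, compact letter display), and
cubic B-spline trends of patch means along lg area.

**Synthetic campaigns.** `clonalgrowth.synthetic_data` simulates the full
monitoring design — 5 patches (0.51–36,075 m²), 5-day aboveground and
10-day rhizome survey cadences, between-cluster variation, sexual
clusters in the largest patch, rhizome baselines and truncated-Gaussian
measurement noise — so every pipeline stage is testable without field
data.

## Worked example

```python
from clonalgrowth import (
    FitConfig, ModelFamily, fit_series, extract_phenology,
)
from clonalgrowth.synthetic_data import CampaignConfig, simulate_campaign
from clonalgrowth.pipeline_io import series_from_frame, rhizome_baseline_correct

# simulate one season of monitoring and pull out a single rhizome series
campaign = simulate_campaign(CampaignConfig(seed=1))
series = [s for s in series_from_frame(campaign)
          if s.trait == "rhizome_length" and s.series_id == "P3-R1"][0]
increments = rhizome_baseline_correct(series)   # subtract pre-season baseline

fit = fit_series(increments, ModelFamily.BIDOSERESP, FitConfig(seed=1))
phen = extract_phenology(fit)

print(f"adjusted R^2 = {fit.adj_r2:.4f}")
print(f"W_max  = {phen.W_max:6.1f} cm     V_max  = {phen.V_max:.2f} cm/day")
print(f"D_o    = {phen.D_o:6.1f} DOY    D_vmax = {phen.D_vmax:.1f} DOY")
print(f"D_t    = {phen.D_t:6.1f} DOY    GD     = {phen.GD:.1f} days")
print(f"second phase: D_vmax2 = {phen.D_vmax2:.1f} DOY, V_max2 = {phen.V_max2:.2f} cm/day")
print(f"V_mean = {phen.V_mean:.2f} cm/day")
```

which prints:

```
adjusted R^2 = 0.9979
W_max  =  135.2 cm     V_max  = 3.03 cm/day
D_o    =  137.1 DOY    D_vmax = 158.5 DOY
D_t    =  268.9 DOY    GD     = 131.8 days
second phase: D_vmax2 = 256.8 DOY, V_max2 = 1.46 cm/day
V_mean = 1.03 cm/day
```

Reading: this rhizome added 135 cm over a 132-day growth period; the
first rapid phase peaked in early June (DOY 158) at 3.0 cm/day and a
weaker second phase peaked in mid September (DOY 257) — the bimodal,
long-season belowground pattern, in contrast to the compact unimodal
aboveground traits.

The full pipeline (fit → phenology → group statistics → ratios →
SMA allometry → lg-area trends) runs from the shell:

```sh
clonalgrowth run-all --simulate --seed 1 --out-dir results
```

writing `phenology.csv`, `population_comparison.csv`,
`patch_phenology.csv`, `sexual_vs_asexual.csv`, `increment_ratios.csv`,
`sma_allometry.csv`, `trends.csv`, `report.txt` and `manifest.json`.

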