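# Methods

This note documents the models, numerical choices and known limits of
the `clonalgrowth` pipeline, in the package's own terms.

## Growth families and derivatives

Three closed-form families describe cumulative seasonal growth
increments over day of year (DOY, Jan 1 = 1, the study calendar is the
non-leap year 2021):

* **Logistic (power-law form)**, `y = A2 + (A1 − A2)/(1 + (t/x0)^p)`,
  for plant height. On the log-time axis this is a symmetric sigmoid
  centred at `x0`; on the linear day axis the rate maximum sits at
  `x0·((p−1)/(p+1))^{1/p}`, slightly *before* `x0` (for `x0 = 110`,
  `p = 8`: DOY 106.6). All phenology here is defined with respect to
  calendar-time derivatives (units per day), since the reported rates
  V_max and V_mean are daily rates — so D_vmax is the dy/dt maximum,
  not the curve centre.
* **BiHill**, `y = Pm/[(1+(Ka/t)^Ha)(1+(t/Ki)^Hi)]`, for leaf area:
  an activating Hill rise times an inhibitory Hill decline, capturing a
  rise to a seasonal peak with a late-season decrease of mean leaf area
  per ramet.
* **BiDoseResp**, a P:(1−P) mixture of two base-10 sigmoids with
  half-rise locations L1 < L2, for rhizome length: a bimodal rate curve
  with two rapid phases. L1/L2 are locations on the DOY axis itself (the
  curve is fitted against DOY, and the fitted half-rise dates in the
  per-patch summaries are plain DOY); the 10^ base of the original
  dose-response parameterization is kept, so slopes h are per-day with
  an extra ln 10 factor in the rate.

First and second derivatives are analytic, written with the numerically
stable logistic function (`scipy.special.expit`), and are verified in
the tests against central difference quotients (1e-6 relative for
dy/dt with step 1e-4 d; 1e-4 relative for d²y/dt² with step 1e-2 d —
the larger step balances truncation against round-off in f/h²).
Rate extrema are bracketed on a 0.1-d grid and refined by bounded
scalar minimisation (xatol 1e-8).

Domain conventions: BiHill is undefined at t ≤ 0 (refused), the
power-law logistic at t < 0; BiDoseResp accepts any real t.

## Curve fitting

`fit_series` minimises unweighted squared residuals with scipy's
trust-region-reflective `least_squares` under per-family box bounds
keyed to the observed span and season (e.g. amplitudes within
0.3–3× the observed maximum, locations within ±50% of the season).
Initialisation is data-driven — half-rise crossings for centres, a
log-log regression for the logistic power, and a smoothed empirical
rate split at its interior minimum for the two-phase family. Eight
starts are run by default: the heuristic start plus seven jittered
copies (±25% log-uniform on positive parameters), all derived from the
single `FitConfig.seed`; the best final cost wins. The two phases of
BiDoseResp are exchangeable, so iterates are canonicalised to L1 ≤ L2
(swapping (L, h) and P ↔ 1−P), which keeps the parameter dataclass
invariants valid during optimisation.

A fit is reported `converged` only when the optimiser succeeded and no
*location or amplitude* parameter is pinned to its box edge; baselines,
the mixture proportion and the shape/steepness coefficients may
legitimately sit on a bound (e.g. a plateau season gives a weakly
identified inhibitory exponent). Constant or all-zero series are
rejected (`DegenerateSeriesError`) rather than force-fitted — their
phenology would be meaningless. Goodness of fit is the adjusted R²,
`1 − (1 − R²)(n − 1)/(n − k − 1)`.

Raw (not standardized) increments are fitted; `standardize_series`
(scale to unit maximum) exists for display only.

## Phenology extraction

The extractor works on the fitted curve, not the raw points:

* **W_max** is the curve maximum over the season window — not the
  asymptote parameter — so declining tails and finite seasons are
  handled uniformly.
* **D_o / D_t** are the earliest window times where the curve reaches
  θ_o·W_max and θ_t·W_max (defaults 5% and 95%, configurable):
  asymptotic curves never literally start or stop, so onset and
  termination must be fractional thresholds.
* **D_vmax / V_max** come from the first rate maximum; for bimodal fits
  the season is split at the interior rate minimum and the second
  phase's set (V_max2, D_r2, D_vmax2, D_st2) is extracted identically
  on the late segment.
* **D_r / D_st** are the inflections of the rate curve: the *last*
  acceleration maximum before the rate peak and the *first* acceleration
  minimum after it. The D_st search is additionally bounded by the
  curve's peak time, so that for a rise-then-decline family the strong
  deceleration at the seasonal turn-over is never mistaken for the
  onset of stable growth. This inflection-based definition was chosen
  because it reproduces the near-symmetry of the published plant-height
  dates about D_vmax; threshold-fraction alternatives can be emulated
  through the configurable θ values.

Dates are bracketed on a θ-independent 0.1-d grid and refined with
`brentq`/bounded minimisation; the test suite checks every extracted
date against a 0.001-d brute-force scan. Durations follow the
identities GD_sl = D_r − D_o, GD_r = D_st − D_r, GD = D_t − D_o, with
GD_st = D_t − D_st for unimodal fits (so GD_sl + GD_r + GD_st = GD) and
GD_st = D_t − D_st2, GD_sl2 = D_r2 − D_st, GD_r2 = D_st2 − D_r2 for
bimodal fits. Every extraction validates the full date ordering and
raises rather than returning an inconsistent record.

## Group statistics

Brown–Forsythe (median-centred Levene) checks homogeneity; p ≤ 0.05
routes the comparison to Welch's F with Games–Howell post hoc,
otherwise classic one-way ANOVA with Fisher's LSD. Compact letters are
assigned by insert-and-absorb, alphabetical from the largest mean, and
are consistent with the pairwise p matrix by construction (property-
tested). A marginal band 0.05 < p < 0.10 and a low-power flag (any
group with n ≤ 2, e.g. a micro patch with two clusters) are reported
rather than suppressing results. Note Welch's F equals the classic F
only for two groups with equal sample variances; with k ≥ 3 the
denominator correction keeps them O(1/n) apart even then.

## Allometry

SMA slopes use observed patch-mean values at each survey before the
early-season cutoff (default DOY 196, mid-July — aboveground growth has
stabilized by then while rhizomes continue), not fitted daily values.
In the pair labels LA-PH, RL-LA, RL-PH the first trait is the dependent
y, so slope b > 1 reads "the first trait gains proportionally faster".
Logs are base 10; pairs with a non-positive member (early-season zeros)
are dropped pairwise and counted. Belowground/aboveground pairs are
matched to the nearest aboveground survey within 2 days, mirroring the
paired field schedule in which every second belowground visit coincides
with an aboveground one. The slope-vs-B test uses the rotated scores
u = y − Bx, v = y + Bx whose correlation vanishes exactly when the
sample SMA slope equals B; r²(u,v) is converted to F on (1, n−2) df.
Aboveground patch means use asexual clusters only, for comparability
across patches (sexual clusters exist only in the largest patch).

## Synthetic campaigns

The generator emulates the study design: five patches of 0.51, 2.29,
201.11, 312.93 and 36,075 m² with 2/3/7/5/8 asexual clusters,
2/3/7/5/17 rhizomes, and 6 sexual clusters in the largest patch;
aboveground surveys every 5 days from 2021-03-25 to 2021-11-05 (46
dates by the inclusive rule) and rhizome surveys every 10 days from
2021-02-25 to 2021-12-15 (30 dates). Per-patch mean parameters are
*calibrated*, once per configuration, so that each trait's W_max,
rate-peak date(s) and (for the unimodal aboveground traits) rapid-onset
date land on the configured per-patch targets; shape values the targets
do not pin are fixed defaults (Hi = 8, Ki = 2·D_vmax; h1 = 0.05,
h2 = 0.08, P = 0.6).

Between-cluster variation is lognormal with CV 0.15 on amplitude
parameters; all location parameters of a series share one Gaussian
shift (SD 4 d — per-patch date spreads in this design imply a far
smaller CV than the amplitudes); shape parameters get a mild lognormal
jitter (CV 0.05). Sexual clusters multiply aboveground amplitudes by
1.8 (leaf) / 1.7 (height) and shift centres 8 d earlier. Measurement
noise is additive Gaussian, SD = 2% of the series span, truncated at
zero — ruler/leaf-meter error with no autocorrelation. Rhizome series
ride on a uniform 30–60 cm pre-season baseline and are non-decreasing
when noise is off. All randomness derives from the single campaign
seed through per-series `SeedSequence` children keyed by (patch, trait,
type, index), so equal configurations reproduce byte-identical tables.

What the generator does **not** emulate: spatial structure within
patches, sand-burial events, resource integration between ramets,
autocorrelated measurement error, missing surveys, or multi-year
dynamics. Passing tests therefore demonstrate the correctness of the
estimation and reporting machinery under the stated statistical shape
of the data — not robustness to every field pathology.

## Identifiability limit of the two-phase slopes

At 2%-of-span noise the multistart estimator is unbiased and reaches
the Cramér–Rao bound for every parameter (verified numerically).
For the BiDoseResp family at population-typical values on the 10-day
belowground cadence, the bound itself puts the relative SD of the
phase-slope parameters at ≈9% (h1) and ≈17% (h2): a sharp sigmoid step
spans only 2–4 surveys, so no estimator can pin its steepness to a few
percent at this noise level. Locations, amplitudes and the phase
proportion are recovered to well under 2%. The recovery test suite
asserts a 5% median-error target per parameter; it passes for the
logistic and BiHill families and fails, expectedly and by this bound,
for the BiDoseResp slopes. Derived phenology is essentially unaffected
(rate-peak dates depend on L1/L2, which are recovered to fractions of
a day).

## Other numerical choices and limitations

* Rhizome baseline correction subtracts the first measurement; noisy
  readings marginally below the baseline are floored at zero, matching
  the generator's truncation.
* lg-area trends use interpolating cubic B-splines (degree reduced with
  a warning below 4 points); with one patch per size class these are
  descriptive visual aids, not inferential fits.
* The pipeline never silently drops a series: input = converged +
  failed is asserted and reconciled in the run manifest, and per-series
  failures carry the stage and reason.
* Report tables are plain CSV plus a text rendering; figures are out of
  scope.
* N = 1 patch per size class in the emulated design: across-patch
  contrasts are descriptive (splines, ratios), and only within-patch
  contrasts (sexual vs asexual) and across-trait population contrasts
  get formal tests — the same analysis boundary the monitoring design
  imposes.
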