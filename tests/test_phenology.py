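"""Phenological parameter extraction and duration identities."""

import numpy as np
import pytest

from clonalgrowth import (
    ExtractionConfig,
    FitConfig,
    GrowthFit,
    ModelFamily,
    PhenologyParams,
    derive_periods,
    evaluate,
    extract_phenology,
    fit_series,
    mean_growth_rate,
    rate,
    acceleration,
)
from clonalgrowth.errors import ContractError

from conftest import (
    ABOVEGROUND_DOYS,
    BDR_POP,
    BIHILL_POP,
    LOGISTIC_POP,
    RHIZOME_DOYS,
    random_valid_params,
    sample_series,
)


def _fit_of(family, params, window):
    """Wrap exact parameters as a converged fit (no estimation involved)."""
    return GrowthFit(
        family=family, params=params, adj_r2=1.0, rss=0.0, n_obs=50,
        converged=True, season_window=window,
    )


def brute_force_extraction(fit, config, step=0.001):
    """Dense-grid scan oracle: plain argmax/argmin and threshold scans."""
    lo, hi = fit.season_window
    ts = np.arange(max(lo, 1e-6), hi + step, step)
    y = evaluate(fit.family, fit.params, ts)
    r = rate(fit.family, fit.params, ts)
    a = acceleration(fit.family, fit.params, ts)
    w = y.max()
    # interior rate maxima / minima
    rmax = [i for i in range(1, len(r) - 1) if r[i] >= r[i - 1] and r[i] > r[i + 1]]
    rmin = [i for i in range(1, len(r) - 1) if r[i] <= r[i - 1] and r[i] < r[i + 1]]
    i_vmax = rmax[0]
    i_peak = int(np.argmax(y))
    bimodal = fit.family is ModelFamily.BIDOSERESP and len(rmax) >= 2
    i_split = (
        [i for i in rmin if rmax[0] < i < rmax[1]][0] if bimodal else len(ts) - 1
    )
    i_end = min(i_split, i_peak) if i_peak > i_vmax else i_split
    amax = [i for i in range(1, len(a) - 1) if a[i] >= a[i - 1] and a[i] > a[i + 1]]
    amin = [i for i in range(1, len(a) - 1) if a[i] <= a[i - 1] and a[i] < a[i + 1]]
    d_r = ts[[i for i in amax if i < i_vmax][-1]]
    d_st = ts[[i for i in amin if i_vmax < i <= i_end][0]]
    d_o = ts[np.nonzero(y >= config.theta_o * w)[0][0]]
    d_t = ts[np.nonzero(y >= config.theta_t * w)[0][0]]
    out = dict(
        W_max=w, V_max=r[i_vmax], D_o=d_o, D_r=d_r, D_vmax=ts[i_vmax],
        D_st=d_st, D_t=d_t,
    )
    if bimodal:
        i_vmax2 = rmax[1]
        out.update(
            D_vmax2=ts[i_vmax2],
            D_r2=ts[[i for i in amax if i_split < i < i_vmax2][-1]],
            D_st2=ts[[i for i in amin if i > i_vmax2][0]],
        )
    return out


class TestExtraction:
    @pytest.mark.parametrize(
        "family,params,window",
        [
            (ModelFamily.LOGISTIC, LOGISTIC_POP, (60.0, 330.0)),
            (ModelFamily.BIHILL, BIHILL_POP, (60.0, 330.0)),
            (ModelFamily.BIDOSERESP, BDR_POP, (56.0, 349.0)),
        ],
    )
    def test_matches_brute_force_dense_grid(self, family, params, window):
        config = ExtractionConfig()
        fit = _fit_of(family, params, window)
        got = extract_phenology(fit, config)
        want = brute_force_extraction(fit, config)
        for key, val in want.items():
            assert getattr(got, key) == pytest.approx(val, abs=config.grid_step), key

    def test_bimodal_rate_peaks_near_phase_locations(self):
        # with well-separated phases the rate peaks sit at the half-rise DOYs
        fit = _fit_of(ModelFamily.BIDOSERESP, BDR_POP, (56.0, 349.0))
        p = extract_phenology(fit)
        assert p.bimodal
        assert p.D_vmax == pytest.approx(162.0, abs=2.0)
        assert p.D_vmax2 == pytest.approx(256.0, abs=2.0)
        assert p.D_st < p.D_r2 < p.D_vmax2 < p.D_st2 <= p.D_t

    @pytest.mark.parametrize("family", list(ModelFamily))
    def test_ordering_and_identities_on_random_draws(self, family, rng):
        """Date ordering and duration identities hold for every successful
        extraction over random valid parameter draws."""
        window = (56.0, 349.0)
        n_ok = 0
        for _ in range(25):
            q = random_valid_params(family, rng)
            fit = _fit_of(family, q, window)
            try:
                p = extract_phenology(fit)
            except Exception:
                continue  # thresholds can fall outside a random window
            n_ok += 1
            assert p.D_o < p.D_r < p.D_vmax < p.D_st <= p.D_t
            assert p.GD == pytest.approx(p.D_t - p.D_o)
            assert p.GD_sl == pytest.approx(p.D_r - p.D_o)
            assert p.GD_r == pytest.approx(p.D_st - p.D_r)
            assert p.V_mean == pytest.approx(p.W_max / p.GD)
            if not p.bimodal:
                assert p.GD_sl + p.GD_r + p.GD_st == pytest.approx(p.GD)
            else:
                assert p.GD_st == pytest.approx(p.D_t - p.D_st2)
        assert n_ok >= 15  # the draws are overwhelmingly extractable

    def test_threshold_monotonicity(self):
        fit = _fit_of(ModelFamily.LOGISTIC, LOGISTIC_POP, (60.0, 330.0))
        base = extract_phenology(fit, ExtractionConfig(theta_o=0.05, theta_t=0.90))
        later = extract_phenology(fit, ExtractionConfig(theta_o=0.08, theta_t=0.97))
        assert later.D_o >= base.D_o
        assert later.D_t >= base.D_t

    def test_nonconverged_fit_rejected(self):
        bad = GrowthFit(
            family=ModelFamily.LOGISTIC, params=LOGISTIC_POP, adj_r2=0.5,
            rss=1.0, n_obs=10, converged=False, season_window=(60.0, 330.0),
        )
        with pytest.raises(ContractError):
            extract_phenology(bad)

    def test_round_trip_recovers_rate_peak_date(self):
        """Generate -> fit -> extract recovers D_vmax within 3 days at 2% noise."""
        for family, params, doys, trait, target in [
            (ModelFamily.LOGISTIC, LOGISTIC_POP, ABOVEGROUND_DOYS, "plant_height", None),
            (ModelFamily.BIDOSERESP, BDR_POP, RHIZOME_DOYS, "rhizome_length", None),
        ]:
            truth = extract_phenology(
                _fit_of(family, params, (doys[0], doys[-1]))
            )
            s = sample_series(family, params, doys, trait, noise_fraction=0.02, seed=13)
            fit = fit_series(s, family, FitConfig(seed=13))
            got = extract_phenology(fit)
            assert got.D_vmax == pytest.approx(truth.D_vmax, abs=3.0)


class TestDerivePeriods:
    def _params(self, d_o, d_r, d_vmax, d_st, d_t, w_max=100.0):
        return PhenologyParams(
            W_max=w_max, V_max=1.0, D_o=d_o, D_r=d_r, D_vmax=d_vmax,
            D_st=d_st, D_t=d_t,
        )

    def test_leaf_area_population_means(self):
        # printed population mean dates for leaf area
        p = derive_periods(self._params(86, 122, 141, 161, 209))
        assert p.GD_sl == 36
        assert p.GD_r == 39
        assert p.GD_st == 48
        assert p.GD == 123

    def test_rhizome_population_means(self):
        p = derive_periods(self._params(77, 141, 162, 182, 316))
        assert p.GD == 239
        assert p.GD_sl == 64

    def test_telescoping_sum(self, rng):
        for _ in range(20):
            d = np.sort(rng.uniform(50, 340, size=5))
            p = derive_periods(self._params(*d))
            assert p.GD_sl + p.GD_r + p.GD_st == pytest.approx(p.GD)


class TestMeanGrowthRate:
    def test_micro_patch_plant_height_cell(self):
        # printed means W_max = 76 cm, GD = 73 d round to the printed 1.0 cm/day
        assert round(mean_growth_rate(76.0, 73.0), 1) == 1.0

    def test_zero_increment(self):
        assert mean_growth_rate(0.0, 50.0) == 0.0

    def test_linear_in_w_max(self):
        assert mean_growth_rate(152.0, 73.0) == pytest.approx(
            2 * mean_growth_rate(76.0, 73.0)
        )

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ContractError):
            mean_growth_rate(76.0, 0.0)
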