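"""Closed-form growth families: values, derivatives, extrema."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalgrowth import (
    BiDoseRespParams,
    BiHillParams,
    LogisticParams,
    ModelFamily,
    acceleration,
    evaluate,
    rate,
    rate_extrema,
)
from clonalgrowth.errors import ContractError, DomainError

from conftest import BDR_POP, BIHILL_POP, FAMILY_CASES, LOGISTIC_POP, random_valid_params


class TestEvaluate:
    def test_logistic_midpoint(self):
        # at t = x0 the power term equals 1, so y is the A1/A2 midpoint
        assert evaluate(ModelFamily.LOGISTIC, LOGISTIC_POP, 110.0) == pytest.approx(50.0)

    def test_logistic_asymptotes(self):
        # conservation: A1 at t -> 0+, A2 at t -> inf (p >= 4)
        q = LOGISTIC_POP
        assert evaluate(ModelFamily.LOGISTIC, q, q.x0 / 100) == pytest.approx(q.A1, abs=1e-9)
        assert evaluate(ModelFamily.LOGISTIC, q, q.x0 * 100) == pytest.approx(q.A2, abs=1e-9)

    def test_bidoseresp_sigmoid_limits(self):
        q = BiDoseRespParams(A1=0, A2=1, L1=150, L2=250, h1=0.05, h2=0.08, P=0.5)
        assert evaluate(ModelFamily.BIDOSERESP, q, -1e4) == pytest.approx(0.0, abs=1e-12)
        assert evaluate(ModelFamily.BIDOSERESP, q, 1e4) == pytest.approx(1.0, abs=1e-12)

    def test_bihill_against_arbitrary_precision_formula(self):
        # independent term-by-term evaluation of the published expression
        t = sympy.Rational(120)
        pm, ka, ha, ki, hi = [sympy.Rational(v) for v in (249, 120, 6, 260, 8)]
        expected = float(
            sympy.N(pm / ((1 + (ka / t) ** ha) * (1 + (t / ki) ** hi)), 50)
        )
        assert evaluate(ModelFamily.BIHILL, BIHILL_POP, 120.0) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("family,params,doys,_t", FAMILY_CASES)
    def test_values_finite_and_bounded(self, family, params, doys, _t):
        y = evaluate(family, params, doys)
        assert np.all(np.isfinite(y))
        if family is ModelFamily.BIHILL:
            assert np.all((y >= 0) & (y <= params.Pm))
        else:
            lo, hi = min(params.A1, params.A2), max(params.A1, params.A2)
            assert np.all((y >= lo - 1e-9) & (y <= hi + 1e-9))

    def test_bihill_rejects_nonpositive_time(self):
        with pytest.raises(DomainError):
            evaluate(ModelFamily.BIHILL, BIHILL_POP, 0.0)

    def test_family_params_mismatch(self):
        with pytest.raises(ContractError):
            evaluate(ModelFamily.LOGISTIC, BIHILL_POP, 100.0)


class TestDerivatives:
    def test_logistic_rate_value_at_center(self):
        # closed form p(A2-A1)/(4 x0) at the curve centre
        q = LOGISTIC_POP
        assert rate(ModelFamily.LOGISTIC, q, q.x0) == pytest.approx(
            q.p * (q.A2 - q.A1) / (4 * q.x0)
        )

    @pytest.mark.parametrize("family", list(ModelFamily))
    def test_rate_matches_central_difference(self, family, rng):
        # 50 random (params, t) draws against a step-1e-4 difference quotient
        for _ in range(50):
            q = random_valid_params(family, rng)
            t = float(rng.uniform(60, 330))
            h = 1e-4
            num = (evaluate(family, q, t + h) - evaluate(family, q, t - h)) / (2 * h)
            assert rate(family, q, t) == pytest.approx(num, rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize("family", list(ModelFamily))
    def test_acceleration_matches_second_difference(self, family, rng):
        for _ in range(50):
            q = random_valid_params(family, rng)
            t = float(rng.uniform(60, 330))
            h = 1e-2  # balances O(h^2) truncation against round-off in f/h^2
            num = (
                evaluate(family, q, t + h)
                - 2 * evaluate(family, q, t)
                + evaluate(family, q, t - h)
            ) / h**2
            assert acceleration(family, q, t) == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_rate_nonnegative_for_monotone_families(self, rng):
        ts = np.linspace(1.0, 400.0, 500)
        for _ in range(20):
            qL = random_valid_params(ModelFamily.LOGISTIC, rng)
            qB = random_valid_params(ModelFamily.BIDOSERESP, rng)
            assert np.all(rate(ModelFamily.LOGISTIC, qL, ts) >= 0)
            assert np.all(rate(ModelFamily.BIDOSERESP, qB, ts) >= 0)

    def test_acceleration_sign_flips_at_rate_peak(self):
        # positive before the rate maximum, negative after (unimodal rate)
        (ext,) = rate_extrema(ModelFamily.LOGISTIC, LOGISTIC_POP, (60, 330))
        assert acceleration(ModelFamily.LOGISTIC, LOGISTIC_POP, ext.time - 5) > 0
        assert acceleration(ModelFamily.LOGISTIC, LOGISTIC_POP, ext.time + 5) < 0
        assert acceleration(ModelFamily.LOGISTIC, LOGISTIC_POP, ext.time) == pytest.approx(
            0.0, abs=1e-6
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(p=st.floats(0.02, 0.15), L=st.floats(100, 200))
    def test_bidoseresp_degenerates_to_single_sigmoid(self, p, L):
        """P=1 (and L1=L2, h1=h2) collapse to one sigmoid pointwise."""
        ts = np.linspace(30, 330, 101)
        one = BiDoseRespParams(A1=0, A2=100, L1=L, L2=L + 50, h1=p, h2=p / 2, P=1.0)
        single = 100.0 / (1.0 + 10.0 ** ((L - ts) * p))
        np.testing.assert_allclose(
            evaluate(ModelFamily.BIDOSERESP, one, ts), single, atol=1e-12
        )
        both = BiDoseRespParams(A1=0, A2=100, L1=L, L2=L, h1=p, h2=p, P=0.3)
        np.testing.assert_allclose(
            evaluate(ModelFamily.BIDOSERESP, both, ts), single, atol=1e-12
        )


def _dense_grid_rate_argmaxes(family, params, window, step=0.01):
    ts = np.arange(window[0], window[1] + step, step)
    if ts[0] <= 0:
        ts = ts[ts > 0]
    r = rate(family, params, ts)
    idx = [
        i
        for i in range(1, len(r) - 1)
        if r[i] >= r[i - 1] and r[i] > r[i + 1]
    ]
    return [float(ts[i]) for i in idx]


class TestRateExtrema:
    def test_logistic_single_maximum_matches_grid(self):
        ext = rate_extrema(ModelFamily.LOGISTIC, LOGISTIC_POP, (60, 330))
        assert [e.kind for e in ext] == ["max"]
        (grid_t,) = _dense_grid_rate_argmaxes(ModelFamily.LOGISTIC, LOGISTIC_POP, (60, 330))
        assert ext[0].time == pytest.approx(grid_t, abs=0.02)

    def test_bidoseresp_two_maxima_match_dense_grid(self):
        ext = rate_extrema(ModelFamily.BIDOSERESP, BDR_POP, (56, 349))
        kinds = [e.kind for e in ext]
        assert kinds == ["max", "min", "max"]
        grid = _dense_grid_rate_argmaxes(ModelFamily.BIDOSERESP, BDR_POP, (56, 349))
        assert len(grid) == 2
        for e, g in zip([ext[0], ext[2]], grid):
            assert e.time == pytest.approx(g, abs=2.0)

    def test_bihill_rate_peak_precedes_curve_peak(self):
        ext = rate_extrema(ModelFamily.BIHILL, BIHILL_POP, (60, 330))
        maxima = [e for e in ext if e.kind == "max"]
        assert len(maxima) == 1
        ts = np.arange(60, 330, 0.01)
        t_peak = ts[np.argmax(evaluate(ModelFamily.BIHILL, BIHILL_POP, ts))]
        assert maxima[0].time < t_peak

    def test_times_sorted(self):
        ext = rate_extrema(ModelFamily.BIDOSERESP, BDR_POP, (56, 349))
        times = [e.time for e in ext]
        assert times == sorted(times)

    def test_empty_window_rejected(self):
        with pytest.raises(ContractError):
            rate_extrema(ModelFamily.LOGISTIC, LOGISTIC_POP, (200, 100))
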