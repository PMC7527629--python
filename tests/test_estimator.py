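"""Two-time-point selection estimator and its mutation-selection trade-off."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from moranselect import (
    InvalidParameterError,
    MeanCurveParams,
    TwoPointObservation,
    alpha_of,
    estimate_s_given_u,
    estimates_to_frame,
    mean_frequency,
    odds,
    read_observations,
    sensitivity_to_lambda,
    tradeoff_curve,
)


def make_obs(y0=0.2, y1=0.5, dt_years=5.0, lam=24.0, **kw):
    return TwoPointObservation(y0=y0, y1=y1, dt_years=dt_years, lam=lam, **kw)


class TestAlphaAndOdds:
    @pytest.mark.parametrize(
        "y, u, expected",
        [
            (0.5, 0.0, 1.0),
            (0.24, 0.0, 0.76 / 0.24),   # reciprocal of the tabulated odds 0.32
            (0.2, 0.1, 0.8 / 0.3),
        ],
    )
    def test_examples(self, y, u, expected):
        assert alpha_of(y, u) == pytest.approx(expected, rel=1e-12)

    def test_alpha_decreasing_in_y_and_u(self):
        assert alpha_of(0.3, 0.0) > alpha_of(0.4, 0.0)
        assert alpha_of(0.3, 0.0) > alpha_of(0.3, 0.2)

    def test_alpha_times_odds_is_one_at_u_zero(self):
        for y in (0.05, 0.24, 0.83):
            assert alpha_of(y, 0.0) * odds(y) == pytest.approx(1.0, rel=1e-12)

    def test_domain(self):
        with pytest.raises(InvalidParameterError):
            alpha_of(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            alpha_of(0.5, -0.1)
        with pytest.raises(InvalidParameterError):
            odds(0.0)


class TestEstimateS:
    def test_aml_phase_row_reproduces_printed_value(self):
        # y0=0.56 -> y1=0.83 over 3 years at 24 divisions/year prints 0.019
        res = estimate_s_given_u(make_obs(y0=0.56, y1=0.83, dt_years=3.0), u=0.0)
        assert round(res.s_hat, 3) == 0.019
        assert res.dt_generations == 72.0

    def test_no_change_gives_zero(self):
        assert estimate_s_given_u(make_obs(y1=0.2), 0.0).s_hat == 0.0

    @pytest.mark.parametrize("s_true", [0.002, 0.01, 0.03, 0.05])
    def test_roundtrip_with_mean_field_curve(self, s_true):
        y0, lam, dt_years = 0.2, 24.0, 6.0
        y1 = mean_frequency(lam * dt_years, MeanCurveParams(y0=y0, s=s_true, mu=0.0))
        res = estimate_s_given_u(make_obs(y0=y0, y1=y1, dt_years=dt_years, lam=lam))
        assert res.s_hat == pytest.approx(s_true, abs=1e-10)

    def test_u_zero_equals_log_odds_rate(self):
        obs = make_obs()
        expected = math.log(odds(obs.y1) / odds(obs.y0)) / obs.dt_generations
        assert estimate_s_given_u(obs, 0.0).s_hat == pytest.approx(expected, rel=1e-14)

    @given(
        y0=st.floats(0.01, 0.99),
        y1=st.floats(0.01, 0.99),
        dt=st.floats(0.1, 20.0),
    )
    def test_sign_follows_frequency_change(self, y0, y1, dt):
        s_hat = estimate_s_given_u(make_obs(y0=y0, y1=y1, dt_years=dt)).s_hat
        if y1 > y0:
            assert s_hat > 0
        elif y1 < y0:
            assert s_hat < 0

    def test_mu_implied_is_u_times_s(self):
        res = estimate_s_given_u(make_obs(), u=0.05)
        assert res.mu_implied == pytest.approx(0.05 * res.s_hat, rel=1e-14)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            make_obs(y1=1.0)
        with pytest.raises(InvalidParameterError):
            make_obs(dt_years=0.0)
        with pytest.raises(InvalidParameterError):
            estimate_s_given_u(make_obs(), u=-0.01)


class TestTradeoffCurve:
    def test_single_point_grid(self):
        obs = make_obs()
        (only,) = tradeoff_curve(obs, [0.0])
        assert only.s_hat == estimate_s_given_u(obs, 0.0).s_hat

    def test_monotone_nonincreasing_for_growing_clone(self):
        obs = make_obs(y0=0.13, y1=0.15, dt_years=2.9)
        u_grid = np.linspace(0.0, 1.0, 1001)
        s = np.array([r.s_hat for r in tradeoff_curve(obs, u_grid)])
        assert np.all(np.diff(s) <= 1e-15)
        # continuity: steps shrink with the grid, no jumps
        assert np.max(np.abs(np.diff(s))) < 0.05 * s[0]

    def test_small_u_changes_little(self):
        obs = make_obs(y0=0.13, y1=0.15, dt_years=2.9)
        s0 = estimate_s_given_u(obs, 0.0).s_hat
        s_small = estimate_s_given_u(obs, 1e-3).s_hat
        assert abs(s_small - s0) / s0 < 0.01


class TestLambdaSensitivity:
    def test_printed_value_and_exact_halving(self):
        obs = make_obs(y0=0.43, y1=0.65, dt_years=0.75)
        res24, res48 = sensitivity_to_lambda(obs, [24.0, 48.0])
        assert round(res24.s_hat, 3) == 0.050
        assert res48.s_hat == pytest.approx(res24.s_hat / 2, rel=1e-12)

    def test_product_with_lambda_invariant(self):
        obs = make_obs()
        results = sensitivity_to_lambda(obs, [6.0, 24.0, 365.0], u=0.02)
        products = [r.s_hat * lam for r, lam in zip(results, [6.0, 24.0, 365.0])]
        assert products[0] == pytest.approx(products[1], rel=1e-12)
        assert products[1] == pytest.approx(products[2], rel=1e-12)

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(InvalidParameterError):
            sensitivity_to_lambda(make_obs(), [24.0, 0.0])


class TestCsvInterface:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text(
            "case_id,y0,y1,dt_years,lambda,phase\n"
            "a,0.2,0.5,5.0,24,MDS\n"
            "b,0.1,0.3,4.5,24,AML\n"
        )
        observations = read_observations(path)
        assert [o.case_id for o in observations] == ["a", "b"]
        assert observations[0].phase == "MDS"
        results = [estimate_s_given_u(o) for o in observations]
        frame = estimates_to_frame(observations, results)
        assert list(frame["s_hat"]) == [r.s_hat for r in results]
        assert round(frame.loc[1, "s_hat"], 3) == 0.012

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("case_id,y0\nx,0.2\n")
        with pytest.raises(InvalidParameterError):
            read_observations(path)
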