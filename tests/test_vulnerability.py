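import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from heatmargin.vulnerability import (SigmaPolicy, binary_risk, daily_tsm,
                                      exceedance_probability, overheating_days,
                                      tsm_summary, weighted_mean_se)


class TestDailyTsm:
    @pytest.mark.parametrize("ct, tmax, expected",
                             [(36, 30, 6), (30, 36, -6), (25, 25, 0)])
    def test_sign_convention(self, ct, tmax, expected):
        assert daily_tsm(ct, tmax) == expected


class TestWeightedMeanSe:
    def test_hand_formula(self):
        mean, se = weighted_mean_se([10.0, 20.0], [1.0, 2.0])
        assert mean == pytest.approx(12.0)
        assert se == pytest.approx(np.sqrt(1 / 1.25))

    def test_equal_ses_arithmetic_mean(self, rng):
        vals = rng.normal(10, 2, 20)
        mean, _ = weighted_mean_se(vals, np.full(20, 0.7))
        assert mean == pytest.approx(vals.mean())

    def test_single_value_identity(self):
        mean, se = weighted_mean_se([5.0], [0.3])
        assert mean == 5.0
        assert se == pytest.approx(0.3)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            weighted_mean_se([], [])

    def test_oracle_formula(self, rng):
        vals = rng.normal(0, 1, 15)
        ses = rng.uniform(0.2, 2.0, 15)
        mean, se = weighted_mean_se(vals, ses)
        w = 1 / ses ** 2
        assert mean == pytest.approx((w * vals).sum() / w.sum())
        assert se == pytest.approx(np.sqrt(1 / w.sum()))


class TestExceedance:
    def test_symmetry_at_ctmax(self):
        assert exceedance_probability(36.0, 36.0, 0.5) == pytest.approx(0.5)

    def test_three_sigma(self):
        p = exceedance_probability(36.0 + 3 * 0.8, 36.0, 0.8)
        assert p == pytest.approx(0.99865, abs=1e-5)

    def test_cap_behaviour(self):
        policy = SigmaPolicy(cap=1.0)
        p_capped = exceedance_probability(37.0, 36.0, 2.0, policy)
        p_unit = exceedance_probability(37.0, 36.0, 1.0, policy)
        assert p_capped == pytest.approx(p_unit)

    def test_cdf_oracle(self, rng):
        t, c, s = 38.2, 36.1, 0.7
        assert exceedance_probability(t, c, s) == pytest.approx(
            norm.cdf((t - c) / s))

    def test_cap_never_increases_p_below_ctmax(self, rng):
        # for daily_max < ctmax_day, capping sigma shrinks the tail prob
        ses = rng.uniform(1.0, 4.0, 50)
        p_raw = exceedance_probability(34.0, 36.0, ses, SigmaPolicy(mode="none", cap=1.0))
        p_cap = exceedance_probability(34.0, 36.0, ses, SigmaPolicy(cap=1.0))
        assert (p_cap <= p_raw + 1e-12).all()

    def test_biological_range_mode(self):
        policy = SigmaPolicy(cap=1.0, mode="biological_range",
                             biological_cap=2.0)
        p = exceedance_probability(37.0, 36.0, 5.0, policy)
        assert p == pytest.approx(norm.cdf(0.5))

    def test_monotone_in_daily_max(self):
        ps = exceedance_probability(np.linspace(30, 40, 50), 36.0, 1.0)
        assert (np.diff(ps) > 0).all()


class TestOverheatingDays:
    def test_all_zero(self):
        assert overheating_days(np.zeros(910)) == (0.0, 0.0)

    def test_binomial_half(self):
        n, se = overheating_days(np.full(910, 0.5))
        assert n == pytest.approx(455.0)
        assert se == pytest.approx(np.sqrt(910 * 0.25))
        assert se == pytest.approx(15.083, abs=1e-3)

    def test_all_one_degenerate(self):
        n, se = overheating_days(np.ones(910))
        assert n == 910.0
        assert se == 0.0

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            overheating_days([0.5, 1.2])


class TestBinaryRisk:
    def test_never_exceeds(self):
        tmax = np.full(100, 30.0)
        assert binary_risk(tmax, tmax + 5.0) == 0

    def test_single_marginal_exceedance(self):
        ct = np.full(100, 36.0)
        tmax = ct.copy() - 5
        tmax[42] = 36.1
        assert binary_risk(tmax, ct) == 1

    def test_ci_variant(self):
        assert binary_risk([], [], variant="ci", n=0.4, se=0.63) == 0
        assert binary_risk([], [], variant="ci", n=10.0, se=2.0) == 1


class TestTsmSummary:
    def _days(self, tsm=6.0, se=0.5, n=910, ct=36.0):
        return pd.DataFrame({
            "species": "sp1", "cell_id": "0_0", "microhabitat": "terrestrial",
            "scenario": "current", "daily_max": np.full(n, ct - tsm),
            "ctmax_day": np.full(n, ct), "ctmax_day_se": np.full(n, se),
        })

    def test_constants_pass_through(self):
        rec = tsm_summary(self._days(tsm=6.0, se=0.5))
        assert rec.tsm_mean == pytest.approx(6.0)
        assert rec.p_bar == pytest.approx(norm.cdf(-6 / 0.5))
        assert rec.n_days_total == 910

    def test_single_heatwave_day(self):
        days = self._days(tsm=6.0, se=0.5)
        days.loc[3, "daily_max"] = days.loc[3, "ctmax_day"] + 2.0
        rec = tsm_summary(days)
        assert rec.risk_binary == 1
        expected_n = norm.cdf(2 / 0.5) + 909 * norm.cdf(-6 / 0.5)
        assert rec.n_overheat_days == pytest.approx(expected_n, rel=1e-6)

    def test_equal_se_equals_arithmetic_mean(self, rng):
        days = self._days()
        days["daily_max"] = rng.normal(30, 2, len(days))
        rec = tsm_summary(days)
        assert rec.tsm_mean == pytest.approx(
            (days.ctmax_day - days.daily_max).mean())

    def test_monotone_in_warming(self):
        base = self._days(tsm=2.0, se=1.0)
        warm = base.copy()
        warm["daily_max"] += 4.0
        r0 = tsm_summary(base)
        r4 = tsm_summary(warm)
        assert r4.n_overheat_days >= r0.n_overheat_days
        assert r4.tsm_mean == pytest.approx(r0.tsm_mean - 4.0)

    def test_p95_variant(self, rng):
        days = self._days()
        days["daily_max"] = rng.normal(30, 2, len(days))
        rec = tsm_summary(days, variant="p95-tsm")
        assert rec.tsm_mean == pytest.approx(
            36.0 - np.percentile(days.daily_max, 95))

    def test_trimmed_variant_reduces_range(self, rng):
        days = self._days()
        days["daily_max"] = rng.normal(30, 2, len(days))
        full = tsm_summary(days)
        trimmed = tsm_summary(days, variant="trimmed")
        assert trimmed.n_days_total < full.n_days_total

    def test_ci_risk_variant(self):
        days = self._days(tsm=0.5, se=1.0, n=20)
        rec_default = tsm_summary(days)
        rec_ci = tsm_summary(days, variant="ci-risk")
        assert rec_default.risk_binary == 0  # never strictly exceeds
        assert rec_ci.risk_binary == 1       # expected count interval > 0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            tsm_summary(self._days().iloc[:0])
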