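import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periodsurv.cohort import PatientRecord
from periodsurv.engine import (
    AnalysisWindow,
    RiskSetTable,
    build_risk_sets,
    compute_estimate,
    conditional_observed_survival,
    cumulative_relative_survival,
    ederer2_conditional_expected,
    greenwood_se,
)

from conftest import make_lifetable
from oracle import oracle_risk_sets, random_mini_cohort


def _rs(n, e, d, c, c_end=None, pstar=None, k=None):
    k = k or len(n)
    z = np.zeros(k)
    return RiskSetTable(
        k=k, n=np.array(n, float), entrants=np.array(e, float),
        deaths=np.array(d, float), withdrawals=np.array(c, float),
        withdrawals_at_end=np.array(c_end, float) if c_end is not None else z,
        expected_p=np.array(pstar, float) if pstar is not None else np.ones(k),
    )


class TestRiskSets:
    def test_three_patient_period_window(self, flat_lifetable):
        """Late entry, window-close censoring and the k-year cap together."""
        patients = [
            PatientRecord(id="P1", sex="male", race="white", age_dx=60,
                          dx_year=2010, dx_month=1, survival_months=30,
                          vital_status="dead"),
            PatientRecord(id="P2", sex="male", race="white", age_dx=60,
                          dx_year=2007, dx_month=1, survival_months=240,
                          vital_status="alive"),
            PatientRecord(id="P3", sex="male", race="white", age_dx=60,
                          dx_year=2013, dx_month=7, survival_months=120,
                          vital_status="alive"),
        ]
        rs = build_risk_sets(patients, AnalysisWindow("period", 2010, 2014, 5),
                             flat_lifetable)
        assert rs.n.tolist() == [2, 2, 1, 1, 1]
        assert rs.entrants.tolist() == [0, 0, 1, 0, 0]
        assert rs.deaths.tolist() == [0, 0, 1, 0, 0]
        assert rs.withdrawals.tolist() == [0, 1, 0, 0, 1]
        # P2 is cut by the 5-year cap exactly at the interval end: fully
        # exposed, so not down-weighted
        assert rs.withdrawals_at_end.tolist() == [0, 0, 0, 0, 1]
        assert rs.eff_n.tolist() == [2, 1.5, 1.5, 1, 1]

    def test_patient_outside_window_contributes_nothing(self, flat_lifetable):
        p = PatientRecord(id="x", sex="male", race="white", age_dx=60,
                          dx_year=2014, dx_month=12, survival_months=60,
                          vital_status="alive")
        rs = build_risk_sets([p], AnalysisWindow("period", 2004, 2008, 5),
                             flat_lifetable)
        assert rs.n.sum() == 0 and any("empty" in f for f in rs.flags)
        est = compute_estimate(rs)
        assert math.isnan(cumulative_relative_survival(est, 5))

    def test_cohort_mode_has_no_entrants(self, flat_lifetable):
        rng = random.Random(5)
        recs = random_mini_cohort(rng, races=("white",))
        rs = build_risk_sets(recs, AnalysisWindow("cohort", 2000, 2018, 5),
                             flat_lifetable)
        assert rs.entrants.sum() == 0

    @given(st.integers(0, 2 ** 31), st.sampled_from(["period", "cohort"]),
           st.integers(2000, 2016), st.integers(1, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_flow_conservation_and_oracle(self, flat_lifetable, seed, mode,
                                          start, k):
        """n_{j+1} = n_j + e_j - d_j - c_j, and every count matches the
        brute-force per-patient bucketing oracle."""
        recs = random_mini_cohort(random.Random(seed))
        win = AnalysisWindow(mode, start, start + 4, k)
        rs = build_risk_sets(recs, win, flat_lifetable)
        expect = oracle_risk_sets(recs, win)
        for key in expect:
            assert getattr(rs, key).tolist() == expect[key], key
        flow = rs.n[:-1] + rs.entrants[:-1] - rs.deaths[:-1] - rs.withdrawals[:-1]
        assert np.array_equal(flow, rs.n[1:])


class TestActuarialEstimator:
    @pytest.mark.parametrize("n,e,d,c,expected", [
        (100, 0, 10, 0, 0.9),
        (100, 0, 10, 20, 1 - 10 / 90),
        (0, 2, 1, 0, 0.0),  # late entrants at half weight: n' = 1
    ])
    def test_conditional_observed(self, n, e, d, c, expected):
        rs = _rs([n], [e], [d], [c])
        assert conditional_observed_survival(rs, 1) == pytest.approx(expected)

    def test_zero_denominator_is_undefined(self):
        rs = _rs([0], [0], [0], [0])
        assert math.isnan(conditional_observed_survival(rs, 1))

    def test_end_of_interval_withdrawals_keep_full_weight(self):
        rs = _rs([100], [0], [10], [90], c_end=[90])
        assert conditional_observed_survival(rs, 1) == pytest.approx(0.9)


class TestEdererII:
    def test_plain_mean(self):
        table = make_lifetable(age_p={60: 0.96, 80: 0.90})
        at_risk = [(60, 2010, "male", "white"), (80, 2010, "male", "white")]
        assert ederer2_conditional_expected(at_risk, table) == pytest.approx(0.93)

    def test_identical_values_return_the_value(self, flat_lifetable):
        at_risk = [(50, 2012, "female", "white")] * 7
        assert ederer2_conditional_expected(at_risk, flat_lifetable) == pytest.approx(0.97)

    def test_half_weight_withdrawer(self):
        """Three full-interval patients plus one mid-interval withdrawer."""
        table = make_lifetable(age_p={60: 0.96, 65: 0.94, 70: 0.90, 75: 0.80})
        at_risk = [(60, 2010, "male", "white", 1.0),
                   (65, 2010, "male", "white", 1.0),
                   (70, 2010, "male", "white", 1.0),
                   (75, 2010, "male", "white", 0.5)]
        expected = (0.96 + 0.94 + 0.90 + 0.5 * 0.80) / 3.5
        assert ederer2_conditional_expected(at_risk, table) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.9142857142857143)

    def test_empty_at_risk_set_is_undefined(self, flat_lifetable):
        assert math.isnan(ederer2_conditional_expected([], flat_lifetable))


class TestRelativeSurvival:
    def test_two_interval_arithmetic(self):
        rs = _rs([100, 90], [0, 0], [10, 9], [0, 0], pstar=[0.95, 0.95])
        est = compute_estimate(rs)
        assert cumulative_relative_survival(est, 2) == pytest.approx(
            (0.9 / 0.95) ** 2)

    def test_observed_equal_expected_gives_one(self):
        rs = _rs([100, 90], [0, 0], [10, 9], [0, 0], pstar=[0.9, 0.9])
        est = compute_estimate(rs)
        assert cumulative_relative_survival(est, 2) == pytest.approx(1.0)

    def test_relative_survival_above_one_is_not_capped(self):
        rs = _rs([100], [0], [1], [0], pstar=[0.95])
        est = compute_estimate(rs)
        assert cumulative_relative_survival(est, 1) == pytest.approx(0.99 / 0.95)
        assert est.R[0] > 1

    def test_se_R_is_se_S_over_Sstar(self):
        rs = _rs([100, 90], [0, 0], [10, 9], [0, 0], pstar=[0.95, 0.94])
        est = compute_estimate(rs)
        assert np.allclose(est.se_R, est.se_S / est.Sstar)


class TestGreenwood:
    def test_single_interval_closed_form(self):
        rs = _rs([100], [0], [10], [0])
        se_S, _ = greenwood_se(rs, 1)
        assert se_S == pytest.approx(0.9 * math.sqrt(10 / (100 * 90)))
        assert se_S == pytest.approx(0.03)

    def test_no_deaths_no_variance(self):
        rs = _rs([50, 50], [0, 0], [0, 0], [0, 0])
        assert greenwood_se(rs, 2) == (0.0, 0.0)

    def test_two_interval_hand_computation(self):
        rs = _rs([100, 90], [0, 0], [10, 9], [0, 0])
        se_S, _ = greenwood_se(rs, 2)
        assert se_S == pytest.approx(0.81 * math.sqrt(10 / 9000 + 9 / 7290))

    def test_everyone_dies_variance_undefined(self):
        rs = _rs([10], [0], [10], [0])
        est = compute_estimate(rs)
        assert math.isnan(est.se_S[0])
        assert any("variance undefined" in f for f in est.flags)
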