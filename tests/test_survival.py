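import math

import numpy as np
import pandas as pd
import pytest

from swgshrd import (
    SeparationError,
    SimulationConfig,
    SurvivalRecord,
    cox_univariate,
    km_estimate,
    logrank_test,
    simulate_cohort,
    survival_report,
)


def recs(times, events, group=""):
    return [
        SurvivalRecord(f"s{i}", t, e, group) for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_hand_computed_curve(self):
        # events at 5, 10, 15 with no censoring:
        # S = 2/3, 1/3, 0; restricted mean = 5*1 + 5*(2/3) + 5*(1/3) = 10
        curve = km_estimate(recs([5, 10, 15], [1, 1, 1]))
        assert curve.times.tolist() == [5.0, 10.0, 15.0]
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3.0, 2.0, 1.0]
        assert curve.restricted_mean == pytest.approx(10.0)
        assert curve.median == pytest.approx(10.0)

    def test_all_censored(self):
        curve = km_estimate(recs([3, 6, 9], [0, 0, 0]))
        assert len(curve.times) == 0
        assert math.isinf(curve.median)  # never reached
        assert curve.restricted_mean == pytest.approx(9.0)  # S == 1 up to 9

    def test_no_censoring_restricted_mean_is_arithmetic_mean(self, rng):
        times = rng.exponential(100, size=200)
        curve = km_estimate(recs(times, np.ones(len(times), dtype=int)))
        assert curve.restricted_mean == pytest.approx(times.mean(), rel=1e-10)

    def test_survival_non_increasing_from_one(self, rng):
        times = rng.exponential(50, size=100)
        events = rng.integers(0, 2, size=100)
        events[0] = 1
        curve = km_estimate(recs(times, events))
        s = np.r_[1.0, curve.survival]
        assert (np.diff(s) <= 1e-12).all()

    def test_censoring_at_event_time_stays_at_risk(self):
        # subject censored exactly at an event time counts in that risk set
        curve = km_estimate(recs([5, 5, 10], [1, 0, 1]))
        assert curve.survival[0] == pytest.approx(2 / 3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("x", -1.0, 1)


class TestLogRank:
    def test_identical_groups_give_null(self):
        g = {"a": recs([5, 10, 15, 20], [1, 1, 1, 0]), "b": recs([5, 10, 15, 20], [1, 1, 1, 0])}
        stat, p = logrank_test(g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_six_subjects(self):
        # manual observed-minus-expected computation, written out naively
        times = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        events = np.array([1, 1, 1, 1, 1, 0])
        groups = np.array([0, 1, 0, 1, 0, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(set(times[events == 1])):
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (groups == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expect = o_minus_e**2 / var
        g = {
            "0": recs(times[groups == 0], events[groups == 0]),
            "1": recs(times[groups == 1], events[groups == 1]),
        }
        stat, _ = logrank_test(g)
        assert stat == pytest.approx(expect, rel=1e-10)

    def test_separated_exponentials_are_detected(self):
        # strongly different PFS scales must be flagged at n = 200/arm
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = {
                "long": recs(rng.exponential(2850, 200), np.ones(200, int)),
                "short": recs(rng.exponential(620, 200), np.ones(200, int)),
            }
            _, p = logrank_test(g)
            assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            logrank_test({"only": recs([1, 2], [1, 1])})

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank_test({"a": recs([1], [0]), "b": recs([2], [0])})


class TestCox:
    def test_two_subject_tied_closed_form(self):
        # both events at the same time, x = (1, 0): the Breslow partial
        # likelihood is beta*(x1+x2) - 2*log(e^b + 1), maximised at beta = 0
        # with information 2 * (1/2 - 1/4) = 1/2, so se = sqrt(2)
        r = recs([5, 5], [1, 1])
        fit = cox_univariate(r, [1.0, 0.0])
        assert fit["beta"] == pytest.approx(0.0, abs=1e-10)
        assert fit["hr"] == pytest.approx(1.0)
        assert fit["se"] == pytest.approx(math.sqrt(2.0), rel=1e-10)

    def test_null_covariate_gives_unit_hazard(self):
        rng = np.random.default_rng(3)
        n = 800
        times = rng.exponential(100, n)
        x = rng.integers(0, 2, n).astype(float)  # independent of time
        fit = cox_univariate(recs(times, np.ones(n, int)), x)
        assert fit["hr"] == pytest.approx(1.0, abs=0.25)
        assert fit["ci_low"] < 1.0 < fit["ci_high"]

    def test_rate_ratio_recovered(self):
        rng = np.random.default_rng(11)
        n = 500
        t0 = rng.exponential(1.0, n)
        t1 = rng.exponential(1.0 / 3.0, n)  # hazard ratio 3
        times = np.r_[t0, t1]
        x = np.r_[np.zeros(n), np.ones(n)]
        fit = cox_univariate(recs(times, np.ones(2 * n, int)), x)
        assert fit["hr"] == pytest.approx(3.0, rel=0.10)
        assert fit["ci_low"] < 3.0 < fit["ci_high"]

    def test_matches_lifelines_on_tie_free_data(self):
        # without ties Breslow and Efron coincide, so lifelines is an
        # independent oracle for the hand-rolled Newton fit
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 120
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.5 * x))
        df = pd.DataFrame({"t": times, "e": 1, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        fit = cox_univariate(recs(times, np.ones(n, int)), x)
        assert fit["beta"] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit["se"] == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_complete_separation_flagged(self):
        r = recs([1, 2, 3, 10, 20, 30], [1, 1, 1, 1, 1, 1])
        with pytest.raises(SeparationError):
            cox_univariate(r, [1, 1, 1, 0, 0, 0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate(recs([1, 2], [1, 1]), [1.0, 1.0])


class TestSurvivalReport:
    def test_synthetic_cohort_means_ordered(self):
        df = simulate_cohort(400, SimulationConfig(seed=21))
        rep = survival_report(df)
        means = {g: s["restricted_mean_days"] for g, s in rep["groups"].items()}
        assert means["HRD"] > means["HRM"] > means["HRN"]
        assert rep["logrank"]["p_value"] < 0.001
        assert rep["cox"]["hr"] < 1.0  # HRD-positive progresses later than HRN

    def test_single_group_km_still_emitted(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "hrd_class": ["HRD"] * 3,
                "pfs_days": [100.0, 200.0, 300.0],
                "pfs_event": [1, 1, 0],
            }
        )
        rep = survival_report(df)
        assert rep["groups"]["HRD"]["n"] == 3
        assert "error" in rep["logrank"]

    def test_all_censored_median_not_reached(self):
        df = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "hrd_class": ["HRD"] * 3 + ["HRN"] * 3,
                "pfs_days": [100.0, 200.0, 300.0] * 2,
                "pfs_event": [0] * 6,
            }
        )
        rep = survival_report(df)
        assert rep["groups"]["HRD"]["median_days"] is None
        assert "error" in rep["logrank"]  # no events: test undefined
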