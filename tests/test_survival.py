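"""Kaplan-Meier median and Cox hazard-ratio contracts, checked against
hand-rolled oracles (brute-force product-limit; 1-D partial-likelihood
maximization)."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from mortsens import (
    DAYS_PER_MONTH,
    EstimationError,
    SurvivalRecord,
    cox_hr,
    km_median,
)


def rec(time, event, arm="x"):
    return SurvivalRecord(time=float(time), event=bool(event), arm=arm)


# ---------------------------------------------------------------------------
# Oracles


def product_limit_median(times, events):
    """Brute-force Kaplan-Meier median: smallest t with S(t) <= 0.5."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    for t in np.unique(times[events.astype(bool)]):
        at_risk = np.sum(times >= t)
        deaths = np.sum((times == t) & events.astype(bool))
        s *= 1 - deaths / at_risk
        if s <= 0.5 + 1e-12:
            return t
    return math.inf


def cox_loglik(beta, times, events, treated):
    """Log partial likelihood for one binary covariate (no ties assumed)."""
    order = np.argsort(times)
    times, events, treated = times[order], events[order], treated[order]
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = times >= times[i]
        ll += beta * treated[i] - math.log(np.sum(np.exp(beta * treated[risk])))
    return ll


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKMMedian:
    def test_common_death_time_is_the_median(self):
        est = km_median([rec(5, True) for _ in range(8)])
        assert est.value * DAYS_PER_MONTH == pytest.approx(5.0)
        assert est.n_events == 8

    def test_five_distinct_deaths_median_at_third(self):
        # survival steps 0.8, 0.6, 0.4 -> first time S <= 0.5 is t=3
        est = km_median([rec(t, True) for t in (1, 2, 3, 4, 5)])
        assert est.value * DAYS_PER_MONTH == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_uncensored_median_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.integers(1, 40, size=rng.integers(3, 30))
        est = km_median([rec(t, True) for t in times])
        oracle = product_limit_median(times, np.ones_like(times))
        assert est.value * DAYS_PER_MONTH == pytest.approx(oracle)

    def test_median_invariant_to_censor_times_beyond_last_event(self):
        # moving censor dates around beyond the last event leaves S on the
        # event range, hence the median, untouched
        events = [rec(t, True) for t in (3, 6, 9, 12)]
        a = km_median(events + [rec(20, False), rec(30, False)])
        b = km_median(events + [rec(13, False), rec(100, False)])
        assert a.value == b.value

    def test_exponential_cohort_recovers_analytic_median(self):
        lam = math.log(2) / 9  # per month: median ln2/lambda = 9 months
        rng = np.random.default_rng(2024)
        times_days = rng.exponential(1 / lam, size=20_000) * DAYS_PER_MONTH
        est = km_median([rec(max(t, 0.5), True) for t in times_days])
        assert est.value == pytest.approx(9.0, abs=0.2)
        assert est.ci_lower < 9.0 < est.ci_upper

    def test_zero_events_flagged_as_open_not_raised(self):
        est = km_median([rec(10, False), rec(20, False)])
        assert math.isinf(est.value)
        assert est.n_events == 0

    def test_curve_never_reaching_half_gives_open_median(self):
        est = km_median([rec(5, True)] + [rec(50, False)] * 9)
        assert math.isinf(est.value)


# ---------------------------------------------------------------------------
# Cox


class TestCoxHR:
    def test_toy_set_matches_partial_likelihood_maximizer(self):
        records = [
            rec(2, True, "ctl"),
            rec(4, True, "exp"),
            rec(6, True, "ctl"),
            rec(8, False, "exp"),
        ]
        est = cox_hr(records, reference_arm="ctl")
        times = np.array([2.0, 4.0, 6.0, 8.0])
        events = np.array([True, True, True, False])
        treated = np.array([0.0, 1.0, 0.0, 1.0])
        opt = minimize_scalar(
            lambda b: -cox_loglik(b, times, events, treated), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert est.value == pytest.approx(math.exp(opt.x), rel=1e-4)

    def test_null_case_two_identical_arms(self):
        rng = np.random.default_rng(8)
        records = [
            rec(max(t, 0.5), True, arm)
            for arm in ("exp", "ctl")
            for t in rng.exponential(100, size=5000)
        ]
        est = cox_hr(records, reference_arm="ctl")
        assert 0.93 <= est.value <= 1.08

    def test_exponential_arms_recover_rate_ratio(self):
        rng = np.random.default_rng(15)
        records = [
            rec(max(t, 0.5), True, "hi") for t in rng.exponential(1 / 0.10, size=5000)
        ] + [
            rec(max(t, 0.5), True, "lo") for t in rng.exponential(1 / 0.05, size=5000)
        ]
        est = cox_hr(records, reference_arm="lo")
        assert est.value == pytest.approx(2.0, abs=0.1)
        assert est.ci_lower < est.value < est.ci_upper

    def test_swapping_reference_inverts_hazard_ratio(self):
        rng = np.random.default_rng(23)
        records = [
            rec(max(t, 0.5), rng.random() < 0.8, arm)
            for arm, scale in (("a", 80), ("b", 120))
            for t in rng.exponential(scale, size=400)
        ]
        fwd = cox_hr(records, reference_arm="a")
        back = cox_hr(records, reference_arm="b")
        assert fwd.value * back.value == pytest.approx(1.0, rel=1e-6)
        assert fwd.ci_lower * back.ci_upper == pytest.approx(1.0, rel=1e-6)

    def test_time_axis_rescaling_leaves_hr_unchanged(self):
        rng = np.random.default_rng(31)
        base = [
            rec(max(t, 0.5), True, arm)
            for arm, scale in (("a", 50), ("b", 90))
            for t in rng.exponential(scale, size=300)
        ]
        scaled = [rec(r.time / DAYS_PER_MONTH, r.event, r.arm) for r in base]
        assert cox_hr(base, "a").value == pytest.approx(
            cox_hr(scaled, "a").value, rel=1e-6
        )

    def test_single_arm_and_eventless_arm_raise(self):
        with pytest.raises(EstimationError, match="two arms"):
            cox_hr([rec(1, True, "only"), rec(2, True, "only")], "only")
        records = [rec(1, True, "a"), rec(2, False, "b"), rec(3, True, "a")]
        with pytest.raises(EstimationError, match="no events"):
            cox_hr(records, "a")

    def test_log_hr_recovery_over_replicates(self):
        """Mean log-HR over 200 replicates (n=1000/arm, true HR 0.7) sits
        within 2 Monte-Carlo SE of log 0.7."""
        rng = np.random.default_rng(77)
        log_hrs = []
        for _ in range(200):
            records = [
                rec(max(t, 0.5), True, "exp")
                for t in rng.exponential(1 / 0.7, size=1000)
            ] + [
                rec(max(t, 0.5), True, "ctl") for t in rng.exponential(1.0, size=1000)
            ]
            log_hrs.append(math.log(cox_hr(records, "ctl").value))
        mc_se = np.std(log_hrs, ddof=1) / math.sqrt(len(log_hrs))
        assert np.mean(log_hrs) == pytest.approx(math.log(0.7), abs=2 * mc_se)
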