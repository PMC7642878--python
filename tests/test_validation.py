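import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coxval import (
    c_statistic,
    calibration_chi2,
    continuous_nri,
    delong_compare,
    expected_vs_observed,
    idi,
    status_at_horizon,
)


def brute_force_c(risks, status):
    """O(n^2) pair enumeration oracle for the C statistic."""
    ev = risks[status]
    ne = risks[~status]
    wins = 0.0
    for x in ev:
        for y in ne:
            wins += 1.0 if x > y else (0.5 if x == y else 0.0)
    return wins / (len(ev) * len(ne))


class TestCStatistic:
    def test_perfect_separation(self):
        risks = np.array([0.9, 0.8, 0.1, 0.2])
        status = np.array([True, True, False, False])
        assert c_statistic(risks, status).c_statistic == 1.0

    def test_small_example_five_sixths(self):
        risks = np.array([0.8, 0.6, 0.7, 0.2, 0.1])
        status = np.array([True, True, False, False, False])
        assert c_statistic(risks, status).c_statistic == pytest.approx(5 / 6)

    def test_all_ties_give_half(self):
        risks = np.full(10, 0.3)
        status = np.arange(10) < 4
        assert c_statistic(risks, status).c_statistic == 0.5

    def test_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 31)
            risks = np.round(rng.random(n), 2)  # rounding forces ties
            status = rng.random(n) < 0.4
            if status.all() or not status.any():
                continue
            assert c_statistic(risks, status).c_statistic == pytest.approx(
                brute_force_c(risks, status), abs=1e-12
            )

    @given(st.floats(0.1, 5.0), st.floats(-1.0, 1.0))
    def test_invariant_under_monotone_transform(self, a, b):
        rng = np.random.default_rng(9)
        risks = rng.random(40)
        status = rng.random(40) < 0.3
        transformed = a * risks + b
        assert (
            c_statistic(risks, status).c_statistic
            == c_statistic(transformed, status).c_statistic
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic(np.array([0.1, 0.2]), np.array([True, True]))


class TestDeLong:
    def test_self_comparison_is_exactly_null(self):
        rng = np.random.default_rng(4)
        risks = rng.random(50)
        status = rng.random(50) < 0.4
        res = delong_compare(risks, risks, status)
        assert res.delta_c == 0.0
        assert res.standard_error == 0.0
        assert res.p_value == 1.0

    def test_variance_bounded_by_component_variances(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n = 60
            status = rng.random(n) < 0.35
            a = rng.normal(size=n) + status
            b = 0.5 * a + rng.normal(size=n)
            if status.all() or not status.any():
                continue
            res = delong_compare(a, b, status)
            va = c_statistic(a, status).standard_error ** 2
            vb = c_statistic(b, status).standard_error ** 2
            bound = va + vb + 2 * np.sqrt(va * vb)
            assert res.standard_error**2 <= bound + 1e-12

    def test_matches_pROC_oracle(self):
        """Full numeric agreement with an independent DeLong implementation (R pROC)."""
        rng = np.random.default_rng(5)
        n = 80
        status = rng.random(n) < 0.35
        a = rng.normal(0, 1, n) + status * 0.8
        b = rng.normal(0, 1, n) + status * 0.4 + 0.5 * a
        script = (
            "suppressMessages(library(pROC));"
            f"a <- c({','.join(map(str, a))});"
            f"b <- c({','.join(map(str, b))});"
            f"s <- c({','.join(map(str, status.astype(int)))});"
            "r1 <- roc(s, a, quiet=TRUE, direction='<');"
            "r2 <- roc(s, b, quiet=TRUE, direction='<');"
            "t <- roc.test(r1, r2, method='delong', paired=TRUE);"
            "cat(sprintf('%.12f %.12f %.12f %.12f', auc(r1), auc(r2), t$p.value, var(r1)))"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/pROC unavailable: {proc.stderr[-200:]}")
        auc_a, auc_b, p, var_a = map(float, proc.stdout.split())
        res = delong_compare(a, b, status)
        assert res.c_a == pytest.approx(auc_a, abs=1e-10)
        assert res.c_b == pytest.approx(auc_b, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert c_statistic(a, status).standard_error ** 2 == pytest.approx(var_a, abs=1e-10)

    def test_paired_lengths_enforced(self):
        with pytest.raises(ValueError):
            delong_compare([0.1, 0.2], [0.1], [True, False])

    def test_coverage_of_true_difference(self):
        """95% CI covers the true delta-C in roughly 95% of simulated cohorts."""
        rng = np.random.default_rng(77)
        n, reps = 500, 200
        # true AUCs under binormal scores with known separation
        from scipy.stats import norm

        d_a, d_b = 1.0, 0.5
        sd = np.sqrt(0.7**2 + 0.7**2)  # total score sd (shared + private parts)
        true_delta = norm.cdf(d_a / (np.sqrt(2) * sd)) - norm.cdf(d_b / (np.sqrt(2) * sd))
        hits = 0
        for _ in range(reps):
            status = rng.random(n) < 0.3
            common = rng.normal(size=n)
            a = rng.normal(size=n) * 0.7 + 0.7 * common + status * d_a
            b = rng.normal(size=n) * 0.7 + 0.7 * common + status * d_b
            res = delong_compare(a, b, status)
            hits += res.ci_lower <= true_delta <= res.ci_upper
        assert 0.90 <= hits / reps <= 0.99


class TestCalibration:
    def test_perfect_calibration_gives_zero(self):
        # uncensored data where each group's observed risk equals its predicted risk
        rng = np.random.default_rng(1)
        n = 1000
        risks = np.repeat(np.linspace(0.05, 0.5, 10), n // 10)
        events = np.concatenate(
            [np.r_[np.ones(int(round(p * 100))), np.zeros(100 - int(round(p * 100)))]
             for p in np.linspace(0.05, 0.5, 10)]
        )
        times = np.where(events == 1, 2.0, 10.0)
        cal = calibration_chi2(risks, times, events, horizon=5.0)
        assert cal.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_single_group_term_formula(self):
        # one (merged) group: n=100, observed 0.2, predicted 0.1
        # -> 100 * (0.1)^2 / (0.1*0.9) = 11.11
        risks = np.full(100, 0.1)
        events = np.r_[np.ones(20), np.zeros(80)]
        times = np.where(events == 1, 1.0, 10.0)
        with pytest.warns(UserWarning, match="merged"):
            cal = calibration_chi2(risks, times, events, horizon=5.0, n_groups=2)
        assert cal.chi2 == pytest.approx(100 * 0.1**2 / 0.09, rel=1e-9)

    def test_km_adjustment_uses_censoring(self):
        """Censored-early subjects inflate observed risk relative to the raw count."""
        risks = np.linspace(0.01, 0.5, 200)
        rng = np.random.default_rng(8)
        events = rng.random(200) < risks
        times = np.where(events, 2.5, 5.5)
        times[::7] = 1.0  # censor some non-events early
        events[::7] = False
        pred, obs = expected_vs_observed(risks, times, events, horizon=5.0)
        assert obs > events.sum()  # KM redistributes censored subjects
        assert pred == pytest.approx(risks.sum())

    def test_no_censoring_observed_equals_count(self):
        risks = np.linspace(0.1, 0.2, 50)
        events = np.r_[np.ones(7), np.zeros(43)]
        times = np.where(events == 1, 3.0, 6.0)
        _, obs = expected_vs_observed(risks, times, events, horizon=5.0)
        assert obs == pytest.approx(7.0)

    def test_zero_risks_predict_zero_events(self):
        pred, _ = expected_vs_observed(
            np.zeros(10), np.full(10, 6.0), np.zeros(10), horizon=5.0
        )
        assert pred == 0.0

    def test_merges_degenerate_groups_with_warning(self):
        risks = np.full(40, 0.25)
        times = np.full(40, 6.0)
        events = np.r_[np.ones(10), np.zeros(30)]
        with pytest.warns(UserWarning, match="merged"):
            cal = calibration_chi2(risks, times, events, horizon=5.0)
        assert cal.table["n"].sum() == 40


class TestReclassification:
    def test_no_movement_gives_zero_nri(self):
        risks = np.linspace(0.1, 0.5, 30)
        status = np.arange(30) < 6
        res = continuous_nri(risks, risks, status)
        assert res.total_nri == 0.0

    def test_maximal_improvement_is_two(self):
        old = np.full(20, 0.3)
        status = np.arange(20) < 8
        new = np.where(status, 0.6, 0.1)
        res = continuous_nri(old, new, status)
        assert res.total_nri == pytest.approx(2.0)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        old = rng.random(n)
        new = old + rng.choice([-1, 1], n) * rng.uniform(0.01, 0.2, n)
        status = rng.random(n) < 0.4
        if status.all() or not status.any():
            return
        ab = continuous_nri(old, new, status).total_nri
        ba = continuous_nri(new, old, status).total_nri
        assert ab == pytest.approx(-ba, abs=1e-12)

    def test_ties_stay_in_denominators(self):
        old = np.array([0.1, 0.2, 0.3, 0.4])
        new = np.array([0.1, 0.25, 0.3, 0.35])  # two ties, one up, one down
        status = np.array([True, True, False, False])
        res = continuous_nri(old, new, status)
        assert res.n_events == 2 and res.n_nonevents == 2
        assert res.event_nri == pytest.approx(0.5)
        assert res.nonevent_nri == pytest.approx(0.5)

    def test_bootstrap_ci_is_seeded_and_close_to_analytic(self):
        rng = np.random.default_rng(13)
        n = 400
        status = rng.random(n) < 0.25
        old = rng.random(n)
        new = np.clip(old + rng.normal(0, 0.1, n) + status * 0.05, 0, 1)
        a = continuous_nri(old, new, status)
        b1 = continuous_nri(old, new, status, ci_method="bootstrap", rng=5)
        b2 = continuous_nri(old, new, status, ci_method="bootstrap", rng=5)
        assert b1.nri_ci == b2.nri_ci
        assert b1.nri_se == pytest.approx(a.nri_se, rel=0.35)


class TestIDI:
    def test_identical_models_zero(self):
        risks = np.linspace(0, 1, 20)
        status = np.arange(20) % 3 == 0
        assert idi(risks, risks, status).idi == 0.0

    def test_direct_arithmetic_example(self):
        # events 0.5 -> 0.6, non-events 0.30 -> 0.25: IDI = 0.10 + 0.05 = 0.15
        old = np.array([0.5, 0.5, 0.30, 0.30])
        new = np.array([0.6, 0.6, 0.25, 0.25])
        status = np.array([True, True, False, False])
        assert idi(old, new, status).idi == pytest.approx(0.15)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        old, new = rng.random(30), rng.random(30)
        status = rng.random(30) < 0.5
        assert idi(old, new, status).idi == pytest.approx(-idi(new, old, status).idi)


class TestStatusAtHorizon:
    def test_censored_before_horizon_excluded(self):
        times = np.array([2.0, 6.0, 4.0, 5.0])
        events = np.array([1, 0, 0, 1])
        status, include = status_at_horizon(times, events, 5.0)
        assert status.tolist() == [True, False, False, True]
        assert include.tolist() == [True, True, False, True]

    def test_event_after_horizon_is_nonevent(self):
        status, include = status_at_horizon([7.0], [1], 5.0)
        assert not status[0] and include[0]
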