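"""Association and survival statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from oligofish.cohort_stats import (
    ModelScope,
    chisq_test,
    cox_fit,
    km_estimate,
    logrank_test,
    records_to_frame,
    survival_table,
)
from oligofish.io_formats import PatientRecord
from oligofish.synthetic_cohort import simulate_survival_frame


def brute_force_chisq(table):
    """O/E summation straight from the definition."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


class TestChisq:
    def test_independent_table_gives_zero(self):
        res = chisq_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_grade_by_polysomy_contingency(self):
        res = chisq_test([[60, 19], [27, 39]])
        assert res.statistic == pytest.approx(18.40, abs=0.01)
        assert res.p_value == pytest.approx(1.79e-5, rel=0.01)
        assert res.p_value < 1e-4

    def test_mitoses_by_polysomy_contingency(self):
        res = chisq_test([[74, 36], [13, 22]])
        assert res.p_value == pytest.approx(0.00153, abs=5e-5)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(30):
            shape = rng.integers(2, 4, size=2)
            t = rng.integers(1, 50, size=tuple(shape))
            res = chisq_test(t.tolist())
            assert res.statistic == pytest.approx(brute_force_chisq(t), rel=1e-12)
            assert res.df == (shape[0] - 1) * (shape[1] - 1)

    def test_permutation_invariance(self, rng):
        t = rng.integers(1, 40, size=(3, 3))
        base = chisq_test(t.tolist()).statistic
        assert chisq_test(t[::-1].tolist()).statistic == pytest.approx(base)
        assert chisq_test(t[:, ::-1].tolist()).statistic == pytest.approx(base)

    def test_yates_correction_reduces_statistic(self):
        plain = chisq_test([[74, 41], [13, 17]])
        corrected = chisq_test([[74, 41], [13, 17]], yates=True)
        assert corrected.statistic < plain.statistic
        assert corrected.corrected

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_test([[0, 0], [5, 5]])


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5, 10, 15], [False, False, False])
        assert all(s == 1.0 for s in curve.survival)
        assert curve.median_months is None

    def test_three_events_product_limit(self):
        curve = km_estimate([1, 2, 3], [True, True, True])
        steps = {t: s for t, s in zip(curve.times, curve.survival)}
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(1 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_censoring_before_event_shrinks_risk_set(self):
        # one censored at 4, one event at 5: at-risk = 1 at t=5, S drops to 0
        curve = km_estimate([4, 5], [False, True])
        assert curve.survival_at(5) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 50, size=40).astype(float)
        curve = km_estimate(times, [True] * 40)
        for t in (5, 20, 45):
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_curve_is_non_increasing_and_starts_at_one(self, rng):
        times = rng.exponential(30, size=50)
        events = rng.random(50) < 0.7
        curve = km_estimate(times, events)
        assert curve.survival_at(0) == 1.0
        assert all(a >= b - 1e-12 for a, b in zip(curve.survival, curve.survival[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        times = [3, 6, 9, 12, 15]
        events = [True, True, False, True, False]
        p = logrank_test([0] * 5 + [1] * 5, times + times, events + events)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_early_vs_late_events_strongly_separated(self):
        times = list(range(1, 11)) + list(range(100, 110))
        p = logrank_test([0] * 10 + [1] * 10, times, [True] * 20)
        assert p < 0.01

    def test_detects_hazard_ratio_three(self, rng):
        hits = 0
        for _ in range(50):
            df = simulate_survival_frame(
                200, rng, polysomy_prevalence=0.5, log_hr_polysomy=np.log(3.0)
            )
            p = logrank_test(
                df["polysomy"], df["os_months"], df["os_event"].astype(bool)
            )
            hits += p < 0.05
        assert hits >= 48  # >= 95% power expected at HR = 3, n = 200

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([0, 0, 0], [1, 2, 3], [True, True, True])


class TestCox:
    def test_recovers_hazard_ratio_two(self, rng):
        covered = 0
        for _ in range(20):
            df = simulate_survival_frame(400, rng, log_hr_polysomy=np.log(2.0))
            (res,) = cox_fit(df, ["polysomy"])
            covered += res.ci_low <= 2.0 <= res.ci_high
        assert covered >= 17

    def test_constant_covariate_flagged(self):
        df = pd.DataFrame(
            {"polysomy": [1] * 10, "os_months": range(1, 11), "os_event": [1] * 10}
        )
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["polysomy"])

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"polysomy": [0, 1] * 5, "os_months": range(1, 11), "os_event": [0] * 10}
        )
        with pytest.raises(ValueError, match="event"):
            cox_fit(df, ["polysomy"])

    def test_multivariate_selects_univariately_significant_covariates(self, rng):
        df = simulate_survival_frame(500, rng, log_hr_polysomy=np.log(2.5))
        df["noise_cov"] = rng.integers(0, 2, size=len(df))
        results = cox_fit(
            df, ["polysomy", "noise_cov"], scope=ModelScope.MULTIVARIATE
        )
        names = {r.covariate for r in results}
        assert "polysomy" in names
        assert all(r.scope is ModelScope.MULTIVARIATE for r in results)
        for r in results:
            assert r.ci_low <= r.hazard_ratio <= r.ci_high
            assert r.hazard_ratio > 0


class TestSurvivalTable:
    def test_all_censored_stratum(self):
        df = pd.DataFrame(
            {"g": [0] * 5, "os_months": [250] * 5, "os_event": [0] * 5}
        )
        table = survival_table(df, "g")
        assert table.loc[0, "median_months"] is None
        for h in (12, 60, 120, 180, 240):
            assert table.loc[0, f"s_{h}m"] == 1.0

    def test_single_subject_event_at_twelve_months(self):
        df = pd.DataFrame({"g": [0], "os_months": [12.0], "os_event": [1]})
        table = survival_table(df, "g")
        assert table.loc[0, "s_12m"] == 0.0

    def test_designed_five_year_survival_recovered(self, rng):
        # exponential with S(60) = 0.78 exactly
        lam = -np.log(0.78) / 60
        n = 4000
        times = rng.exponential(1 / lam, size=n)
        df = pd.DataFrame({"g": [0] * n, "os_months": times, "os_event": [1] * n})
        table = survival_table(df, "g")
        assert table.loc[0, "s_60m"] == pytest.approx(0.78, abs=0.02)


class TestRecordsToFrame:
    def test_indicator_encoding_and_unknowns(self):
        records = [
            PatientRecord("P1", "O3", 10, True, 20, True, mvp="glomeruloid",
                          mitoses_class="gt5"),
            PatientRecord("P2", "O2", 30, False, 30, False),
        ]
        df = records_to_frame(records, extra={"polysomy": {"P1": 1.0}})
        assert df.loc["P1", "grade_O3"] == 1
        assert df.loc["P2", "grade_O3"] == 0
        assert df.loc["P1", "mvp_glomeruloid"] == 1
        assert np.isnan(df.loc["P2", "mvp_glomeruloid"])
        assert df.loc["P1", "polysomy"] == 1.0
        assert np.isnan(df.loc["P2", "polysomy"])
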