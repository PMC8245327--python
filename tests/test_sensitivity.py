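"""Sensitivity analyses: leave-one-out, cohort restriction, and the
90-day first-event follow-up variant."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import saeratio as sr
from saeratio.standardise import DAYS_PER_YEAR


def pooled_ratio_fit(expected):
    """Closed-form pooled E/O fit used to test the leave-one-out driver
    without MCMC."""

    def fit(trials):
        e = sum(expected[t.trial_id] for t in trials)
        o = sum(t.observed_count for t in trials)
        return {"sr": e / o}

    return fit


def make_trial(tid, n_sae):
    return sr.TrialRecord(tid, "standard", 1000, 100.0, n_sae,
                          mean_age=55.0, pct_women=0.5)


class TestLeaveOneOut:
    def test_identical_trials_give_identical_variants(self):
        trials = [make_trial(f"t{i}", 10) for i in range(10)]
        expected = {t.trial_id: 40.0 for t in trials}
        report = sr.leave_one_out(trials, pooled_ratio_fit(expected))
        values = [res["sr"] for _, res in report.per_variant_results]
        assert len(set(values)) == 1

    def test_variant_count_matches_trials(self):
        trials = [make_trial(f"t{i}", 5 + i) for i in range(11)]
        expected = {t.trial_id: 30.0 for t in trials}
        report = sr.leave_one_out(trials, pooled_ratio_fit(expected))
        assert len(report.per_variant_results) == 11
        labels = {label for label, _ in report.per_variant_results}
        assert labels == {f"excluding_{t.trial_id}" for t in trials}

    def test_outlier_exclusion_moves_estimate_most(self):
        trials = [make_trial(f"t{i}", 10) for i in range(9)]
        trials.append(make_trial("outlier", 400))
        expected = {t.trial_id: 40.0 for t in trials}
        full = pooled_ratio_fit(expected)(trials)["sr"]
        report = sr.leave_one_out(trials, pooled_ratio_fit(expected))
        shifts = {label: abs(res["sr"] - full)
                  for label, res in report.per_variant_results}
        assert max(shifts, key=shifts.get) == "excluding_outlier"

    def test_failing_variant_is_isolated(self):
        trials = [make_trial(f"t{i}", 10) for i in range(5)]
        expected = {t.trial_id: 40.0 for t in trials if t.trial_id != "t0"}

        def fragile(subset):
            return {"sr": sum(expected[t.trial_id] for t in subset)}

        report = sr.leave_one_out(trials, fragile)
        by_label = dict(report.per_variant_results)
        assert isinstance(by_label["excluding_t0"], dict)
        assert sum(isinstance(v, Exception) for v in by_label.values()) == 4

    def test_requires_three_trials(self):
        with pytest.raises(ValueError, match="3 trials"):
            sr.leave_one_out([make_trial("a", 1), make_trial("b", 1)],
                             lambda ts: {})


class TestRestrictCohort:
    def test_no_flags_is_identity(self):
        scn = sr.CohortScenario(
            n_persons=500, seed=1,
            condition_prevalence={k: 0.0 for k in
                                  ("recent_mi_stroke", "diabetes",
                                   "heart_failure", "ckd")})
        cohort = sr.generate_cohort(scn, with_event_times=False)
        restricted = sr.restrict_cohort(cohort)
        pd.testing.assert_frame_equal(restricted, cohort)

    def test_all_flagged_gives_empty(self):
        scn = sr.CohortScenario(
            n_persons=200, seed=1,
            condition_prevalence={"recent_mi_stroke": 0.0, "diabetes": 1.0,
                                  "heart_failure": 0.0, "ckd": 0.0})
        cohort = sr.generate_cohort(scn, with_event_times=False)
        restricted = sr.restrict_cohort(cohort)
        assert len(restricted) == 0
        from saeratio.rates import RateModelError
        with pytest.raises(RateModelError):
            sr.fit_rate_model(restricted)

    def test_missing_flag_column_named(self):
        cohort = pd.DataFrame({"age": [60.0], "sex": ["male"],
                               "person_years": [1.0], "n_events": [0]})
        with pytest.raises(ValueError, match="diabetes"):
            sr.restrict_cohort(cohort)

    def test_planted_high_risk_subgroup_direction(self):
        """Flagged persons carry doubled rates: the restricted-cohort
        model predicts lower rates at every age and sex."""
        scn = sr.CohortScenario(
            n_persons=60_000, seed=8,
            condition_prevalence={"recent_mi_stroke": 0.0, "diabetes": 0.3,
                                  "heart_failure": 0.0, "ckd": 0.0},
            condition_rate_multiplier={"recent_mi_stroke": 1.0, "diabetes": 2.0,
                                       "heart_failure": 1.0, "ckd": 1.0})
        cohort = sr.generate_cohort(scn, with_event_times=False)
        full = sr.fit_rate_model(cohort)
        restricted = sr.fit_rate_model(sr.restrict_cohort(cohort))
        ages = np.arange(30, 91, 10, dtype=float)
        for sex in ("male", "female"):
            assert np.all(sr.predict_rate(restricted, ages, sex)
                          < sr.predict_rate(full, ages, sex))


class TestTruncateFollowupFirstEvent:
    def _cohort(self, rows):
        return pd.DataFrame(rows)

    def test_no_event_person_censored_at_window(self):
        cohort = self._cohort([{
            "person_id": "a", "age": 60.0, "sex": "male",
            "person_years": 3.0, "n_events": 0, "event_times": ""}])
        out = sr.truncate_followup_first_event(cohort, window_days=90.0)
        assert out.loc[0, "person_years"] == pytest.approx(90 / DAYS_PER_YEAR)
        assert out.loc[0, "n_events"] == 0

    def test_event_at_day_ten_censors_there(self):
        cohort = self._cohort([{
            "person_id": "a", "age": 60.0, "sex": "male",
            "person_years": 3.0, "n_events": 2, "event_times": "10.0;200.0"}])
        out = sr.truncate_followup_first_event(cohort, window_days=90.0)
        assert out.loc[0, "person_years"] == pytest.approx(10 / DAYS_PER_YEAR)
        assert out.loc[0, "n_events"] == 1

    def test_short_followup_beats_window(self):
        cohort = self._cohort([{
            "person_id": "a", "age": 60.0, "sex": "male",
            "person_years": 0.1, "n_events": 0, "event_times": ""}])
        out = sr.truncate_followup_first_event(cohort, window_days=90.0)
        assert out.loc[0, "person_years"] == pytest.approx(0.1)

    def test_event_after_window_not_counted(self):
        cohort = self._cohort([{
            "person_id": "a", "age": 60.0, "sex": "male",
            "person_years": 3.0, "n_events": 1, "event_times": "200.0"}])
        out = sr.truncate_followup_first_event(cohort, window_days=90.0)
        assert out.loc[0, "n_events"] == 0
        assert out.loc[0, "person_years"] == pytest.approx(90 / DAYS_PER_YEAR)

    def test_missing_event_times_instructs_regeneration(self):
        cohort = pd.DataFrame({"person_id": ["a"], "person_years": [1.0],
                               "n_events": [0]})
        with pytest.raises(ValueError, match="regenerate"):
            sr.truncate_followup_first_event(cohort)

    def test_constant_hazard_intercept_consistency(self, clean_cohort_scenario):
        """Under a homogeneous Poisson process, the first-event/90-day
        rate model recovers the same intercept as the full model."""
        import dataclasses as dc

        scn = dc.replace(clean_cohort_scenario, n_persons=60_000, seed=31)
        cohort = sr.generate_cohort(scn, with_event_times=True)
        full = sr.fit_rate_model(cohort)
        truncated = sr.truncate_followup_first_event(cohort, window_days=90.0)
        trunc_model = sr.fit_rate_model(truncated)
        se = math.sqrt(full.vcov[0, 0] + trunc_model.vcov[0, 0])
        assert abs(full.coefficients[0] - trunc_model.coefficients[0]) < 3 * se
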