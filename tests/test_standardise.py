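"""Person-time, age-sex distributions, expected counts and the E/O
Monte Carlo procedure."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

import saeratio as sr
from saeratio.standardise import (
    PersonTimeError,
    StandardisationIneligibleError,
    _zero_truncated_poisson,
)


class TestPersonYears:
    @pytest.mark.parametrize(
        "n, followup, n_sae, expected",
        [
            (100, 365.25, 0, 100.0),
            (100, 365.25, 10, 95.0),
            (722, 73.05, 8, 0.2 * (722 - 4)),
        ],
    )
    def test_printed_formula(self, n, followup, n_sae, expected):
        t = sr.TrialRecord("t", "standard", n, followup, n_sae,
                           mean_age=55.0, pct_women=0.5)
        assert sr.estimate_person_years(t) == pytest.approx(expected)

    def test_nonpositive_exposure_is_domain_error(self):
        t = sr.TrialRecord("t", "standard", 5, 100.0, 10,
                           mean_age=55.0, pct_women=0.5)
        with pytest.raises(PersonTimeError):
            sr.estimate_person_years(t)


class TestAgeSexDistribution:
    def test_all_women_zeroes_male_strata(self, simple_trial):
        t = dataclasses.replace(simple_trial, pct_women=1.0)
        dist = sr.trial_age_sex_distribution(t)
        male = dist.strata[dist.strata["sex"] == "male"]
        assert (male["weight"] == 0).all()

    @pytest.mark.parametrize("pct_women", [0.0, 0.3, 0.45, 0.9])
    def test_weights_sum_to_one(self, simple_trial, pct_women):
        t = dataclasses.replace(simple_trial, pct_women=pct_women)
        dist = sr.trial_age_sex_distribution(t)
        assert dist.strata["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_discretised_mean_matches_reported(self, simple_trial):
        dist = sr.trial_age_sex_distribution(simple_trial, bin_width=1.0)
        assert abs(dist.mean_age() - simple_trial.mean_age) < 0.5

    def test_missing_age_sex_data_signals_exclusion(self, simple_trial):
        t = dataclasses.replace(simple_trial, mean_age=None, sd_age=None)
        with pytest.raises(StandardisationIneligibleError):
            sr.trial_age_sex_distribution(t)
        t2 = dataclasses.replace(simple_trial, pct_women=None)
        with pytest.raises(StandardisationIneligibleError):
            sr.trial_age_sex_distribution(t2)


class TestExpectedCount:
    def test_rate_times_exposure(self):
        model = sr.RateModel(["intercept"], np.array([math.log(0.5)]),
                             np.zeros((1, 1)))
        t = sr.TrialRecord("t", "standard", 100, 365.25, 10,
                           mean_age=55.0, sd_age=8.0, pct_women=0.5)
        dist = sr.trial_age_sex_distribution(t)
        assert sr.expected_count(t, dist, model) == pytest.approx(95.0 * 0.5)

    def test_linear_in_exposure(self, simple_trial, point_rate_model):
        dist = sr.trial_age_sex_distribution(simple_trial)
        e1 = sr.expected_count(simple_trial, dist, point_rate_model)
        doubled = dataclasses.replace(
            simple_trial, followup_days=2 * simple_trial.followup_days
        )
        e2 = sr.expected_count(doubled, dist, point_rate_model)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_brute_force_individual_oracle(self, simple_trial, point_rate_model):
        """Simulating 200k individuals from the fitted truncated normal and
        sex mix reproduces the weighted-strata expected count within 1%."""
        t = simple_trial
        params = sr.fit_truncated_normal(t.mean_age, t.sd_age, t.min_age,
                                         math.inf)
        rng = np.random.default_rng(123)
        n = 200_000
        a = (max(params.lower, 18.0) - params.mu) / params.sigma
        b = (100.0 - params.mu) / params.sigma
        ages = stats.truncnorm.rvs(a, b, loc=params.mu, scale=params.sigma,
                                   size=n, random_state=rng)
        female = rng.random(n) < t.pct_women
        rates = sr.predict_rate(point_rate_model, ages, female.astype(float))
        oracle = sr.estimate_person_years(t) * rates.mean()
        dist = sr.trial_age_sex_distribution(t)
        e = sr.expected_count(t, dist, point_rate_model)
        assert e == pytest.approx(oracle, rel=0.01)

    def test_invariant_to_bin_refinement(self, simple_trial, point_rate_model):
        d1 = sr.trial_age_sex_distribution(simple_trial, bin_width=1.0)
        d2 = sr.trial_age_sex_distribution(simple_trial, bin_width=0.5)
        e1 = sr.expected_count(simple_trial, d1, point_rate_model)
        e2 = sr.expected_count(simple_trial, d2, point_rate_model)
        assert abs(e2 - e1) / e1 < 1e-3


class TestEORatioMC:
    def test_zero_events_excluded(self, simple_trial, point_rate_model):
        t = dataclasses.replace(simple_trial, n_sae=0)
        res = sr.eo_ratio_mc(t, point_rate_model, n_samples=100, seed=0)
        assert res.status == "excluded_zero_events"
        assert res.ratio_mean is None

    def test_one_event_flagged_unstable(self, simple_trial, point_rate_model):
        t = dataclasses.replace(simple_trial, n_sae=1)
        res = sr.eo_ratio_mc(t, point_rate_model, n_samples=500, seed=0)
        assert res.status == "unstable_low_events"
        assert res.ratio_mean is not None

    def test_hard_outcome_pools_endpoint_events(self, simple_trial):
        t = dataclasses.replace(simple_trial, outcome_type="hard",
                                n_endpoint_events=5)
        assert t.observed_count == simple_trial.n_sae + 5
        soft = dataclasses.replace(simple_trial, outcome_type="soft",
                                   n_endpoint_events=5)
        assert soft.observed_count == simple_trial.n_sae

    def test_degenerate_limit(self, point_rate_model):
        """vcov = 0 and a huge observed count: the ratio collapses to
        expected/observed with vanishing interval width."""
        t = sr.TrialRecord("t", "standard", 3_000_000, 365.25, 1_000_000,
                           mean_age=55.0, sd_age=8.0, pct_women=0.5)
        res = sr.eo_ratio_mc(t, point_rate_model, n_samples=4000, seed=1)
        target = res.expected_count / t.observed_count
        assert res.ratio_mean == pytest.approx(target, rel=0.005)
        assert (res.ratio_hi - res.ratio_lo) / res.ratio_mean < 0.02

    def test_truncated_poisson_reciprocal_oracle(self, simple_trial,
                                                 point_rate_model):
        """vcov = 0: ratio_mean -> expected x E[1/T], T zero-truncated
        Poisson(observed), brute-forced with 1e6 draws."""
        res = sr.eo_ratio_mc(simple_trial, point_rate_model,
                             n_samples=20_000, seed=7)
        rng = np.random.default_rng(99)
        draws = _zero_truncated_poisson(rng, float(simple_trial.observed_count),
                                        1_000_000)
        recip = 1.0 / draws
        oracle = res.expected_count * recip.mean()
        se = res.expected_count * recip.std() / math.sqrt(res.n_samples)
        assert abs(res.ratio_mean - oracle) < 3 * se

    def test_deterministic_under_seed(self, simple_trial, rate_model):
        a = sr.eo_ratio_mc(simple_trial, rate_model, n_samples=1000, seed=5)
        b = sr.eo_ratio_mc(simple_trial, rate_model, n_samples=1000, seed=5)
        assert (a.ratio_mean, a.ratio_lo, a.ratio_hi) == (
            b.ratio_mean, b.ratio_lo, b.ratio_hi)

    def test_cross_pairing_cap(self, simple_trial, rate_model):
        with pytest.raises(ValueError, match="cross"):
            sr.eo_ratio_mc(simple_trial, rate_model, n_samples=10_000,
                           seed=0, pairing="cross")

    def test_cross_and_paired_agree_in_mean(self, simple_trial, rate_model):
        paired = sr.eo_ratio_mc(simple_trial, rate_model, n_samples=4000,
                                seed=3, pairing="paired")
        cross = sr.eo_ratio_mc(simple_trial, rate_model, n_samples=4000,
                               seed=3, pairing="cross")
        assert cross.ratio_mean == pytest.approx(paired.ratio_mean, rel=0.05)

    def test_zero_truncated_sampler_never_returns_zero(self):
        rng = np.random.default_rng(0)
        draws = _zero_truncated_poisson(rng, 0.05, 10_000)
        assert draws.min() >= 1
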