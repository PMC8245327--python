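"""Hierarchical Poisson models: frequentist oracles at degenerate
settings, null behaviour, recovery, and summary-scale consistency."""

import math

import numpy as np
import pytest
import statsmodels.api as smapi

import saeratio as sr
from saeratio._mcmc import PriorSpec
from saeratio.hier import EmptyComparisonError, HierModelSpec, build_trial_design

FAST = dict(chains=2, warmup=600, draws=600)


def flat_spec(**kw):
    base = dict(prior=PriorSpec(flat=True), tau_fixed=0.0, seed=1, **FAST)
    base.update(kw)
    return HierModelSpec(**base)


@pytest.fixture(scope="module")
def registry():
    return sr.generate_irr_registry(n_standard=40, n_older=12, seed=3,
                                    random_intercept_sd=0.3)


class TestGLMOracle:
    def test_fixed_effects_match_poisson_glm(self, registry):
        """Random intercept fixed at 0 with flat priors: posterior medians
        agree with the classical Poisson GLM MLE within 2%."""
        res = sr.fit_irr(registry, flat_spec())
        y = np.array([t.n_sae for t in registry], dtype=float)
        offset = np.log([sr.estimate_person_years(t) for t in registry])
        X, names = build_trial_design(registry, ("older_group",))
        glm = smapi.GLM(y, X, family=smapi.families.Poisson(),
                        offset=offset).fit()
        med = res.term_summaries.query("scale == 'log'").set_index("term")["median"]
        for j, name in enumerate(names):
            assert med[name] == pytest.approx(glm.params[j], abs=0.02)

    def test_closed_form_sr(self, registry):
        """Single group, no random intercept, flat prior: the SR equals
        the indirectly standardised ratio sum(E)/sum(O)."""
        standard = [t for t in registry if t.group == "standard"]
        expected = {t.trial_id: 2.0 * t.n_sae + 3.0 for t in standard}
        res = sr.fit_sr(standard, expected, flat_spec())
        total_e = sum(expected.values())
        total_o = sum(t.observed_count for t in standard)
        sr_hat = res.derived_contrasts["sr_standard"]["median"]
        assert sr_hat == pytest.approx(total_e / total_o, rel=0.01)


class TestSummaries:
    @pytest.fixture(scope="class")
    def result(self, registry):
        return sr.fit_irr(registry, HierModelSpec(seed=2, **FAST))

    def test_exp_scale_is_monotone_transform_of_log(self, result):
        log_s = result.term_summaries.query("scale == 'log'").set_index("term")
        exp_s = result.term_summaries.query("scale == 'exp'").set_index("term")
        for term in result.term_names:
            for col in ("median", "lo", "hi"):
                assert exp_s.loc[term, col] == pytest.approx(
                    math.exp(log_s.loc[term, col]), rel=1e-9)

    def test_interval_ordering(self, result):
        df = result.term_summaries
        assert (df["lo"] <= df["median"]).all()
        assert (df["median"] <= df["hi"]).all()

    def test_diagnostics_reported_for_every_parameter(self, result):
        assert set(result.diagnostics["rhat"]) >= set(result.term_names)
        assert "random_intercept_sd" in result.diagnostics["rhat"]

    def test_deterministic_under_seed(self, registry):
        a = sr.fit_irr(registry, HierModelSpec(seed=7, **FAST))
        b = sr.fit_irr(registry, HierModelSpec(seed=7, **FAST))
        assert a.derived_contrasts == b.derived_contrasts

    def test_stable_across_seeds(self, registry):
        a = sr.fit_irr(registry, HierModelSpec(seed=7, **FAST))
        b = sr.fit_irr(registry, HierModelSpec(seed=8, **FAST))
        ma = a.derived_contrasts["irr_older_vs_standard"]["median"]
        mb = b.derived_contrasts["irr_older_vs_standard"]["median"]
        assert ma == pytest.approx(mb, rel=0.06)


class TestRecovery:
    def test_null_irr_coverage(self):
        """Equal true rates in both groups: the 95% CrI for the group
        contrast contains 1.0 in at least 90% of 50 replicates."""
        covered = 0
        for seed in range(50):
            recs = sr.generate_irr_registry(
                n_standard=50, n_older=50, true_irr=1.0,
                random_intercept_sd=0.3, seed=seed)
            res = sr.fit_irr(recs, HierModelSpec(seed=seed, chains=2,
                                                 warmup=300, draws=300))
            d = res.derived_contrasts["irr_older_vs_standard"]
            covered += d["lo"] <= 1.0 <= d["hi"]
        assert covered >= 45

    def test_irr_recovery(self):
        recs = sr.generate_irr_registry(seed=0)  # 60+12 at IRR 1.75
        res = sr.fit_irr(recs, HierModelSpec(seed=0, **FAST))
        d = res.derived_contrasts["irr_older_vs_standard"]
        assert abs(math.log(d["median"] / 1.75)) < math.log(1.2)
        assert d["lo"] <= 1.75 <= d["hi"]

    def test_degenerate_variance_recovery(self):
        """Registry generated without heterogeneity: the posterior for the
        intercept SD concentrates near zero."""
        recs = sr.generate_irr_registry(n_standard=80, n_older=20,
                                        random_intercept_sd=0.0, seed=9)
        res = sr.fit_irr(recs, HierModelSpec(seed=9, **FAST))
        assert res.random_intercept_sd_summary["hi"] < 0.3

    def test_sr_identity_at_true_sr_one(self, point_rate_model):
        scn = sr.TrialScenario(n_trials_standard=40, n_trials_older=10,
                               true_sr_standard=1.0, true_sr_older=1.0,
                               random_intercept_sd=0.05, seed=13)
        recs = sr.trials_frame_to_records(
            sr.generate_trials(scn, point_rate_model))
        expected = {t.trial_id: sr.expected_count(
            t, sr.trial_age_sex_distribution(t), point_rate_model)
            for t in recs}
        res = sr.fit_sr(recs, expected, HierModelSpec(seed=13, **FAST))
        for name in ("sr_standard", "sr_older"):
            d = res.derived_contrasts[name]
            assert d["lo"] <= 1.0 <= d["hi"]


class TestCompareArms:
    def _arm_records(self, true_irr, n_trials, seed):
        scn = sr.TrialScenario(
            n_trials_standard=n_trials, n_trials_older=0, seed=seed,
            random_intercept_sd=0.2,
            covariate_mix={"renin_inhibitor": 0.3, "placebo": 1.0,
                           "other_class_3char": 0.0, "other_class_5char": 0.0,
                           "phase4": 0.35, "hard_outcome": 0.0},
        )
        model = sr.RateModel(["intercept", "age", "female"],
                             np.array([-4.8, 0.05, -0.10]), np.zeros((3, 3)))
        trials = sr.generate_trials(scn, model)
        arms = sr.generate_trial_arms(trials, true_arm_irr=true_irr, seed=seed)
        return sr.trials_frame_to_records(arms)

    def test_null_arm_ratio(self):
        recs = self._arm_records(1.0, 40, 17)
        res = sr.compare_arms(recs, HierModelSpec(fixed_terms=("arm",),
                                                  seed=17, **FAST))
        d = res.derived_contrasts["irr_treatment_vs_placebo"]
        assert d["lo"] <= 1.0 <= d["hi"]

    def test_arm_ratio_recovery(self):
        recs = self._arm_records(0.8, 30, 23)
        res = sr.compare_arms(recs, HierModelSpec(fixed_terms=("arm",),
                                                  seed=23, **FAST))
        d = res.derived_contrasts["irr_treatment_vs_placebo"]
        assert abs(math.log(d["median"] / 0.8)) < math.log(1.25)

    def test_single_trial_runs_with_flag(self):
        recs = self._arm_records(0.8, 1, 29)
        res = sr.compare_arms(recs, HierModelSpec(fixed_terms=("arm",),
                                                  seed=29, **FAST))
        assert any("low-information" in n for n in res.notes)
        d = res.derived_contrasts["irr_treatment_vs_placebo"]
        assert d["hi"] > d["lo"]

    def test_no_placebo_trials_signals_empty(self, registry):
        with pytest.raises(EmptyComparisonError):
            sr.compare_arms([t for t in registry if t.arm is None])


def test_separation_warns(registry):
    zeroed = [sr.TrialRecord(
        trial_id=t.trial_id, group=t.group, n_participants=t.n_participants,
        followup_days=t.followup_days,
        n_sae=0 if t.drug_class == "renin_inhibitor" else t.n_sae,
        mean_age=t.mean_age, min_age=t.min_age, pct_women=t.pct_women,
        drug_class=t.drug_class, comparison_type=t.comparison_type,
        phase=t.phase, outcome_type=t.outcome_type) for t in registry]
    with pytest.warns(UserWarning, match="zero events"):
        sr.fit_irr(zeroed, HierModelSpec(
            fixed_terms=("older_group", "drug_class"), seed=1,
            chains=2, warmup=200, draws=200))
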