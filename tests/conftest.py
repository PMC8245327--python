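import numpy as np
import pytest

import saeratio as sr


@pytest.fixture(scope="session")
def clean_cohort_scenario():
    """Cohort scenario with comorbidity effects switched off, so the
    age-sex model is correctly specified (parameter-recovery surface)."""
    return sr.CohortScenario(
        n_persons=30_000,
        beta0=-4.8,
        beta_age=0.05,
        beta_sex=-0.10,
        condition_prevalence={k: 0.0 for k in
                              ("recent_mi_stroke", "diabetes", "heart_failure", "ckd")},
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(clean_cohort_scenario):
    return sr.generate_cohort(clean_cohort_scenario, with_event_times=False)


@pytest.fixture(scope="session")
def rate_model(cohort):
    return sr.fit_rate_model(cohort)


@pytest.fixture(scope="session")
def point_rate_model():
    """Rate model with exact coefficients and zero vcov: deterministic
    expected counts, no coefficient uncertainty."""
    k = 3
    return sr.RateModel(
        terms=["intercept", "age", "female"],
        coefficients=np.array([-4.8, 0.05, -0.10]),
        vcov=np.zeros((k, k)),
        n_fitted=0,
    )


@pytest.fixture()
def simple_trial():
    return sr.TrialRecord(
        trial_id="t1",
        group="standard",
        n_participants=722,
        followup_days=98.0,
        n_sae=8,
        mean_age=55.6,
        sd_age=8.0,
        min_age=18.0,
        pct_women=0.45,
    )
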