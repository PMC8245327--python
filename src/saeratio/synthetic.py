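"""Synthetic community cohort and trial registry with known ground truth.

The generators stand in for the two external data sources the pipeline
was designed around: a community cohort of adults starting
antihypertensive (RAAS) treatment, and a registry of hypertension trials
reporting serious adverse events (SAEs).  Ground truth — the log-linear
age-sex rate coefficients, the true standardised ratio (SR) per trial
group, and the between-trial heterogeneity — is known by construction,
so every downstream stage has a parameter-recovery test surface.

Cohort: ages are truncated-normal, follow-up is censored by an
exponential deregistration process, and hospitalisation/death counts are
Poisson under rate = exp(beta0 + beta_age*age + beta_sex*I[female]),
optionally multiplied up for comorbid subgroups (condition flags used by
the sensitivity analyses).  Event times are uniform over follow-up
(homogeneous Poisson process), enabling first-event/90-day censoring.

Trials: each trial's expected community count E is computed through the
same standardisation machinery used for inference; its observed SAE
count is Poisson(E / SR_group x exp(u)) with a lognormal trial-level
random effect u ~ Normal(0, random_intercept_sd^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .rates import RateModel
from .standardise import (
    DAYS_PER_YEAR,
    TrialRecord,
    estimate_person_years,
    expected_count,
    trial_age_sex_distribution,
)

#: comorbidity flags carried by every synthetic cohort.  recent_mi_stroke is
#: excluded at baseline cohort construction; the other three are the
#: misclassification sensitivity analysis.
CONDITION_FLAGS = ("recent_mi_stroke", "diabetes", "heart_failure", "ckd")


def _validate(obj, checks: dict[str, bool]) -> None:
    for name, ok in checks.items():
        if not ok:
            raise ValueError(f"{type(obj).__name__}: invalid field {name!r}")


@dataclass
class CohortScenario:
    """Generative settings for the community cohort.

    Defaults describe a cohort of ~56k adults with hypertension starting
    RAAS drugs, followed up to 3 years: mean age 60.6 (SD 13.9), 50.3%
    women.  The rate coefficients are calibrated from the registry-side
    anchors (trial SAE rates around 0.11/0.18 events per person-year at
    mean ages 55.6/73.1, with community rates roughly 4.2-4.8 times
    higher): about 0.46 events/person-year at age 55.6 rising to about
    0.86 at 73.1, i.e. a log-rate slope of 0.036 per year of age.
    """

    n_persons: int = 56_036
    age_mean: float = 60.6
    age_sd: float = 13.9
    age_range: tuple[float, float] = (18.0, 100.0)
    prop_female: float = 0.503
    beta0: float = -2.75  # log events/person-year at age 0, male
    beta_age: float = 0.036  # per year of age
    beta_sex: float = -0.10  # female vs male
    max_followup: float = 3.0  # years
    annual_dropout_prob: float = 0.03
    seed: int = 0
    condition_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "recent_mi_stroke": 0.0,
            "diabetes": 0.15,
            "heart_failure": 0.05,
            "ckd": 0.08,
        }
    )
    condition_rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {
            "recent_mi_stroke": 2.0,
            "diabetes": 1.5,
            "heart_failure": 2.0,
            "ckd": 1.8,
        }
    )

    def __post_init__(self) -> None:
        _validate(
            self,
            {
                "n_persons": self.n_persons > 0,
                "prop_female": 0.0 <= self.prop_female <= 1.0,
                "age_range": self.age_range[0] < self.age_range[1],
                "age_sd": self.age_sd > 0,
                "max_followup": self.max_followup > 0,
                "annual_dropout_prob": 0.0 <= self.annual_dropout_prob < 1.0,
                "beta_age": np.isfinite(self.beta_age),
                "beta_sex": np.isfinite(self.beta_sex),
                "beta0": not math.isnan(self.beta0),  # -inf allowed: zero rate
            },
        )
        for cond in CONDITION_FLAGS:
            p = self.condition_prevalence.get(cond, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"CohortScenario: invalid field 'condition_prevalence[{cond}]'"
                )


def generate_cohort(
    scenario: CohortScenario, with_event_times: bool = True
) -> pd.DataFrame:
    """Simulate the cohort table (one row per person).

    Columns: person_id, age, sex, person_years, n_events, the four
    condition flags, and (optionally) event_times — a semicolon-joined
    list of event offsets in days, sorted ascending.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_persons

    lo, hi = scenario.age_range
    a = (lo - scenario.age_mean) / scenario.age_sd
    b = (hi - scenario.age_mean) / scenario.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=scenario.age_mean, scale=scenario.age_sd, size=n, random_state=rng
    )
    female = rng.random(n) < scenario.prop_female

    if scenario.annual_dropout_prob > 0:
        hazard = -math.log1p(-scenario.annual_dropout_prob)
        dropout = rng.exponential(1.0 / hazard, size=n)
    else:
        dropout = np.full(n, np.inf)
    person_years = np.minimum(scenario.max_followup, dropout)

    log_rate = (
        scenario.beta0
        + scenario.beta_age * ages
        + scenario.beta_sex * female.astype(float)
    )
    flags = {}
    for cond in CONDITION_FLAGS:
        p = scenario.condition_prevalence.get(cond, 0.0)
        flag = rng.random(n) < p if p > 0 else np.zeros(n, dtype=bool)
        flags[cond] = flag
        mult = scenario.condition_rate_multiplier.get(cond, 1.0)
        if mult != 1.0:
            log_rate = log_rate + math.log(mult) * flag.astype(float)

    mean_counts = person_years * np.exp(log_rate)
    n_events = rng.poisson(mean_counts)

    df = pd.DataFrame(
        {
            "person_id": [f"p{i:06d}" for i in range(n)],
            "age": ages,
            "sex": np.where(female, "female", "male"),
            "person_years": person_years,
            "n_events": n_events,
        }
    )
    for cond in CONDITION_FLAGS:
        df[cond] = flags[cond]

    if with_event_times:
        total = int(n_events.sum())
        window_days = np.repeat(person_years * DAYS_PER_YEAR, n_events)
        raw = rng.random(total) * window_days
        starts = np.concatenate(([0], np.cumsum(n_events)))
        times = []
        for i in range(n):
            seg = np.sort(raw[starts[i]: starts[i + 1]])
            times.append(";".join(f"{t:.4f}" for t in seg))
        df["event_times"] = times
    return df


@dataclass
class TrialScenario:
    """Generative settings for the trial registry.

    Defaults emulate a registry of 99 standard + 11 older-people
    hypertension trials: true standardised ratios ~4 in both groups
    (community rates four times trial SAE rates), substantial
    between-trial heterogeneity, trial sizes with median in the
    hundreds, and follow-up mostly of a few months.
    """

    n_trials_standard: int = 99
    n_trials_older: int = 11
    true_sr_standard: float = 4.23
    true_sr_older: float = 4.76
    random_intercept_sd: float = 0.5
    trial_size_range: tuple[int, int] = (100, 3000)
    followup_range: tuple[float, float] = (28.0, 365.0)  # days
    min_age_older: float = 60.0
    mean_age_standard: tuple[float, float] = (55.6, 2.5)  # (mean, sd) of trial means
    mean_age_older: tuple[float, float] = (73.1, 2.0)
    pct_women_standard: float = 0.45
    pct_women_older: float = 0.55
    covariate_mix: dict[str, float] = field(
        default_factory=lambda: {
            "renin_inhibitor": 0.30,
            "placebo": 0.21,
            "other_class_3char": 0.40,
            "other_class_5char": 0.39,
            "phase4": 0.35,
            "hard_outcome": 0.05,
        }
    )
    prob_sd_age_reported: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        _validate(
            self,
            {
                "n_trials_standard": self.n_trials_standard >= 0,
                "n_trials_older": self.n_trials_older >= 0,
                "true_sr_standard": self.true_sr_standard > 0,
                "true_sr_older": self.true_sr_older > 0,
                "random_intercept_sd": self.random_intercept_sd >= 0,
                "trial_size_range": 0 < self.trial_size_range[0] <= self.trial_size_range[1],
                "followup_range": 0 <= self.followup_range[0] <= self.followup_range[1],
            },
        )


class TrialGenerationError(RuntimeError):
    """Raised when a synthetic trial's expected count is not positive."""


def _attrition_consistent_mean(full_exposure_mean: float, n: int) -> float:
    """Event mean consistent with attrition-corrected person-time.

    Downstream person-time is followup x (n - 0.5 x events).  Drawing
    counts at the full-exposure mean m would bias the rate estimand
    upward by ~0.5 m/n; the self-consistent mean lambda solves
    lambda = m (1 - 0.5 lambda / n), i.e. lambda = m / (1 + 0.5 m / n).
    """
    return full_exposure_mean / (1.0 + 0.5 * full_exposure_mean / n)


def _draw_one_trial(
    rng: np.random.Generator,
    scenario: TrialScenario,
    group: str,
    index: int,
) -> TrialRecord:
    mix = scenario.covariate_mix
    n = int(rng.integers(scenario.trial_size_range[0], scenario.trial_size_range[1] + 1))
    f_lo, f_hi = scenario.followup_range
    if f_lo > 0 and f_hi > f_lo:
        followup = float(np.exp(rng.uniform(np.log(f_lo), np.log(f_hi))))
    else:
        followup = float(f_hi)

    if group == "older":
        min_age = float(rng.choice([60.0, 65.0, 70.0], p=[0.6, 0.3, 0.1]))
        min_age = max(min_age, scenario.min_age_older)
        max_age = None if rng.random() < 0.8 else float(rng.choice([85.0, 90.0]))
        m, s = scenario.mean_age_older
        mean_age = float(np.clip(rng.normal(m, s), min_age + 3.0,
                                 (max_age - 3.0) if max_age else 95.0))
        pct_women = float(np.clip(rng.normal(scenario.pct_women_older, 0.05), 0.2, 0.8))
    else:
        min_age = 18.0
        max_age = None if rng.random() < 0.5 else float(rng.choice([75.0, 80.0]))
        m, s = scenario.mean_age_standard
        mean_age = float(np.clip(rng.normal(m, s), min_age + 5.0,
                                 (max_age - 5.0) if max_age else 95.0))
        pct_women = float(np.clip(rng.normal(scenario.pct_women_standard, 0.05), 0.2, 0.8))

    if rng.random() < scenario.prob_sd_age_reported:
        # a reported (truncated) SD is bounded by the uniform limit on the
        # eligibility window and the exponential limit above the minimum age
        sd_age = float(rng.uniform(7.0, 10.0))
        sd_age = min(sd_age, 0.8 * (mean_age - min_age))
        if max_age is not None:
            sd_age = min(sd_age, 0.75 * (max_age - min_age) / math.sqrt(12.0))
    else:
        sd_age = None

    p_pl = mix.get("placebo", 0.2)
    p_3 = mix.get("other_class_3char", 0.4)
    p_5 = max(0.0, 1.0 - p_pl - p_3)
    comparison = str(
        rng.choice(
            ["placebo", "other_class_3char", "other_class_5char"],
            p=np.array([p_pl, p_3, p_5]) / (p_pl + p_3 + p_5),
        )
    )
    return TrialRecord(
        trial_id=f"{'O' if group == 'older' else 'S'}{index:03d}",
        group=group,
        n_participants=n,
        followup_days=followup,
        n_sae=0,  # filled in after the expected count is known
        mean_age=mean_age,
        sd_age=sd_age,
        min_age=min_age,
        max_age=max_age,
        pct_women=pct_women,
        outcome_type="hard" if rng.random() < mix.get("hard_outcome", 0.05) else "soft",
        drug_class=(
            "renin_inhibitor" if rng.random() < mix.get("renin_inhibitor", 0.3) else "other"
        ),
        comparison_type=comparison,
        phase=4 if rng.random() < mix.get("phase4", 0.35) else 3,
    )


def generate_trials(
    trial_scenario: TrialScenario,
    rate_model: RateModel,
    default_sd: float = 8.0,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Simulate the trial registry (one row per trial).

    Returns the trial table with ground-truth columns prefixed ``true_``
    (the generative expected count, random intercept and group SR).
    """
    rng = np.random.default_rng(trial_scenario.seed)
    records: list[dict] = []
    for group, n_trials, true_sr in (
        ("standard", trial_scenario.n_trials_standard, trial_scenario.true_sr_standard),
        ("older", trial_scenario.n_trials_older, trial_scenario.true_sr_older),
    ):
        for i in range(n_trials):
            trial = _draw_one_trial(rng, trial_scenario, group, i)
            dist = trial_age_sex_distribution(
                trial, default_sd=default_sd, bin_width=bin_width
            )
            # full-cohort exposure: the SAE count does not yet exist
            e_gen = expected_count(trial, dist, rate_model)
            if not e_gen > 0:
                raise TrialGenerationError(
                    f"trial {trial.trial_id}: nonpositive expected count"
                )
            u = rng.normal(0.0, trial_scenario.random_intercept_sd)
            lam = _attrition_consistent_mean(
                e_gen / true_sr * math.exp(u), trial.n_participants
            )
            total_events = int(rng.poisson(lam))
            total_events = min(total_events, trial.n_participants)  # <=1 SAE/person
            if trial.outcome_type == "hard" and total_events > 0:
                n_endpoint = int(rng.binomial(total_events, 0.3))
            else:
                n_endpoint = 0
            row = {f.name: getattr(trial, f.name) for f in fields(TrialRecord)}
            row.update(
                n_sae=total_events - n_endpoint,
                n_endpoint_events=n_endpoint,
                true_expected_count=e_gen,
                true_log_random_intercept=u,
                true_sr=true_sr,
            )
            records.append(row)
    return pd.DataFrame(records)


def generate_irr_registry(
    n_standard: int = 60,
    n_older: int = 12,
    base_rate: float = 0.11,
    true_irr: float = 1.75,
    random_intercept_sd: float = 0.3,
    trial_size_range: tuple[int, int] = (100, 3000),
    followup_range: tuple[float, float] = (28.0, 365.0),
    seed: int = 0,
) -> list[TrialRecord]:
    """Registry with a known SAE rate ratio between trial groups.

    SAE counts are Poisson(person-years x base_rate x IRR^[older] x e^u)
    with a shared lognormal trial effect — the direct generative mirror
    of the incidence-rate-ratio model, used for parameter recovery.
    Demographic fields are filled in but do not drive the counts.
    """
    rng = np.random.default_rng(seed)
    records = []
    for group, n_trials in (("standard", n_standard), ("older", n_older)):
        for i in range(n_trials):
            n = int(rng.integers(trial_size_range[0], trial_size_range[1] + 1))
            f_lo, f_hi = followup_range
            followup = float(np.exp(rng.uniform(np.log(f_lo), np.log(f_hi))))
            py = (followup / DAYS_PER_YEAR) * n
            rate = base_rate * (true_irr if group == "older" else 1.0)
            u = rng.normal(0.0, random_intercept_sd)
            lam = _attrition_consistent_mean(py * rate * math.exp(u), n)
            n_sae = int(min(rng.poisson(lam), n))
            records.append(
                TrialRecord(
                    trial_id=f"{'O' if group == 'older' else 'S'}{i:03d}",
                    group=group,
                    n_participants=n,
                    followup_days=followup,
                    n_sae=n_sae,
                    mean_age=73.0 if group == "older" else 55.0,
                    min_age=60.0 if group == "older" else 18.0,
                    pct_women=0.5,
                    drug_class="renin_inhibitor" if rng.random() < 0.3 else "other",
                    comparison_type=str(
                        rng.choice(["placebo", "other_class_3char",
                                    "other_class_5char"], p=[0.2, 0.4, 0.4])
                    ),
                    phase=4 if rng.random() < 0.35 else 3,
                    outcome_type="hard" if rng.random() < 0.05 else "soft",
                )
            )
    return records


def generate_trial_arms(
    trials: pd.DataFrame,
    true_arm_irr: float = 0.81,
    seed: int = 0,
) -> pd.DataFrame:
    """Split placebo-controlled trials into treatment/control arm rows.

    Arm event counts are re-drawn Poisson around the trial's generative
    mean, with the treatment:control rate ratio equal to ``true_arm_irr``
    and the trial-level random intercept shared between arms.
    """
    if true_arm_irr <= 0:
        raise ValueError("true_arm_irr must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    placebo = trials[trials["comparison_type"] == "placebo"]
    for _, t in placebo.iterrows():
        mean_total = t["true_expected_count"] / t["true_sr"] * math.exp(
            t["true_log_random_intercept"]
        )
        n_t = int(t["n_participants"]) // 2
        n_c = int(t["n_participants"]) - n_t
        # normalise so the two arms average to the trial mean rate
        r_t = 2.0 * true_arm_irr / (1.0 + true_arm_irr)
        r_c = 2.0 / (1.0 + true_arm_irr)
        for arm, n_arm, rel in (("treatment", n_t, r_t), ("control", n_c, r_c)):
            m = mean_total * (n_arm / t["n_participants"]) * rel
            y = int(min(rng.poisson(_attrition_consistent_mean(m, n_arm)), n_arm))
            rows.append(
                {
                    "trial_id": t["trial_id"],
                    "group": t["group"],
                    "arm": arm,
                    "n_participants": n_arm,
                    "followup_days": t["followup_days"],
                    "n_sae": y,
                    "n_endpoint_events": 0,
                    "outcome_type": t["outcome_type"],
                    "drug_class": t["drug_class"],
                    "comparison_type": "placebo",
                    "phase": t["phase"],
                    "mean_age": t["mean_age"],
                    "sd_age": t["sd_age"],
                    "min_age": t["min_age"],
                    "max_age": t["max_age"],
                    "pct_women": t["pct_women"],
                    "true_arm_irr": true_arm_irr,
                }
            )
    return pd.DataFrame(rows)


def trials_frame_to_records(trials: pd.DataFrame) -> list[TrialRecord]:
    """Convert a trial table (as produced by :func:`generate_trials` or
    read from CSV) into typed :class:`TrialRecord` objects."""
    names = {f.name for f in fields(TrialRecord)}
    records = []
    for _, row in trials.iterrows():
        kwargs = {}
        for k, v in row.items():
            if k not in names:
                continue
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kwargs[k] = None
            elif k in ("n_participants", "n_sae", "n_endpoint_events", "phase"):
                kwargs[k] = int(v)
            else:
                kwargs[k] = v
        records.append(TrialRecord(**kwargs))
    return records


def sae_rate_per_person_year(trial: TrialRecord) -> float:
    """Crude SAE rate: SAE count over estimated person-years."""
    return trial.n_sae / estimate_person_years(trial)
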