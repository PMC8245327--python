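"""End-to-end orchestration: simulate -> fit rates -> standardise -> models.

A run is driven by a :class:`RunConfig` (loadable from a YAML file) and a
single global seed.  Per-stage seeds are derived deterministically from
the global seed with ``numpy.random.SeedSequence(seed, spawn_key=(k,))``
where ``k`` is the stage's fixed index, so stages can be rerun
independently and a completed run's manifest suffices to reproduce its
result files byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hier import EmptyComparisonError, HierModelSpec, compare_arms, fit_irr, fit_sr
from .io import (
    eo_summaries_to_frame,
    read_cohort,
    read_trials,
    write_cohort,
    write_table,
    write_trials,
)
from .rates import RateModel, fit_rate_model
from .sensitivity import (
    leave_one_out,
    restrict_cohort,
    truncate_followup_first_event,
)
from .standardise import (
    StandardisationIneligibleError,
    TrialRecord,
    eo_ratio_mc,
    expected_count,
    trial_age_sex_distribution,
)
from .synthetic import (
    CohortScenario,
    TrialScenario,
    generate_cohort,
    generate_trial_arms,
    generate_trials,
    trials_frame_to_records,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "fit_rates", "standardise", "fit_irr", "fit_sr",
           "compare_arms", "sensitivity")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31)."""
    k = _STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    out_dir: str = "run_output"
    seed: int = 0
    # inputs: either paths to CSVs, or None to simulate
    trial_csv: str | None = None
    cohort_csv: str | None = None
    cohort_scenario: dict = field(default_factory=dict)
    trial_scenario: dict = field(default_factory=dict)
    true_arm_irr: float = 0.81
    # module parameters
    covariate_spec: str = "age_sex"
    default_sd: float = 8.0
    bin_width: float = 1.0
    n_mc_samples: int = 10_000
    pairing: str = "paired"
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    rhat_threshold: float = 1.01
    # stage toggles
    run_sensitivity: tuple[str, ...] = ("leave_one_out", "cohort_restriction",
                                        "followup_90d_first_event")
    loo_max_trials: int = 30  # cap leave-one-out refits in large registries

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _spec(config: RunConfig, offset_kind: str, fixed_terms, stage: str) -> HierModelSpec:
    return HierModelSpec(
        offset_kind=offset_kind,
        fixed_terms=fixed_terms,
        chains=config.chains,
        warmup=config.warmup,
        draws=config.draws,
        seed=stage_seed(config.seed, stage),
        rhat_threshold=config.rhat_threshold,
    )


def standardise_trials(
    records: list[TrialRecord],
    model: RateModel,
    config: RunConfig,
) -> tuple[dict[str, float], list, list[tuple[str, str]]]:
    """Expected counts and E/O ratio summaries for every eligible trial."""
    expected: dict[str, float] = {}
    summaries = []
    exclusions: list[tuple[str, str]] = []
    mc_seed = stage_seed(config.seed, "standardise")
    for i, trial in enumerate(records):
        if trial.arm is not None:
            continue  # arm rows are handled by the arm comparison
        try:
            dist = trial_age_sex_distribution(
                trial, default_sd=config.default_sd, bin_width=config.bin_width
            )
            expected[trial.trial_id] = expected_count(trial, dist, model)
            summaries.append(
                eo_ratio_mc(
                    trial,
                    model,
                    n_samples=config.n_mc_samples,
                    seed=mc_seed + i,
                    pairing=config.pairing,
                    dist=dist,
                )
            )
        except StandardisationIneligibleError as err:
            exclusions.append((trial.trial_id, f"insufficient age-sex data: {err}"))
        except ValueError as err:
            exclusions.append((trial.trial_id, str(err)))
    for tid, why in exclusions:
        logger.info("standardisation exclusion: %s (%s)", tid, why)
    return expected, summaries, exclusions


def _contrast_extractor(expected: dict[str, float], config: RunConfig, stage: str):
    """fit_fn for leave-one-out: refit the SR model, return the contrast."""

    def fit_fn(trials: list[TrialRecord]) -> dict:
        res = fit_sr(trials, expected,
                     _spec(config, "log_expected_count", ("older_group",), stage))
        out = {}
        for name, s in res.derived_contrasts.items():
            out[f"{name}_median"] = s["median"]
            out[f"{name}_lo"] = s["lo"]
            out[f"{name}_hi"] = s["hi"]
        return out

    return fit_fn


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "exclusions": {},
        "results": {},
        "status": "incomplete",
    }

    try:
        # --- inputs ----------------------------------------------------
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
        else:
            cs = CohortScenario(**{"seed": stage_seed(config.seed, "simulate"),
                                   **config.cohort_scenario})
            cohort = generate_cohort(cs)
            write_cohort(cohort, out / "cohort.csv")

        # baseline cohort construction: exclude recent MI/stroke
        if "recent_mi_stroke" in cohort.columns:
            cohort_base = restrict_cohort(cohort, ("recent_mi_stroke",))
        else:
            cohort_base = cohort

        # --- cohort rate model -----------------------------------------
        model = fit_rate_model(cohort_base, covariate_spec=config.covariate_spec)
        model.to_json(out / "rate_model.json")

        if config.trial_csv:
            records, issues = read_trials(config.trial_csv)
            manifest["exclusions"]["trial_read_issues"] = issues
            trials_df = None
        else:
            ts = TrialScenario(**{"seed": stage_seed(config.seed, "simulate") + 1,
                                  **config.trial_scenario})
            trials_df = generate_trials(ts, model, default_sd=config.default_sd,
                                        bin_width=config.bin_width)
            write_trials(trials_frame_to_records(trials_df), out / "trials.csv")
            records = trials_frame_to_records(trials_df)

        whole_trials = [t for t in records if t.arm is None]

        # --- standardisation -------------------------------------------
        expected, summaries, std_exclusions = standardise_trials(
            whole_trials, model, config
        )
        manifest["exclusions"]["standardisation"] = std_exclusions
        manifest["exclusions"]["eo_status"] = {
            s.trial_id: s.status for s in summaries if s.status != "ok"
        }
        write_table(eo_summaries_to_frame(summaries), out / "eo_ratios.csv")

        # --- hierarchical models ---------------------------------------
        irr_unadj = fit_irr(whole_trials,
                            _spec(config, "log_person_years", ("older_group",),
                                  "fit_irr"))
        irr_adj = fit_irr(whole_trials,
                          _spec(config, "log_person_years", ("older_group",),
                                "fit_irr").adjusted())
        write_table(irr_unadj.to_frame(), out / "irr_unadjusted.csv")
        write_table(irr_adj.to_frame(), out / "irr_adjusted.csv")

        sr_unadj = fit_sr(whole_trials, expected,
                          _spec(config, "log_expected_count", ("older_group",),
                                "fit_sr"))
        sr_adj = fit_sr(whole_trials, expected,
                        _spec(config, "log_expected_count", ("older_group",),
                              "fit_sr").adjusted())
        write_table(sr_unadj.to_frame(), out / "sr_unadjusted.csv")
        write_table(sr_adj.to_frame(), out / "sr_adjusted.csv")

        manifest["results"]["irr"] = {
            "unadjusted": irr_unadj.derived_contrasts,
            "adjusted": irr_adj.derived_contrasts,
        }
        manifest["results"]["sr"] = {
            "unadjusted": sr_unadj.derived_contrasts,
            "adjusted": sr_adj.derived_contrasts,
        }

        # --- arm comparison --------------------------------------------
        arm_records = [t for t in records if t.arm is not None]
        if not arm_records and trials_df is not None:
            arm_df = generate_trial_arms(
                trials_df, true_arm_irr=config.true_arm_irr,
                seed=stage_seed(config.seed, "compare_arms"),
            )
            if len(arm_df):
                write_trials(trials_frame_to_records(arm_df), out / "trial_arms.csv")
                arm_records = trials_frame_to_records(arm_df)
        if arm_records:
            try:
                arm_res = compare_arms(
                    arm_records, _spec(config, "log_person_years", ("arm",),
                                       "compare_arms"))
                write_table(arm_res.to_frame(), out / "arm_irr.csv")
                manifest["results"]["arm_irr"] = arm_res.derived_contrasts
            except EmptyComparisonError as err:
                manifest["results"]["arm_irr"] = {"unavailable": str(err)}

        # --- sensitivity analyses --------------------------------------
        sens = {}
        if "leave_one_out" in config.run_sensitivity:
            loo_trials = [t for t in whole_trials if t.trial_id in expected]
            if len(loo_trials) > config.loo_max_trials:
                loo_trials = loo_trials[: config.loo_max_trials]
            if len(loo_trials) >= 3:
                report = leave_one_out(
                    loo_trials, _contrast_extractor(expected, config, "sensitivity")
                )
                write_table(report.to_frame(), out / "sensitivity_leave_one_out.csv")
                sens["leave_one_out"] = {"n_variants": len(report.per_variant_results)}
        if "cohort_restriction" in config.run_sensitivity:
            restricted = restrict_cohort(cohort_base)
            model_r = fit_rate_model(restricted, covariate_spec=config.covariate_spec)
            exp_r, summ_r, _ = standardise_trials(whole_trials, model_r, config)
            write_table(eo_summaries_to_frame(summ_r),
                        out / "sensitivity_cohort_restriction_eo.csv")
            sr_r = fit_sr(whole_trials, exp_r,
                          _spec(config, "log_expected_count", ("older_group",),
                                "sensitivity"))
            write_table(sr_r.to_frame(), out / "sensitivity_cohort_restriction_sr.csv")
            sens["cohort_restriction"] = {
                "n_excluded": int(len(cohort_base) - len(restricted)),
                "sr": sr_r.derived_contrasts,
            }
        if "followup_90d_first_event" in config.run_sensitivity:
            truncated = truncate_followup_first_event(cohort_base, window_days=90.0)
            model_t = fit_rate_model(truncated, covariate_spec=config.covariate_spec)
            exp_t, summ_t, _ = standardise_trials(whole_trials, model_t, config)
            write_table(eo_summaries_to_frame(summ_t),
                        out / "sensitivity_followup_90d_eo.csv")
            sr_t = fit_sr(whole_trials, exp_t,
                          _spec(config, "log_expected_count", ("older_group",),
                                "sensitivity"))
            write_table(sr_t.to_frame(), out / "sensitivity_followup_90d_sr.csv")
            sens["followup_90d_first_event"] = {"sr": sr_t.derived_contrasts}
        manifest["results"]["sensitivity"] = sens

        manifest["status"] = "complete"
    except Exception as err:
        manifest["status"] = f"failed: {type(err).__name__}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    finally:
        manifest["elapsed_seconds"] = round(time.time() - t_start, 2)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def rerun_from_manifest(manifest_path, out_dir: str | None = None) -> dict:
    """Reproduce a run from its manifest's embedded config."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    if out_dir is not None:
        cfg_dict["out_dir"] = out_dir
    for key in ("run_sensitivity",):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    return run_pipeline(RunConfig.from_dict(cfg_dict))
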