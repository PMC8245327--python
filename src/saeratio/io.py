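"""Readers and writers for the pipeline's tables.

Trial CSV schema (one row per trial, or per arm when ``arm`` is set):

    trial_id, group, n_participants, followup_days, n_sae,
    n_endpoint_events, outcome_type, drug_class, comparison_type, phase,
    mean_age, sd_age, min_age, max_age, pct_women, arm

Cohort CSV schema (one row per person):

    person_id, age, sex, person_years, n_events,
    recent_mi_stroke, diabetes, heart_failure, ckd, event_times

Rows violating hard invariants are rejected with row-numbered messages;
rows merely missing the age-sex fields are loaded but are ineligible for
the standardisation stages (they cannot yield an expected count).
"""

from __future__ import annotations

import logging
import math
from dataclasses import fields

import numpy as np
import pandas as pd
import yaml

from .standardise import TrialRecord

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [f.name for f in fields(TrialRecord)]
_INT_FIELDS = {"n_participants", "n_sae", "n_endpoint_events", "phase"}


class TrialTableError(ValueError):
    """Malformed trial table."""


def read_trials(path) -> tuple[list[TrialRecord], list[str]]:
    """Read a trial CSV into typed records.

    Returns (records, issues).  Issues are row-numbered messages for
    rejected rows and warnings for standardisation-ineligible rows.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "group", "n_participants", "followup_days", "n_sae"}
    missing = required - set(df.columns)
    if missing:
        raise TrialTableError(f"trial table missing columns: {sorted(missing)}")
    if df["trial_id"].duplicated().any():
        dupes = df.loc[df["trial_id"].duplicated(), "trial_id"].tolist()
        if "arm" not in df.columns or df.loc[df["trial_id"].isin(dupes), "arm"].isna().any():
            raise TrialTableError(f"duplicate trial_id values: {sorted(set(dupes))}")

    records: list[TrialRecord] = []
    issues: list[str] = []
    if len(df) == 0:
        logger.warning("trial table %s is empty", path)
        issues.append("empty trial table")
        return records, issues

    for idx, row in df.iterrows():
        kwargs = {}
        for name in TRIAL_COLUMNS:
            if name not in df.columns:
                continue
            v = row[name]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kwargs[name] = 0 if name == "n_endpoint_events" else None
            elif name in _INT_FIELDS:
                kwargs[name] = int(v)
            else:
                kwargs[name] = v
        try:
            rec = TrialRecord(**kwargs)
        except (TypeError, ValueError) as err:
            issues.append(f"row {idx + 2}: rejected ({err})")
            continue
        if not rec.standardisation_eligible:
            issues.append(
                f"row {idx + 2}: trial {rec.trial_id} loaded but ineligible for "
                "standardisation (insufficient age-sex data)"
            )
        records.append(rec)
    for msg in issues:
        logger.warning("%s", msg)
    return records, issues


def write_trials(records: list[TrialRecord], path) -> None:
    rows = [{f.name: getattr(r, f.name) for f in fields(TrialRecord)} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    required = {"age", "sex", "person_years", "n_events"}
    missing = required - set(df.columns)
    if missing:
        raise TrialTableError(f"cohort table missing columns: {sorted(missing)}")
    if "event_times" in df.columns:
        df["event_times"] = df["event_times"].fillna("").astype(str)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6g")


def write_table(df: pd.DataFrame, path) -> None:
    """Write a results table: integer counts, 6-significant-digit floats."""
    df.to_csv(path, index=False, float_format="%.6g")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def eo_summaries_to_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "trial_id": s.trial_id,
                "expected_count": s.expected_count,
                "observed_count": s.observed_count,
                "ratio_mean": np.nan if s.ratio_mean is None else s.ratio_mean,
                "ratio_lo": np.nan if s.ratio_lo is None else s.ratio_lo,
                "ratio_hi": np.nan if s.ratio_hi is None else s.ratio_hi,
                "n_samples": s.n_samples,
                "status": s.status,
            }
        )
    return pd.DataFrame(rows)
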