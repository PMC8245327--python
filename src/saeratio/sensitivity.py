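"""Sensitivity analyses: re-runs of the core pipeline under perturbed inputs.

Three designs are supported:

* leave-one-out over trials — refit the registry model excluding each
  trial in turn (robustness to single influential trials, important
  because the older-people group is small);
* cohort restriction — drop community participants flagged with
  diabetes, heart failure or chronic kidney disease, guarding against
  misclassified treatment indication;
* 90-day first-event follow-up — censor each community participant at
  the first event, the 90-day mark, or their original end of follow-up,
  whichever comes first, matching the short follow-up of most trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .standardise import DAYS_PER_YEAR, TrialRecord

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_FLAGS = ("diabetes", "heart_failure", "ckd")


@dataclass
class SensitivityReport:
    analysis_name: str
    per_variant_results: list  # (variant label, result-or-error)
    baseline_reference: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, res in self.per_variant_results:
            if isinstance(res, dict):
                rows.append({"variant": label, **res})
            else:
                rows.append({"variant": label, "error": str(res)})
        return pd.DataFrame(rows)


def leave_one_out(
    trials: Sequence[TrialRecord],
    fit_fn: Callable[[list[TrialRecord]], dict],
) -> SensitivityReport:
    """Refit once per excluded trial.

    ``fit_fn`` maps a trial list to a flat summary dict (e.g. the group
    contrast's median and CrI).  A variant that fails (for instance by
    losing an entire covariate level) is recorded with its error; the
    other variants are unaffected.
    """
    trials = list(trials)
    if len(trials) < 3:
        raise ValueError("leave-one-out needs at least 3 trials")
    variants = []
    for t in trials:
        rest = [x for x in trials if x.trial_id != t.trial_id]
        label = f"excluding_{t.trial_id}"
        try:
            variants.append((label, fit_fn(rest)))
        except Exception as err:  # noqa: BLE001 - variant-level isolation
            logger.warning("leave-one-out variant %s failed: %s", label, err)
            variants.append((label, err))
    return SensitivityReport(
        analysis_name="leave_one_out",
        per_variant_results=variants,
        baseline_reference={"n_trials": len(trials)},
    )


def restrict_cohort(
    cohort: pd.DataFrame,
    exclusion_flags: Sequence[str] = DEFAULT_EXCLUSION_FLAGS,
) -> pd.DataFrame:
    """Subset of the cohort with all named condition flags false."""
    missing = [f for f in exclusion_flags if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing flag columns: {missing}")
    mask = np.ones(len(cohort), dtype=bool)
    for flag in exclusion_flags:
        mask &= ~cohort[flag].astype(bool).to_numpy()
    n_excluded = int((~mask).sum())
    logger.info(
        "cohort restriction: excluded %d of %d participants (%s)",
        n_excluded, len(cohort), ", ".join(exclusion_flags),
    )
    return cohort.loc[mask].reset_index(drop=True)


def _parse_event_times(value) -> np.ndarray:
    if isinstance(value, (list, tuple, np.ndarray)):
        return np.asarray(value, dtype=float)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.array([])
    text = str(value).strip()
    if not text:
        return np.array([])
    return np.array([float(x) for x in text.split(";")])


def truncate_followup_first_event(
    cohort: pd.DataFrame, window_days: float = 90.0
) -> pd.DataFrame:
    """First-event analysis with follow-up capped at ``window_days``.

    Each person is censored at the first event, the window, or their
    original end of follow-up — whichever happens first; counts become
    0/1.
    """
    if "event_times" not in cohort.columns:
        raise ValueError(
            "cohort table has no 'event_times' column; regenerate the "
            "cohort with event times to run the first-event analysis"
        )
    out = cohort.copy()
    new_py = np.empty(len(cohort))
    new_events = np.empty(len(cohort), dtype=int)
    for i, (_, row) in enumerate(cohort.iterrows()):
        end_days = float(row["person_years"]) * DAYS_PER_YEAR
        times = _parse_event_times(row["event_times"])
        horizon = min(window_days, end_days)
        first = times[times <= horizon]
        if first.size:
            new_py[i] = first[0] / DAYS_PER_YEAR
            new_events[i] = 1
        else:
            new_py[i] = horizon / DAYS_PER_YEAR
            new_events[i] = 0
    out["person_years"] = new_py
    out["n_events"] = new_events
    out["event_times"] = [
        f"{t:.4f}" if k else "" for t, k in zip(new_py * DAYS_PER_YEAR, new_events)
    ]
    return out
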