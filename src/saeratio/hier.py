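"""Hierarchical (random-intercept) Poisson models for trial registries.

Two model families share one engine:

* incidence-rate-ratio (IRR) models — SAE counts offset by log estimated
  person-time, contrasting older-people vs standard trials;
* standardised-ratio (SR) models — observed counts offset by the log of
  the community-expected count, so exp(intercept) estimates the
  observed/expected rate and its inverse is the SR (expected/observed:
  SR > 1 means community rates exceed trial rates).

Both support the trial-characteristics adjustment set (drug class,
comparison type, phase, outcome type) and report posterior medians with
2.5/97.5-centile credible intervals on the log and exponentiated scales,
plus rank-normalised R-hat and effective-sample-size diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._mcmc import (
    GroupedPoissonData,
    PriorSpec,
    adaptive_metropolis,
    find_map,
    make_log_posterior,
)
from .standardise import PersonTimeError, TrialRecord, estimate_person_years

logger = logging.getLogger(__name__)

ADJUSTMENT_TERMS = ("drug_class", "comparison_type", "phase", "outcome_type")


class EmptyComparisonError(ValueError):
    """No trials available for the requested comparison."""


@dataclass
class HierModelSpec:
    """Settings for one hierarchical Poisson fit."""

    offset_kind: str = "log_person_years"  # or "log_expected_count"
    fixed_terms: tuple[str, ...] = ("older_group",)
    prior: PriorSpec = field(default_factory=PriorSpec)
    tau_fixed: float | None = None  # fix the random-intercept SD (0 = none)
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01
    gh_nodes: int = 20

    def adjusted(self) -> "HierModelSpec":
        """Variant adding the trial-characteristics adjustment set."""
        terms = tuple(dict.fromkeys([*self.fixed_terms, *ADJUSTMENT_TERMS]))
        return replace(self, fixed_terms=terms)


@dataclass
class HierFitResult:
    """Posterior summaries from one hierarchical Poisson fit."""

    term_names: list[str]
    term_summaries: pd.DataFrame  # term, scale, median, mean, lo, hi, rhat, ess
    random_intercept_sd_summary: dict | None
    derived_contrasts: dict  # name -> summary dict
    diagnostics: dict
    n_trials_used: int
    excluded_trials: list[tuple[str, str]]
    converged: bool
    beta_draws: np.ndarray  # (chains, draws, p)
    tau_draws: np.ndarray | None
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy results table: term, scale, median, lo, hi, diagnostic."""
        rows = [self.term_summaries]
        extra = []
        for name, s in self.derived_contrasts.items():
            extra.append({"term": name, "scale": "derived", **s})
        if self.random_intercept_sd_summary is not None:
            extra.append(
                {"term": "random_intercept_sd", "scale": "sd",
                 **self.random_intercept_sd_summary}
            )
        if extra:
            rows.append(pd.DataFrame(extra))
        return pd.concat(rows, ignore_index=True)


def _summary(draws: np.ndarray) -> dict:
    flat = np.asarray(draws).ravel()
    lo, med, hi = np.percentile(flat, [2.5, 50.0, 97.5])
    return {
        "median": float(med),
        "mean": float(flat.mean()),
        "lo": float(lo),
        "hi": float(hi),
    }


def build_trial_design(
    trials: list[TrialRecord], fixed_terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept plus requested trial-level terms.

    Reference levels: standard group, non-renin-inhibitor drug, placebo
    comparison, phase 3, soft outcome, control arm.
    """
    n = len(trials)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for term in fixed_terms:
        if term == "older_group":
            cols.append(np.array([1.0 if t.group == "older" else 0.0 for t in trials]))
            names.append("older_group")
        elif term == "drug_class":
            cols.append(
                np.array([1.0 if t.drug_class == "renin_inhibitor" else 0.0
                          for t in trials])
            )
            names.append("drug_renin_inhibitor")
        elif term == "comparison_type":
            for level in ("other_class_3char", "other_class_5char"):
                cols.append(
                    np.array([1.0 if t.comparison_type == level else 0.0
                              for t in trials])
                )
                names.append(f"comparison_{level}")
        elif term == "phase":
            cols.append(np.array([1.0 if int(t.phase) == 4 else 0.0 for t in trials]))
            names.append("phase_4")
        elif term == "outcome_type":
            cols.append(np.array([1.0 if t.outcome_type == "hard" else 0.0
                                  for t in trials]))
            names.append("outcome_hard")
        elif term == "arm":
            cols.append(np.array([1.0 if t.arm == "treatment" else 0.0
                                  for t in trials]))
            names.append("arm_treatment")
        else:
            raise ValueError(f"unknown fixed term {term!r}")
    X = np.column_stack(cols)
    # drop constant (all-zero) dummies so the posterior stays identified
    keep = [0] + [
        j for j in range(1, X.shape[1]) if not np.allclose(X[:, j], X[0, j])
    ]
    return X[:, keep], [names[j] for j in keep]


def _check_separation(y: np.ndarray, X: np.ndarray, names: list[str]) -> list[str]:
    flagged = []
    for j in range(1, X.shape[1]):
        for level, mask in (("1", X[:, j] == 1), ("0", X[:, j] == 0)):
            if mask.any() and y[mask].sum() == 0:
                flagged.append(f"{names[j]}={level}")
    for msg in flagged:
        warnings.warn(f"covariate level with zero events across all trials: {msg}",
                      stacklevel=3)
    return flagged


def _fit(
    y: np.ndarray,
    offset: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str],
    spec: HierModelSpec,
) -> tuple[np.ndarray, np.ndarray | None, dict, float]:
    data = GroupedPoissonData(y=y, offset=offset, X=X, groups=groups)
    log_post = make_log_posterior(
        data, spec.prior, tau_fixed=spec.tau_fixed, n_nodes=spec.gh_nodes
    )
    # GLM start for the fixed effects
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta0 = np.asarray(glm.params)
    except Exception:  # noqa: BLE001 - any GLM failure falls back to zeros
        beta0 = np.zeros(X.shape[1])
    x0 = beta0 if spec.tau_fixed is not None else np.append(beta0, 0.3)
    x_map, cov = find_map(log_post, x0)
    theta, accept = adaptive_metropolis(
        log_post,
        x_map,
        cov,
        n_chains=spec.chains,
        n_warmup=spec.warmup,
        n_draws=spec.draws,
        seed=spec.seed,
    )
    p = X.shape[1]
    beta_draws = theta[:, :, :p]
    tau_draws = None if spec.tau_fixed is not None else np.abs(theta[:, :, p])

    ds = {names[j]: beta_draws[:, :, j] for j in range(p)}
    if tau_draws is not None:
        ds["random_intercept_sd"] = tau_draws
    idata = az.convert_to_dataset(ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diagnostics = {
        "rhat": {k: float(rhat[k].values) for k in ds},
        "ess": {k: float(ess[k].values) for k in ds},
        "accept_rate": float(accept),
    }
    diagnostics["max_rhat"] = max(diagnostics["rhat"].values())
    diagnostics["min_ess"] = min(diagnostics["ess"].values())
    return beta_draws, tau_draws, diagnostics, accept


def _summaries_frame(
    names: list[str],
    beta_draws: np.ndarray,
    diagnostics: dict,
) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(names):
        d = beta_draws[:, :, j]
        log_s = _summary(d)
        # centiles are equivariant under the monotone exp transform; the
        # mean is not, so it is recomputed on the exponentiated draws
        exp_s = {
            "median": float(np.exp(log_s["median"])),
            "mean": float(np.exp(d).mean()),
            "lo": float(np.exp(log_s["lo"])),
            "hi": float(np.exp(log_s["hi"])),
        }
        for scale, s in (("log", log_s), ("exp", exp_s)):
            rows.append(
                {
                    "term": name,
                    "scale": scale,
                    **s,
                    "rhat": diagnostics["rhat"][name],
                    "ess": diagnostics["ess"][name],
                }
            )
    return pd.DataFrame(rows)


def _result(
    names, beta_draws, tau_draws, diagnostics, spec, n_used, excluded, derived, notes
) -> HierFitResult:
    converged = diagnostics["max_rhat"] <= spec.rhat_threshold
    if not converged:
        notes = [*notes,
                 f"convergence flag: max R-hat {diagnostics['max_rhat']:.4f} "
                 f"exceeds threshold {spec.rhat_threshold}"]
        logger.warning(notes[-1])
    return HierFitResult(
        term_names=names,
        term_summaries=_summaries_frame(names, beta_draws, diagnostics),
        random_intercept_sd_summary=(
            None if tau_draws is None else _summary(tau_draws)
        ),
        derived_contrasts=derived,
        diagnostics=diagnostics,
        n_trials_used=n_used,
        excluded_trials=excluded,
        converged=converged,
        beta_draws=beta_draws,
        tau_draws=tau_draws,
        notes=list(notes),
    )


def fit_irr(trials: list[TrialRecord], spec: HierModelSpec | None = None) -> HierFitResult:
    """Incidence-rate-ratio model: SAE counts with log person-time offset.

    The derived contrast ``irr_older_vs_standard`` is exp(older-group
    coefficient): the SAE rate in older-people trials relative to
    standard trials.
    """
    spec = spec or HierModelSpec(offset_kind="log_person_years")
    included, offsets, excluded = [], [], []
    for t in trials:
        try:
            offsets.append(np.log(estimate_person_years(t)))
            included.append(t)
        except PersonTimeError as err:
            excluded.append((t.trial_id, str(err)))
    if not included:
        raise EmptyComparisonError("no trials with positive person-time")
    groups_present = {t.group for t in included}
    terms = spec.fixed_terms
    notes = []
    if "older_group" in terms:
        counts = {g: sum(t.group == g for t in included) for g in ("older", "standard")}
        if min(counts.values()) < 2:
            terms = tuple(x for x in terms if x != "older_group")
            notes.append(
                "group contrast dropped: fewer than 2 trials in "
                f"{min(counts, key=counts.get)!r} group"
            )
    y = np.array([float(t.n_sae) for t in included])
    X, names = build_trial_design(included, terms)
    _check_separation(y, X, names)
    groups = np.arange(len(included))
    beta_draws, tau_draws, diagnostics, _ = _fit(
        y, np.array(offsets), X, groups, names, spec
    )
    derived = {}
    if "older_group" in names:
        j = names.index("older_group")
        derived["irr_older_vs_standard"] = _summary(np.exp(beta_draws[:, :, j]))
    return _result(names, beta_draws, tau_draws, diagnostics, spec,
                   len(included), excluded, derived, notes)


def fit_sr(
    trials: list[TrialRecord],
    expected_counts: dict[str, float],
    spec: HierModelSpec | None = None,
) -> HierFitResult:
    """Standardised-ratio model: observed counts with log expected-count
    offset.

    The likelihood estimates observed/expected; all SR outputs are
    reported on the expected/observed scale (negated log-scale
    posterior), so SR > 1 means community rates exceed trial rates.
    Group SRs are evaluated at the reference levels of any adjustment
    covariates and at random intercept = 0.
    """
    spec = spec or HierModelSpec(offset_kind="log_expected_count")
    included, offsets, excluded = [], [], []
    for t in trials:
        e = expected_counts.get(t.trial_id)
        if e is None or not np.isfinite(e) or e <= 0:
            excluded.append((t.trial_id, "no computable expected count"))
            continue
        included.append(t)
        offsets.append(np.log(e))
    if not included:
        raise EmptyComparisonError("no trials with computable expected counts")
    groups_present = {t.group for t in included}
    terms = spec.fixed_terms
    notes = []
    if "older_group" in terms and len(groups_present) < 2:
        terms = tuple(x for x in terms if x != "older_group")
        only = next(iter(groups_present))
        notes.append(f"group contrast absent: only {only!r} trials present")
    y = np.array([float(t.observed_count) for t in included])
    X, names = build_trial_design(included, terms)
    _check_separation(y, X, names)
    groups = np.arange(len(included))
    beta_draws, tau_draws, diagnostics, _ = _fit(
        y, np.array(offsets), X, groups, names, spec
    )

    derived = {}
    i0 = names.index("intercept")
    alpha = beta_draws[:, :, i0]
    if "older_group" in names:
        j = names.index("older_group")
        b_old = beta_draws[:, :, j]
        derived["sr_standard"] = _summary(np.exp(-alpha))
        derived["sr_older"] = _summary(np.exp(-(alpha + b_old)))
        derived["ratio_of_srs"] = _summary(np.exp(-b_old))
    else:
        only = next(iter(groups_present))
        derived[f"sr_{only}"] = _summary(np.exp(-alpha))
    return _result(names, beta_draws, tau_draws, diagnostics, spec,
                   len(included), excluded, derived, notes)


def compare_arms(
    arm_trials: list[TrialRecord], spec: HierModelSpec | None = None
) -> HierFitResult:
    """Treatment vs placebo arm IRR with the trial as the random-intercept
    grouping unit (arms of one trial share an intercept)."""
    spec = spec or HierModelSpec(fixed_terms=("arm",))
    rows = [
        t for t in arm_trials
        if t.arm in ("treatment", "control") and t.comparison_type == "placebo"
    ]
    if not rows:
        raise EmptyComparisonError("no placebo-controlled arm-level trials")
    included, offsets, excluded = [], [], []
    for t in rows:
        try:
            offsets.append(np.log(estimate_person_years(t)))
            included.append(t)
        except PersonTimeError as err:
            excluded.append((t.trial_id, str(err)))
    trial_ids = sorted({t.trial_id for t in included})
    notes = []
    if len(trial_ids) <= 1:
        notes.append("low-information: a single placebo-controlled trial")
    id_index = {tid: i for i, tid in enumerate(trial_ids)}
    groups = np.array([id_index[t.trial_id] for t in included])
    terms = spec.fixed_terms if "arm" in spec.fixed_terms else ("arm", *spec.fixed_terms)
    y = np.array([float(t.n_sae) for t in included])
    X, names = build_trial_design(included, terms)
    _check_separation(y, X, names)
    beta_draws, tau_draws, diagnostics, _ = _fit(
        y, np.array(offsets), X, groups, names, spec
    )
    derived = {}
    if "arm_treatment" in names:
        j = names.index("arm_treatment")
        derived["irr_treatment_vs_placebo"] = _summary(np.exp(beta_draws[:, :, j]))
    return _result(names, beta_draws, tau_draws, diagnostics, spec,
                   len(trial_ids), excluded, derived, notes)
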