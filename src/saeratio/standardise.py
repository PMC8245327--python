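"""Indirect standardisation of trial populations against community rates.

Each trial reports only aggregate demographics (mean age, sometimes an
age SD, eligibility age cutoffs, % women).  The age distribution is
reconstructed as a normal distribution truncated to the eligibility
window and calibrated to the reported moments; community age-sex rates
are then applied to the discretised age-sex distribution to obtain the
expected number of hospitalisations/deaths the trial population would
have experienced in the community, and the expected-to-observed (E/O)
ratio with a Monte Carlo credible interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rates import RateModel, build_design, predict_rate

DAYS_PER_YEAR = 365.25

#: age support (years) when eligibility bounds are absent: adult trials
DEFAULT_AGE_SUPPORT = (18.0, 100.0)

#: underlying-normal SD (years) used when a trial does not report an age SD
DEFAULT_AGE_SD = 8.0


class StandardisationIneligibleError(ValueError):
    """Trial lacks the age-sex information needed for standardisation."""


class PersonTimeError(ValueError):
    """Estimated person-time is not positive."""


class TruncatedNormalError(ValueError):
    """Truncated-normal moment inversion failed or is infeasible."""


# ---------------------------------------------------------------------------
# trial records


@dataclass
class TrialRecord:
    """Aggregate report of one trial (or one arm of a trial)."""

    trial_id: str
    group: str  # "older" | "standard"
    n_participants: int
    followup_days: float
    n_sae: int
    mean_age: float | None = None
    sd_age: float | None = None
    min_age: float | None = None
    max_age: float | None = None
    pct_women: float | None = None
    n_endpoint_events: int = 0
    outcome_type: str = "soft"  # "hard" | "soft"
    drug_class: str = "other"  # "renin_inhibitor" | "other"
    comparison_type: str = "placebo"  # placebo | other_class_3char | other_class_5char
    phase: int = 3
    arm: str | None = None  # optional: "treatment" | "control"

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError(f"trial {self.trial_id}: n_participants must be > 0")
        if self.followup_days <= 0:
            raise ValueError(f"trial {self.trial_id}: followup_days must be > 0")
        if self.n_sae < 0:
            raise ValueError(f"trial {self.trial_id}: n_sae must be >= 0")
        if self.pct_women is not None and not (0.0 <= self.pct_women <= 1.0):
            raise ValueError(f"trial {self.trial_id}: pct_women outside [0, 1]")
        if self.mean_age is not None:
            if self.min_age is not None and self.min_age >= self.mean_age:
                raise ValueError(f"trial {self.trial_id}: min_age >= mean_age")
            if self.max_age is not None and self.max_age <= self.mean_age:
                raise ValueError(f"trial {self.trial_id}: max_age <= mean_age")

    @property
    def observed_count(self) -> int:
        """SAE count, pooled with clinical-endpoint events for hard-outcome
        trials (both represent hospitalisations or deaths)."""
        extra = self.n_endpoint_events if self.outcome_type == "hard" else 0
        return int(self.n_sae + extra)

    @property
    def standardisation_eligible(self) -> bool:
        return self.mean_age is not None and self.pct_women is not None


# ---------------------------------------------------------------------------
# person-time


def estimate_person_years(trial: TrialRecord) -> float:
    """Person-years of trial observation.

    Uses follow-up x (participants - 0.5 x SAE count): participants with a
    serious adverse event are assumed, on average, to contribute half the
    follow-up window.
    """
    effective_n = trial.n_participants - 0.5 * trial.n_sae
    if effective_n <= 0:
        raise PersonTimeError(
            f"trial {trial.trial_id}: n_participants ({trial.n_participants}) "
            f"<= 0.5 x n_sae ({trial.n_sae}); person-time is not positive"
        )
    return (trial.followup_days / DAYS_PER_YEAR) * effective_n


# ---------------------------------------------------------------------------
# truncated-normal age reconstruction


@dataclass
class TruncNormParams:
    """Parameters of the underlying normal and its truncation window."""

    mu: float
    sigma: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")

    def moments(self) -> tuple[float, float]:
        """(mean, sd) of the truncated distribution."""
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        m, v = stats.truncnorm.stats(a, b, loc=self.mu, scale=self.sigma,
                                     moments="mv")
        return float(m), float(math.sqrt(v))


def _trunc_mean(mu: float, sigma: float, lower: float, upper: float) -> float:
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    return float(stats.truncnorm.mean(a, b, loc=mu, scale=sigma))


def fit_truncated_normal(
    target_mean: float,
    target_sd: float | None,
    lower: float = -math.inf,
    upper: float = math.inf,
    default_sd: float = DEFAULT_AGE_SD,
    tol: float = 1e-10,
) -> TruncNormParams:
    """Invert truncated-normal moments to underlying (mu, sigma).

    With ``target_sd`` given, solves both moment equations so the
    truncated distribution's mean and SD match the targets; without it,
    fixes ``sigma = default_sd`` and matches the mean only.
    """
    if not (lower < target_mean < upper):
        raise TruncatedNormalError(
            f"target mean {target_mean} outside truncation window "
            f"({lower}, {upper})"
        )
    if target_sd is not None and target_sd <= 0:
        raise TruncatedNormalError("target_sd must be > 0")
    width = upper - lower
    if target_sd is not None:
        # attainability bounds: the truncated-normal SD on a finite window
        # is below the uniform limit width/sqrt(12); with one-sided
        # truncation it is below the exponential limit |mean - bound|
        if math.isfinite(width):
            sd_sup = width / math.sqrt(12.0)
            if target_sd >= sd_sup:
                raise TruncatedNormalError(
                    f"target SD {target_sd} is not attainable on a window of "
                    f"width {width} (supremum {sd_sup:.6g})"
                )
        elif math.isfinite(lower) and target_sd >= target_mean - lower:
            raise TruncatedNormalError(
                f"target SD {target_sd} is not attainable with lower bound "
                f"{lower} and mean {target_mean} (supremum "
                f"{target_mean - lower:.6g})"
            )
        elif math.isfinite(upper) and target_sd >= upper - target_mean:
            raise TruncatedNormalError(
                f"target SD {target_sd} is not attainable with upper bound "
                f"{upper} and mean {target_mean} (supremum "
                f"{upper - target_mean:.6g})"
            )

    if target_sd is None:
        sigma = float(default_sd)
        if not (math.isfinite(lower) or math.isfinite(upper)):
            return TruncNormParams(target_mean, sigma, lower, upper)

        mu = _solve_mu(target_mean, sigma, lower, upper, tol=tol)
        return TruncNormParams(mu, sigma, lower, upper)

    if not (math.isfinite(lower) or math.isfinite(upper)):
        return TruncNormParams(float(target_mean), float(target_sd), lower, upper)

    def residual(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        p = TruncNormParams(mu, math.exp(log_sigma), lower, upper)
        m, s = p.moments()
        return np.array([m - target_mean, s - target_sd])

    x0 = np.array([target_mean, math.log(target_sd)])
    sol = optimize.root(residual, x0, method="hybr", tol=1e-13)
    res = residual(sol.x)
    if sol.success and np.max(np.abs(res)) <= 1e-9:
        mu, log_sigma = sol.x
        return TruncNormParams(float(mu), float(math.exp(log_sigma)), lower, upper)
    # robust fallback for edge-hugging targets: nested monotone 1-D solves
    # (inner: truncated mean is increasing in mu; outer: for a mean-matched
    # mu the truncated SD is increasing in sigma)
    return _fit_nested(target_mean, target_sd, lower, upper, tol)


def _solve_mu(target_mean: float, sigma: float, lower: float, upper: float,
              tol: float = 1e-12) -> float:
    def f(mu: float) -> float:
        return _trunc_mean(mu, sigma, lower, upper) - target_mean

    lo, hi = target_mean - sigma, target_mean + sigma
    for _ in range(200):
        if f(lo) < 0:
            break
        lo -= sigma
    for _ in range(200):
        if f(hi) > 0:
            break
        hi += sigma
    if not (f(lo) < 0 < f(hi)):
        raise TruncatedNormalError(
            "could not bracket mu for the mean equation "
            f"(targets mean={target_mean}, sigma={sigma} on ({lower}, {upper}))"
        )
    return float(optimize.brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def _fit_nested(target_mean: float, target_sd: float, lower: float,
                upper: float, tol: float) -> TruncNormParams:
    def achieved_sd(sigma: float) -> float:
        mu = _solve_mu(target_mean, sigma, lower, upper)
        return TruncNormParams(mu, sigma, lower, upper).moments()[1]

    def g(sigma: float) -> float:
        return achieved_sd(sigma) - target_sd

    lo = hi = target_sd
    for _ in range(80):
        if g(lo) < 0:
            break
        lo /= 1.6
    for _ in range(80):
        if g(hi) > 0:
            break
        hi *= 1.6
        if hi > 1e6:
            break
    if not (g(lo) < 0 < g(hi)):
        raise TruncatedNormalError(
            "moment inversion did not converge: could not bracket sigma for "
            f"targets mean={target_mean}, sd={target_sd} on ({lower}, {upper})"
        )
    sigma = float(optimize.brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16))
    mu = _solve_mu(target_mean, sigma, lower, upper)
    fitted = TruncNormParams(mu, sigma, lower, upper)
    m, s = fitted.moments()
    if max(abs(m - target_mean), abs(s - target_sd)) > 1e-8:
        raise TruncatedNormalError(
            "moment inversion did not converge: residuals "
            f"(mean {m - target_mean:.3e}, sd {s - target_sd:.3e}) for "
            f"targets mean={target_mean}, sd={target_sd} on ({lower}, {upper})"
        )
    return fitted


# ---------------------------------------------------------------------------
# age-sex distribution


@dataclass
class AgeSexDistribution:
    """Discretised age x sex weights for one trial population."""

    strata: pd.DataFrame  # columns: age_mid, sex, weight
    bin_width: float

    def __post_init__(self) -> None:
        w = self.strata["weight"].to_numpy()
        if np.any(w < 0):
            raise ValueError("negative stratum weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum():.12f}, not 1")

    def mean_age(self) -> float:
        return float((self.strata["age_mid"] * self.strata["weight"]).sum())


def age_sex_distribution(
    trial: TrialRecord,
    params: TruncNormParams,
    bin_width: float = 1.0,
    support: tuple[float, float] = DEFAULT_AGE_SUPPORT,
) -> AgeSexDistribution:
    """Discretise the trial's reconstructed age distribution into
    ``bin_width``-year bins split between the sexes by % women."""
    if trial.pct_women is None or trial.mean_age is None:
        raise StandardisationIneligibleError(
            f"trial {trial.trial_id}: insufficient age-sex data "
            "(mean_age and pct_women are required)"
        )
    lo = params.lower if math.isfinite(params.lower) else support[0]
    hi = params.upper if math.isfinite(params.upper) else support[1]
    lo, hi = max(lo, support[0]), min(hi, support[1])
    if not lo < hi:
        raise ValueError("empty age support after clipping")

    edges = np.arange(lo, hi, bin_width, dtype=float)
    edges = np.append(edges, hi)
    z = (edges - params.mu) / params.sigma
    cdf = stats.norm.cdf(z)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        raise ValueError("no probability mass on the clipped age support")
    mass = mass / total
    mids = (edges[:-1] + edges[1:]) / 2

    pw = float(trial.pct_women)
    frames = []
    for sex, share in (("female", pw), ("male", 1.0 - pw)):
        frames.append(
            pd.DataFrame({"age_mid": mids, "sex": sex, "weight": mass * share})
        )
    strata = pd.concat(frames, ignore_index=True)
    strata["weight"] = strata["weight"] / strata["weight"].sum()
    return AgeSexDistribution(strata=strata, bin_width=bin_width)


def trial_age_sex_distribution(
    trial: TrialRecord,
    default_sd: float = DEFAULT_AGE_SD,
    bin_width: float = 1.0,
    support: tuple[float, float] = DEFAULT_AGE_SUPPORT,
) -> AgeSexDistribution:
    """Convenience: fit the truncated normal from the trial's reported
    moments and cutoffs, then discretise."""
    if not trial.standardisation_eligible:
        raise StandardisationIneligibleError(
            f"trial {trial.trial_id}: insufficient age-sex data"
        )
    lower = trial.min_age if trial.min_age is not None else -math.inf
    upper = trial.max_age if trial.max_age is not None else math.inf
    params = fit_truncated_normal(
        trial.mean_age, trial.sd_age, lower, upper, default_sd=default_sd
    )
    return age_sex_distribution(trial, params, bin_width=bin_width, support=support)


# ---------------------------------------------------------------------------
# expected counts and E/O ratios


def expected_count(
    trial: TrialRecord,
    dist: AgeSexDistribution,
    model: RateModel,
) -> float:
    """Expected hospitalisations/deaths for the trial population under the
    community rate model: person-years x weighted mean stratum rate.

    Person-time is split across strata proportionally to the age-sex
    weights (exchangeable follow-up).
    """
    py = estimate_person_years(trial)
    ages = dist.strata["age_mid"].to_numpy()
    sexes = dist.strata["sex"].to_numpy()
    w = dist.strata["weight"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rates = predict_rate(model, ages, sexes)
    e = py * float(np.dot(w, rates))
    if e <= 0:
        raise ValueError(f"trial {trial.trial_id}: expected count is not positive")
    return e


@dataclass
class EORatioSummary:
    """Expected-to-observed ratio for one trial with Monte Carlo CrI."""

    trial_id: str
    expected_count: float
    observed_count: int
    ratio_mean: float | None = None
    ratio_lo: float | None = None
    ratio_hi: float | None = None
    n_samples: int = 0
    seed: int | None = None
    status: str = "ok"  # ok | excluded_zero_events | unstable_low_events
    meta: dict = field(default_factory=dict)


def _zero_truncated_poisson(
    rng: np.random.Generator, lam: float, size: int
) -> np.ndarray:
    """Draws from Poisson(lam) conditioned on being >= 1 (inverse CDF on
    uniforms restricted above P(0))."""
    p0 = math.exp(-lam)
    u = p0 + (1.0 - p0) * rng.random(size)
    return stats.poisson.ppf(u, lam)


def eo_ratio_mc(
    trial: TrialRecord,
    model: RateModel,
    n_samples: int = 10_000,
    seed: int | None = None,
    default_sd: float = DEFAULT_AGE_SD,
    bin_width: float = 1.0,
    pairing: str = "paired",
    dist: AgeSexDistribution | None = None,
) -> EORatioSummary:
    """Monte Carlo expected-to-observed ratio for one trial.

    Coefficient uncertainty: ``n_samples`` draws from the MVN of the rate
    model propagate to the expected count.  Count uncertainty: draws from
    a zero-truncated Poisson at the observed count (zero draws would make
    the ratio infinite, and trials with zero observed events are excluded
    outright).  ``pairing`` = "paired" divides the two streams
    elementwise; "cross" forms the full outer product (capped in size).
    """
    if pairing not in ("paired", "cross"):
        raise ValueError("pairing must be 'paired' or 'cross'")
    if dist is None:
        dist = trial_age_sex_distribution(
            trial, default_sd=default_sd, bin_width=bin_width
        )
    e_point = expected_count(trial, dist, model)
    observed = trial.observed_count

    if observed == 0:
        return EORatioSummary(
            trial_id=trial.trial_id,
            expected_count=e_point,
            observed_count=0,
            n_samples=0,
            seed=seed,
            status="excluded_zero_events",
            meta={"reason": "zero observed events: ratio would be infinite"},
        )

    rng = np.random.default_rng(seed)
    from .rates import sample_coefficients  # local to avoid cycle at import

    draws = sample_coefficients(model, n_samples, seed=rng)
    ages = dist.strata["age_mid"].to_numpy()
    female = (dist.strata["sex"].to_numpy() == "female").astype(float)
    w = dist.strata["weight"].to_numpy()
    X = build_design(model.terms, ages, female)
    py = estimate_person_years(trial)
    expected_draws = py * (w @ np.exp(X @ draws.T))  # (n_samples,)

    denom = _zero_truncated_poisson(rng, float(observed), n_samples)

    if pairing == "paired":
        ratios = expected_draws / denom
    else:
        if n_samples * n_samples > 2e7:
            raise ValueError(
                "cross pairing at this n_samples would form "
                f"{n_samples**2:.0f} ratios; reduce n_samples (<=4472)"
            )
        ratios = (expected_draws[:, None] / denom[None, :]).ravel()

    status = "unstable_low_events" if observed == 1 else "ok"
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return EORatioSummary(
        trial_id=trial.trial_id,
        expected_count=e_point,
        observed_count=observed,
        ratio_mean=float(ratios.mean()),
        ratio_lo=float(lo),
        ratio_hi=float(hi),
        n_samples=int(ratios.size),
        seed=seed,
        status=status,
        meta={
            "pairing": pairing,
            "denominator": "zero-truncated Poisson at observed count",
        },
    )
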