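"""Community age-sex event-rate model.

Fits a Poisson log-linear model for the rate of emergency/urgent
hospitalisations or deaths per person-year in a community cohort, with
log person-years as the exposure offset.  The fitted coefficients and
their variance-covariance matrix are the only artefacts consumed
downstream (they can be serialised to JSON and shipped out of a secure
data environment), so the covariate parameterisation is a configuration
concern: linear age + sex is the default, with quadratic-age and
5-year-age-band alternatives.

Ages are centered at 60 years internally to stabilise the intercept;
coefficients are mapped back to the natural age scale before export, so
a serialised model is always on the natural scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: age (years) used to center the age covariate during fitting
AGE_CENTER = 60.0

#: band edges for the "agebands_sex" covariate spec (reference band 55-65)
AGE_BAND_EDGES = (18, 35, 45, 55, 65, 75, 85, 101)
_REFERENCE_BAND = 3  # 55-65

#: warn (not fail) when predicting outside this age window
PLAUSIBLE_AGE_RANGE = (18.0, 100.0)

COVARIATE_SPECS = ("age_sex", "age2_sex", "agebands_sex")


class RateModelError(ValueError):
    """Raised when a rate model cannot be fitted or decomposed."""


def _band_labels() -> list[str]:
    return [
        f"age_{AGE_BAND_EDGES[i]}_{AGE_BAND_EDGES[i + 1]}"
        for i in range(len(AGE_BAND_EDGES) - 1)
        if i != _REFERENCE_BAND
    ]


def _terms_for_spec(covariate_spec: str) -> list[str]:
    if covariate_spec == "age_sex":
        return ["intercept", "age", "female"]
    if covariate_spec == "age2_sex":
        return ["intercept", "age", "age2", "female"]
    if covariate_spec == "agebands_sex":
        return ["intercept", *_band_labels(), "female"]
    if covariate_spec == "intercept":
        return ["intercept"]
    raise ValueError(
        f"unknown covariate_spec {covariate_spec!r}; "
        f"choose one of {COVARIATE_SPECS} or 'intercept'"
    )


def build_design(terms: list[str], age: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Design matrix for the given ordered term names, natural age scale."""
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=float)
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones_like(age))
        elif term == "age":
            cols.append(age)
        elif term == "age2":
            cols.append(age**2)
        elif term == "female":
            cols.append(female)
        elif term.startswith("age_"):
            lo, hi = (int(x) for x in term.split("_")[1:])
            cols.append(((age >= lo) & (age < hi)).astype(float))
        else:
            raise ValueError(f"unknown covariate term {term!r}")
    return np.column_stack(cols)


@dataclass
class RateModel:
    """Fitted age-sex Poisson rate model (rates per person-year).

    ``coefficients`` are on the log-rate scale and the natural age scale;
    ``vcov`` is the matching variance-covariance matrix.
    """

    terms: list[str]
    coefficients: np.ndarray
    vcov: np.ndarray
    n_fitted: int = 0
    total_events: int = 0
    total_person_years: float = 0.0
    covariate_spec: str = "age_sex"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        k = len(self.terms)
        if self.coefficients.shape != (k,):
            raise ValueError("coefficient vector does not match term count")
        if self.vcov.shape != (k, k):
            raise ValueError("vcov dimensions do not match coefficient count")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
            raise ValueError("vcov is not symmetric within 1e-10")

    # -- persistence ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "terms": list(self.terms),
            "coefficients": self.coefficients.tolist(),
            "vcov": self.vcov.tolist(),
            "n_fitted": int(self.n_fitted),
            "total_events": int(self.total_events),
            "total_person_years": float(self.total_person_years),
            "covariate_spec": self.covariate_spec,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RateModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(
            terms=list(payload["terms"]),
            coefficients=np.array(payload["coefficients"], dtype=float),
            vcov=np.array(payload["vcov"], dtype=float),
            n_fitted=payload.get("n_fitted", 0),
            total_events=payload.get("total_events", 0),
            total_person_years=payload.get("total_person_years", 0.0),
            covariate_spec=payload.get("covariate_spec", "age_sex"),
            meta=payload.get("meta", {}),
        )


def _centering_transform(terms: list[str]) -> np.ndarray:
    """Matrix A such that natural-scale beta = A @ centered-scale beta.

    Centered design uses (age - AGE_CENTER) and its square; all other
    columns are unchanged.  eta = b0c + b1c*(a-c) + b2c*(a-c)^2 expands to
    (b0c - c*b1c + c^2*b2c) + (b1c - 2c*b2c)*a + b2c*a^2.
    """
    k = len(terms)
    A = np.eye(k)
    c = AGE_CENTER
    if "age" in terms:
        i0, i1 = terms.index("intercept"), terms.index("age")
        A[i0, i1] = -c
        if "age2" in terms:
            i2 = terms.index("age2")
            A[i0, i2] = c**2
            A[i1, i2] = -2 * c
    return A


def fit_rate_model(
    cohort: pd.DataFrame,
    covariate_spec: str = "age_sex",
    tol: float = 1e-8,
    maxiter: int = 100,
) -> RateModel:
    """Fit the Poisson rate model to an individual-level cohort table.

    Parameters
    ----------
    cohort
        One row per person with columns ``age`` (years), ``sex``
        ("male"/"female"), ``person_years`` and ``n_events``.
    covariate_spec
        "age_sex" (default), "age2_sex", "agebands_sex" or "intercept".

    Persons with zero person-years are dropped (they carry no exposure);
    the dropped count is logged and recorded in ``meta``.
    """
    if len(cohort) == 0:
        raise RateModelError("cohort is empty")
    required = {"age", "sex", "person_years", "n_events"}
    missing = required - set(cohort.columns)
    if missing:
        raise RateModelError(f"cohort table missing columns: {sorted(missing)}")

    age = np.asarray(cohort["age"], dtype=float)
    female = (np.asarray(cohort["sex"]) == "female").astype(float)
    py = np.asarray(cohort["person_years"], dtype=float)
    y = np.asarray(cohort["n_events"], dtype=float)

    if not (np.all(np.isfinite(age)) and np.all(np.isfinite(py))):
        raise RateModelError("non-finite age or person_years in cohort")

    keep = py > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d persons with zero person-years", n_dropped)
        age, female, py, y = age[keep], female[keep], py[keep], y[keep]
    if len(y) == 0 or py.sum() <= 0:
        raise RateModelError("no positive person-time in cohort")
    if y.sum() == 0:
        raise RateModelError(
            "cohort has zero events in total; the log-rate MLE is -inf "
            "(consider a rate floor or a larger cohort)"
        )

    terms = _terms_for_spec(covariate_spec)
    # centered design for numerical stability
    age_c = age - AGE_CENTER if ("age" in terms) else age
    X = build_design(terms, age_c, female) if "age" in terms else build_design(
        terms, age, female
    )

    model = sm.GLM(y, X, family=sm.families.Poisson(), exposure=py)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, tol=tol)

    A = _centering_transform(terms) if "age" in terms else np.eye(len(terms))
    beta = A @ res.params
    vcov = A @ res.cov_params() @ A.T
    vcov = (vcov + vcov.T) / 2

    return RateModel(
        terms=terms,
        coefficients=beta,
        vcov=vcov,
        n_fitted=int(len(y)),
        total_events=int(y.sum()),
        total_person_years=float(py.sum()),
        covariate_spec=covariate_spec,
        meta={
            "n_dropped_zero_exposure": n_dropped,
            "converged": bool(res.converged),
            "deviance": float(res.deviance),
        },
    )


def predict_rate(model: RateModel, age, sex) -> np.ndarray | float:
    """Predicted events per person-year at the given age(s) and sex(es).

    ``sex`` may be "male"/"female" strings or a 0/1 female indicator.
    Ages outside the plausible adult range trigger a warning (the model
    still extrapolates log-linearly).
    """
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    if isinstance(sex, str):
        female = np.full_like(age_arr, 1.0 if sex == "female" else 0.0)
    else:
        sex_arr = np.atleast_1d(np.asarray(sex))
        if sex_arr.dtype.kind in "UO":
            female = (sex_arr == "female").astype(float)
        else:
            female = sex_arr.astype(float)
        female = np.broadcast_to(female, age_arr.shape).astype(float)
    lo, hi = PLAUSIBLE_AGE_RANGE
    if np.any((age_arr < lo) | (age_arr > hi)):
        warnings.warn(
            f"predicting outside the plausible age range {PLAUSIBLE_AGE_RANGE}",
            stacklevel=2,
        )
    X = build_design(model.terms, age_arr, female)
    rate = np.exp(X @ model.coefficients)
    return float(rate[0]) if np.isscalar(age) and rate.size == 1 else rate


def sample_coefficients(
    model: RateModel,
    n_samples: int,
    seed: int | np.random.Generator | None = None,
    clip_negative_eigenvalues: bool = False,
) -> np.ndarray:
    """Draw coefficient vectors from MVN(coefficients, vcov).

    Returns an (n_samples, k) matrix.  A vcov with negative eigenvalues
    raises unless ``clip_negative_eigenvalues`` is set, in which case
    offending eigenvalues are clipped to zero before factorisation.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    evals, evecs = np.linalg.eigh(model.vcov)
    tol = 1e-10 * max(1.0, float(np.abs(evals).max(initial=0.0)))
    if np.any(evals < -tol):
        if not clip_negative_eigenvalues:
            raise RateModelError(
                "vcov is not positive semi-definite "
                f"(min eigenvalue {evals.min():.3e}); pass "
                "clip_negative_eigenvalues=True to repair by clipping"
            )
        evals = np.clip(evals, 0.0, None)
    evals = np.clip(evals, 0.0, None)
    factor = evecs * np.sqrt(evals)
    z = rng.standard_normal((n_samples, len(model.terms)))
    return model.coefficients + z @ factor.T
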