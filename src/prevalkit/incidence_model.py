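"""Polynomial age-cohort model of incidence on the logit scale.

Registries observe incident cases and person-years on an (age group x birth
cohort) grid; to reconstruct diagnoses made before the registration window
began, the annual risk of diagnosis is smoothed as

    logit I(age, cohort) = b0 + sum_k a_k * P_k(age~) + sum_k c_k * P_k(cohort~)

two additive polynomials (default degree 6 each, no interaction) in age and
birth cohort, both centred and scaled to roughly [-1, 1] before expansion so
high-degree terms stay numerically tame. Fitting is a binomial GLM
(cases out of person-years), the classical age-cohort formulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DEFAULT_DEGREE = 6


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class IncidenceModel:
    """Fitted (or specified) age-cohort incidence surface for one stratum.

    ``intercept`` plus ``age_coef``/``cohort_coef`` act on centred-scaled
    predictors ``(x - center) / scale``; ``age_range``/``cohort_range`` bound
    the region where the surface is interpolation rather than extrapolation.
    """

    intercept: float
    age_coef: np.ndarray
    cohort_coef: np.ndarray
    age_center: float
    age_scale: float
    cohort_center: float
    cohort_scale: float
    age_range: tuple[float, float]
    cohort_range: tuple[float, float]
    stratum: tuple = ("all", "all")
    deviance: float | None = None
    degree: int = DEFAULT_DEGREE

    def __post_init__(self) -> None:
        self.age_coef = np.asarray(self.age_coef, dtype=float)
        self.cohort_coef = np.asarray(self.cohort_coef, dtype=float)

    # -- evaluation ------------------------------------------------------

    def linear_predictor(self, age, cohort) -> np.ndarray:
        a = (np.asarray(age, dtype=float) - self.age_center) / self.age_scale
        c = (np.asarray(cohort, dtype=float) - self.cohort_center) / self.cohort_scale
        eta = np.full(np.broadcast(a, c).shape, self.intercept, dtype=float)
        for k, beta in enumerate(self.age_coef, start=1):
            eta = eta + beta * a**k
        for k, beta in enumerate(self.cohort_coef, start=1):
            eta = eta + beta * c**k
        return eta

    def predict(self, age, cohort, *, clamp: bool = True) -> np.ndarray:
        """Annual risk of diagnosis in (0, 1); see :func:`predict_incidence`."""
        age = np.asarray(age, dtype=float)
        cohort = np.asarray(cohort, dtype=float)
        out_age = (age < self.age_range[0]) | (age > self.age_range[1])
        out_coh = (cohort < self.cohort_range[0]) | (cohort > self.cohort_range[1])
        if np.any(out_age | out_coh):
            logger.warning(
                "incidence surface %s evaluated outside fitted range "
                "(%d age, %d cohort points)%s",
                self.stratum,
                int(np.sum(out_age)),
                int(np.sum(out_coh)),
                "; clamping to range edge" if clamp else "",
            )
            if clamp:
                age = np.clip(age, *self.age_range)
                cohort = np.clip(cohort, *self.cohort_range)
        return _expit(self.linear_predictor(age, cohort))

    def cohort_risks(self, ages, cohort, *, clamp: bool = True) -> np.ndarray:
        """Risks I(x, cohort) along one birth cohort for an array of ages."""
        return np.atleast_1d(self.predict(ages, np.full(np.shape(ages), cohort), clamp=clamp))

    # -- construction of "known truth" surfaces --------------------------

    @classmethod
    def from_loglinear(
        cls,
        *,
        rate_at_ref: float,
        age_slope: float,
        cohort_slope: float = 0.0,
        age_ref: float = 60.0,
        cohort_ref: float = 1940.0,
        age_range: tuple[float, float] = (0.0, 99.0),
        cohort_range: tuple[float, float] = (1880.0, 2010.0),
        stratum: tuple = ("all", "all"),
    ) -> "IncidenceModel":
        """Surface with logit I linear in age and cohort (log-linear for small
        risks): ``I ~ rate_at_ref * exp(age_slope*(age-age_ref)) *
        exp(cohort_slope*(cohort-cohort_ref))``. Used as a fully-known
        generating surface in simulations."""
        age_center = np.mean(age_range)
        age_scale = (age_range[1] - age_range[0]) / 2 or 1.0
        coh_center = np.mean(cohort_range)
        coh_scale = (cohort_range[1] - cohort_range[0]) / 2 or 1.0
        intercept = (
            float(_logit(rate_at_ref))
            + age_slope * (age_center - age_ref)
            + cohort_slope * (coh_center - cohort_ref)
        )
        return cls(
            intercept=intercept,
            age_coef=np.array([age_slope * age_scale]),
            cohort_coef=np.array([cohort_slope * coh_scale]),
            age_center=age_center,
            age_scale=age_scale,
            cohort_center=coh_center,
            cohort_scale=coh_scale,
            age_range=age_range,
            cohort_range=cohort_range,
            stratum=stratum,
            degree=1,
        )

    # -- IO --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [("intercept", 0, self.intercept)]
        rows += [("age", k + 1, v) for k, v in enumerate(self.age_coef)]
        rows += [("cohort", k + 1, v) for k, v in enumerate(self.cohort_coef)]
        df = pd.DataFrame(rows, columns=["term", "power", "coef"])
        df["cancer_type"], df["sex"] = self.stratum
        for name in (
            "age_center",
            "age_scale",
            "cohort_center",
            "cohort_scale",
        ):
            df[name] = getattr(self, name)
        df["age_min"], df["age_max"] = self.age_range
        df["cohort_min"], df["cohort_max"] = self.cohort_range
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceModel":
        """Rebuild a surface from its :meth:`to_frame` coefficient table."""
        meta = df.iloc[0]
        age = df[df["term"] == "age"].sort_values("power")
        coh = df[df["term"] == "cohort"].sort_values("power")
        return cls(
            intercept=float(df.loc[df["term"] == "intercept", "coef"].iloc[0]),
            age_coef=age["coef"].to_numpy(float),
            cohort_coef=coh["coef"].to_numpy(float),
            age_center=float(meta["age_center"]),
            age_scale=float(meta["age_scale"]),
            cohort_center=float(meta["cohort_center"]),
            cohort_scale=float(meta["cohort_scale"]),
            age_range=(float(meta["age_min"]), float(meta["age_max"])),
            cohort_range=(float(meta["cohort_min"]), float(meta["cohort_max"])),
            stratum=(meta["cancer_type"], meta["sex"]),
            degree=max(len(age), 1),
        )


def _design(age_s: np.ndarray, cohort_s: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(age_s)]
    cols += [age_s**k for k in range(1, degree + 1)]
    cols += [cohort_s**k for k in range(1, degree + 1)]
    return np.column_stack(cols)


def fit_incidence(
    cells: pd.DataFrame,
    *,
    stratum: tuple = ("all", "all"),
    degree: int = DEFAULT_DEGREE,
) -> IncidenceModel:
    """Fit the age-cohort surface to an incidence cell table.

    Parameters
    ----------
    cells : DataFrame with columns ``age`` (group midpoint in years),
        ``cohort`` (birth-cohort midpoint), ``cases``, ``person_years``.
    degree : polynomial degree of each additive component (default 6).

    Raises
    ------
    ValueError on all-zero counts, cases exceeding person-years, or fewer
    than two distinct ages/cohorts. Degenerate high-degree fits fall back to
    a lower degree with a warning rather than failing.
    """
    required = {"age", "cohort", "cases", "person_years"}
    if not required.issubset(cells.columns):
        raise ValueError(f"incidence cell table needs columns {sorted(required)}")
    cells = cells.sort_values(["age", "cohort"], kind="mergesort").reset_index(drop=True)
    cases = cells["cases"].to_numpy(float)
    py = cells["person_years"].to_numpy(float)
    if np.any(cases > py):
        raise ValueError("cases exceed person-years in at least one cell")
    if cases.sum() == 0:
        raise ValueError("all-zero case counts: nothing to fit")
    age = cells["age"].to_numpy(float)
    cohort = cells["cohort"].to_numpy(float)
    if np.unique(age).size < 2 or np.unique(cohort).size < 2:
        raise ValueError("need at least two distinct ages and cohorts")

    age_center, age_scale = _center_scale(age)
    coh_center, coh_scale = _center_scale(cohort)
    age_s = (age - age_center) / age_scale
    coh_s = (cohort - coh_center) / coh_scale

    keep = py > 0
    endog = np.column_stack([cases[keep], py[keep] - cases[keep]])

    for deg in range(degree, 0, -1):
        X = _design(age_s[keep], coh_s[keep], deg)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=200)
            if np.all(np.isfinite(res.params)) and res.converged:
                break
        except Exception:  # noqa: BLE001 - separation / singular design
            res = None
        logger.warning(
            "incidence fit for %s degenerate at degree %d; reducing degree", stratum, deg
        )
    else:
        raise RuntimeError(f"incidence fit failed for stratum {stratum} at every degree")

    params = res.params
    return IncidenceModel(
        intercept=float(params[0]),
        age_coef=params[1 : deg + 1],
        cohort_coef=params[deg + 1 :],
        age_center=age_center,
        age_scale=age_scale,
        cohort_center=coh_center,
        cohort_scale=coh_scale,
        age_range=(float(age.min()), float(age.max())),
        cohort_range=(float(cohort.min()), float(cohort.max())),
        stratum=stratum,
        deviance=float(res.deviance),
        degree=deg,
    )


def _center_scale(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    scale = (hi - lo) / 2.0
    return (lo + hi) / 2.0, scale if scale > 0 else 1.0


def predict_incidence(model: IncidenceModel, age, cohort, *, clamp: bool = True):
    """Annual diagnosis risk at (age, cohort); extrapolation beyond the fitted
    range is logged and, with ``clamp`` (default), pinned to the range edge."""
    return model.predict(age, cohort, clamp=clamp)


def first_primary_risks(model: IncidenceModel, ages: np.ndarray, cohort, *, clamp: bool = True) -> np.ndarray:
    """Annual risk of a *first* primary at each age along one cohort.

    The surface gives the tumour rate among persons alive; the first-primary
    rate per person alive is thinned by the probability of having remained
    tumour-free: ``I1(x) = I(x) * prod_{x' < x} (1 - I(x'))``. Used for
    all-types-combined prevalence, which counts persons via first primaries.
    """
    ages = np.asarray(ages)
    all_ages = np.arange(0, int(np.max(ages)) + 1)
    risks = model.cohort_risks(all_ages, cohort, clamp=clamp)
    free = np.concatenate([[1.0], np.cumprod(1.0 - risks[:-1])])
    return (risks * free)[ages]
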