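"""Completeness indices: from limited-duration to complete prevalence.

A registry observing only the last L years of diagnoses sees the fraction

    R(L) = sum_{t=0}^{L-1} w(t) / sum_{t=0}^{a-1} w(t),
    w(t) = I(a - t, c) * S(t + 1/2)

of the complete prevalence at attained age ``a`` (birth cohort
``c = index_year - 1 - a``): the modelled diagnoses made ``t`` years before
the index date that are still alive, with annual discretisation and
mid-interval survival evaluation (the midpoint rule for the underlying
integrals; the denominator's ``a`` terms reach back to diagnoses in the first
full year of life). Complete prevalence is then estimated as N_L / R.

``S`` defaults to cumulative *relative* survival from the cure model: under
independence of background and excess mortality, the background survival from
birth to the index age factors out of numerator and denominator alike
(survival birth->(a-t) times background survival (a-t)->index equals survival
birth->index for every t), so only the excess component shapes the index.
The ``survival="observed"`` mode (expected times relative survival) is kept
for comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cure_survival import CureParamSet, age_class, relative_survival
from .incidence_model import IncidenceModel, first_primary_risks
from .lifetable import LifeTable

logger = logging.getLogger(__name__)


def duration_weights(
    inc_model: IncidenceModel,
    cure: CureParamSet,
    life_table: LifeTable | None,
    *,
    cancer_type: str,
    sex: str,
    age: int,
    index_year: int,
    period_ref: int | None = None,
    survival: str = "relative",
    first_primary: bool = False,
) -> np.ndarray:
    """Modelled prevalent mass w(t) by whole years since diagnosis, t = 0..age-1.

    ``first_primary=True`` thins the incidence surface to first primaries
    (used for the all-types stratum, which counts persons once).
    """
    a = int(age)
    if a < 1:
        raise ValueError("attained age must be at least 1")
    cohort = index_year - 1 - a
    t = np.arange(a)
    ages_at_dx = a - t
    if first_primary:
        risks = first_primary_risks(inc_model, ages_at_dx, cohort)
    else:
        risks = inc_model.cohort_risks(ages_at_dx, cohort)

    surv = np.empty(a)
    dx_years = index_year - 1 - t
    periods = (dx_years - period_ref) if period_ref is not None else np.zeros(a)
    classes = np.atleast_1d(age_class(ages_at_dx))
    for label in np.unique(classes):
        m = classes == label
        params = cure.lookup(cancer_type, sex, ages_at_dx[m][0])
        surv[m] = relative_survival(params, t[m] + 0.5, periods[m])

    if survival == "observed":
        if life_table is None:
            raise ValueError("observed-survival weights need a life table")
        # log survival along the cohort diagonal: age a-k in year index-1-k
        k = np.arange(a)
        q = life_table.annual_q(
            np.full(a, sex, dtype=object), a - k, index_year - 1 - k
        )
        l = np.log1p(-np.minimum(q, 1 - 1e-12))
        # S_exp(t + 1/2) = exp(sum_{k=1..t} l(k) + l(0)/2)
        cum = np.concatenate([[0.0], np.cumsum(l[1:])])
        surv = surv * np.exp(cum + 0.5 * l[0])
    elif survival != "relative":
        raise ValueError(f"unknown survival mode {survival!r}")

    return risks * surv


def completeness_index(
    inc_model: IncidenceModel,
    cure: CureParamSet,
    life_table: LifeTable | None,
    *,
    cancer_type: str,
    sex: str,
    age: int,
    index_year: int,
    window_L: int,
    period_ref: int | None = None,
    survival: str = "relative",
    first_primary: bool = False,
) -> float:
    """Completeness index R in (0, 1] for one (type, sex, age, window) cell."""
    if window_L < 1:
        raise ValueError("window length must be at least 1 year")
    if age <= window_L:
        # the window reaches back to birth: every diagnosis is observable
        return 1.0
    w = duration_weights(
        inc_model,
        cure,
        life_table,
        cancer_type=cancer_type,
        sex=sex,
        age=age,
        index_year=index_year,
        period_ref=period_ref,
        survival=survival,
        first_primary=first_primary,
    )
    denom = float(w.sum())
    if denom <= 0:
        logger.warning(
            "no modelled incidence mass for (%s, %s, age %d); defining R = 1",
            cancer_type,
            sex,
            age,
        )
        return 1.0
    return float(w[: min(window_L, age)].sum() / denom)


def completeness_table(
    incidence: dict,
    cure: CureParamSet,
    life_table: LifeTable | None,
    *,
    ages,
    window_L: int,
    index_year: int,
    cancer_types=None,
    sexes=("male", "female"),
    period_ref: int | None = None,
    survival: str = "relative",
    first_primary_types=("all",),
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Materialise R over a grid of (type, sex, age) cells.

    ``incidence`` maps cancer type -> sex -> surface; the special type
    ``"all"`` (or any type listed in ``first_primary_types``) uses
    first-primary thinning. Unmapped strata raise with the offending key.
    """
    cancer_types = list(incidence) if cancer_types is None else list(cancer_types)
    rows = []
    for ct in cancer_types:
        if ct not in incidence:
            raise KeyError(f"no incidence surface for cancer type {ct!r}")
        for sex in sexes:
            if sex not in incidence[ct]:
                raise KeyError(f"no incidence surface for stratum ({ct!r}, {sex!r})")
            for a in ages:
                R = completeness_index(
                    incidence[ct][sex],
                    cure,
                    life_table,
                    cancer_type=ct,
                    sex=sex,
                    age=int(a),
                    index_year=index_year,
                    window_L=window_L,
                    period_ref=period_ref,
                    survival=survival,
                    first_primary=ct in first_primary_types,
                )
                rows.append(
                    {
                        "cancer_type": ct,
                        "sex": sex,
                        "age": int(a),
                        "window_L": window_L,
                        "index_year": index_year,
                        "R": R,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["metadata"] = {"survival": survival, "period_ref": period_ref, **(metadata or {})}
    return out


def completeness_for_age_groups(
    incidence: dict,
    cure: CureParamSet,
    life_table: LifeTable | None,
    *,
    age_groups,
    window_L: int,
    index_year: int,
    max_age: int = 99,
    **kwargs,
) -> pd.DataFrame:
    """R evaluated at each reporting age-group midpoint (labelled by group)."""
    from .limited_prevalence import group_label

    mids, labels = [], []
    for lo, hi in age_groups:
        hi_eff = min(hi, max_age)
        mids.append(int(round((lo + hi_eff) / 2)))
        labels.append(group_label(lo, hi))
    table = completeness_table(
        incidence,
        cure,
        life_table,
        ages=mids,
        window_L=window_L,
        index_year=index_year,
        **kwargs,
    )
    mapping = dict(zip(mids, labels))
    table["age_group"] = table["age"].map(mapping)
    return table.drop(columns="age")
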