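"""Linear projection of complete prevalence proportions to future index years.

Per stratum, an ordinary least-squares line is fitted to the proportions of
the last three calendar years (five as a sensitivity mode); the projected
proportion, clamped at zero, is multiplied by the forecast population to give
counts. Trends act on proportions, not counts: demographic change enters only
through the population multiplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TREND_YEARS = 3


@dataclass
class TrendFit:
    """Per-stratum OLS lines: columns ``intercept`` and ``slope`` indexed by
    the stratum keys, plus the fitting years used."""

    table: pd.DataFrame
    years: tuple[int, ...]
    keys: tuple[str, ...]

    @property
    def mode(self) -> str:
        return f"{len(self.years)}-year"


def fit_linear_trend(
    series: pd.DataFrame,
    *,
    years=None,
    keys=("cancer_type", "sex", "age_group", "duration_bin"),
    value: str = "proportion",
) -> TrendFit:
    """OLS line per stratum through (year, proportion) points.

    ``series`` has one row per stratum x year with columns ``year`` and the
    value column. ``years`` selects the fitting window (default: the last
    three calendar years present). At least two distinct years are required.
    """
    keys = tuple(k for k in keys if k in series.columns)
    if years is None:
        years = sorted(series["year"].unique())[-DEFAULT_TREND_YEARS:]
    years = tuple(int(y) for y in years)
    if len(set(years)) < 2:
        raise ValueError("need at least two distinct years to fit a trend")
    sub = series[series["year"].isin(years)]

    def ols(group: pd.DataFrame) -> pd.Series:
        x = group["year"].to_numpy(float)
        y = group[value].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        return pd.Series({"intercept": intercept, "slope": slope})

    table = sub.groupby(list(keys), observed=True).apply(ols, include_groups=False).reset_index()
    return TrendFit(table=table, years=years, keys=keys)


def project(
    trend: TrendFit,
    target_year: int,
    forecast_population: pd.DataFrame | None = None,
    *,
    population_keys=("sex", "age_group"),
) -> pd.DataFrame:
    """Proportions (and counts, if a forecast population is given) at
    ``target_year``; negative projected proportions are clamped to zero."""
    out = trend.table.copy()
    out["year"] = int(target_year)
    out["proportion"] = out["intercept"] + out["slope"] * target_year
    neg = out["proportion"] < 0
    if neg.any():
        logger.warning(
            "clamped %d projected proportions below zero to 0", int(neg.sum())
        )
        out.loc[neg, "proportion"] = 0.0
    out = out.drop(columns=["intercept", "slope"])
    if forecast_population is not None:
        pk = [k for k in population_keys if k in out.columns]
        out = out.merge(forecast_population[pk + ["population"]], on=pk, how="left")
        if out["population"].isna().any():
            missing = out[out["population"].isna()][pk].drop_duplicates()
            raise ValueError(
                f"missing forecast population cells: {missing.to_dict('records')[:10]}"
            )
        out["count"] = out["proportion"] * out["population"] / 1e5
    return out


def variation(count_base: float, count_target: float) -> float:
    """Percent change between two counts, to one decimal (half-even).

    Undefined for a zero base; returned as NaN and logged."""
    if count_base == 0:
        logger.warning("variation undefined for zero base count")
        return float("nan")
    v = 100.0 * (count_target / count_base - 1.0)
    return float(np.round(v, 1))
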