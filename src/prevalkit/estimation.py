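"""Complete prevalence estimation: N = N_L / R, duration splits, national scaling.

Estimated counts are kept non-integer internally and only rounded at report
time, so rounding never accumulates across strata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .completeness import duration_weights
from .limited_prevalence import DURATION_BINS, bin_label, limited_totals

logger = logging.getLogger(__name__)

COMPLETE = "complete"


def complete_prevalence(limited_cells: pd.DataFrame, R_table: pd.DataFrame) -> pd.DataFrame:
    """Correct limited-duration totals by completeness indices.

    ``limited_cells`` come from the counting method (any duration resolution);
    ``R_table`` must carry one R per (cancer_type, sex, age cell). Returns one
    row per cell with ``N_L``, ``R``, the estimate ``N = N_L / R`` and a
    Poisson-style standard error ``sqrt(N_L) / R`` (reported, not headline).
    """
    age_col = "age_group" if "age_group" in limited_cells.columns else "age"
    if age_col not in R_table.columns:
        raise ValueError(f"completeness table lacks the {age_col!r} key of the counts")
    totals = limited_totals(limited_cells)
    merged = totals.merge(
        R_table[["cancer_type", "sex", age_col, "R"]],
        on=["cancer_type", "sex", age_col],
        how="left",
    )
    if merged["R"].isna().any():
        missing = merged[merged["R"].isna()][["cancer_type", "sex", age_col]]
        raise ValueError(
            f"no completeness index for cells: {missing.to_dict('records')[:10]}"
        )
    merged["N"] = merged["N_L"] / merged["R"]
    merged["se"] = np.sqrt(merged["N_L"]) / merged["R"]
    return merged


def duration_split(
    limited_by_year: pd.DataFrame,
    complete_table: pd.DataFrame,
    incidence: dict,
    cure,
    life_table,
    *,
    window_L: int,
    index_year: int,
    period_ref: int | None = None,
    survival: str = "relative",
    duration_bins=DURATION_BINS,
    first_primary_types=("all",),
) -> pd.DataFrame:
    """Distribute complete prevalence over time-since-diagnosis bins.

    Observed durations (t < L, from ``limited_by_year`` with a single-year
    ``duration`` column) keep their counted values; the surplus ``N - N_L`` is
    spread over beyond-window durations (L <= t < age) proportionally to the
    modelled prevalent mass w(t), then everything is regrouped to the
    reporting bins. Rows sum exactly to the complete count per cell.
    """
    if "duration" not in limited_by_year.columns:
        raise ValueError("duration_split needs single-year durations (duration_bins=None)")
    age_col = "age_group" if "age_group" in limited_by_year.columns else "age"
    if age_col != "age":
        raise ValueError("duration_split operates on single-year ages")

    edges = np.array([b[0] for b in duration_bins] + [np.inf])
    labels = [bin_label(lo, hi) for lo, hi in duration_bins]

    def to_bin(t):
        return labels[int(np.searchsorted(edges, t, side="right")) - 1]

    rows = []
    for rec in complete_table.itertuples():
        obs = limited_by_year[
            (limited_by_year["cancer_type"] == rec.cancer_type)
            & (limited_by_year["sex"] == rec.sex)
            & (limited_by_year["age"] == getattr(rec, "age"))
        ]
        split = {label: 0.0 for label in labels}
        for dur, cnt in obs[["duration", "count"]].itertuples(index=False, name=None):
            split[to_bin(dur)] += cnt
        surplus = rec.N - rec.N_L
        if surplus < -1e-9:
            logger.warning(
                "negative beyond-window surplus (%.2f) for %s/%s age %s; clamping to 0",
                surplus,
                rec.cancer_type,
                rec.sex,
                getattr(rec, "age"),
            )
        surplus = max(surplus, 0.0)
        age = int(getattr(rec, "age"))
        if surplus > 0 and age > window_L:
            w = duration_weights(
                incidence[rec.cancer_type][rec.sex],
                cure,
                life_table,
                cancer_type=rec.cancer_type,
                sex=rec.sex,
                age=age,
                index_year=index_year,
                period_ref=period_ref,
                survival=survival,
                first_primary=rec.cancer_type in first_primary_types,
            )
            beyond = w[window_L:]
            if beyond.sum() > 0:
                shares = beyond / beyond.sum()
                for t, s in zip(range(window_L, age), shares):
                    split[to_bin(t)] += surplus * s
            else:
                split[labels[-1]] += surplus
        elif surplus > 0:
            split[labels[-1]] += surplus
        for label in labels:
            rows.append(
                {
                    "cancer_type": rec.cancer_type,
                    "sex": rec.sex,
                    "age": age,
                    "duration_bin": label,
                    "count": split[label],
                }
            )
        rows.append(
            {
                "cancer_type": rec.cancer_type,
                "sex": rec.sex,
                "age": age,
                "duration_bin": COMPLETE,
                "count": rec.N_L + surplus,
            }
        )
    return pd.DataFrame(rows)


def add_proportions(
    table: pd.DataFrame, population: pd.DataFrame, *, keys=("sex", "age")
) -> pd.DataFrame:
    """Attach per-100,000 proportions: proportion = 1e5 * count / population.

    ``population`` needs the key columns plus ``population`` (residents).
    """
    keys = list(keys)
    merged = table.merge(population[keys + ["population"]], on=keys, how="left")
    if merged["population"].isna().any():
        missing = merged[merged["population"].isna()][keys].drop_duplicates()
        raise ValueError(f"missing population cells: {missing.to_dict('records')[:10]}")
    count_col = "N" if "N" in merged.columns else "count"
    merged["proportion"] = 1e5 * merged[count_col] / merged["population"]
    return merged


def scale_to_national(
    proportions: pd.DataFrame,
    national_population: pd.DataFrame,
    *,
    keys=("sex", "age_group"),
) -> pd.DataFrame:
    """Registry proportions applied to the national population.

    National count per cell = proportion x population / 100,000 (exact
    arithmetic, linear in the population table). Missing population cells are
    an error.
    """
    keys = list(keys)
    merged = proportions.merge(
        national_population[keys + ["population"]], on=keys, how="left",
        suffixes=("_registry", ""),
    )
    if merged["population"].isna().any():
        missing = merged[merged["population"].isna()][keys].drop_duplicates()
        raise ValueError(f"missing national population cells: {missing.to_dict('records')[:10]}")
    merged["count"] = merged["proportion"] * merged["population"] / 1e5
    return merged


def national_totals(scaled: pd.DataFrame, *, by=("cancer_type",)) -> pd.DataFrame:
    """Sum national cell counts over age/sex, keeping the ``by`` keys."""
    return scaled.groupby(list(by), observed=True)["count"].sum().reset_index()
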