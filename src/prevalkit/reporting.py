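"""Report tables: prevalence by type and age, 10-year variations, duration shares.

All outputs are plain CSV. Counts are rounded half-even to integers and
percentages to one decimal only here, at render time; upstream estimates stay
unrounded. Missing strata surface as explicit ``NA`` markers, never silent
zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import COMPLETE
from .projection import variation


def share_of_total(count_type: float, count_all_types: float) -> float:
    """Percent share of one type among all types, to one decimal (half-even)."""
    if count_all_types <= 0:
        raise ValueError("total count must be positive")
    return float(np.round(100.0 * count_type / count_all_types, 1))


def duration_share_table(
    duration_resolved: pd.DataFrame, *, by=("cancer_type",)
) -> pd.DataFrame:
    """Percent of prevalent cases by time-since-diagnosis bin per stratum.

    Rows whose duration bin is the ``complete`` total are excluded; shares sum
    to 100 per stratum (within rounding).
    """
    by = list(by)
    sub = duration_resolved[duration_resolved["duration_bin"] != COMPLETE]
    totals = sub.groupby(by, observed=True)["count"].transform("sum")
    out = sub.copy()
    out["share"] = np.round(100.0 * sub["count"] / totals, 1)
    return (
        out.groupby(by + ["duration_bin"], observed=True)
        .agg(count=("count", "sum"), share=("share", "sum"))
        .reset_index()
    )


def variation_table(
    counts_base: pd.DataFrame,
    counts_target: pd.DataFrame,
    *,
    by=("cancer_type", "sex"),
) -> pd.DataFrame:
    """Ten-year-variation layout: target counts next to percent change.

    Inputs carry the ``by`` keys plus a ``count`` column for the base and
    target years; the variation column is 100 * (target/base - 1), one
    decimal, undefined (NA) where the base is zero.
    """
    by = list(by)
    merged = counts_base.merge(
        counts_target, on=by, how="outer", suffixes=("_base", "_target")
    )
    merged["variation_pct"] = [
        variation(b, t) if b > 0 else float("nan")
        for b, t in zip(merged["count_base"].fillna(0), merged["count_target"].fillna(0))
    ]
    return merged


def prevalence_table(
    estimates: pd.DataFrame,
    *,
    sex: str,
    cancer_types=None,
    value: str = "N",
) -> pd.DataFrame:
    """One-sex prevalence table: counts by age group with an all-ages total
    and the percent share of the all-types total (the layout of the published
    prevalence-by-type-and-age tables)."""
    sub = estimates[estimates["sex"] == sex]
    pivot = sub.pivot_table(
        index="cancer_type", columns="age_group", values=value, aggfunc="sum",
        observed=True,
    )
    if cancer_types is not None:
        pivot = pivot.reindex(cancer_types)
    out = pivot.copy()
    out.insert(0, "all_ages", pivot.sum(axis=1, min_count=1))
    if "all" in out.index and out.loc["all", "all_ages"] > 0:
        total = out.loc["all", "all_ages"]
        out.insert(1, "pct", np.round(100.0 * out["all_ages"] / total, 1))
    return out.reset_index()


def trend_by_duration(series: pd.DataFrame) -> pd.DataFrame:
    """Proportions by calendar year and duration bin (trend-figure layout)."""
    return series.pivot_table(
        index="year", columns="duration_bin", values="proportion", aggfunc="sum",
        observed=True,
    ).reset_index()


def round_counts(df: pd.DataFrame, columns=("count", "N")) -> pd.DataFrame:
    """Half-even integer rounding of count columns, NA-preserving."""
    out = df.copy()
    for c in columns:
        if c in out.columns:
            out[c] = np.round(out[c].astype(float), 0)
    return out


def render_tables(tables: dict, out_dir, *, metadata: dict | None = None) -> list:
    """Write each table as deterministic CSV with one leading metadata line.

    Identical inputs produce byte-identical files: the metadata line holds
    only caller-supplied key=value pairs (versions, seeds), never wall-clock
    values, and floats are fixed-format. Missing cells render as ``NA``.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = ",".join(f"{k}={v}" for k, v in sorted((metadata or {}).items()))
    paths = []
    for name, df in tables.items():
        path = out / f"{name}.csv"
        body = df.to_csv(index=False, float_format="%.6f", na_rep="NA", lineterminator="\n")
        path.write_text(f"# {meta}\n{body}")
        paths.append(path)
    return paths
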