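"""Counting-method limited-duration prevalence.

Direct enumeration of registered persons alive at an index date, by cancer
type, sex, attained age, and time since diagnosis. A person contributes to a
cancer type if any of their primaries carries that type (duration from the
first primary of that type); the all-types-combined stratum uses first
primaries only, so each person is counted once.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: attained-age reporting groups (low, high inclusive); high=inf is open-ended
AGE_GROUPS = ((0, 14), (15, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, np.inf))

#: years-since-diagnosis reporting bins [low, high)
DURATION_BINS = ((0, 2), (2, 5), (5, 10), (10, 15), (15, 20), (20, np.inf))

ALL_TYPES = "all"


def group_label(lo, hi) -> str:
    if np.isinf(hi):
        return f"{lo:g}+"
    return f"{lo:g}-{hi:g}"


def bin_label(lo, hi) -> str:
    return f">={lo:g}" if np.isinf(hi) else f"[{lo:g},{hi:g})"


def person_level_dedup(records: pd.DataFrame) -> pd.DataFrame:
    """One record per person: the first primary.

    Keeps the minimum sequence number; ties broken by earliest diagnosis date
    then lexicographic cancer-type code, so the result is deterministic.
    """
    if records.duplicated(["person_id", "sequence_number"]).any():
        dup = records[records.duplicated(["person_id", "sequence_number"], keep=False)]
        raise ValueError(
            "duplicate (person, sequence) pairs: "
            f"{dup[['person_id', 'sequence_number']].drop_duplicates().to_dict('records')[:5]}"
        )
    ordered = records.sort_values(
        ["sequence_number", "diagnosis_date", "cancer_type"], kind="mergesort"
    )
    return ordered.drop_duplicates("person_id").sort_index()


def _floor_years(later: pd.Series, earlier: pd.Series) -> np.ndarray:
    return np.floor(
        (pd.to_datetime(later) - pd.to_datetime(earlier)).dt.days / 365.25
    ).astype(int)


def _clip_duration_bins(duration_bins, window_L):
    bins = []
    for lo, hi in duration_bins:
        if lo >= window_L:
            break
        bins.append((lo, min(hi, window_L)))
    return bins


def count_limited_prevalence(
    records: pd.DataFrame,
    index_date,
    window_L: int,
    *,
    age_groups=AGE_GROUPS,
    duration_bins=DURATION_BINS,
    count_lost_as_alive: bool = True,
    include_all_types: bool = True,
    max_age: int = 99,
) -> pd.DataFrame:
    """Limited-duration prevalence cells at ``index_date`` for window ``L``.

    A tumour contributes iff diagnosed before the index date, within the last
    ``L`` years (duration in exact days floored to whole years), and the
    person is not known to have died before the index date. Persons lost to
    follow-up before the index date count as alive by default (counting-method
    convention), switchable with ``count_lost_as_alive``.

    Parameters
    ----------
    age_groups : iterable of (low, high) attained-age groups, or None for
        single years of age.
    duration_bins : iterable of [low, high) year bins, clipped to the window,
        or None for single whole years of duration.

    Returns
    -------
    DataFrame with columns cancer_type, sex, age_group (or age), duration_bin
    (or duration), count.
    """
    index_date = pd.Timestamp(index_date)
    rec = records.copy()
    rec["diagnosis_date"] = pd.to_datetime(rec["diagnosis_date"])
    rec["exit_date"] = pd.to_datetime(rec["exit_date"])
    rec["birth_date"] = pd.to_datetime(rec["birth_date"])

    dead_before_dx = (rec["vital_status"] == "dead") & (rec["exit_date"] < rec["diagnosis_date"])
    if dead_before_dx.any():
        raise ValueError(
            f"{int(dead_before_dx.sum())} records report death before diagnosis"
        )

    after = rec["diagnosis_date"] >= index_date
    if after.any():
        logger.warning(
            "excluded %d records diagnosed on or after the index date", int(after.sum())
        )
        rec = rec[~after]

    known_dead = (rec["vital_status"] == "dead") & (rec["exit_date"] < index_date)
    keep = ~known_dead
    if not count_lost_as_alive:
        keep &= ~((rec["vital_status"] == "lost") & (rec["exit_date"] < index_date))
    rec = rec[keep].copy()

    rec["duration"] = _floor_years(index_date, rec["diagnosis_date"])
    rec = rec[rec["duration"] < window_L]
    rec["age"] = _floor_years(index_date, rec["birth_date"]).clip(upper=max_age)

    frames = []
    per_type = rec.sort_values("diagnosis_date", kind="mergesort").drop_duplicates(
        ["person_id", "cancer_type"]
    )
    strata = [(ct, per_type[per_type["cancer_type"] == ct]) for ct in sorted(per_type["cancer_type"].unique())]
    if include_all_types:
        strata = [(ALL_TYPES, person_level_dedup(rec))] + strata

    for ct, sub in strata:
        sub = sub.copy()
        if age_groups is not None:
            edges = [g[0] for g in age_groups] + [np.inf]
            labels = [group_label(lo, hi) for lo, hi in age_groups]
            sub["age_group"] = pd.cut(sub["age"], bins=edges, labels=labels, right=False)
            age_col = "age_group"
        else:
            age_col = "age"
        if duration_bins is not None:
            bins = _clip_duration_bins(duration_bins, window_L)
            edges = [b[0] for b in bins] + [bins[-1][1]]
            labels = [bin_label(lo, hi) for lo, hi in bins]
            sub["duration_bin"] = pd.cut(sub["duration"], bins=edges, labels=labels, right=False)
            dur_col = "duration_bin"
        else:
            dur_col = "duration"
        g = (
            sub.groupby(["sex", age_col, dur_col], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        g = g[g["count"] > 0]
        g.insert(0, "cancer_type", ct)
        frames.append(g)

    if not frames:
        return pd.DataFrame(columns=["cancer_type", "sex", "age_group", "duration_bin", "count"])
    return pd.concat(frames, ignore_index=True)


def limited_totals(cells: pd.DataFrame) -> pd.DataFrame:
    """N_L per (cancer_type, sex, age cell): sum over duration bins."""
    age_col = "age_group" if "age_group" in cells.columns else "age"
    return (
        cells.groupby(["cancer_type", "sex", age_col], observed=True)["count"]
        .sum()
        .rename("N_L")
        .reset_index()
    )
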