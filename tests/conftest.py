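import numpy as np
import pandas as pd
import pytest

from prevalkit import LifeTable, default_config, gompertz_life_table, simulate_registry
from prevalkit.lifetable import MAX_AGE


@pytest.fixture(scope="session")
def life_table():
    return gompertz_life_table(1880, 2030)


@pytest.fixture(scope="session")
def zero_mortality_table():
    """No background deaths: isolates the cancer components."""
    return LifeTable(q=np.zeros((2, MAX_AGE + 1, 151)), year_min=1880, name="zero-q")


@pytest.fixture(scope="session")
def constant_q_table():
    """Flat 10% annual death probability everywhere (hand-computable)."""
    return LifeTable(q=np.full((2, MAX_AGE + 1, 151), 0.1), year_min=1880, name="q-0.1")


@pytest.fixture(scope="session")
def small_registry():
    """Shared down-scaled simulated registry (default study conditions)."""
    cfg = default_config(seed=7, cohort_size=400)
    return simulate_registry(cfg)


def random_toy_records(rng: np.random.Generator, n_persons: int = 400) -> pd.DataFrame:
    """Randomised hand-checkable registry records: a few hundred persons,
    multiple primaries, mixed vital statuses, diagnoses 1995-2012."""
    rows = []
    for pid in range(n_persons):
        sex = "male" if rng.random() < 0.5 else "female"
        birth = pd.Timestamp(int(rng.integers(1915, 1990)), int(rng.integers(1, 13)), 1)
        n_prim = 1 + (rng.random() < 0.25) + (rng.random() < 0.08)
        dx_days = np.sort(rng.integers(0, 6500, size=n_prim))
        first_dx = pd.Timestamp(1995, 1, 1) + pd.Timedelta(int(dx_days[0]), "D")
        status = rng.choice(["alive", "dead", "lost"], p=[0.55, 0.35, 0.10])
        if status == "alive":
            exit_date = pd.Timestamp(2013, 12, 31)
        else:
            last_dx = pd.Timestamp(1995, 1, 1) + pd.Timedelta(int(dx_days[-1]), "D")
            exit_date = last_dx + pd.Timedelta(int(rng.integers(1, 4000)), "D")
        for seq, d in enumerate(dx_days, start=1):
            rows.append(
                {
                    "person_id": pid,
                    "sex": sex,
                    "birth_date": birth,
                    "diagnosis_date": pd.Timestamp(1995, 1, 1) + pd.Timedelta(int(d), "D"),
                    "cancer_type": rng.choice(["alpha", "beta"]),
                    "sequence_number": seq,
                    "vital_status": status,
                    "exit_date": exit_date,
                }
            )
    return pd.DataFrame(rows)


def brute_force_limited(records: pd.DataFrame, index_date, window_L: int) -> dict:
    """Independent enumeration of the counting method, one record at a time.

    Returns {(cancer_type, sex, age, duration): count} with 'all' meaning the
    all-types first-primary stratum; persons lost to follow-up count as alive.
    """
    index_date = pd.Timestamp(index_date)
    counts: dict = {}
    persons: dict = {}
    for _, r in records.iterrows():
        persons.setdefault(r["person_id"], []).append(r)

    def eligible(r):
        if r["diagnosis_date"] >= index_date:
            return False
        if r["vital_status"] == "dead" and r["exit_date"] < index_date:
            return False
        dur = int(np.floor((index_date - r["diagnosis_date"]).days / 365.25))
        return dur < window_L

    for pid, recs in persons.items():
        ok = [r for r in recs if eligible(r)]
        if not ok:
            continue
        # per-type: one count per (person, type), earliest diagnosis of the type
        by_type: dict = {}
        for r in ok:
            ct = r["cancer_type"]
            if ct not in by_type or r["diagnosis_date"] < by_type[ct]["diagnosis_date"]:
                by_type[ct] = r
        # all-types: first primary (min sequence; ties by date then type code)
        first = min(ok, key=lambda r: (r["sequence_number"], r["diagnosis_date"], r["cancer_type"]))
        for ct, r in [("all", first)] + list(by_type.items()):
            age = int(np.floor((index_date - r["birth_date"]).days / 365.25))
            dur = int(np.floor((index_date - r["diagnosis_date"]).days / 365.25))
            key = (ct, r["sex"], min(age, MAX_AGE), dur)
            counts[key] = counts.get(key, 0) + 1
    return counts


def cells_to_dict(cells: pd.DataFrame) -> dict:
    return {
        (r["cancer_type"], r["sex"], int(r["age"]), int(r["duration"])): int(r["count"])
        for r in cells.to_dict("records")
    }
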