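"""Simulated population-based cancer registry with a fully known history.

The generator emulates the data a registry contributes to a complete-prevalence
study: tumour records accumulated over a fixed registration window (at least 7
years before the index date) with vital status ascertained at a later
follow-up cut, on top of a population whose mortality follows a life table.
Because the complete pre-window history is retained (``full_history``), every
downstream estimate has an exact ground-truth oracle.

Mechanics: one hundred single-year birth cohorts (ages 0-99 at the index
date), each person followed in continuous time with annual piecewise-constant
hazards; tumours arrive cell-wise from an age-cohort incidence surface, and a
diagnosed tumour is either cured (probability pi from the stratum's cure
parameters; general-population mortality only) or fatal, with a
period-modulated Weibull cancer death time competing with background death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cure_survival import AGE_CLASSES, CureParams, CureParamSet
from .incidence_model import IncidenceModel
from .lifetable import MAX_AGE, SEXES, LifeTable, gompertz_life_table

#: quinquennial birth-cohort labels start ("<1899", "1900-1904", ...)
COHORT_QUINQUENNIA_START = 1900

MIN_REGISTRATION_YEARS = 7


@dataclass
class SimConfig:
    """Conditions of one simulated registry study.

    ``cohort_size`` is the number of persons per sex per single-year birth
    cohort; cohorts are the hundred birth years giving ages 0-99 at the index
    date. ``incidence`` maps cancer type -> sex -> generating surface.
    """

    seed: int
    registry_start_year: int
    registry_end_year: int
    followup_cut_year: int
    index_date: pd.Timestamp
    cohort_size: int
    incidence: dict
    cure: CureParamSet
    life_table: LifeTable
    period_ref: int = 2000
    max_primaries: int = 3
    lost_to_followup_rate: float = 0.0

    def __post_init__(self) -> None:
        self.index_date = pd.Timestamp(self.index_date)
        if (self.index_date.month, self.index_date.day) != (1, 1):
            raise ValueError("index_date must be the first day of a calendar year")
        span = self.registry_end_year - self.registry_start_year + 1
        if span < MIN_REGISTRATION_YEARS:
            raise ValueError(
                f"registration window of {span} years is below the required "
                f"minimum of {MIN_REGISTRATION_YEARS}"
            )
        if self.followup_cut_year < self.index_date.year:
            raise ValueError("follow-up cut must not precede the index date")

    @property
    def index_year(self) -> int:
        return int(self.index_date.year)

    @property
    def cohorts(self) -> np.ndarray:
        return np.arange(self.index_year - 100, self.index_year)

    @property
    def window_years(self) -> int:
        return self.registry_end_year - self.registry_start_year + 1


@dataclass
class SimulatedRegistry:
    """Output of :func:`simulate_registry`.

    ``records`` mimic what the registry observes (diagnoses within the
    registration window, vital status at the follow-up cut); ``full_history``
    keeps every tumour with the person's true death date and exists only to
    serve as an oracle; ``population`` is person-years by sex, age, year.
    """

    records: pd.DataFrame
    full_history: pd.DataFrame
    population: pd.DataFrame
    config: SimConfig = field(repr=False)

    def write_csv(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.full_history.to_csv(out / "full_history.csv", index=False)
        self.population.to_csv(out / "population.csv", index=False)
        self.config.life_table.to_csv(out / "life_table.csv")


def _time_to_date(tau: np.ndarray) -> pd.Series:
    """Fractional calendar years -> dates (day-resolution, 365-day grid)."""
    tau = np.asarray(tau, dtype=float)
    year = np.floor(tau).astype(int)
    day = np.minimum((tau - year) * 365.0, 364.0).astype(int)
    base = pd.to_datetime(pd.DataFrame({"year": year, "month": 1, "day": 1}))
    return base + pd.to_timedelta(day, unit="D")


def simulate_registry(config: SimConfig) -> SimulatedRegistry:
    """Run the microsimulation defined by ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    cohorts = config.cohorts
    B = config.cohort_size
    n = cohorts.size * 2 * B

    person_cohort = np.repeat(cohorts, 2 * B)
    person_sex = np.tile(np.repeat(np.arange(2), B), cohorts.size)
    birth_time = person_cohort + 0.5
    death_time = np.full(n, np.inf)
    n_tumours = np.zeros(n, dtype=int)

    types = list(config.incidence)
    end_year = max(config.followup_cut_year, config.index_year - 1)
    years = np.arange(cohorts.min(), end_year + 1)

    pop = np.zeros((2, MAX_AGE + 1, years.size))
    tumour_person: list[np.ndarray] = []
    tumour_time: list[np.ndarray] = []
    tumour_type: list[np.ndarray] = []

    for yi, y in enumerate(years):
        exists = person_cohort <= y
        alive = exists & (death_time > y)
        if not alive.any():
            continue
        x = np.clip(y - person_cohort, 0, MAX_AGE)

        # background death candidate within this calendar year
        h_bg = np.zeros(n)
        h_bg[alive] = config.life_table.annual_hazard(
            person_sex[alive], x[alive], np.full(alive.sum(), y)
        )
        draw = np.full(n, np.inf)
        pos = alive & (h_bg > 0)
        draw[pos] = rng.exponential(size=int(pos.sum())) / h_bg[pos]
        bg_cand = np.where(draw < 1.0, y + draw, np.inf)

        # tumour arrival: total hazard over types, then a type choice
        eligible = alive & (n_tumours < config.max_primaries)
        h_type = np.zeros((len(types), n))
        for ti, ct in enumerate(types):
            for s in (0, 1):
                m = eligible & (person_sex == s)
                if not m.any():
                    continue
                risk = config.incidence[ct][SEXES[s]].predict(x[m], person_cohort[m])
                h_type[ti, m] = -np.log1p(-np.minimum(risk, 1 - 1e-12))
        h_tot = h_type.sum(axis=0)
        draw2 = np.full(n, np.inf)
        pos2 = eligible & (h_tot > 0)
        draw2[pos2] = rng.exponential(size=int(pos2.sum())) / h_tot[pos2]
        dx_time = y + draw2
        got = pos2 & (draw2 < 1.0) & (dx_time < death_time) & (dx_time < bg_cand) & (
            dx_time >= birth_time
        )
        if got.any():
            idx = np.flatnonzero(got)
            if len(types) == 1:
                chosen = np.zeros(idx.size, dtype=int)
            else:
                p = h_type[:, idx] / h_tot[idx]
                chosen = (rng.random(idx.size)[None, :] > np.cumsum(p, axis=0)).sum(axis=0)
                chosen = np.minimum(chosen, len(types) - 1)
            n_tumours[idx] += 1
            tumour_person.append(idx)
            tumour_time.append(dx_time[idx])
            tumour_type.append(chosen)

            # cure / fatal outcome per new tumour
            age_dx = np.floor(dx_time[idx] - birth_time[idx]).astype(int)
            cancer_death = np.full(idx.size, np.inf)
            for ti, ct in enumerate(types):
                for s in (0, 1):
                    for lo, hi, label in AGE_CLASSES:
                        m = (chosen == ti) & (person_sex[idx] == s) & (age_dx >= lo) & (age_dx <= hi)
                        if not m.any():
                            continue
                        par = config.cure.lookup(ct, SEXES[s], lo)
                        cured = rng.random(int(m.sum())) < par.pi
                        u = rng.random(int(m.sum()))
                        t_w = par.lam * (
                            -np.log(u) * np.exp(-par.beta_period * (y - config.period_ref))
                        ) ** (1.0 / par.gamma)
                        cd = np.where(cured, np.inf, dx_time[idx][m] + t_w)
                        cancer_death[m] = cd
            death_time[idx] = np.minimum(death_time[idx], cancer_death)

        death_time = np.minimum(death_time, bg_cand)

        alive_mid = exists & (death_time > y + 0.5)
        if alive_mid.any():
            np.add.at(pop, (person_sex[alive_mid], x[alive_mid], yi), 1.0)

    # ---- assemble tumour history ----------------------------------------
    if tumour_person:
        t_person = np.concatenate(tumour_person)
        t_time = np.concatenate(tumour_time)
        t_type = np.concatenate(tumour_type)
    else:
        t_person = np.array([], dtype=int)
        t_time = np.array([], dtype=float)
        t_type = np.array([], dtype=int)

    hist = pd.DataFrame(
        {
            "person_id": t_person,
            "sex": np.array(SEXES)[person_sex[t_person]] if t_person.size else pd.Series(dtype=object),
            "birth_time": birth_time[t_person],
            "dx_time": t_time,
            "cancer_type": np.array(types)[t_type] if t_person.size else pd.Series(dtype=object),
            "death_time": death_time[t_person],
        }
    )
    hist = hist.sort_values(["person_id", "dx_time"], kind="mergesort").reset_index(drop=True)
    hist["sequence_number"] = hist.groupby("person_id").cumcount() + 1

    full_history = pd.DataFrame(
        {
            "person_id": hist["person_id"],
            "sex": hist["sex"],
            "birth_date": _time_to_date(hist["birth_time"]),
            "diagnosis_date": _time_to_date(hist["dx_time"]),
            "cancer_type": hist["cancer_type"],
            "sequence_number": hist["sequence_number"],
            "death_date": pd.Series(
                np.where(np.isfinite(hist["death_time"]), hist["death_time"], np.nan)
            ).pipe(lambda s: _time_to_date(s.fillna(2200.0)).where(s.notna(), pd.NaT)),
        }
    )

    # ---- registry view: window truncation + follow-up cut ----------------
    in_window = hist[
        (hist["dx_time"] >= config.registry_start_year)
        & (hist["dx_time"] < config.registry_end_year + 1)
    ].copy()
    in_window = in_window.sort_values(["person_id", "dx_time"], kind="mergesort")
    in_window["sequence_number"] = in_window.groupby("person_id").cumcount() + 1

    cut_time = config.followup_cut_year + 1.0  # vital status through Dec 31
    dead = in_window["death_time"] < cut_time
    exit_time = np.minimum(in_window["death_time"].to_numpy(), cut_time - 1e-9)
    status = np.where(dead, "dead", "alive")

    if config.lost_to_followup_rate > 0:
        persons = in_window["person_id"].unique()
        first_dx = in_window.groupby("person_id")["dx_time"].min()
        loss = rng.exponential(1.0 / config.lost_to_followup_rate, size=persons.size)
        loss_time = pd.Series(first_dx.loc[persons].to_numpy() + loss, index=persons)
        lt = loss_time.loc[in_window["person_id"]].to_numpy()
        lost = lt < exit_time
        status = np.where(lost, "lost", status)
        exit_time = np.where(lost, lt, exit_time)

    records = pd.DataFrame(
        {
            "person_id": in_window["person_id"].to_numpy(),
            "sex": in_window["sex"].to_numpy(),
            "birth_date": _time_to_date(in_window["birth_time"]).to_numpy(),
            "diagnosis_date": _time_to_date(in_window["dx_time"]).to_numpy(),
            "cancer_type": in_window["cancer_type"].to_numpy(),
            "sequence_number": in_window["sequence_number"].to_numpy(),
            "vital_status": status,
            "exit_date": _time_to_date(exit_time).to_numpy(),
        }
    ).reset_index(drop=True)

    population = (
        pd.DataFrame(
            {
                "sex": np.repeat(SEXES, (MAX_AGE + 1) * years.size),
                "age": np.tile(np.repeat(np.arange(MAX_AGE + 1), years.size), 2),
                "year": np.tile(years, 2 * (MAX_AGE + 1)),
                "person_years": pop.ravel(),
            }
        )
    )
    return SimulatedRegistry(
        records=records, full_history=full_history, population=population, config=config
    )


def true_complete_prevalence(
    full_history: pd.DataFrame,
    index_date,
    *,
    by_age: bool = True,
    duration_bins=None,
) -> pd.DataFrame:
    """Oracle complete prevalence from the untruncated history.

    Counts persons alive at ``index_date`` with at least one tumour of each
    type diagnosed at any time before the index date; the ``"all"`` stratum
    counts each person once via the first primary. Duration (if binned) is
    years since the first diagnosis of the type, floored.
    """
    index_date = pd.Timestamp(index_date)
    h = full_history
    alive = h["death_date"].isna() | (h["death_date"] >= index_date)
    prior = pd.to_datetime(h["diagnosis_date"]) < index_date
    h = h[alive & prior]

    frames = []
    # first diagnosis per (person, type), and first overall for "all"
    per_type = h.sort_values("diagnosis_date", kind="mergesort").drop_duplicates(
        ["person_id", "cancer_type"]
    )
    first = h.sort_values(["diagnosis_date", "sequence_number"], kind="mergesort").drop_duplicates(
        "person_id"
    )
    for ct, sub in [("all", first)] + [
        (ct, per_type[per_type["cancer_type"] == ct]) for ct in sorted(per_type["cancer_type"].unique())
    ]:
        sub = sub.copy()
        sub["age"] = (
            (index_date - pd.to_datetime(sub["birth_date"])).dt.days / 365.25
        ).astype(int).clip(upper=MAX_AGE)
        sub["duration"] = np.floor(
            (index_date - pd.to_datetime(sub["diagnosis_date"])).dt.days / 365.25
        ).astype(int)
        keys = ["sex"] + (["age"] if by_age else [])
        if duration_bins is not None:
            edges = [b[0] for b in duration_bins] + [np.inf]
            labels = [_bin_label(lo, hi) for lo, hi in duration_bins]
            sub["duration_bin"] = pd.cut(
                sub["duration"], bins=edges, labels=labels, right=False
            )
            keys = keys + ["duration_bin"]
        g = sub.groupby(keys, observed=True).size().rename("count").reset_index()
        g.insert(0, "cancer_type", ct)
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def _bin_label(lo, hi) -> str:
    return f">={lo:g}" if np.isinf(hi) else f"[{lo:g},{hi:g})"


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_cure_params(
    cancer_type: str = "allsites", *, pi_shift: float = 0.0
) -> CureParamSet:
    """Once-chosen realistic all-sites cure parameters by sex and age class:
    cure fraction declining with age at diagnosis, median fatal survival of
    1-2.5 years, and a mild survival improvement over calendar time."""
    pi_by_class = {"0-14": 0.70, "15-44": 0.60, "45-54": 0.50, "55-64": 0.42, "65-74": 0.35, "75+": 0.28}
    lam_by_class = {"0-14": 2.5, "15-44": 2.5, "45-54": 2.2, "55-64": 2.0, "65-74": 1.8, "75+": 1.4}
    params = []
    for sex, extra in (("male", 0.0), ("female", 0.03)):
        for _, _, label in AGE_CLASSES:
            params.append(
                CureParams(
                    pi=min(pi_by_class[label] + extra + pi_shift, 1.0),
                    lam=lam_by_class[label],
                    gamma=1.1,
                    beta_period=-0.015,
                    stratum=(cancer_type, sex, label),
                )
            )
    return CureParamSet(params)


def default_incidence(cancer_type: str = "allsites", *, rate_scale: float = 1.0) -> dict:
    """All-sites-like generating surface: incidence rising exponentially with
    age (about 0.5% per year at age 70 in men) with a mild upward cohort
    drift; women at 80% of the male level."""
    out = {}
    for sex, scale in (("male", 1.0), ("female", 0.8)):
        out[sex] = IncidenceModel.from_loglinear(
            rate_at_ref=0.005 * scale * rate_scale,
            age_slope=0.085,
            cohort_slope=0.002,
            age_ref=70.0,
            cohort_ref=1940.0,
            age_range=(0.0, 99.0),
            cohort_range=(1880.0, 2015.0),
            stratum=(cancer_type, sex),
        )
    return out


def default_config(
    seed: int = 0,
    *,
    cohort_size: int = 21000,
    registry_start_year: int = 1980,
    registry_end_year: int = 2009,
    followup_cut_year: int = 2013,
    index_date: str = "2010-01-01",
    types: tuple[str, ...] = ("allsites",),
    lost_to_followup_rate: float = 0.0,
    max_primaries: int = 3,
) -> SimConfig:
    """Canonical study conditions: a pooled registry with 30 years of
    registration before a January 1, 2010 index date, vital status cut at the
    end of 2013, and about fifty thousand in-window incident cases at the
    default cohort size."""
    incidence = {}
    cure_list = []
    for i, ct in enumerate(types):
        incidence[ct] = default_incidence(ct, rate_scale=1.0 / len(types))
        cure_list.extend(default_cure_params(ct, pi_shift=0.02 * i))
    return SimConfig(
        seed=seed,
        registry_start_year=registry_start_year,
        registry_end_year=registry_end_year,
        followup_cut_year=followup_cut_year,
        index_date=pd.Timestamp(index_date),
        cohort_size=cohort_size,
        incidence=incidence,
        cure=CureParamSet(cure_list),
        life_table=gompertz_life_table(1880, max(followup_cut_year, 2030)),
        period_ref=2000,
        max_primaries=max_primaries,
        lost_to_followup_rate=lost_to_followup_rate,
    )


def load_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file of scalar overrides to the
    default study conditions (keys mirror :func:`default_config` arguments)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "types" in raw:
        raw["types"] = tuple(raw["types"])
    return default_config(**raw)
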