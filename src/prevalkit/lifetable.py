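"""Population life tables: annual death probabilities by sex, age, and calendar year.

The life table is the source of *expected* (general-population) mortality used
both by the registry simulator and by the expected-survival factor of the cure
model. Probabilities are stored on a dense ``sex x age x year`` grid so lookups
vectorise; ages are capped at :data:`MAX_AGE` (open-ended last age class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_AGE = 99

SEXES = ("male", "female")


class MissingLifeTableCell(KeyError):
    """A (sex, age, year) cell required by a computation is absent."""


@dataclass
class LifeTable:
    """Annual probability of death ``q(sex, age, year)``.

    Parameters
    ----------
    q : ndarray, shape (2, MAX_AGE + 1, n_years)
        ``q[s, a, y - year_min]`` is the probability of dying within one year
        for a person of sex ``s`` (0 = male, 1 = female) aged ``a`` at the
        start of calendar year ``y``. Ages above :data:`MAX_AGE` reuse the
        last row.
    year_min : int
        First calendar year covered by the grid.
    """

    q: np.ndarray
    year_min: int
    name: str = field(default="life-table")

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 3 or self.q.shape[0] != 2 or self.q.shape[1] != MAX_AGE + 1:
            raise ValueError(
                f"q must have shape (2, {MAX_AGE + 1}, n_years); got {self.q.shape}"
            )
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")

    @property
    def year_max(self) -> int:
        return self.year_min + self.q.shape[2] - 1

    # -- lookups ---------------------------------------------------------

    def _year_index(self, year: np.ndarray) -> np.ndarray:
        year = np.asarray(year)
        bad = (year < self.year_min) | (year > self.year_max)
        if np.any(bad):
            y = np.atleast_1d(year)[np.atleast_1d(bad)][0]
            raise MissingLifeTableCell(
                f"{self.name}: no column for calendar year {int(y)} "
                f"(covered: {self.year_min}-{self.year_max})"
            )
        return year - self.year_min

    def annual_q(self, sex, age, year) -> np.ndarray:
        """Vectorised ``q`` lookup; ages above the cap use the last age row."""
        sex = sex_code(sex)
        age = np.minimum(np.asarray(age, dtype=int), MAX_AGE)
        if np.any(age < 0):
            raise MissingLifeTableCell(f"{self.name}: negative age requested")
        return self.q[sex, age, self._year_index(year)]

    def annual_hazard(self, sex, age, year) -> np.ndarray:
        """Piecewise-constant hazard ``-log(1 - q)`` for the given cells."""
        q = self.annual_q(sex, age, year)
        return -np.log1p(-np.minimum(q, 1.0 - 1e-12))

    def survival(self, sex, age: int, year: int, t: float) -> float:
        """Expected survival over ``t`` years from exact age ``age`` at the
        start of calendar year ``year`` (cohort-wise product of ``1 - q``,
        fractional final year handled as a partial power)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        whole = int(np.floor(t))
        frac = t - whole
        s = 1.0
        for k in range(whole):
            s *= 1.0 - self.annual_q(sex, age + k, year + k)
        if frac > 0:
            s *= (1.0 - self.annual_q(sex, age + whole, year + whole)) ** frac
        return float(s)

    def cohort_survival_curve(self, sex, age: int, year: int, n_years: int) -> np.ndarray:
        """Survival at exact year boundaries 0..n_years from (age, year)."""
        ages = age + np.arange(n_years)
        years = year + np.arange(n_years)
        q = self.annual_q(sex, ages, years)
        return np.concatenate([[1.0], np.cumprod(1.0 - q)])

    # -- IO --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        years = np.arange(self.year_min, self.year_max + 1)
        idx = pd.MultiIndex.from_product(
            [SEXES, range(MAX_AGE + 1), years], names=["sex", "age", "year"]
        )
        return pd.DataFrame({"qx": self.q.ravel()}, index=idx).reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "life-table") -> "LifeTable":
        required = {"sex", "age", "year", "qx"}
        if not required.issubset(df.columns):
            raise ValueError(f"life-table frame needs columns {sorted(required)}")
        year_min, year_max = int(df["year"].min()), int(df["year"].max())
        n_years = year_max - year_min + 1
        q = np.full((2, MAX_AGE + 1, n_years), np.nan)
        s = df["sex"].map(lambda v: sex_code(v)).to_numpy()
        q[s, df["age"].to_numpy(int), df["year"].to_numpy(int) - year_min] = df[
            "qx"
        ].to_numpy(float)
        if np.isnan(q).any():
            s_i, a_i, y_i = np.argwhere(np.isnan(q))[0]
            raise MissingLifeTableCell(
                f"{name}: missing cell sex={SEXES[s_i]} age={a_i} year={year_min + y_i}"
            )
        return cls(q=q, year_min=year_min, name=name)

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path), name=str(path))


def sex_code(sex) -> np.ndarray:
    """Map 'male'/'female' (or 0/1, 'M'/'F') to the internal 0/1 code."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "iu":
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("integer sex codes must be 0 (male) or 1 (female)")
        return arr
    mapping = {"male": 0, "female": 1, "m": 0, "f": 1}
    try:
        if arr.ndim == 0:
            return np.asarray(mapping[str(arr).lower()])
        return np.asarray([mapping[str(v).lower()] for v in arr.ravel()]).reshape(arr.shape)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown sex label {exc}") from exc


def gompertz_life_table(
    year_min: int,
    year_max: int,
    *,
    q0: float = 2e-4,
    slope: float = 0.092,
    female_advantage: float = 0.35,
    secular_decline: float = 0.004,
    ref_year: int = 2000,
    name: str = "synthetic-gompertz",
) -> LifeTable:
    """Synthetic but demographically plausible life table.

    Adult mortality follows a Gompertz law ``q = q0 * exp(slope * age)``
    (capped at 0.7), females get a proportional hazard advantage, and all
    rates decline by ``secular_decline`` per calendar year relative to
    ``ref_year`` -- enough structure to exercise sex/age/period lookups
    without aiming at any particular national table.
    """
    ages = np.arange(MAX_AGE + 1)
    years = np.arange(year_min, year_max + 1)
    base = q0 * np.exp(slope * ages)
    # mild infant-mortality bump so q is not monotone from age 0
    base[0] *= 12.0
    base[1:5] *= 2.0
    grid = np.empty((2, MAX_AGE + 1, years.size))
    period = np.exp(-secular_decline * (years - ref_year))
    grid[0] = np.minimum(0.7, base[:, None] * period[None, :])
    grid[1] = np.minimum(0.7, (base * np.exp(-female_advantage))[:, None] * period[None, :])
    return LifeTable(q=grid, year_min=year_min, name=name)
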