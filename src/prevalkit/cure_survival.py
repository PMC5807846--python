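"""Mixture cure model of relative survival.

A fraction pi of patients ("cured") experiences only general-population
mortality; the complement ("fatal cases") additionally carries an excess
(cancer) hazard whose survival is Weibull. Relative survival is

    RS(t) = pi + (1 - pi) * exp(-(t / lam)**gamma * exp(beta * period))

with ``period`` a calendar offset of the diagnosis year from a reference year
(the period effect acts multiplicatively on the excess hazard). Observed
survival is expected (life-table) survival times RS. Parameters are estimated
per (cancer type, sex, age class) stratum, primarily by individual-data
maximum likelihood with the background hazard as a fixed offset; a
least-squares fit to annual actuarial relative-survival points is available
for comparability with life-table based fitters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .lifetable import LifeTable, sex_code

logger = logging.getLogger(__name__)

#: (low, high, label) attained-age classes at diagnosis used for survival strata
AGE_CLASSES = (
    (0, 14, "0-14"),
    (15, 44, "15-44"),
    (45, 54, "45-54"),
    (55, 64, "55-64"),
    (65, 74, "65-74"),
    (75, 200, "75+"),
)

_T_MIN = 1.0 / 365.25  # same-day deaths contribute one day of follow-up


def age_class(age) -> np.ndarray:
    """Label of the survival age class containing ``age`` (vectorised)."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    out = np.empty(age.shape, dtype=object)
    for lo, hi, label in AGE_CLASSES:
        out[(age >= lo) & (age <= hi)] = label
    if (out == None).any():  # noqa: E711
        raise ValueError("age outside 0-200")
    return out if out.size > 1 else out[0]


@dataclass
class CureParams:
    """Cure fraction and Weibull excess-survival parameters for one stratum."""

    pi: float
    lam: float
    gamma: float
    beta_period: float = 0.0
    stratum: tuple = ("all", "all", "all")  # (cancer_type, sex, age_class)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"cure fraction pi={self.pi} outside [0, 1]")
        if self.lam <= 0 or self.gamma <= 0:
            raise ValueError("Weibull scale and shape must be positive")


class CureParamSet:
    """Lookup of :class:`CureParams` by (cancer_type, sex, age at diagnosis)."""

    def __init__(self, params: list[CureParams]):
        self._by_key = {p.stratum: p for p in params}
        if len(self._by_key) != len(params):
            raise ValueError("duplicate strata in cure parameter set")

    def lookup(self, cancer_type: str, sex: str, age) -> CureParams:
        key = (cancer_type, sex, str(age_class(age)))
        try:
            return self._by_key[key]
        except KeyError as exc:
            raise KeyError(f"no cure parameters for stratum {key}") from exc

    def __iter__(self):
        return iter(self._by_key.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cancer_type": p.stratum[0],
                "sex": p.stratum[1],
                "age_class": p.stratum[2],
                "pi": p.pi,
                "lam": p.lam,
                "gamma": p.gamma,
                "beta_period": p.beta_period,
            }
            for p in self
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CureParamSet":
        return cls(
            [
                CureParams(
                    pi=r.pi,
                    lam=r.lam,
                    gamma=r.gamma,
                    beta_period=r.beta_period,
                    stratum=(r.cancer_type, r.sex, r.age_class),
                )
                for r in df.itertuples()
            ]
        )


# ---------------------------------------------------------------------------
# Survival functions
# ---------------------------------------------------------------------------

def excess_cumhaz(params: CureParams, t, period=0.0) -> np.ndarray:
    """Cumulative excess hazard of the fatal component at time t."""
    t = np.asarray(t, dtype=float)
    return (t / params.lam) ** params.gamma * np.exp(params.beta_period * np.asarray(period))


def relative_survival(params: CureParams, t, period=0.0) -> np.ndarray:
    """RS(t) = pi + (1 - pi) exp(-(t/lam)^gamma e^{beta*period}); in [pi, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since diagnosis must be non-negative")
    return params.pi + (1.0 - params.pi) * np.exp(-excess_cumhaz(params, t, period))


def observed_survival(
    params: CureParams,
    life_table: LifeTable,
    sex,
    age_at_dx: int,
    dx_year: int,
    t,
    *,
    period_ref: int | None = None,
) -> np.ndarray:
    """Expected (life-table) survival times relative survival.

    The period offset is ``dx_year - period_ref`` when a reference year is
    given, else 0 (no period effect applied).
    """
    period = (dx_year - period_ref) if period_ref is not None else 0.0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    exp_surv = np.array(
        [life_table.survival(sex, age_at_dx, dx_year, float(ti)) for ti in t_arr]
    )
    out = exp_surv * relative_survival(params, t_arr, period)
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class CureFitResult:
    params: CureParams
    se: dict
    loglik: float
    grad_norm: float
    converged: bool
    n: int
    n_events: int
    method: str
    warnings: list[str] = field(default_factory=list)


def prepare_survival_data(
    records: pd.DataFrame, *, index_like_columns: bool = True
) -> pd.DataFrame:
    """Subject-level survival frame from tumour records.

    Returns columns ``time`` (years diagnosis -> exit), ``event`` (death at
    exit), ``sex``, ``age_at_dx``, ``dx_year``.
    """
    dx = pd.to_datetime(records["diagnosis_date"])
    exit_ = pd.to_datetime(records["exit_date"])
    time = (exit_ - dx).dt.days / 365.25
    if (time < 0).any():
        raise ValueError("exit before diagnosis")
    age_at_dx = ((dx - pd.to_datetime(records["birth_date"])).dt.days / 365.25).astype(int)
    return pd.DataFrame(
        {
            "time": np.maximum(time.to_numpy(), _T_MIN),
            "event": (records["vital_status"] == "dead").to_numpy(),
            "sex": records["sex"].to_numpy(),
            "age_at_dx": age_at_dx.to_numpy(),
            "dx_year": dx.dt.year.to_numpy(),
        }
    )


def _unpack(theta, fit_beta):
    pi = 1.0 / (1.0 + np.exp(-theta[0]))
    lam = np.exp(theta[1])
    gamma = np.exp(theta[2])
    beta = theta[3] if fit_beta else 0.0
    return pi, lam, gamma, beta


def _neg_loglik(theta, t, d, h_bg, period, fit_beta):
    pi, lam, gamma, beta = _unpack(theta, fit_beta)
    per = np.exp(beta * period)
    Lam = (t / lam) ** gamma * per
    eS = np.exp(-Lam)
    rs = pi + (1.0 - pi) * eS
    dLam = gamma / lam * (t / lam) ** (gamma - 1.0) * per
    h_ex = (1.0 - pi) * eS * dLam / rs
    with np.errstate(divide="ignore"):
        ll = np.sum(d * np.log(np.maximum(h_bg + h_ex, 1e-300))) + np.sum(np.log(np.maximum(rs, 1e-300)))
    return -ll if np.isfinite(ll) else 1e12


def fit_cure_model(
    data: pd.DataFrame,
    life_table: LifeTable,
    *,
    stratum: tuple = ("all", "all", "all"),
    period_ref: int | None = None,
    method: str = "mle",
    min_events: int = 25,
    pi_starts=(0.2, 0.5, 0.8),
) -> CureFitResult:
    """Estimate cure-model parameters for one stratum.

    ``data`` is a prepared survival frame (see :func:`prepare_survival_data`)
    already restricted to the stratum. The total hazard is modelled as
    background (life-table) hazard plus the mixture-model excess hazard, and
    the background cumulative hazard drops from the likelihood as a constant.
    """
    t = np.maximum(data["time"].to_numpy(float), _T_MIN)
    d = data["event"].to_numpy(bool).astype(float)
    n, n_events = t.size, int(d.sum())
    if n_events < min_events:
        raise ValueError(
            f"stratum {stratum}: {n_events} events < required minimum {min_events}"
        )
    sex = data["sex"].to_numpy()
    age_dx = data["age_at_dx"].to_numpy(int)
    dx_year = data["dx_year"].to_numpy(int)
    # background hazard at exit time (annual piecewise-constant)
    h_bg = life_table.annual_hazard(sex, age_dx + np.floor(t).astype(int), dx_year + np.floor(t).astype(int))

    period = (dx_year - period_ref).astype(float) if period_ref is not None else np.zeros(n)
    fit_beta = period_ref is not None
    warnings_: list[str] = []
    if fit_beta and np.ptp(period) == 0:
        warnings_.append("period column constant: beta not identifiable, fixed at 0")
        logger.warning("stratum %s: %s", stratum, warnings_[-1])
        fit_beta = False
        period = np.zeros(n)

    if method == "ls":
        return _fit_ls(t, d, sex, age_dx, dx_year, life_table, stratum, warnings_, n, n_events)
    if method != "mle":
        raise ValueError(f"unknown fitting method {method!r}")

    lam0 = max(float(np.median(t[d > 0])) if n_events else 2.0, 0.1)
    bounds = [(-10, 10), (-5, 5), (-2, 2), (-2, 2)]
    best = None
    for pi0 in pi_starts:
        theta0 = np.array([np.log(pi0 / (1 - pi0)), np.log(lam0), 0.0, 0.0])
        res = minimize(
            _neg_loglik,
            theta0,
            args=(t, d, h_bg, period, fit_beta),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    pi, lam, gamma, beta = _unpack(best.x, fit_beta)
    if pi > 0.995 or pi < 0.005:
        warnings_.append(f"cure fraction at boundary (pi={pi:.4f})")
        logger.warning("stratum %s: %s", stratum, warnings_[-1])
    se = _mle_se(best.x, t, d, h_bg, period, fit_beta)
    params = CureParams(pi=min(pi, 1.0), lam=lam, gamma=gamma, beta_period=beta, stratum=stratum)
    return CureFitResult(
        params=params,
        se=se,
        loglik=-best.fun,
        grad_norm=float(np.max(np.abs(best.jac))),
        converged=bool(best.success),
        n=n,
        n_events=n_events,
        method="mle",
        warnings=warnings_,
    )


def _mle_se(theta, t, d, h_bg, period, fit_beta):
    """Delta-method standard errors from a finite-difference Hessian."""
    k = 4 if fit_beta else 3
    h = 1e-4
    H = np.zeros((k, k))

    def f(th):
        full = np.array(theta, dtype=float)
        full[:k] = th
        return _neg_loglik(full, t, d, h_bg, period, fit_beta)

    x0 = np.array(theta[:k], dtype=float)
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.eye(k)[i] * h, np.eye(k)[j] * h
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei) - f(x0 + ej) + f0
            ) / h**2
    names = ["pi", "lam", "gamma", "beta_period"][:k]
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError
        pi = 1 / (1 + np.exp(-theta[0]))
        grad_nat = np.array([pi * (1 - pi), np.exp(theta[1]), np.exp(theta[2]), 1.0])[:k]
        return dict(zip(names, np.sqrt(var) * grad_nat))
    except np.linalg.LinAlgError:
        return {name: float("nan") for name in names}


def actuarial_relative_survival(
    t: np.ndarray,
    d: np.ndarray,
    sex,
    age_dx: np.ndarray,
    dx_year: np.ndarray,
    life_table: LifeTable,
    n_intervals: int | None = None,
) -> pd.DataFrame:
    """Annual life-table (actuarial, Ederer-II expected) relative survival.

    Returns one row per completed year with the cumulative relative survival
    at the interval end and the number at risk at the interval start.
    """
    if n_intervals is None:
        n_intervals = max(int(np.floor(t.max())), 1)
    rows = []
    cum_rs = 1.0
    for j in range(n_intervals):
        at_risk = t >= j
        n_j = int(at_risk.sum())
        if n_j == 0:
            break
        in_j = at_risk & (t < j + 1)
        d_j = int((in_j & (d > 0)).sum())
        w_j = int((in_j & (d == 0)).sum())
        eff = n_j - w_j / 2.0
        p_obs = 1.0 - d_j / eff if eff > 0 else 1.0
        q_j = life_table.annual_q(sex[at_risk], age_dx[at_risk] + j, dx_year[at_risk] + j)
        p_exp = float(np.mean(1.0 - q_j))
        cum_rs *= p_obs / p_exp
        rows.append({"interval_end": j + 1.0, "cum_rs": cum_rs, "n_at_risk": n_j})
    return pd.DataFrame(rows)


def _fit_ls(t, d, sex, age_dx, dx_year, life_table, stratum, warnings_, n, n_events):
    """Weighted least squares of the RS curve on annual actuarial points."""
    pts = actuarial_relative_survival(t, d, sex, age_dx, dx_year, life_table)
    if len(pts) < 3:
        raise ValueError(f"stratum {stratum}: too few annual intervals for LS fit")
    tt = pts["interval_end"].to_numpy()
    y = pts["cum_rs"].to_numpy()
    w = pts["n_at_risk"].to_numpy(float)
    warnings_ = warnings_ + ["LS mode: period effect not modelled (beta fixed at 0)"]

    def obj(theta):
        pi, lam, gamma, _ = _unpack(np.append(theta, 0.0), False)
        rs = pi + (1 - pi) * np.exp(-((tt / lam) ** gamma))
        return float(np.sum(w * (rs - y) ** 2))

    best = None
    for pi0 in (0.2, 0.5, 0.8):
        res = minimize(
            obj,
            np.array([np.log(pi0 / (1 - pi0)), np.log(2.0), 0.0]),
            method="L-BFGS-B",
            bounds=[(-10, 10), (-5, 5), (-2, 2)],
        )
        if best is None or res.fun < best.fun:
            best = res
    pi, lam, gamma, _ = _unpack(np.append(best.x, 0.0), False)
    if pi > 0.995 or pi < 0.005:
        warnings_.append(f"cure fraction at boundary (pi={pi:.4f})")
    params = CureParams(pi=min(pi, 1.0), lam=lam, gamma=gamma, beta_period=0.0, stratum=stratum)
    return CureFitResult(
        params=params,
        se={},
        loglik=float("nan"),
        grad_norm=float(np.max(np.abs(best.jac))),
        converged=bool(best.success),
        n=n,
        n_events=n_events,
        method="ls",
        warnings=warnings_,
    )


def mle_loglik(params: CureParams, data: pd.DataFrame, life_table: LifeTable, *, period_ref: int | None = None) -> float:
    """Individual-data log-likelihood (background cumulative hazard dropped)
    of a given parameter vector on a prepared survival frame."""
    t = np.maximum(data["time"].to_numpy(float), _T_MIN)
    d = data["event"].to_numpy(bool).astype(float)
    sex = data["sex"].to_numpy()
    age_dx = data["age_at_dx"].to_numpy(int)
    dx_year = data["dx_year"].to_numpy(int)
    h_bg = life_table.annual_hazard(sex, age_dx + np.floor(t).astype(int), dx_year + np.floor(t).astype(int))
    period = (dx_year - period_ref).astype(float) if period_ref is not None else np.zeros(t.size)
    theta = np.array(
        [np.log(params.pi / (1 - params.pi)) if 0 < params.pi < 1 else (10.0 if params.pi >= 1 else -10.0),
         np.log(params.lam), np.log(params.gamma), params.beta_period]
    )
    return -_neg_loglik(theta, t, d, h_bg, period, True)


def simulate_cure_cohort(
    params: CureParams,
    life_table: LifeTable,
    n: int,
    *,
    sex: str = "male",
    age_at_dx: int = 60,
    dx_year: int = 2000,
    followup_years: float = 10.0,
    period_ref: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw subject-level survival data from the cure model over a life table.

    Background death times use annual piecewise-constant hazards; fatal cases
    additionally draw a Weibull cancer death time (period-scaled when a
    reference year is given). Administrative censoring at ``followup_years``.
    """
    rng = np.random.default_rng() if rng is None else rng
    dx_year_arr = np.broadcast_to(np.asarray(dx_year), (n,)).astype(int)
    period = (dx_year_arr - period_ref) if period_ref is not None else np.zeros(n)

    horizon = int(np.ceil(followup_years)) + 1
    t_bg = np.full(n, np.inf)
    alive = np.ones(n, bool)
    for j in range(horizon):
        h = life_table.annual_hazard(
            np.full(n, sex_code(sex)), np.full(n, age_at_dx + j), dx_year_arr + j
        )
        draw = rng.exponential(size=n) / np.maximum(h, 1e-300)
        hit = alive & (draw < 1.0)
        t_bg[hit] = j + draw[hit]
        alive &= ~hit

    cured = rng.random(n) < params.pi
    u = rng.random(n)
    t_cancer = np.where(
        cured,
        np.inf,
        params.lam * (-np.log(u) * np.exp(-params.beta_period * period)) ** (1.0 / params.gamma),
    )
    t_death = np.minimum(t_bg, t_cancer)
    time = np.minimum(t_death, followup_years)
    event = t_death <= followup_years
    return pd.DataFrame(
        {
            "time": np.maximum(time, _T_MIN),
            "event": event,
            "sex": sex,
            "age_at_dx": age_at_dx,
            "dx_year": dx_year_arr,
        }
    )
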