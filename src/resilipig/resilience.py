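"""Resilience phenotypes from daily feed-intake and feeder-duration data.

Two families of phenotypes quantify how much an animal's day-to-day feed
intake departs from its own trend under a disease challenge:

* ``RMSE_FI`` / ``RMSE_DUR`` — root mean square error of daily intake (kg)
  or feeder duration (min) about the animal's own OLS regression on age.
  Larger values mean larger day-to-day deviations, i.e. less resilience.

* ``QR_FI`` / ``QR_DUR`` — the animal's proportion of "off-feed" days,
  where a day is off-feed if it lies strictly below a population-level
  5% quantile-regression line of intake (or duration) on age, fitted by
  linear programming on the pooled days of all eligible animals across
  batches.

Validation traits: mortality (0/1), number of individual treatments to
slaughter (TRT), and the treatment rate standardized to 180 days (TRT180)
for animals reaching 65 days of age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog


@dataclass
class QuantileLine:
    """Population quantile-regression line: value = intercept + slope*age."""

    trait: str  # 'fi' or 'dur'
    tau: float
    intercept: float
    slope: float
    n_days: int

    def predict(self, age) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "tau": self.tau,
            "intercept": self.intercept,
            "slope": self.slope,
            "n_days": self.n_days,
        }


def pinball_loss(y, age, intercept, slope, tau) -> float:
    """Mean-free check-function loss of a candidate line."""
    r = np.asarray(y, float) - (intercept + slope * np.asarray(age, float))
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))


def fit_quantile_line(
    ages: np.ndarray, values: np.ndarray, tau: float = 0.05, trait: str = "fi"
) -> QuantileLine:
    """Fit a linear tau-quantile regression of value on age by LP.

    Minimizes the check loss  sum rho_tau(y - a - b*age)  as a linear
    program in its dual form (Koenker-d'Orey): maximize y'd subject to
    X'd = 0 with d_i in [tau-1, tau]; the fitted coefficients are the
    multipliers of the two equality constraints.  For the solution, the
    fraction of points strictly below the line is <= tau and the fraction
    below-or-on is >= tau.
    """
    age = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~np.isnan(y)
    age, y = age[keep], y[keep]
    n = len(y)
    if len(np.unique(age)) < 2:
        raise ValueError("need at least 2 distinct ages to fit a line")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    X = np.column_stack([np.ones(n), age])
    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=np.zeros(2),
        bounds=[(tau - 1.0, tau)] * n,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a, b = -res.eqlin.marginals
    return QuantileLine(trait=trait, tau=tau, intercept=float(a), slope=float(b), n_days=n)


def rmse_trait(ages: np.ndarray, values: np.ndarray, ddof: int = 0) -> float:
    """Within-animal RMSE about the OLS regression of value on age.

    ``ddof=0`` (default) returns the literal root mean square of the
    residuals, sqrt(SSE/n); ``ddof=2`` gives the regression standard
    error sqrt(SSE/(n-2)).  Missing values are dropped.
    """
    age = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~np.isnan(y)
    age, y = age[keep], y[keep]
    n = len(y)
    if n - ddof <= 0 or len(np.unique(age)) < 2:
        return float("nan")
    X = np.column_stack([np.ones(n), age])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ beta) ** 2))
    return float(np.sqrt(sse / (n - ddof)))


def qr_trait(ages: np.ndarray, values: np.ndarray, line: QuantileLine) -> float:
    """Proportion of the animal's days strictly below the quantile line.

    Ties (exactly on the line) count as on-feed.  The denominator is the
    animal's number of non-missing days.
    """
    age = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~np.isnan(y)
    age, y = age[keep], y[keep]
    if len(y) == 0:
        return float("nan")
    below = y < line.predict(age)
    return float(below.mean())


def treatment_traits(
    treatments_ages,
    death_age: int | None,
    slaughter_age: int | None,
    trt180_min_age: int = 65,
):
    """Mortality, TRT and TRT180 for one animal.

    mortality: 1 if the pig died before slaughter, else 0.
    TRT: count of individual treatments; recorded only for pigs that
    survived to slaughter.
    TRT180: treatments per 180 days alive, (count / last-alive age) * 180;
    recorded only for pigs reaching ``trt180_min_age`` days of age.
    """
    ages = sorted(int(a) for a in treatments_ages)
    died = death_age is not None
    last_alive = death_age if died else slaughter_age
    if last_alive is None:
        raise ValueError("animal needs a death age or a slaughter age")
    if ages and ages[-1] > last_alive:
        raise ValueError("treatment recorded after the animal's death")
    count = len(ages)
    mortality = 1 if died else 0
    trt = None if died else count
    trt180 = (count / last_alive) * 180.0 if last_alive >= trt180_min_age else None
    return mortality, trt, trt180


def build_resilience_table(
    daily: pd.DataFrame,
    animals: pd.DataFrame,
    treatments: pd.DataFrame,
    tau: float = 0.05,
    min_days: int = 60,
    rmse_ddof: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One row of resilience phenotypes per animal.

    The quantile lines are fitted once on the pooled days of all eligible
    animals (>= ``min_days`` recorded intake days) across batches, then
    frozen for classification.  Animals failing the eligibility filter get
    missing RMSE/QR traits but still receive mortality/treatment traits.

    Returns (table, {'fi': QuantileLine, 'dur': QuantileLine}).
    """
    counts = daily.groupby("animal_id")["fi"].count()
    eligible = set(counts.index[counts >= min_days])
    pool = daily[daily["animal_id"].isin(eligible)]
    lines = {}
    for ch in ("fi", "dur"):
        lines[ch] = fit_quantile_line(
            pool["age"].to_numpy(), pool[ch].to_numpy(), tau=tau, trait=ch
        )

    trt_by_animal = treatments.groupby("animal_id")["age"].apply(list).to_dict()
    grouped = dict(tuple(daily.groupby("animal_id")))
    rows = []
    for rec in animals.itertuples(index=False):
        aid = rec.animal_id
        death = rec.death_age
        death = None if (pd.isna(death) or death == "") else int(death)
        slaughter = rec.slaughter_age
        slaughter = None if (pd.isna(slaughter) or slaughter == "") else int(slaughter)
        mort, trt, trt180 = treatment_traits(
            trt_by_animal.get(aid, []), death, slaughter
        )
        row = {
            "animal_id": aid,
            "n_days": 0,
            "rmse_fi": np.nan,
            "rmse_dur": np.nan,
            "qr_fi": np.nan,
            "qr_dur": np.nan,
            "mortality": mort,
            "trt": np.nan if trt is None else trt,
            "trt180": np.nan if trt180 is None else trt180,
        }
        g = grouped.get(aid)
        if g is not None:
            row["n_days"] = int(g["fi"].count())
        if aid in eligible and g is not None:
            a = g["age"].to_numpy()
            for ch in ("fi", "dur"):
                v = g[ch].to_numpy()
                row[f"rmse_{ch}"] = rmse_trait(a, v, ddof=rmse_ddof)
                row[f"qr_{ch}"] = qr_trait(a, v, lines[ch])
        rows.append(row)
    return pd.DataFrame(rows), lines
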