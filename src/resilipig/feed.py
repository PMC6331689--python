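"""Cleaning and completion of daily feed-intake / feeder-duration records.

Daily totals arrive as one row per animal-day with feed intake (kg) and
time at the feeder (minutes).  Cleaning applies, in order: a physiological
cap that sets implausibly large daily intakes to missing, then a centred
5-day rolling-average imputation within animal.  Eligibility for the
resilience phenotypes requires a minimum number of recorded intake days.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    pass


@dataclass
class CleaningReport:
    """Counts of values touched by a cleaning step."""

    n_capped: int = 0
    n_imputed: int = 0
    n_unfilled: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _canonical(daily: pd.DataFrame) -> pd.DataFrame:
    out = daily.sort_values(["animal_id", "age"], kind="mergesort").reset_index(
        drop=True
    )
    if out.duplicated(["animal_id", "age"]).any():
        raise ValueError("duplicate (animal_id, age) rows in daily records")
    return out


def cap_daily_fi(
    daily: pd.DataFrame, cap: float = 5.0
) -> tuple[pd.DataFrame, CleaningReport]:
    """Set daily feed intakes strictly greater than ``cap`` kg to missing.

    A daily total above the cap is treated as a recording error of the
    electronic feeder.  Exactly-at-cap values are kept; duration is never
    capped.  Returns the cleaned table and a report with ``n_capped``.
    """
    if cap < 0:
        raise ConfigError("cap must be non-negative")
    out = _canonical(daily).copy()
    mask = out["fi"] > cap  # strictly greater; NaN compares False
    out.loc[mask, "fi"] = np.nan
    return out, CleaningReport(n_capped=int(mask.sum()))


def impute_rolling(
    daily: pd.DataFrame, window: int = 5, centred: bool = True
) -> tuple[pd.DataFrame, CleaningReport]:
    """Fill missing daily values with a rolling average within animal.

    Each missing intake (and, separately, duration) is replaced by the mean
    of the *originally observed* values among the ``window`` calendar days
    centred on the gap, so a two-day adjacent gap fills from its flanking
    observations only and the result does not depend on fill order.  Days
    with no observed neighbour in the window stay missing.  Sets
    ``imputed_fi`` / ``imputed_dur`` flags.  ``centred=False`` uses a
    trailing window of the same width instead.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigError("window must be an odd integer >= 3")
    half = window // 2
    out = _canonical(daily).copy()
    for col in ("fi", "dur"):
        flag = f"imputed_{col}"
        if flag not in out.columns:
            out[flag] = False
    n_imp = 0
    n_unf = 0
    filled = []
    for _, grp in out.groupby("animal_id", sort=False):
        g = grp.copy()
        ages = g["age"].to_numpy()
        # reindex to the full calendar span so window arithmetic is in days
        full = np.arange(ages.min(), ages.max() + 1)
        pos = np.searchsorted(full, ages)
        for col in ("fi", "dur"):
            obs = np.full(len(full), np.nan)
            obs[pos] = g[col].to_numpy(dtype=float)
            miss = np.isnan(obs[pos])
            newv = obs[pos].copy()
            for j in np.nonzero(miss)[0]:
                p = pos[j]
                lo = full[p] - half if centred else full[p] - window + 1
                hi = full[p] + half if centred else full[p]
                sel = (full >= lo) & (full <= hi)
                vals = obs[sel]
                vals = vals[~np.isnan(vals)]
                if len(vals):
                    newv[j] = vals.mean()
                    n_imp += 1
                else:
                    n_unf += 1
            g[col] = newv
            g.loc[g.index[miss & ~np.isnan(newv)], f"imputed_{col}"] = True
        filled.append(g)
    out = pd.concat(filled).sort_values(["animal_id", "age"], kind="mergesort")
    return out.reset_index(drop=True), CleaningReport(
        n_imputed=n_imp, n_unfilled=n_unf
    )


def eligible_for_resilience(daily: pd.DataFrame, min_days: int = 60) -> pd.Series:
    """Flag animals with at least ``min_days`` non-missing intake days.

    Imputed days count as recorded.  Returns a boolean Series indexed by
    animal_id covering every animal present in ``daily``.
    """
    counts = daily.groupby("animal_id")["fi"].count()
    return counts >= min_days


def clean_daily(
    daily: pd.DataFrame, cap: float = 5.0, window: int = 5, centred: bool = True
) -> tuple[pd.DataFrame, CleaningReport]:
    """Cap then impute; merge the two step reports."""
    capped, r1 = cap_daily_fi(daily, cap=cap)
    imputed, r2 = impute_rolling(capped, window=window, centred=centred)
    return imputed, CleaningReport(
        n_capped=r1.n_capped, n_imputed=r2.n_imputed, n_unfilled=r2.n_unfilled
    )
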