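"""Production traits: intake, growth efficiency, and carcass measures.

ADFI is the mean of daily intake records over the finishing period; FCR is
total finishing feed over total body-weight gain (gain taken from the
LOESS-predicted daily weights at the phase endpoints); RFI is the residual
of ADFI from a linear model with batch / start-age / pen fixed effects and
average finisher body weight, finishing ADG and ultrasound backfat as
covariates.  Carcass traits: dressing proportion (warm carcass over live
weight) and a fixed Quebec prediction polynomial for carcass lean yield
from backfat and loin depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


def adfi(fi_values: np.ndarray) -> float:
    """Mean non-missing daily feed intake (kg/day) over finishing."""
    v = np.asarray(fi_values, dtype=float)
    v = v[~np.isnan(v)]
    return float(v.mean()) if len(v) else float("nan")


def fcr(fi_values: np.ndarray, weight_start: float, weight_end: float) -> float:
    """Feed conversion ratio: total finishing feed over total gain.

    Returns NaN when the gain is non-positive (division guard).
    """
    v = np.asarray(fi_values, dtype=float)
    total = float(np.nansum(v))
    gain = weight_end - weight_start
    if gain <= 0:
        return float("nan")
    return total / gain


def dressing(cwt: float, live_weight: float) -> float:
    """Dressing proportion: warm carcass weight over live weight."""
    if live_weight <= 0:
        raise ValueError("live weight must be positive")
    return cwt / live_weight


def lean_yield(cbf: float, cld: float):
    """Carcass lean yield (%) from backfat and loin depth (mm).

    Fixed Quebec prediction equation:
    68.1863 - 0.7833*CBF + 0.0689*CLD + 0.008*CBF^2 - 0.0002*CLD^2
    + 0.0006*CBF*CLD.  The prediction is dominated by backfat.
    """
    cbf = np.asarray(cbf, dtype=float)
    cld = np.asarray(cld, dtype=float)
    if np.any(cbf < 0) or np.any(cld < 0):
        raise ValueError("backfat and loin depth must be non-negative")
    out = (
        68.1863
        - 0.7833 * cbf
        + 0.0689 * cld
        + 0.008 * cbf**2
        - 0.0002 * cld**2
        + 0.0006 * cbf * cld
    )
    return float(out) if out.ndim == 0 else out


def rfi(table: pd.DataFrame) -> pd.Series:
    """Two-step residual feed intake (kg/day), indexed like ``table``.

    Fits ADFI on batch, finishing start age and pen (fixed effects) plus
    average finisher body weight, finishing ADG and ultrasound backfat
    (covariates); the residuals are RFI.  Rows with any missing field are
    excluded (NaN in the result).  Aliased design columns are dropped by
    the fitter.
    """
    need = ["adfi", "batch", "finishing_start_age", "pen", "avg_bw", "fin_adg", "ultrasound_bf"]
    d = table[need].dropna()
    out = pd.Series(np.nan, index=table.index, name="rfi")
    if len(d) < 8:
        return out
    model = smf.ols(
        "adfi ~ C(batch) + finishing_start_age + C(pen) + avg_bw + fin_adg + ultrasound_bf",
        data=d,
    ).fit()
    out.loc[d.index] = model.resid
    return out


def build_production_table(
    daily: pd.DataFrame,
    animals: pd.DataFrame,
    curves: dict,
    carcass: pd.DataFrame,
    metabolic_bw: bool = False,
) -> pd.DataFrame:
    """One row of production traits per animal.

    Finishing phase spans the animal's first to last recorded intake day;
    only pigs that completed finishing (survived to slaughter) receive
    ADFI/FCR/ADG phenotypes.  ``metabolic_bw=True`` uses mean daily
    weight^0.75 as the body-weight covariate for RFI.
    """
    from .growth import phase_adg

    carc = carcass.set_index("animal_id") if len(carcass) else carcass
    grouped = dict(tuple(daily.groupby("animal_id")))
    rows = []
    for rec in animals.itertuples(index=False):
        aid = rec.animal_id
        died = not (pd.isna(rec.death_age) or rec.death_age == "")
        row = {
            "animal_id": aid,
            "batch": rec.batch,
            "pen": rec.pen,
            "finishing_start_age": rec.finishing_start_age,
            "nur_adg": np.nan,
            "fin_adg": np.nan,
            "adfi": np.nan,
            "fcr": np.nan,
            "avg_bw": np.nan,
            "cwt": np.nan,
            "drs": np.nan,
            "lyld": np.nan,
            "cbf": np.nan,
            "cld": np.nan,
            "ultrasound_bf": np.nan,
        }
        g = grouped.get(aid)
        curve = curves.get(aid)
        if curve is not None and g is not None and len(g):
            first_fi = int(g["age"].min())
            last_fi = int(g["age"].max())
            row["nur_adg"] = _none_nan(
                phase_adg(curve, int(rec.quarantine_entry_age), first_fi)
            )
            if not died:  # completed the finishing phase
                row["fin_adg"] = _none_nan(phase_adg(curve, first_fi, last_fi))
                row["adfi"] = adfi(g["fi"].to_numpy())
                lo = max(first_fi, int(curve.ages[0]))
                hi = min(last_fi, int(curve.ages[-1]))
                if hi > lo:
                    w = curve.daily_weights[lo - curve.ages[0] : hi - curve.ages[0] + 1]
                    row["fcr"] = fcr(
                        g.loc[(g["age"] >= lo) & (g["age"] <= hi), "fi"].to_numpy(),
                        w[0],
                        w[-1],
                    )
                    bw = w**0.75 if metabolic_bw else w
                    row["avg_bw"] = float(bw.mean())
        if not died and len(carc) and aid in carc.index:
            c = carc.loc[aid]
            row["cwt"] = c["cwt"]
            row["drs"] = dressing(c["cwt"], c["live_weight"])
            row["lyld"] = lean_yield(c["cbf"], c["cld"])
            row["cbf"] = c["cbf"]
            row["cld"] = c["cld"]
            row["ultrasound_bf"] = c["ultrasound_bf"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table["rfi"] = rfi(table)
    return table


def _none_nan(x):
    return np.nan if x is None else x
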