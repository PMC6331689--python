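"""Daily body weights by local regression, and phase average daily gain.

Body weights are recorded only every ~3 weeks; production traits need a
weight for every day.  A locally weighted polynomial regression (tricube
kernel, span 0.75, degree 2 — the classical LOESS defaults) is fitted to
each animal's weights and evaluated at every integer age between its first
and last weighing.  Average daily gain (ADG) over a phase is the ordinary
least-squares slope of these predicted daily weights on age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GrowthCurve:
    animal_id: str
    ages: np.ndarray  # consecutive integer ages, observation range
    daily_weights: np.ndarray  # predicted kg, aligned with ages
    fit_quality: float  # corr(predicted, observed) at observed ages
    method: str  # 'loess' or 'linear' fallback

    def weight_at(self, age: int) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise KeyError(f"age {age} outside curve range for {self.animal_id}")
        return float(self.daily_weights[age - self.ages[0]])


def loess_predict(
    x: np.ndarray,
    y: np.ndarray,
    xnew: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Pointwise LOESS: tricube-weighted polynomial fit at each target.

    At each target point the ``q = floor(span * n)`` nearest observations
    receive tricube weights scaled by the distance to the q-th nearest, and
    a weighted polynomial of the stated degree is solved by least squares.
    No robustness iterations are applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = int(span * n + 1e-9)
    q = min(max(q, degree + 1), n)
    out = np.empty(len(xnew))
    for k, x0 in enumerate(np.asarray(xnew, dtype=float)):
        d = np.abs(x - x0)
        dq = np.partition(d, q - 1)[q - 1]
        if span > 1.0:
            dq *= span ** (1.0 / 1)
        if dq <= 0:
            out[k] = y[d == 0].mean()
            continue
        w = (1.0 - np.clip(d / dq, 0.0, 1.0) ** 3) ** 3
        m = w > 0
        xc = x[m] - x0  # centre at target for conditioning
        X = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w[m])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[m] * sw, rcond=None)
        out[k] = beta[0]
    return out


def fit_loess_weights(
    weights: pd.DataFrame,
    animal_id: str | None = None,
    span: float = 0.75,
    degree: int = 2,
) -> GrowthCurve | None:
    """Fit one animal's growth curve over its observed age range.

    With >= 4 weights a degree-``degree`` LOESS is used; with 2-3 weights
    (common for pigs dying early) the fit falls back to linear
    interpolation, flagged in ``method``.  Returns None with < 2 records.
    Predictions are never extrapolated beyond the observed range.
    """
    w = weights if animal_id is None else weights[weights["animal_id"] == animal_id]
    w = w.sort_values("age")
    x = w["age"].to_numpy(dtype=float)
    y = w["weight"].to_numpy(dtype=float)
    aid = str(w["animal_id"].iloc[0]) if len(w) else str(animal_id)
    if len(x) < 2:
        return None
    ages = np.arange(int(x[0]), int(x[-1]) + 1)
    if len(x) >= 4:
        pred = loess_predict(x, y, ages, span=span, degree=degree)
        at_obs = loess_predict(x, y, x, span=span, degree=degree)
        method = "loess"
    else:
        pred = np.interp(ages, x, y)
        at_obs = np.interp(x, x, y)
        method = "linear"
    if np.std(y) > 0 and np.std(at_obs) > 0:
        fq = float(np.corrcoef(at_obs, y)[0, 1])
    else:
        fq = 1.0
    return GrowthCurve(aid, ages, pred, fq, method)


def fit_all_curves(weights: pd.DataFrame, span: float = 0.75, degree: int = 2):
    """Fit curves for every animal; returns {animal_id: GrowthCurve}."""
    curves = {}
    for aid, grp in weights.groupby("animal_id", sort=True):
        c = fit_loess_weights(grp, span=span, degree=degree)
        if c is not None:
            curves[str(aid)] = c
    return curves


def phase_adg(curve: GrowthCurve, start_age: int, end_age: int) -> float | None:
    """OLS slope (kg/day) of predicted daily weight on age over a phase.

    The phase is clipped to the curve's observed range; a clipped phase
    shorter than 2 days yields None (trait missing).
    """
    lo = max(int(start_age), int(curve.ages[0]))
    hi = min(int(end_age), int(curve.ages[-1]))
    if hi - lo < 1:
        return None
    a = np.arange(lo, hi + 1, dtype=float)
    wgt = curve.daily_weights[lo - curve.ages[0] : hi - curve.ages[0] + 1]
    a_c = a - a.mean()
    return float(a_c @ (wgt - wgt.mean()) / (a_c @ a_c))


def curves_to_frame(curves: dict) -> pd.DataFrame:
    """Flatten fitted curves to a daily_weights table."""
    rows = []
    for aid, c in curves.items():
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": aid,
                    "age": c.ages,
                    "pred_weight": np.round(c.daily_weights, 4),
                    "method": c.method,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["animal_id", "age", "pred_weight", "method"])
    return pd.concat(rows, ignore_index=True)
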