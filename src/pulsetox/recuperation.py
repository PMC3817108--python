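"""Recuperation deltas and the nonparametric / feeding-endpoint analyses.

The recuperation statistic for a variable X is the per-colony difference
``X_off - X_on``; a positive value means the colony performed better after
the dose was removed.  Dose dependence of the deltas is assessed with
Spearman rank correlation, the relationship of brood to food intake with
partial Pearson correlation controlling for dosage, the group-level trend
with an OLS fit on ln(dosage), and feeding endpoints with a fixed-bottom
log-logistic suppression model and its EC_p accessor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .colonies import ColonyRecord, period_table
from .curves import DEFAULT_RANGE_LIMIT

__all__ = [
    "RecuperationResult",
    "TrendFit",
    "NoDoseEffectError",
    "recuperation_delta",
    "recuperation_test",
    "spearman",
    "partial_pearson",
    "log_trend_fit",
    "LogLogistic",
    "loglogistic_fit",
]


class NoDoseEffectError(RuntimeError):
    """The response does not decrease with dosage: EC fitting is meaningless."""


@dataclass(frozen=True)
class RecuperationResult:
    """Per-colony deltas plus the dose-dependence test."""

    variable: str
    deltas: pd.Series          # index: colony_id
    dosages: pd.Series         # aligned with deltas
    rho: float
    p_value: float
    n: int
    n_excluded: int = 0


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of group-mean deltas on ln(dosage)."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, dosage):
        d = np.asarray(dosage, float)
        if np.any(d <= 0):
            raise ValueError("trend is defined for dosage > 0 (ln scale)")
        return self.slope * np.log(d) + self.intercept


def recuperation_delta(
    records: Iterable[ColonyRecord], variable: str = "brood"
) -> pd.DataFrame:
    """Per-colony ``X_off - X_on`` for brood, syrup_gpd or pollen_gpd.

    Colonies missing either period (or with the variable unmeasured in a
    period) are excluded with a warning reporting the count.  Returns a
    DataFrame indexed by colony_id with columns ``dosage_ugkg`` and
    ``delta``.
    """
    if variable not in ("brood", "syrup_gpd", "pollen_gpd"):
        raise ValueError(f"unsupported variable {variable!r}")
    wide = period_table(records)
    on, off = f"{variable}_on", f"{variable}_off"
    for col in (on, off):
        if col not in wide.columns:
            wide[col] = np.nan
    ok = wide[on].notna() & wide[off].notna()
    n_excl = int((~ok).sum())
    if n_excl:
        warnings.warn(
            f"{n_excl} colony(ies) missing a period for {variable!r}; excluded",
            stacklevel=2,
        )
    out = wide.loc[ok, ["dosage_ugkg"]].copy()
    out["delta"] = (wide.loc[ok, off] - wide.loc[ok, on]).astype(float)
    return out


def recuperation_test(
    records: Iterable[ColonyRecord], variable: str = "brood"
) -> RecuperationResult:
    """Dose dependence of recuperation: Spearman of delta vs dosage."""
    df = recuperation_delta(records, variable)
    rho, p = spearman(df["dosage_ugkg"].to_numpy(), df["delta"].to_numpy())
    wide = period_table(records)
    return RecuperationResult(
        variable=variable,
        deltas=df["delta"],
        dosages=df["dosage_ugkg"],
        rho=rho,
        p_value=p,
        n=len(df),
        n_excluded=len(wide) - len(df),
    )


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by exhaustive enumeration over orderings of ry."""
    n = rx.size
    cx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float(cx @ cx) * float(sy @ sy))
    hits = total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in permutations(sy):
        r = float(cx @ np.asarray(perm)) / denom
        hits += abs(r) >= thresh
        total += 1
    return hits / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    For n <= 8 the two-sided p comes from exhaustive permutation
    enumeration; for larger n from the usual t approximation with
    ``df = n - 2``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman rho is undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def partial_pearson(x, y, control) -> tuple[float, float]:
    """First-order partial Pearson correlation of x and y controlling for z.

    ``r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1-r_xz²)(1-r_yz²))`` with a
    t-based two-sided p on ``df = n - 3``.  A control variable that is
    perfectly correlated with x or y is degenerate; a constant control
    reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(control, float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y and control must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    if np.all(z == z[0]):
        r = r_xy
    else:
        r_xz = float(np.corrcoef(x, z)[0, 1])
        r_yz = float(np.corrcoef(y, z)[0, 1])
        if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
            raise ValueError(
                "control is perfectly correlated with x or y: "
                "partial correlation is degenerate"
            )
        r = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if abs(r) >= 1.0:
        return float(np.clip(r, -1.0, 1.0)), 0.0
    t = r * math.sqrt((n - 3) / (1.0 - r**2))
    return float(r), float(2.0 * stats.t.sf(abs(t), df=n - 3))


def log_trend_fit(group_mean_deltas, dosages) -> TrendFit:
    """OLS of mean deltas on ln(dosage) (control excluded: ln 0 undefined)."""
    y = np.asarray(group_mean_deltas, float)
    d = np.asarray(dosages, float)
    if y.size != d.size:
        raise ValueError("deltas and dosages must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 dose groups")
    if np.any(d <= 0):
        raise ValueError("dosages must be > 0 (exclude the control)")
    X = np.log(d)
    res = stats.linregress(X, y)
    r2 = float(res.rvalue**2)
    if not math.isfinite(r2):  # zero-variance response: no trend explained
        r2 = 0.0
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# Feeding-endpoint log-logistic model

class LogLogistic(BaseEstimator, RegressorMixin):
    """Fixed-bottom three-parameter log-logistic dose-response model.

    ``response = top / (1 + (dosage / ec50)**hill)`` fitted by least
    squares.  The model is constrained decreasing (all parameters
    positive); data whose response trends upward with dosage raise
    :class:`NoDoseEffectError` instead of returning a meaningless fit.

    Attributes: ``top_``, ``ec50_``, ``hill_``, ``r_squared_``.
    """

    def __init__(self, *, range_limit: float = DEFAULT_RANGE_LIMIT,
                 max_iter: int = 10_000):
        self.range_limit = range_limit
        self.max_iter = max_iter

    @staticmethod
    def _model(d, top, ec50, hill):
        return top / (1.0 + (d / ec50) ** hill)

    def fit(self, X, y):
        d = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        if d.size != y.size:
            raise ValueError("X and y must have equal length")
        if np.unique(d).size < 5:
            raise ValueError("need at least 5 dose groups including control")
        if np.any(d < 0):
            raise ValueError("dosages must be >= 0")
        pos = d > 0
        slope = stats.linregress(np.log1p(d), y).slope
        if slope >= 0:
            raise NoDoseEffectError(
                "response does not decrease with dosage; EC values undefined"
            )
        p0 = (
            max(float(y[~pos].mean()) if np.any(~pos) else float(y.max()), 1e-6),
            float(np.median(d[pos])),
            1.0,
        )
        try:
            popt, _ = optimize.curve_fit(
                self._model, d, y, p0=p0,
                bounds=([1e-12, 1e-12, 1e-3], [np.inf, np.inf, 50.0]),
                maxfev=self.max_iter,
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"log-logistic fit did not converge (start {p0}): {err}"
            ) from err
        self.top_, self.ec50_, self.hill_ = map(float, popt)
        resid = y - self._model(d, *popt)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        d = np.asarray(X, float).reshape(-1)
        return self._model(d, self.top_, self.ec50_, self.hill_)

    def ec(self, p: float):
        """EC_p = ec50 * (p/(100-p))**(1/hill), with a beyond-range marker."""
        from .curves import ECEstimate

        if not 0 < p < 100:
            raise ValueError(f"p must lie in (0, 100), got {p}")
        dose = self.ec50_ * (p / (100.0 - p)) ** (1.0 / self.hill_)
        return ECEstimate(p=p, dosage=float(dose), range_limit=self.range_limit)


def loglogistic_fit(
    consumption, dosages, p_levels: Sequence[float] = (50.0, 10.0),
    range_limit: float = DEFAULT_RANGE_LIMIT,
):
    """Fit the feeding suppression model; returns (model, {p: ECEstimate})."""
    model = LogLogistic(range_limit=range_limit).fit(dosages, consumption)
    return model, {p: model.ec(p) for p in p_levels}
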