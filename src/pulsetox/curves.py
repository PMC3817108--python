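"""Dose-response curve evaluation, EC_p inversion, credible bands, tables.

The fitted relationship is ``brood = exp(alpha + beta * log10(dosage + 1))``:
``alpha`` sets the control (zero-dose) level and ``beta < 0`` the strength of
suppression.  The covariate log is base 10 throughout the package; with the
reported 14-day coefficients this convention reproduces the published
EC_50 of 1.44 ppb exactly, which natural log does not.

The "best-fit" curve is the median-colony curve (colony random effect
λ = 0), not the marginal mean over colonies — the marginal mean would carry
an extra ``exp(σ²/2)`` factor and does not reproduce the reported EC and
reduction-table values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bhm import Posterior

__all__ = [
    "DoseResponseCurve",
    "ECEstimate",
    "CredibleBand",
    "BROOD_ON_DOSE",
    "BROOD_PULSE_TOTAL",
    "DEFAULT_RANGE_LIMIT",
    "expected_brood",
    "percent_reduction",
    "ec",
    "ec_from_posterior",
    "credible_band",
    "reduction_table",
]

#: Top of the tested dosage range (125 µg L⁻¹ stock / 1.27 kg L⁻¹ syrup), ppb.
DEFAULT_RANGE_LIMIT = 125.0 / 1.27


@dataclass(frozen=True)
class DoseResponseCurve:
    """Pair (alpha, beta) defining expected brood vs dosage on the log10 scale."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("curve coefficients must be finite")

    def __call__(self, dosage):
        return expected_brood(self, dosage)


#: Reported best-fit curve for brood produced during the 14-day on-dose period.
BROOD_ON_DOSE = DoseResponseCurve(2.002, -1.788)
#: Reported best-fit curve for total brood over the full 28-day pulsed exposure.
BROOD_PULSE_TOTAL = DoseResponseCurve(2.770, -0.198)


@dataclass(frozen=True)
class ECEstimate:
    """Dosage at which expected brood drops ``p`` percent below control.

    When the solution exceeds ``range_limit`` the estimate is flagged
    ``beyond_range`` — the numeric inversion is still recorded in
    ``dosage`` so no information is lost, but it should be reported as
    ``"> {range_limit}"`` rather than as an extrapolated point value.
    """

    p: float
    dosage: float
    range_limit: float = DEFAULT_RANGE_LIMIT
    interval: tuple[float, float] | None = None

    @property
    def beyond_range(self) -> bool:
        return self.dosage > self.range_limit

    def __str__(self) -> str:
        if self.beyond_range:
            return f"EC{self.p:g} > {self.range_limit:.2f} ppb"
        s = f"EC{self.p:g} = {self.dosage:.2f} ppb"
        if self.interval is not None:
            s += f" (95% CrI {self.interval[0]:.2f}-{self.interval[1]:.2f})"
        return s


@dataclass(frozen=True)
class CredibleBand:
    """Pointwise posterior band of expected brood over a dosage grid."""

    dosages: np.ndarray
    lower: np.ndarray
    point: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dosage_ugkg": self.dosages,
                "lower_2.5": self.lower,
                "point": self.point,
                "upper_97.5": self.upper,
            }
        )


def _check_dosage(dosage):
    d = np.asarray(dosage, dtype=float)
    if np.any(d < 0):
        raise ValueError("dosage must be >= 0")
    return d


def expected_brood(curve: DoseResponseCurve, dosage):
    """Median-colony expected brood ``exp(alpha + beta*log10(dosage+1))``."""
    d = _check_dosage(dosage)
    out = np.exp(curve.alpha + curve.beta * np.log10(d + 1.0))
    return float(out) if out.ndim == 0 else out


def percent_reduction(curve: DoseResponseCurve, dosage):
    """Percent reduction of expected brood relative to control.

    ``100 * (1 - exp(beta * log10(dosage+1)))``; independent of alpha.
    """
    d = _check_dosage(dosage)
    out = 100.0 * (1.0 - np.exp(curve.beta * np.log10(d + 1.0)))
    return float(out) if out.ndim == 0 else out


def _invert_reduction(beta: float, p: float) -> float:
    # exp(beta * log10(d+1)) = 1 - p/100  =>  d = 10**(ln(1-p/100)/beta) - 1
    return 10.0 ** (np.log1p(-p / 100.0) / beta) - 1.0


def ec(
    curve: DoseResponseCurve,
    p: float,
    range_limit: float = DEFAULT_RANGE_LIMIT,
) -> ECEstimate:
    """Effective concentration: dosage giving a ``p``-percent brood reduction.

    Closed-form inversion of :func:`percent_reduction`.  Requires ``beta < 0``
    (a suppressive dose response) and ``0 < p < 100``.
    """
    if not 0 < p < 100:
        raise ValueError(f"p must lie in (0, 100), got {p}")
    if curve.beta >= 0:
        raise ValueError(
            "EC undefined: beta >= 0 means no suppressive dose response"
        )
    return ECEstimate(p=p, dosage=_invert_reduction(curve.beta, p),
                      range_limit=range_limit)


def ec_from_posterior(
    posterior: Posterior,
    p: float,
    range_limit: float = DEFAULT_RANGE_LIMIT,
) -> ECEstimate:
    """EC_p with a posterior 95% interval from the beta draws.

    The point estimate inverts the posterior-median reduction; interval
    endpoints are the 2.5/97.5 percentiles of the per-draw inversions
    (draws with non-negative beta yield +inf — no finite EC).
    """
    if not 0 < p < 100:
        raise ValueError(f"p must lie in (0, 100), got {p}")
    betas = posterior.stack("beta")
    with np.errstate(over="ignore"):
        draws = np.where(
            betas < 0,
            10.0 ** (np.log1p(-p / 100.0) / np.where(betas < 0, betas, -1.0)) - 1.0,
            np.inf,
        )
    point = float(np.median(draws))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return ECEstimate(p=p, dosage=point, range_limit=range_limit,
                      interval=(float(lo), float(hi)))


def credible_band(posterior: Posterior, dosage_grid) -> CredibleBand:
    """Pointwise 2.5/97.5% band of ``exp(alpha + beta*log10(d+1))`` over draws.

    The colony random effect is excluded (median-colony convention); the
    point curve is the posterior median at each grid dosage.  Percentiles use
    linear interpolation between order statistics.
    """
    d = _check_dosage(dosage_grid)
    alphas = posterior.stack("alpha")
    betas = posterior.stack("beta")
    if alphas.size == 0:
        raise ValueError("empty posterior")
    L = np.log10(d + 1.0)
    fitted = np.exp(alphas[:, None] + betas[:, None] * L[None, :])
    lo, mid, hi = np.percentile(fitted, [2.5, 50.0, 97.5], axis=0)
    return CredibleBand(dosages=d, lower=lo, point=mid, upper=hi)


def reduction_table(
    source: DoseResponseCurve | Posterior,
    scenario_dosages: Sequence[float] = (0.3, 0.8, 1.9, 10.0),
) -> pd.DataFrame:
    """Percent brood reductions (with 95% intervals) at scenario dosages.

    With a :class:`DoseResponseCurve` the point column is the direct
    evaluation and the interval columns are NaN; with a :class:`Posterior`
    the point is the posterior-median reduction and the interval the
    2.5/97.5 percentiles of the per-draw reductions.  Values are unrounded;
    round to integers at presentation.
    """
    d = _check_dosage(scenario_dosages)
    L = np.log10(d + 1.0)
    if isinstance(source, DoseResponseCurve):
        point = 100.0 * (1.0 - np.exp(source.beta * L))
        lo = np.full_like(point, np.nan)
        hi = np.full_like(point, np.nan)
    else:
        betas = source.stack("beta")
        red = 100.0 * (1.0 - np.exp(betas[:, None] * L[None, :]))
        lo, point, hi = np.percentile(red, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "dosage_ugkg": d,
            "reduction_pct": point,
            "lower_2.5": lo,
            "upper_97.5": hi,
        }
    )
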