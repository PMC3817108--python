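"""Synthetic colony datasets with the statistical structure the analysis assumes.

The generator emulates the pulsed-exposure design: per dosage level and
colony it draws

* on-dose brood from a lognormal-mixed Poisson — ``Poisson(exp(alpha_on +
  beta_on * log10(d+1) + lambda))`` with ``lambda ~ Normal(0, sigma_on²)``;
* off-dose brood around the difference between the 28-day total curve and
  the on-dose curve (floored at a small epsilon), with its own lognormal
  colony effect, so that the median colony's 28-day total follows the
  28-day curve;
* syrup and pollen consumption from a fixed-bottom log-logistic suppression
  curve with multiplicative lognormal noise, reverting off dose (pollen with
  a residual dose-dependent elevation);
* day of first oviposition: dose-independent on dose (possibly absent at
  high dosages), delayed off dose in proportion to log10(d+1).

Identical seeds give byte-identical datasets.  Defaults are the study
conditions (coefficients and overdispersion SDs of the reported fits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .colonies import ColonyRecord, ExposureDesign

__all__ = [
    "GeneratorConfig",
    "on_dose_mean",
    "pulse_total_mean",
    "off_dose_mean",
    "feeding_mean",
    "off_dose_delay_mean",
    "simulate_brood",
    "simulate_feeding",
    "simulate_oviposition",
    "simulate_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-data generator.

    Brood defaults are the reported best-fit coefficients and
    overdispersion SDs; feeding and oviposition parameters are not printed
    anywhere and are fixed at realistic values for a queen-plus-four-workers
    micro-colony (see docs/methods.md).
    """

    # brood dose-response (median-colony curves, log10 covariate)
    alpha_on: float = 2.002
    beta_on: float = -1.788
    sigma_on: float = 1.89
    alpha_28: float = 2.770
    beta_28: float = -0.198
    sigma_off: float = 1.25
    off_floor: float = 0.01          # floor for the off-dose mean (brood)

    # feeding (g/day, fixed-bottom log-logistic suppression)
    syrup_top: float = 2.0
    pollen_top: float = 0.44
    syrup_ec50: float = 120.0        # beyond the tested range, as observed
    pollen_ec50: float = 4.4
    hill_slope: float = 1.0
    feeding_cv: float = 0.2
    pollen_rebound: float = 0.3      # off-dose elevation of pollen at top dose

    # oviposition (days)
    ovi_on_mean: float = 4.2
    ovi_off_base: float = 1.3
    ovi_delay_slope: float = 3.0     # days per log10(dosage+1) off dose
    ovi_sd: float = 1.5
    ovi_absent_max: float = 0.9      # P(no on-dose oviposition) at the top dose
    ovi_absent_power: float = 8.0

    trial_effect: float = 0.0        # optional log-scale trial-2 offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_on < 0 or self.sigma_off < 0:
            raise ValueError("overdispersion SDs must be >= 0")
        for name in ("syrup_top", "pollen_top", "syrup_ec50", "pollen_ec50",
                     "hill_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.feeding_cv < 0 or self.ovi_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.ovi_absent_max <= 1:
            raise ValueError("ovi_absent_max must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Mean functions (median colony; closed forms used by the tests)

def _L(dosage):
    return np.log10(np.asarray(dosage, float) + 1.0)


def on_dose_mean(config: GeneratorConfig, dosage):
    """Median-colony on-dose brood mean exp(alpha_on + beta_on*log10(d+1))."""
    return np.exp(config.alpha_on + config.beta_on * _L(dosage))


def pulse_total_mean(config: GeneratorConfig, dosage):
    """Median-colony 28-day total brood mean from the 28-day curve."""
    return np.exp(config.alpha_28 + config.beta_28 * _L(dosage))


def off_dose_mean(config: GeneratorConfig, dosage):
    """Median-colony off-dose brood mean: 28-day total minus on-dose, floored.

    No off-dose curve is observed directly; defining the off-dose mean by
    subtraction makes the median colony's 28-day total follow the 28-day
    curve.  The floor keeps the Poisson mean positive at dosages where the
    subtraction would go non-positive.
    """
    return np.maximum(
        pulse_total_mean(config, dosage) - on_dose_mean(config, dosage),
        config.off_floor,
    )


def feeding_mean(config: GeneratorConfig, dosage, food: str = "pollen"):
    """On-dose consumption mean: top / (1 + (d/ec50)**hill), g/day."""
    d = np.asarray(dosage, float)
    if food == "pollen":
        top, ec50 = config.pollen_top, config.pollen_ec50
    elif food == "syrup":
        top, ec50 = config.syrup_top, config.syrup_ec50
    else:
        raise ValueError(f"food must be 'pollen' or 'syrup', got {food!r}")
    return top / (1.0 + (d / ec50) ** config.hill_slope)


def off_dose_delay_mean(config: GeneratorConfig, dosage):
    """Expected day of first off-dose oviposition: base + slope*log10(d+1)."""
    return config.ovi_off_base + config.ovi_delay_slope * _L(dosage)


# ---------------------------------------------------------------------------
# Layout and sampling

def _layout(design: ExposureDesign) -> pd.DataFrame:
    """Deterministic colony layout: ids, trials and dosages."""
    rows = []
    for level, dosage in enumerate(design.dosages()):
        tag = "C" if dosage == 0 else f"D{level}"
        for j in range(design.colonies_per_level):
            trial = j % design.n_trials + 1
            rows.append(
                {
                    "colony_id": f"T{trial}-{tag}-{j + 1}",
                    "trial": trial,
                    "dosage": float(dosage),
                }
            )
    return pd.DataFrame(rows)


def _rng(config: GeneratorConfig, seed, stream: int):
    base = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(base).spawn(4)[stream])


def simulate_brood(
    config: GeneratorConfig, design: ExposureDesign, seed: int | None = None
) -> list[ColonyRecord]:
    """Brood counts for both periods of every colony (feeding fields unset)."""
    lay = _layout(design)
    rng = _rng(config, seed, 0)
    n = len(lay)
    d = lay["dosage"].to_numpy()
    toff = np.where(lay["trial"].to_numpy() == 2, config.trial_effect, 0.0)
    lam_on = rng.normal(0.0, config.sigma_on, n)
    lam_off = rng.normal(0.0, config.sigma_off, n)
    mu_on = on_dose_mean(config, d) * np.exp(lam_on + toff)
    mu_off = off_dose_mean(config, d) * np.exp(lam_off + toff)
    y_on = rng.poisson(mu_on)
    y_off = rng.poisson(mu_off)
    records = []
    for i, row in enumerate(lay.itertuples(index=False)):
        for period, y in (("on", y_on[i]), ("off", y_off[i])):
            records.append(
                ColonyRecord(
                    colony_id=row.colony_id,
                    trial=row.trial,
                    dosage=row.dosage,
                    period=period,
                    brood=int(y),
                )
            )
    return records


def simulate_feeding(
    config: GeneratorConfig, design: ExposureDesign, seed: int | None = None
) -> pd.DataFrame:
    """Daily syrup and pollen consumption per colony × period (g/day).

    On dose both foods follow the log-logistic suppression curve with
    multiplicative lognormal noise (CV = feeding_cv).  Off dose syrup
    reverts to its control level; pollen overshoots in proportion to the
    prior dosage, mirroring the observed compensatory elevation.
    """
    lay = _layout(design)
    rng = _rng(config, seed, 1)
    n = len(lay)
    d = lay["dosage"].to_numpy()
    sig = np.sqrt(np.log1p(config.feeding_cv**2))
    # lognormal noise with unit mean
    noise = lambda: np.exp(rng.normal(-sig**2 / 2, sig, n))  # noqa: E731
    lmax = _L(design.max_dosage)
    rebound = 1.0 + config.pollen_rebound * _L(d) / (lmax if lmax > 0 else 1.0)
    rows = {
        ("on", "syrup_gpd"): feeding_mean(config, d, "syrup") * noise(),
        ("on", "pollen_gpd"): feeding_mean(config, d, "pollen") * noise(),
        ("off", "syrup_gpd"): config.syrup_top * noise(),
        ("off", "pollen_gpd"): config.pollen_top * rebound * noise(),
    }
    out = []
    for period in ("on", "off"):
        out.append(
            pd.DataFrame(
                {
                    "colony_id": lay["colony_id"],
                    "period": period,
                    "syrup_gpd": rows[(period, "syrup_gpd")],
                    "pollen_gpd": rows[(period, "pollen_gpd")],
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def simulate_oviposition(
    config: GeneratorConfig, design: ExposureDesign, seed: int | None = None
) -> pd.DataFrame:
    """Day of first oviposition per colony × period (NaN = none in period).

    On dose the mean day is dose-independent but oviposition fails entirely
    with probability rising steeply toward ``ovi_absent_max`` at the top
    dosage; off dose the mean day is delayed by ``ovi_delay_slope`` days per
    log10(d+1).  Days beyond the period length also count as absent.
    """
    lay = _layout(design)
    rng = _rng(config, seed, 2)
    n = len(lay)
    d = lay["dosage"].to_numpy()
    lmax = _L(design.max_dosage)
    frac = _L(d) / (lmax if lmax > 0 else 1.0)
    p_absent = config.ovi_absent_max * frac**config.ovi_absent_power
    absent_on = rng.random(n) < p_absent

    def days(mean):
        raw = np.rint(rng.normal(mean, config.ovi_sd, n))
        out = np.clip(raw, 1, None)
        out[raw > design.period_days] = np.nan
        return out

    day_on = days(np.full(n, config.ovi_on_mean))
    day_on[absent_on] = np.nan
    day_off = days(off_dose_delay_mean(config, d))
    out = []
    for period, day in (("on", day_on), ("off", day_off)):
        out.append(
            pd.DataFrame(
                {
                    "colony_id": lay["colony_id"],
                    "period": period,
                    "oviposition_day": day,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def simulate_dataset(
    config: GeneratorConfig | None = None,
    design: ExposureDesign | None = None,
    seed: int | None = None,
) -> list[ColonyRecord]:
    """Full simulated dataset: brood, feeding and oviposition per record."""
    config = config or GeneratorConfig()
    design = design or ExposureDesign()
    brood = simulate_brood(config, design, seed)
    feed = simulate_feeding(config, design, seed).set_index(["colony_id", "period"])
    ovi = simulate_oviposition(config, design, seed).set_index(["colony_id", "period"])
    records = []
    for r in brood:
        key = (r.colony_id, r.period)
        day = ovi.loc[key, "oviposition_day"]
        records.append(
            ColonyRecord(
                colony_id=r.colony_id,
                trial=r.trial,
                dosage=r.dosage,
                period=r.period,
                brood=r.brood,
                syrup_gpd=float(feed.loc[key, "syrup_gpd"]),
                pollen_gpd=float(feed.loc[key, "pollen_gpd"]),
                oviposition_day=None if np.isnan(day) else int(day),
                worker_deaths=0,
            )
        )
    return records
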