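"""Colony observation records, table IO, and dosing-ladder arithmetic.

The experimental unit is a standardised micro-colony (a queen plus four adult
workers) observed over two consecutive 14-day periods: an ``on`` period feeding
on pesticide-spiked syrup, and an ``off`` period feeding on clean syrup.
Dosages are stored throughout as µg of active ingredient per kg of syrup
(mass ppb).  Concentrations per litre of syrup appear only at ingestion and
are converted through the syrup density; all downstream statistics work in
mass ppb because that is the scale on which effect concentrations are
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PERIODS",
    "CSV_COLUMNS",
    "ColonyRecord",
    "ExposureDesign",
    "to_mass_concentration",
    "dilution_series",
    "read_colony_table",
    "write_colony_table",
    "records_to_frame",
    "period_table",
]

PERIODS = ("on", "off")

#: Stable column order of the on-disk CSV representation.
CSV_COLUMNS = [
    "colony_id",
    "trial",
    "dosage_ugkg",
    "period",
    "brood",
    "syrup_gpd",
    "pollen_gpd",
    "oviposition_day",
    "worker_deaths",
]


@dataclass(frozen=True)
class ColonyRecord:
    """One colony × period observation.

    Parameters
    ----------
    colony_id : str
        Label of the experimental colony.
    trial : int
        Replicate trial the colony belongs to (1-based).
    dosage : float
        Dietary dosage in µg kg⁻¹ syrup (mass ppb); 0 for controls.
    period : {"on", "off"}
        Whether the observation covers the dosed or the clean-diet period.
    brood : int
        Total eggs plus larvae collected at the end of the period.
    syrup_gpd, pollen_gpd : float, optional
        Mean daily consumption in g/day, evaporation-corrected.  ``None``
        when not measured.
    oviposition_day : int, optional
        Day (within the period) of the first wax-covered egg cell; ``None``
        means oviposition did not occur during the period.  This is a
        distinguished absent value, never 0.
    worker_deaths : int
        Workers that died during the period.
    """

    colony_id: str
    trial: int
    dosage: float
    period: str
    brood: int
    syrup_gpd: float | None = None
    pollen_gpd: float | None = None
    oviposition_day: int | None = None
    worker_deaths: int = 0

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(
                f"period must be one of {PERIODS}, got {self.period!r}"
            )
        if not (self.dosage >= 0):
            raise ValueError(f"dosage must be >= 0, got {self.dosage}")
        if self.brood != int(self.brood) or self.brood < 0:
            raise ValueError(
                f"brood must be a non-negative integer, got {self.brood}"
            )
        for name in ("syrup_gpd", "pollen_gpd"):
            v = getattr(self, name)
            if v is not None and not (v >= 0):
                raise ValueError(f"{name} must be >= 0 or absent, got {v}")
        if self.oviposition_day is not None and self.oviposition_day < 1:
            raise ValueError(
                "oviposition_day must be a positive day number or absent, "
                f"got {self.oviposition_day}"
            )
        if self.worker_deaths < 0:
            raise ValueError(
                f"worker_deaths must be >= 0, got {self.worker_deaths}"
            )


@dataclass(frozen=True)
class ExposureDesign:
    """Geometry of the pulsed-exposure dosing design.

    Defaults encode the study design: nine dosages by serial dilution
    (factor 0.4) from a 125 µg L⁻¹ stock in syrup of density 1.27 kg L⁻¹,
    plus an undosed control, six colonies per level split over two trials,
    and 14-day on/off periods.
    """

    stock_conc: float = 125.0        # µg L⁻¹
    dilution_factor: float = 0.4
    n_levels: int = 9
    syrup_density: float = 1.27      # kg L⁻¹
    colonies_per_level: int = 6
    n_trials: int = 2
    period_days: int = 14

    def __post_init__(self) -> None:
        if self.stock_conc <= 0:
            raise ValueError("stock_conc must be > 0")
        if not (0 < self.dilution_factor < 1):
            raise ValueError("dilution_factor must lie in (0, 1)")
        if self.syrup_density <= 0:
            raise ValueError("syrup_density must be > 0")
        for name in ("n_levels", "colonies_per_level", "n_trials", "period_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def dosages(self) -> np.ndarray:
        """Descending dosage ladder in µg kg⁻¹, control (0) last."""
        return dilution_series(self)

    @property
    def max_dosage(self) -> float:
        """Top of the tested range in µg kg⁻¹."""
        return to_mass_concentration(self.stock_conc, self.syrup_density)


def to_mass_concentration(conc_per_volume: float, density: float) -> float:
    """Convert µg L⁻¹ in syrup to µg kg⁻¹ (mass ppb).

    ``conc_per_volume / density``; e.g. a 125 µg L⁻¹ stock in 1.27 kg L⁻¹
    syrup is 98.43 µg kg⁻¹ (at 2 dp).
    """
    if not density > 0:
        raise ValueError(f"density must be > 0, got {density}")
    if np.any(np.asarray(conc_per_volume) < 0):
        raise ValueError("concentration must be >= 0")
    return conc_per_volume / density


def dilution_series(design: ExposureDesign) -> np.ndarray:
    """Dosage ladder of the serial-dilution design, in µg kg⁻¹.

    Level ``k`` equals ``stock_conc * dilution_factor**k / syrup_density``
    for ``k = 0 .. n_levels-1``; the list is strictly decreasing and a 0
    (control) is always appended.  Values are unrounded — rounding to 2 dp
    is a presentation concern only.
    """
    k = np.arange(design.n_levels)
    ladder = to_mass_concentration(
        design.stock_conc * design.dilution_factor**k, design.syrup_density
    )
    return np.append(ladder, 0.0)


# ---------------------------------------------------------------------------
# Table IO

_REQUIRED = set(CSV_COLUMNS)


def _opt_float(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_day(v):
    v = _opt_float(v)
    if v is None:
        return None
    if v != int(v):
        raise ValueError(f"oviposition_day must be an integer day, got {v}")
    return int(v)


def read_colony_table(path: str | Path) -> list[ColonyRecord]:
    """Read a colony observation CSV into validated records.

    Rows violating record invariants raise a ``ValueError`` naming the
    offending line (header = line 1).  Duplicate ``(colony_id, period)``
    pairs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records: list[ColonyRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            brood = float(row.brood)
            if not brood.is_integer():
                raise ValueError(f"brood must be an integer, got {row.brood}")
            rec = ColonyRecord(
                colony_id=str(row.colony_id),
                trial=int(row.trial),
                dosage=float(row.dosage_ugkg),
                period=str(row.period),
                brood=int(brood),
                syrup_gpd=_opt_float(row.syrup_gpd),
                pollen_gpd=_opt_float(row.pollen_gpd),
                oviposition_day=_opt_day(row.oviposition_day),
                worker_deaths=int(row.worker_deaths),
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: line {i}: {err}") from err
        key = (rec.colony_id, rec.period)
        if key in seen:
            raise ValueError(
                f"{path}: line {i}: duplicate (colony_id, period) pair {key}"
            )
        seen.add(key)
        records.append(rec)
    return records


def records_to_frame(records: Iterable[ColonyRecord]) -> pd.DataFrame:
    """Long-format DataFrame (one row per colony × period) in CSV column order."""
    rows = [
        {
            "colony_id": r.colony_id,
            "trial": r.trial,
            "dosage_ugkg": r.dosage,
            "period": r.period,
            "brood": r.brood,
            "syrup_gpd": r.syrup_gpd,
            "pollen_gpd": r.pollen_gpd,
            "oviposition_day": r.oviposition_day,
            "worker_deaths": r.worker_deaths,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df["oviposition_day"] = df["oviposition_day"].astype("Int64")
    return df


def write_colony_table(records: Iterable[ColonyRecord], path: str | Path) -> Path:
    """Write records as CSV (RFC-4180, UTF-8, '.' decimal) in stable column order.

    ``read_colony_table`` inverts this exactly: numeric fields are written at
    full repr precision, and an absent oviposition day is an empty field.
    """
    path = Path(path)
    df = records_to_frame(records)
    df.to_csv(path, index=False)
    return path


def period_table(records: Iterable[ColonyRecord]) -> pd.DataFrame:
    """Wide per-colony table with on/off columns for each endpoint.

    Columns: ``trial, dosage_ugkg, <var>_on, <var>_off`` for brood,
    syrup_gpd, pollen_gpd and oviposition_day, plus ``brood_total``.
    Colonies missing a period keep NaN in that period's columns.
    """
    df = records_to_frame(records)
    wide = df.pivot(index="colony_id", columns="period",
                    values=["brood", "syrup_gpd", "pollen_gpd", "oviposition_day"])
    wide.columns = [f"{v}_{p}" for v, p in wide.columns]
    meta = df.groupby("colony_id")[["trial", "dosage_ugkg"]].first()
    out = meta.join(wide)
    if {"brood_on", "brood_off"} <= set(out.columns):
        out["brood_total"] = out["brood_on"] + out["brood_off"]
    return out
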