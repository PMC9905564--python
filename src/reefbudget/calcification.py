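"""Coral calcification rates from buoyant-weight out-plant time series.

A submerged coral's apparent (buoyant) weight relates to its dry skeletal
mass through the density contrast between aragonite and seawater:

    W_b = W_d * (1 - rho_sw / rho_arag)

so dry weight is recovered hydrostatically without killing the tissue.
Calcification over a growth interval is the change in dry weight
standardized by the mean planar surface area over the interval and by the
elapsed time, in g CaCO3 cm^-2 yr^-1.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

#: Hydrostatic-weighing defaults (g cm^-3); both configurable per call.
SEAWATER_DENSITY = 1.023
ARAGONITE_DENSITY = 2.93

DAYS_PER_YEAR = 365.25

#: Month -> season mapping.  Default labelling: the warm, thermally stable
#: March-September window carries the higher rates ("non_upwelling"); the
#: October-February window of cool, low-saturation upwelled water carries
#: the lower rates.  Configurable because regional usage of the labels
#: varies.
DEFAULT_SEASON_MONTHS = {
    3: "non_upwelling", 4: "non_upwelling", 5: "non_upwelling",
    6: "non_upwelling", 7: "non_upwelling", 8: "non_upwelling",
    9: "non_upwelling",
    10: "upwelling", 11: "upwelling", 12: "upwelling",
    1: "upwelling", 2: "upwelling",
}


@dataclass(frozen=True)
class Observation:
    date: dt.date
    buoyant_weight: float  # g
    planar_area: float  # cm^2


@dataclass
class OutplantRecord:
    """Time series of buoyant weight and planar area for one out-plant."""

    coral_id: str
    site: str
    gulf: str
    observations: list[Observation]

    def __post_init__(self) -> None:
        if len(self.observations) < 2:
            raise ValueError(f"coral {self.coral_id}: need >= 2 observations")
        dates = [o.date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"coral {self.coral_id}: dates must be strictly increasing")
        for o in self.observations:
            if o.buoyant_weight <= 0 or o.planar_area <= 0:
                raise ValueError(
                    f"coral {self.coral_id}: weights and areas must be positive"
                )


@dataclass(frozen=True)
class CalcificationEstimate:
    coral_id: str
    site: str
    gulf: str
    start: dt.date
    end: dt.date
    season: str
    rate: float  # g CaCO3 cm^-2 yr^-1


def buoyant_to_dry_weight(
    buoyant: float,
    seawater_density: float = SEAWATER_DENSITY,
    aragonite_density: float = ARAGONITE_DENSITY,
) -> float:
    """Convert buoyant weight (g) to dry skeletal weight (g)."""
    if buoyant < 0:
        raise ValueError("buoyant weight must be non-negative")
    if not 0 < seawater_density < aragonite_density:
        raise ValueError(
            "require 0 < seawater density < aragonite density, got "
            f"{seawater_density} vs {aragonite_density}"
        )
    return buoyant / (1.0 - seawater_density / aragonite_density)


def dry_to_buoyant_weight(
    dry: float,
    seawater_density: float = SEAWATER_DENSITY,
    aragonite_density: float = ARAGONITE_DENSITY,
) -> float:
    """Inverse of :func:`buoyant_to_dry_weight` (used by the generator)."""
    if not 0 < seawater_density < aragonite_density:
        raise ValueError("require 0 < seawater density < aragonite density")
    return dry * (1.0 - seawater_density / aragonite_density)


def assign_season(
    start: dt.date, end: dt.date, season_months: dict[int, str] | None = None
) -> str:
    """Season of a growth interval, by its midpoint date."""
    months = DEFAULT_SEASON_MONTHS if season_months is None else season_months
    midpoint = start + (end - start) / 2
    return months[midpoint.month]


def interval_calcification_rate(
    rec: OutplantRecord,
    start_idx: int,
    end_idx: int,
    seawater_density: float = SEAWATER_DENSITY,
    aragonite_density: float = ARAGONITE_DENSITY,
    season_months: dict[int, str] | None = None,
) -> CalcificationEstimate:
    """Calcification rate over one observation interval.

    rate = delta dry weight / mean(start area, end area) / delta t(years).
    """
    if not 0 <= start_idx < end_idx < len(rec.observations):
        raise IndexError(f"invalid interval indices ({start_idx}, {end_idx})")
    a = rec.observations[start_idx]
    b = rec.observations[end_idx]
    dt_years = (b.date - a.date).days / DAYS_PER_YEAR
    if dt_years <= 0:
        raise ValueError("interval has zero duration")
    mean_area = 0.5 * (a.planar_area + b.planar_area)
    if mean_area <= 0:
        raise ValueError("mean planar area must be positive")
    dw = buoyant_to_dry_weight(
        b.buoyant_weight, seawater_density, aragonite_density
    ) - buoyant_to_dry_weight(a.buoyant_weight, seawater_density, aragonite_density)
    return CalcificationEstimate(
        coral_id=rec.coral_id,
        site=rec.site,
        gulf=rec.gulf,
        start=a.date,
        end=b.date,
        season=assign_season(a.date, b.date, season_months),
        rate=dw / mean_area / dt_years,
    )


def records_from_frame(df: pd.DataFrame) -> list[OutplantRecord]:
    """Build out-plant records from the long CSV layout
    (coral_id, site, gulf, date, buoyant_weight_g, planar_area_cm2)."""
    records = []
    for (coral_id, site, gulf), grp in df.groupby(["coral_id", "site", "gulf"], sort=True):
        grp = grp.sort_values("date")
        obs = [
            Observation(
                date=pd.Timestamp(r.date).date(),
                buoyant_weight=float(r.buoyant_weight_g),
                planar_area=float(r.planar_area_cm2),
            )
            for r in grp.itertuples(index=False)
        ]
        records.append(OutplantRecord(str(coral_id), str(site), str(gulf), obs))
    return records


def all_interval_estimates(
    records: Iterable[OutplantRecord], **kwargs
) -> list[CalcificationEstimate]:
    """Consecutive-interval estimates for every out-plant."""
    out = []
    for rec in records:
        for i in range(len(rec.observations) - 1):
            out.append(interval_calcification_rate(rec, i, i + 1, **kwargs))
    return out


def aggregate_rates(
    estimates: Sequence[CalcificationEstimate],
    by: Literal["gulf", "gulf_season", "gulf_year"] = "gulf",
) -> pd.DataFrame:
    """Mean +/- SE of per-coral calcification rates per group.

    Per-coral rates are averaged first so a coral observed over several
    intervals contributes once.  ``se`` is the standard error of the group
    mean; for a single-member group it is reported as 0 with ``n`` = 1
    flagging it as undefined.  The ``gulf`` aggregate gives the annual
    gulf means that feed gross carbonate production.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    df = pd.DataFrame(
        {
            "coral_id": [e.coral_id for e in estimates],
            "gulf": [e.gulf for e in estimates],
            "season": [e.season for e in estimates],
            "year": [e.start.year for e in estimates],
            "rate": [e.rate for e in estimates],
        }
    )
    keys = {"gulf": ["gulf"], "gulf_season": ["gulf", "season"], "gulf_year": ["gulf", "year"]}[by]
    per_coral = df.groupby(keys + ["coral_id"], sort=True)["rate"].mean().reset_index()
    grouped = per_coral.groupby(keys, sort=True)["rate"]
    out = grouped.agg(mean="mean", n="count").reset_index()
    sd = grouped.std(ddof=1).reset_index(drop=True)
    out["se"] = np.where(out["n"] > 1, sd / np.sqrt(out["n"]), 0.0)
    return out


def percent_change(old: float, new: float, as_int: bool = True) -> float:
    """Percent change 100 * (old - new) / old, rounded half-up to an
    integer for report tables (the package-wide convention)."""
    if old == 0:
        raise ZeroDivisionError("percent change undefined for old value 0")
    pct = 100.0 * (old - new) / old
    if not as_int:
        return pct
    return float(math.floor(pct + 0.5))
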