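"""Tabular I/O and rate-library configuration.

All survey, grazer, core, and budget tables travel as plain CSV.  The rate
library — every fixed constant that parameterizes the budget equations
(taxon calcification rates, gulf-specific macroborer and sea-urchin rates,
sponge-infestation prevalences, parrotfish bite parameters, microbioerosion,
skeletal/seawater densities, per-site sediment contributions) — is loaded
from a YAML file layered over packaged defaults, so an empty file yields a
complete, valid library.

Covers are handled internally as fractions in [0, 1]; percentages appear
only at I/O edges and in report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

GULFS = ("GoP", "GoC")

#: Closed benthic-category vocabulary for point-intercept surveys.
CORAL_TAXA = ("pocillopora", "porites", "pavona", "gardineroseris")
CATEGORIES = CORAL_TAXA + (
    "cca",
    "fine_turf",
    "thick_turf",
    "macroalgae",
    "rubble",
    "dead_framework",
    "sand",
)

#: Categories pooled into the "dead substrate" term of the macroborer and
#: sea-urchin equations.  Rubble is excluded here because it enters the
#: sponge-dissolution equation through its own term.
DEAD_SUBSTRATE_CATEGORIES = ("dead_framework", "fine_turf")

SURVEY_COLUMNS = ["site", "gulf", "period", "transect_id", "category", "count"]
GRAZER_COLUMNS = ["site", "gulf", "period", "transect_id", "taxon", "density_ind_m2"]
CORE_COLUMNS = ["site", "compaction_fraction", "sediment_mm_yr"]

#: PSMSL monthly metric/RLR files flag missing months with this sentinel.
TIDE_GAUGE_SENTINEL = -99999


class SchemaError(ValueError):
    """A table or configuration file violates its documented schema."""


@dataclass(frozen=True)
class SurveyRow:
    """One (transect, category) cell of a point-intercept survey."""

    site: str
    gulf: str
    period: str
    transect_id: str
    category: str
    count: int

    def __post_init__(self) -> None:
        if self.gulf not in GULFS:
            raise SchemaError(f"unknown gulf {self.gulf!r}; expected one of {GULFS}")
        if self.category not in CATEGORIES:
            raise SchemaError(f"unknown category {self.category!r}")
        if not (isinstance(self.count, (int, np.integer)) and self.count >= 0):
            raise SchemaError(f"count must be a non-negative integer, got {self.count!r}")


@dataclass(frozen=True)
class ParrotfishParams:
    """Per-species parrotfish bioerosion parameters (ReefBudget structure)."""

    bite_rate: float  # bites h^-1
    prop_scars: float  # fraction of bites leaving scars
    scar_volume: float  # cm^3 removed per scar
    feeding_hours: float  # h day^-1


@dataclass(frozen=True)
class SpongeRates:
    """Boring-sponge infestation prevalences and chemical dissolution rate."""

    prev_live: float = 0.46
    prev_rubble: float = 0.46
    prev_framework: float = 0.56
    dissolution: float = 0.85  # kg CaCO3 m^-2 yr^-1


@dataclass(frozen=True)
class PufferParams:
    """Corallivorous pufferfish (Arothron meleagris) bioerosion parameters."""

    d_a: float = 17.0  # g CaCO3 ind^-1 day^-1
    feeding_fraction: float = 0.6  # proportion of fish actively feeding


@dataclass(frozen=True)
class Densities:
    """Reference densities (g cm^-3)."""

    framework: float = 1.84  # mean Pocillopora skeletal density, D_f
    seawater: float = 1.03  # D_w, used in the porosity correction
    aragonite: float = 2.93


@dataclass
class RateLibrary:
    """All fixed rate constants consumed by the budget equations.

    ``taxon_calcification`` maps benthic calcifier -> gulf -> g CaCO3
    cm^-2 yr^-1.  ``macroborer`` maps gulf -> {ml, mt, md} in kg CaCO3
    m^-2 yr^-1 (borers on live coral, thick turf, dead substrate).
    ``urchin`` maps gulf -> {ul, ud, ut} in g CaCO3 ind^-1 day^-1.
    ``sediment_contribution`` maps site -> mm yr^-1, with a ``default``
    entry applied to unlisted sites.
    """

    taxon_calcification: dict = field(default_factory=dict)
    macroborer: dict = field(default_factory=dict)
    urchin: dict = field(default_factory=dict)
    sponge: SpongeRates = field(default_factory=SpongeRates)
    puffer: PufferParams = field(default_factory=PufferParams)
    parrotfish: dict = field(default_factory=dict)
    microbioerosion: float = 0.233  # kg CaCO3 m^-2 yr^-1, flat per transect
    densities: Densities = field(default_factory=Densities)
    sediment_contribution: dict = field(default_factory=lambda: {"default": 0.0})

    def calcification_rate(self, taxon: str, gulf: str) -> float:
        try:
            per_gulf = self.taxon_calcification[taxon]
        except KeyError:
            raise SchemaError(f"no calcification rate configured for taxon {taxon!r}")
        return per_gulf[gulf]

    def sediment_for(self, site: str) -> float:
        return self.sediment_contribution.get(site, self.sediment_contribution.get("default", 0.0))

    def validate(self) -> "RateLibrary":
        for taxon, per_gulf in self.taxon_calcification.items():
            for gulf in GULFS:
                if gulf not in per_gulf:
                    raise SchemaError(f"taxon_calcification[{taxon!r}] missing gulf {gulf!r}")
                if per_gulf[gulf] < 0:
                    raise SchemaError(f"negative calcification rate for {taxon!r}/{gulf}")
        for name, table in (("macroborer", self.macroborer), ("urchin", self.urchin)):
            for gulf in GULFS:
                if gulf not in table:
                    raise SchemaError(f"{name} rates missing gulf {gulf!r}")
                for key, value in table[gulf].items():
                    if value < 0:
                        raise SchemaError(f"negative {name} rate {key!r} for gulf {gulf}")
        sp = self.sponge
        for key in ("prev_live", "prev_rubble", "prev_framework"):
            prevalence = getattr(sp, key)
            if not 0.0 <= prevalence <= 1.0:
                raise SchemaError(f"sponge {key} must be a fraction in [0, 1]")
        if sp.dissolution < 0:
            raise SchemaError("sponge dissolution rate must be non-negative")
        if self.puffer.d_a < 0 or not 0.0 <= self.puffer.feeding_fraction <= 1.0:
            raise SchemaError("invalid puffer parameters")
        for species, params in self.parrotfish.items():
            if min(params.bite_rate, params.prop_scars, params.scar_volume, params.feeding_hours) < 0:
                raise SchemaError(f"negative parrotfish parameter for {species!r}")
            if params.prop_scars > 1:
                raise SchemaError(f"parrotfish prop_scars > 1 for {species!r}")
        if self.microbioerosion < 0:
            raise SchemaError("microbioerosion rate must be non-negative")
        if min(self.densities.framework, self.densities.seawater, self.densities.aragonite) <= 0:
            raise SchemaError("densities must be positive")
        for site, s in self.sediment_contribution.items():
            if s < 0:
                raise SchemaError(f"negative sediment contribution for site {site!r}")
        return self


def default_rate_library() -> RateLibrary:
    """Packaged default rate library.

    Gulf-mean Pocillopora calcification (2.23 GoP / 2.08 GoC g cm^-2 yr^-1)
    comes from in-situ buoyant-weight out-plants; minor massive taxa and CCA
    carry literature-style eastern-Pacific rates.  Macroborer and urchin
    rates are gulf-specific (Saboga-type framework for the GoP, Uva-type for
    the GoC): upwelling-driven nutrient supply sustains denser macroboring
    infauna in the GoP.
    """
    return RateLibrary(
        taxon_calcification={
            "pocillopora": {"GoP": 2.23, "GoC": 2.08},
            "porites": {"GoP": 1.33, "GoC": 1.33},
            "pavona": {"GoP": 1.13, "GoC": 1.13},
            "gardineroseris": {"GoP": 1.00, "GoC": 1.00},
            "cca": {"GoP": 0.30, "GoC": 0.30},
        },
        macroborer={
            "GoP": {"ml": 6.0, "mt": 30.0, "md": 35.0},
            "GoC": {"ml": 2.0, "mt": 30.0, "md": 15.0},
        },
        urchin={
            "GoP": {"ul": 0.10, "ud": 1.10, "ut": 0.55},
            "GoC": {"ul": 0.10, "ud": 1.00, "ut": 0.50},
        },
        parrotfish={
            "scarus_ghobban": ParrotfishParams(
                bite_rate=528.0, prop_scars=0.04, scar_volume=0.09, feeding_hours=8.0
            ),
            "scarus_rubroviolaceus": ParrotfishParams(
                bite_rate=276.0, prop_scars=0.11, scar_volume=0.33, feeding_hours=8.0
            ),
        },
    ).validate()


def _deep_update(base: dict, override: Mapping) -> dict:
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_rate_library(path: str | Path | None = None) -> RateLibrary:
    """Load a rate library from YAML, layering overrides on the defaults.

    A missing or empty file yields the packaged defaults.  Scalar
    calcification rates in the file are broadcast to both gulfs.
    """
    defaults = default_rate_library()
    if path is None:
        return defaults
    text = Path(path).read_text()
    override = yaml.safe_load(text) or {}
    if not isinstance(override, Mapping):
        raise SchemaError(f"rate-library file {path} must contain a mapping")

    data = {
        "taxon_calcification": {t: dict(g) for t, g in defaults.taxon_calcification.items()},
        "macroborer": {g: dict(v) for g, v in defaults.macroborer.items()},
        "urchin": {g: dict(v) for g, v in defaults.urchin.items()},
        "sponge": asdict(defaults.sponge),
        "puffer": asdict(defaults.puffer),
        "parrotfish": {s: asdict(p) for s, p in defaults.parrotfish.items()},
        "microbioerosion": defaults.microbioerosion,
        "densities": asdict(defaults.densities),
        "sediment_contribution": dict(defaults.sediment_contribution),
    }
    # broadcast scalar taxon rates before the deep merge
    taxon_over = override.get("taxon_calcification", {})
    if taxon_over:
        override = dict(override)
        override["taxon_calcification"] = {
            taxon: (rate if isinstance(rate, Mapping) else {g: rate for g in GULFS})
            for taxon, rate in taxon_over.items()
        }
    _deep_update(data, override)

    return RateLibrary(
        taxon_calcification=data["taxon_calcification"],
        macroborer=data["macroborer"],
        urchin=data["urchin"],
        sponge=SpongeRates(**data["sponge"]),
        puffer=PufferParams(**data["puffer"]),
        parrotfish={s: ParrotfishParams(**p) if not isinstance(p, ParrotfishParams) else p
                    for s, p in data["parrotfish"].items()},
        microbioerosion=float(data["microbioerosion"]),
        densities=Densities(**data["densities"]),
        sediment_contribution=data["sediment_contribution"],
    ).validate()


def read_benthic_survey(
    path: str | Path, points_per_transect: int = 100
) -> list[SurveyRow]:
    """Read and validate a point-intercept survey CSV.

    Raises :class:`SchemaError` naming the offending row for unknown
    category tokens, and the offending transect when its counts do not sum
    to ``points_per_transect``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"survey file {path} missing columns {sorted(missing)}")

    rows: list[SurveyRow] = []
    for idx, rec in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            rows.append(
                SurveyRow(
                    site=str(rec.site),
                    gulf=str(rec.gulf),
                    period=str(rec.period),
                    transect_id=str(rec.transect_id),
                    category=str(rec.category),
                    count=int(rec.count),
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}, row {idx}: {exc}") from exc

    totals = (
        pd.DataFrame(rows)
        .groupby(["site", "period", "transect_id"], sort=False)["count"]
        .sum()
    )
    bad = totals[totals != points_per_transect]
    if len(bad):
        key = bad.index[0]
        raise SchemaError(
            f"{path}: transect {key} has {bad.iloc[0]} points, "
            f"expected {points_per_transect}"
        )
    return rows


def survey_to_frame(rows: Iterable[SurveyRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows], columns=SURVEY_COLUMNS)


def read_grazer_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GRAZER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"grazer file {path} missing columns {sorted(missing)}")
    if (df["density_ind_m2"] < 0).any():
        row = int(df.index[df["density_ind_m2"] < 0][0]) + 2
        raise SchemaError(f"{path}, row {row}: negative density")
    return df


def read_core_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CORE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"core file {path} missing columns {sorted(missing)}")
    c = df["compaction_fraction"]
    if ((c < 0) | (c > 1)).any():
        raise SchemaError(f"{path}: compaction_fraction outside [0, 1]")
    return df


def read_tide_gauge(path: str | Path) -> pd.Series:
    """Read a PSMSL-style monthly mean-sea-level text file.

    Format: semicolon-separated ``decimal_year; level_mm; ...`` with the
    sentinel -99999 flagging a missing month.  Returns a Series indexed by
    decimal year; missing months are NaN, never zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    times: list[float] = []
    levels: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(";")]
        try:
            t = float(parts[0])
            level = float(parts[1])
        except (IndexError, ValueError) as exc:
            raise SchemaError(f"{path}, line {lineno}: unparsable record {line!r}") from exc
        if times and t <= times[-1]:
            raise SchemaError(
                f"{path}, line {lineno}: time {t} not after previous {times[-1]}"
            )
        times.append(t)
        levels.append(math.nan if level == TIDE_GAUGE_SENTINEL else level)
    series = pd.Series(levels, index=pd.Index(times, name="decimal_year"), name="level_mm")
    return series


def write_tide_gauge(series: pd.Series, path: str | Path) -> None:
    lines = []
    for t, level in series.items():
        value = TIDE_GAUGE_SENTINEL if pd.isna(level) else f"{level:.1f}"
        lines.append(f"{t:.4f}; {value}; 0; 000")
    Path(path).write_text("\n".join(lines) + "\n")


BUDGET_COLUMNS = [
    "site",
    "gulf",
    "period",
    "transect_id",
    "coral_cover_pct",
    "gross",
    "macroborer",
    "microborer",
    "sponge",
    "urchin",
    "parrotfish",
    "puffer",
    "total_bioerosion",
    "net",
    "framework_density",
    "rap",
    "millennial_rap",
]


def write_budget_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-transect budget/accretion table with fixed float
    formatting so repeated runs are byte-stable."""
    df = results.loc[:, [c for c in BUDGET_COLUMNS if c in results.columns]]
    df.to_csv(path, index=False, float_format="%.6f")


def read_budget_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"site", "gulf", "period", "transect_id", "gross", "net"} - set(df.columns)
    if missing:
        raise SchemaError(f"budget file {path} missing columns {sorted(missing)}")
    return df
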