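"""Synthetic survey, out-plant, grazer, core, and tide-gauge generators.

Every downstream stage of the budget pipeline is testable against known
ground truth because the generator draws from the same statistical
structure the analysis assumes:

* benthic points  — multinomial draws of 100 points per transect around
  gulf- and period-specific mean cover vectors (coral declining 81->75%
  in the strongly upwelling gulf, 51->39% in the weakly upwelling gulf);
* out-plants      — dry-weight increments = true seasonal calcification
  rate x mean planar area x elapsed time + Gaussian noise, emitted as
  buoyant weights so the calcification module must invert the hydrostatic
  relation;
* grazers         — Poisson belt-transect counts around per-period urchin
  density trajectories and fixed fish densities (fish surveyed in the
  final spring only, as in the field campaign);
* cores           — per-site compaction fractions, porosity = 1 - compaction
  by construction;
* tide gauge      — monthly levels = intercept + trend x years + seasonal
  harmonic + noise, with a few months missing at random.

One integer seed drives every channel through independent spawned
substreams, so fixtures are fully reproducible and channels are
statistically independent.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calcification import dry_to_buoyant_weight
from .io_config import (
    CATEGORIES,
    GRAZER_COLUMNS,
    GULFS,
    SURVEY_COLUMNS,
    write_tide_gauge,
)
from .production_bioerosion import PUFFER_TAXON, URCHIN_TAXON

DEFAULT_PERIODS = (
    "spring-2016",
    "autumn-2016",
    "spring-2017",
    "autumn-2017",
    "spring-2018",
)

#: Nominal survey dates for the five periods (spring = April, autumn = October).
PERIOD_DATES = {
    "spring-2016": dt.date(2016, 4, 1),
    "autumn-2016": dt.date(2016, 10, 1),
    "spring-2017": dt.date(2017, 4, 1),
    "autumn-2017": dt.date(2017, 10, 1),
    "spring-2018": dt.date(2018, 4, 1),
}

SITE_NAMES = {
    "GoP": ("saboga", "contadora", "pedro_gonzalez"),
    "GoC": ("uva", "coiba", "canales"),
}


def _interp(start: float, end: float, n: int) -> list[float]:
    return list(np.linspace(start, end, n))


def default_cover_means(periods: tuple[str, ...] = DEFAULT_PERIODS) -> dict:
    """Per-gulf, per-period mean category proportions.

    Coral cover declines linearly between the observed survey endpoints
    (81->75% GoP, 51->39% GoC); thick algal turfs decline in the GoP as
    urchin grazing intensifies, while dead framework accumulates in the
    GoC as corals die.  Pocillopora is all but ~1% of live coral.
    """
    n = len(periods)
    means: dict[str, dict[str, dict[str, float]]] = {g: {} for g in GULFS}

    gop_coral = _interp(0.81, 0.75, n)
    gop_thick = _interp(0.06, 0.02, n)
    for p, coral, thick in zip(periods, gop_coral, gop_thick):
        vec = {
            "pocillopora": coral - 0.010,
            "porites": 0.004,
            "pavona": 0.003,
            "gardineroseris": 0.003,
            "cca": 0.02,
            "fine_turf": 0.03,
            "thick_turf": thick,
            "macroalgae": 0.01,
            "rubble": 0.02,
            "dead_framework": 0.04,
        }
        vec["sand"] = 1.0 - sum(vec.values())
        means["GoP"][p] = vec

    goc_coral = _interp(0.51, 0.39, n)
    goc_dead = _interp(0.10, 0.20, n)
    for p, coral, deadfw in zip(periods, goc_coral, goc_dead):
        vec = {
            "pocillopora": coral - 0.010,
            "porites": 0.004,
            "pavona": 0.003,
            "gardineroseris": 0.003,
            "cca": 0.03,
            "fine_turf": 0.06,
            "thick_turf": 0.08,
            "macroalgae": 0.04,
            "rubble": 0.05,
            "dead_framework": deadfw,
        }
        vec["sand"] = 1.0 - sum(vec.values())
        means["GoC"][p] = vec
    return means


def default_urchin_trajectories(periods: tuple[str, ...] = DEFAULT_PERIODS) -> dict:
    """Diadema mexicanum densities (ind m^-2) rising 0.5->1.7 in the GoP
    and 0.4->4.9 in the GoC over the study, interpolated per period."""
    n = len(periods)
    return {
        "GoP": dict(zip(periods, _interp(0.5, 1.7, n))),
        "GoC": dict(zip(periods, _interp(0.4, 4.9, n))),
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; defaults emulate the field
    campaign's design and observed magnitudes."""

    seed: int = 0
    n_sites_per_gulf: int = 3
    n_transects: int = 6
    points_per_transect: int = 100
    periods: tuple[str, ...] = DEFAULT_PERIODS
    gulf_cover_means: dict = field(default_factory=default_cover_means)
    # true seasonal Pocillopora calcification, g CaCO3 cm^-2 yr^-1
    true_calcification: dict = field(
        default_factory=lambda: {
            "GoP": {"non_upwelling": 3.1, "upwelling": 2.0},
            "GoC": {"non_upwelling": 2.9, "upwelling": 2.3},
        }
    )
    n_corals_per_site: int = 20
    initial_dry_weight_g: float = 30.0
    initial_area_cm2: float = 25.0
    area_growth_cm2_per_interval: float = 3.0
    outplant_noise_sd_g: float = 3.0  # Gaussian noise per dry-weight increment
    urchin_density_traj: dict = field(default_factory=default_urchin_trajectories)
    fish_density: dict = field(
        default_factory=lambda: {
            "scarus_ghobban": 0.008,
            "scarus_rubroviolaceus": 0.004,
            PUFFER_TAXON: 0.004,
        }
    )
    urchin_belt_area_m2: float = 25.0  # 25 x 1 m video belt
    fish_belt_area_m2: float = 100.0  # 25 x 4 m visual belt
    fish_survey_period: str = "spring-2018"
    compaction_mean: float = 0.62
    compaction_sd: float = 0.05
    sediment_mm_yr: float = 0.4
    slr_trend: float = 1.4  # mm yr^-1
    tide_start_year: int = 1965
    tide_n_years: int = 50
    tide_intercept_mm: float = 7000.0
    tide_seasonal_amp_mm: float = 60.0
    tide_noise_sd_mm: float = 30.0
    tide_missing_fraction: float = 0.02

    def validate(self) -> "SynthConfig":
        if self.n_sites_per_gulf < 1 or self.n_transects < 1:
            raise ValueError("need at least one site and one transect per gulf")
        if self.points_per_transect < 1:
            raise ValueError("points_per_transect must be positive")
        for gulf in GULFS:
            for period in self.periods:
                vec = self.gulf_cover_means[gulf][period]
                unknown = set(vec) - set(CATEGORIES)
                if unknown:
                    raise ValueError(f"unknown categories in cover means: {unknown}")
                if any(v < 0 for v in vec.values()):
                    raise ValueError(f"negative cover mean for {gulf}/{period}")
                if abs(sum(vec.values()) - 1.0) > 1e-9:
                    raise ValueError(
                        f"cover means for {gulf}/{period} must sum to 1"
                    )
        for traj in self.urchin_density_traj.values():
            if any(v < 0 for v in traj.values()):
                raise ValueError("urchin densities must be non-negative")
        if any(v < 0 for v in self.fish_density.values()):
            raise ValueError("fish densities must be non-negative")
        if not 0 < self.compaction_mean < 1 or self.compaction_sd < 0:
            raise ValueError("compaction mean must be in (0,1), sd non-negative")
        if min(self.outplant_noise_sd_g, self.tide_noise_sd_mm, self.sediment_mm_yr) < 0:
            raise ValueError("noise scales and sediment must be non-negative")
        if self.tide_n_years < 1:
            raise ValueError("tide series needs at least one year")
        return self

    def sites(self, gulf: str) -> list[str]:
        names = SITE_NAMES[gulf]
        if self.n_sites_per_gulf <= len(names):
            return list(names[: self.n_sites_per_gulf])
        extra = [f"{gulf.lower()}_site{i}" for i in range(len(names), self.n_sites_per_gulf)]
        return list(names) + extra


_CHANNELS = ("benthic", "outplant", "grazer", "core", "tide")


def _rng(cfg: SynthConfig, channel: str) -> np.random.Generator:
    """Independent substream per channel from the one global seed."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(_CHANNELS))
    return np.random.default_rng(children[_CHANNELS.index(channel)])


def gen_benthic_transects(cfg: SynthConfig) -> pd.DataFrame:
    """Point-intercept survey table: multinomial point counts per transect."""
    cfg.validate()
    rng = _rng(cfg, "benthic")
    records = []
    for gulf in GULFS:
        for site in cfg.sites(gulf):
            for period in cfg.periods:
                probs = cfg.gulf_cover_means[gulf][period]
                cats = [c for c in CATEGORIES if probs.get(c, 0.0) > 0]
                p = np.array([probs[c] for c in cats])
                p = p / p.sum()
                for t in range(1, cfg.n_transects + 1):
                    counts = rng.multinomial(cfg.points_per_transect, p)
                    for cat, n in zip(cats, counts):
                        if n > 0:
                            records.append(
                                (site, gulf, period, f"{site}-T{t}", cat, int(n))
                            )
    return pd.DataFrame(records, columns=SURVEY_COLUMNS)


def gen_outplant_series(cfg: SynthConfig) -> pd.DataFrame:
    """Out-plant buoyant-weight/area time series (long CSV layout).

    Dry weight accrues each 6-month interval at the gulf's true seasonal
    rate times the interval-mean planar area, plus Gaussian noise; the
    emitted weights are buoyant, via the hydrostatic relation.
    """
    cfg.validate()
    rng = _rng(cfg, "outplant")
    dates = [PERIOD_DATES[p] for p in cfg.periods]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("period dates must be strictly increasing")
    records = []
    for gulf in GULFS:
        rates = cfg.true_calcification[gulf]
        for site in cfg.sites(gulf):
            for k in range(1, cfg.n_corals_per_site + 1):
                coral_id = f"{site}-C{k:02d}"
                dry = cfg.initial_dry_weight_g * float(rng.uniform(0.8, 1.2))
                area = cfg.initial_area_cm2 * float(rng.uniform(0.8, 1.2))
                records.append(
                    (coral_id, site, gulf, dates[0], dry_to_buoyant_weight(dry), area)
                )
                for a, b in zip(dates, dates[1:]):
                    # spring->autumn spans the warm season, autumn->spring the
                    # upwelling season (midpoint rule in the estimator agrees)
                    season = "non_upwelling" if a.month < 9 else "upwelling"
                    dt_years = (b - a).days / 365.25
                    next_area = area + cfg.area_growth_cm2_per_interval
                    mean_area = 0.5 * (area + next_area)
                    increment = rates[season] * mean_area * dt_years
                    if cfg.outplant_noise_sd_g > 0:
                        increment += float(rng.normal(0.0, cfg.outplant_noise_sd_g))
                    dry = max(dry + increment, 1e-6)
                    area = next_area
                    records.append(
                        (coral_id, site, gulf, b, dry_to_buoyant_weight(dry), area)
                    )
    return pd.DataFrame(
        records,
        columns=["coral_id", "site", "gulf", "date", "buoyant_weight_g", "planar_area_cm2"],
    )


def gen_grazer_densities(cfg: SynthConfig) -> pd.DataFrame:
    """Urchin and fish belt-transect densities (ind m^-2).

    Counts are Poisson at mean density x belt area, scaled back to ind
    m^-2.  Urchins are surveyed every period along their configured
    trajectory; fish only in ``fish_survey_period``.
    """
    cfg.validate()
    rng = _rng(cfg, "grazer")
    records = []
    for gulf in GULFS:
        for site in cfg.sites(gulf):
            for period in cfg.periods:
                mean_u = cfg.urchin_density_traj[gulf][period]
                for t in range(1, cfg.n_transects + 1):
                    count = rng.poisson(mean_u * cfg.urchin_belt_area_m2)
                    records.append(
                        (site, gulf, period, f"{site}-T{t}", URCHIN_TAXON,
                         count / cfg.urchin_belt_area_m2)
                    )
            for taxon, mean_f in cfg.fish_density.items():
                for t in range(1, cfg.n_transects + 1):
                    count = rng.poisson(mean_f * cfg.fish_belt_area_m2)
                    records.append(
                        (site, gulf, cfg.fish_survey_period, f"{site}-T{t}", taxon,
                         count / cfg.fish_belt_area_m2)
                    )
    return pd.DataFrame(records, columns=GRAZER_COLUMNS)


def gen_cores(cfg: SynthConfig) -> pd.DataFrame:
    """Per-site core summaries: compaction fraction and sediment input.
    Porosity is 1 - compaction by construction and is not stored."""
    cfg.validate()
    rng = _rng(cfg, "core")
    records = []
    for gulf in GULFS:
        for site in cfg.sites(gulf):
            c = float(rng.normal(cfg.compaction_mean, cfg.compaction_sd))
            c = min(max(c, 0.01), 0.99) if cfg.compaction_sd > 0 else cfg.compaction_mean
            records.append((site, c, cfg.sediment_mm_yr))
    return pd.DataFrame(records, columns=["site", "compaction_fraction", "sediment_mm_yr"])


def gen_tide_gauge(cfg: SynthConfig) -> pd.Series:
    """Monthly mean-sea-level series with a linear trend, an annual
    harmonic, Gaussian noise, and a few missing months (NaN)."""
    cfg.validate()
    rng = _rng(cfg, "tide")
    n = cfg.tide_n_years * 12
    t = cfg.tide_start_year + (np.arange(n) + 0.5) / 12.0
    years = t - t[0]
    level = (
        cfg.tide_intercept_mm
        + cfg.slr_trend * years
        + cfg.tide_seasonal_amp_mm * np.sin(2.0 * np.pi * t)
    )
    if cfg.tide_noise_sd_mm > 0:
        level = level + rng.normal(0.0, cfg.tide_noise_sd_mm, size=n)
    if cfg.tide_missing_fraction > 0:
        missing = rng.random(n) < cfg.tide_missing_fraction
        level = np.where(missing, np.nan, level)
    return pd.Series(level, index=pd.Index(t, name="decimal_year"), name="level_mm")


def generate_all(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture set in the pipeline's interchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": outdir / "survey.csv",
        "outplants": outdir / "outplants.csv",
        "grazers": outdir / "grazers.csv",
        "cores": outdir / "cores.csv",
        "tide": outdir / "tide.txt",
    }
    gen_benthic_transects(cfg).to_csv(paths["survey"], index=False)
    gen_outplant_series(cfg).to_csv(paths["outplants"], index=False, float_format="%.6f")
    gen_grazer_densities(cfg).to_csv(paths["grazers"], index=False, float_format="%.6f")
    gen_cores(cfg).to_csv(paths["cores"], index=False, float_format="%.6f")
    write_tide_gauge(gen_tide_gauge(cfg), paths["tide"])
    return paths
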