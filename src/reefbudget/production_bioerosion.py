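"""Gross carbonate production and the five bioerosion components.

All rates are per planar square meter of reef (no rugosity correction) in
kg CaCO3 m^-2 yr^-1.  Bioerosion components are returned as positive
magnitudes throughout; the minus sign the field prints on erosion rates is
applied only at report-formatting time, which keeps the arithmetic free of
double-negation mistakes.

Components:

* macroborers   MB = L*ml_g + T*mt_g + D*md_g        (internal infauna)
* microborers        flat regional constant, optionally scaled by dead cover
* sponges       SB = (L*0.46 + RC*0.46 + FC*0.56) * 0.85   (chemical dissolution)
* sea urchins   UB = (L*ul_g + D*ud_g + T*ut_g) * U * 365/1000
* parrotfish    PB = sum_species density * per-capita ReefBudget rate
* pufferfish    AB = d_a * 365/1000 * A * feeding_fraction

where L, T, D, RC, FC are proportional covers of live coral, thick turf,
dead substrate, rubble, and in-place dead framework; U and A are grazer
densities in ind m^-2; the g->kg day->yr conversion is 365/1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_config import (
    CATEGORIES,
    CORAL_TAXA,
    DEAD_SUBSTRATE_CATEGORIES,
    RateLibrary,
    SchemaError,
    SurveyRow,
)

#: g CaCO3 ind^-1 day^-1  ->  kg CaCO3 ind^-1 yr^-1
GRAMS_PER_DAY_TO_KG_PER_YEAR = 365.0 / 1000.0

#: g CaCO3 cm^-2 yr^-1  ->  kg CaCO3 m^-2 yr^-1
G_CM2_TO_KG_M2 = 10.0

URCHIN_TAXON = "diadema_mexicanum"
PUFFER_TAXON = "arothron_meleagris"

COMPONENT_NAMES = ("macroborer", "microborer", "sponge", "urchin", "parrotfish", "puffer")


@dataclass(frozen=True)
class CoverProfile:
    """Proportional benthic cover for one transect.

    ``live_by_taxon`` holds the per-taxon live-coral fractions; ``live``
    is their total (L).  ``dead`` (D) pools the configured dead-substrate
    categories (in-place dead framework plus fine turf by default); rubble
    is kept separate because the sponge equation has its own rubble term.
    """

    transect_id: str
    site: str
    gulf: str
    period: str
    live_by_taxon: Mapping[str, float]
    thick_turf: float
    dead: float
    rubble: float
    framework: float
    cca: float
    fine_turf: float
    macroalgae: float
    sand: float

    @property
    def live(self) -> float:
        return sum(self.live_by_taxon.values())

    @classmethod
    def from_counts(
        cls,
        rows: Sequence[SurveyRow],
        dead_categories: Sequence[str] = DEAD_SUBSTRATE_CATEGORIES,
    ) -> "CoverProfile":
        """Build a cover profile from the point counts of one transect."""
        if not rows:
            raise ValueError("no survey rows supplied")
        keys = {(r.site, r.gulf, r.period, r.transect_id) for r in rows}
        if len(keys) > 1:
            raise ValueError(f"rows span multiple transects: {sorted(keys)}")
        site, gulf, period, transect_id = rows[0].site, rows[0].gulf, rows[0].period, rows[0].transect_id
        counts = {c: 0 for c in CATEGORIES}
        for r in rows:
            counts[r.category] += r.count
        total = sum(counts.values())
        if total <= 0:
            raise ValueError("transect has zero points")
        frac = {c: n / total for c, n in counts.items()}
        return cls(
            transect_id=transect_id,
            site=site,
            gulf=gulf,
            period=period,
            live_by_taxon={t: frac[t] for t in CORAL_TAXA if frac[t] > 0},
            thick_turf=frac["thick_turf"],
            dead=sum(frac[c] for c in dead_categories),
            rubble=frac["rubble"],
            framework=frac["dead_framework"],
            cca=frac["cca"],
            fine_turf=frac["fine_turf"],
            macroalgae=frac["macroalgae"],
            sand=frac["sand"],
        )


@dataclass(frozen=True)
class GrazerDensity:
    """Grazer densities (ind m^-2) for one transect."""

    transect_id: str
    urchin: float = 0.0
    fish: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.urchin < 0 or any(v < 0 for v in self.fish.values()):
            raise ValueError(f"transect {self.transect_id}: negative grazer density")

    @property
    def puffer(self) -> float:
        return self.fish.get(PUFFER_TAXON, 0.0)

    def parrotfish_density(self, species: str) -> float:
        return self.fish.get(species, 0.0)


def gross_production(cover: CoverProfile, rates: RateLibrary) -> float:
    """Gross carbonate production: sum over calcifiers (live coral taxa and
    CCA) of cover fraction x taxon rate, converted from g cm^-2 yr^-1 to
    kg m^-2 yr^-1."""
    total = 0.0
    for taxon, fraction in cover.live_by_taxon.items():
        total += fraction * rates.calcification_rate(taxon, cover.gulf) * G_CM2_TO_KG_M2
    if cover.cca > 0:
        total += cover.cca * rates.calcification_rate("cca", cover.gulf) * G_CM2_TO_KG_M2
    return total


def macroborer_rate(cover: CoverProfile, rates: RateLibrary, gulf: str | None = None) -> float:
    """Macroborer bioerosion MB = L*ml + T*mt + D*md (kg m^-2 yr^-1)."""
    g = gulf or cover.gulf
    try:
        r = rates.macroborer[g]
    except KeyError:
        raise SchemaError(f"no macroborer rates for gulf {g!r}")
    return cover.live * r["ml"] + cover.thick_turf * r["mt"] + cover.dead * r["md"]


def microborer_rate(
    cover: CoverProfile, rates: RateLibrary, scale_by_dead: bool = False
) -> float:
    """Microbioerosion: the flat regional constant by default; optionally
    scaled by dead-substrate fraction for sensitivity analysis."""
    if scale_by_dead:
        return rates.microbioerosion * cover.dead
    return rates.microbioerosion


def sponge_rate(cover: CoverProfile, rates: RateLibrary) -> float:
    """Sponge chemical dissolution
    SB = (L*prev_live + RC*prev_rubble + FC*prev_framework) * dissolution."""
    sp = rates.sponge
    return (
        cover.live * sp.prev_live
        + cover.rubble * sp.prev_rubble
        + cover.framework * sp.prev_framework
    ) * sp.dissolution


def urchin_rate(
    cover: CoverProfile,
    density: GrazerDensity,
    rates: RateLibrary,
    gulf: str | None = None,
) -> float:
    """Sea-urchin bioerosion UB = (L*U*ul + D*U*ud + T*U*ut) * 365/1000."""
    g = gulf or cover.gulf
    try:
        r = rates.urchin[g]
    except KeyError:
        raise SchemaError(f"no urchin rates for gulf {g!r}")
    u = density.urchin
    if u < 0:
        raise ValueError("negative urchin density")
    per_day = u * (cover.live * r["ul"] + cover.dead * r["ud"] + cover.thick_turf * r["ut"])
    return per_day * GRAMS_PER_DAY_TO_KG_PER_YEAR


def parrotfish_percapita(rates: RateLibrary, species: str, substrate_density: float | None = None) -> float:
    """Per-capita parrotfish erosion (kg CaCO3 ind^-1 yr^-1), ReefBudget
    structure: bites/h x feeding h/day x 365 x scar fraction x scar volume
    x substrate density, cm^3 -> kg via /1000."""
    try:
        p = rates.parrotfish[species]
    except KeyError:
        raise SchemaError(f"no parrotfish parameters for species {species!r}")
    rho = rates.densities.framework if substrate_density is None else substrate_density
    return (
        p.bite_rate * p.feeding_hours * 365.0 * p.prop_scars * p.scar_volume * rho / 1000.0
    )


def parrotfish_rate(
    density: GrazerDensity, percapita: Mapping[str, float]
) -> float:
    """Areal parrotfish bioerosion: sum over species of density x
    per-capita rate."""
    return sum(
        density.parrotfish_density(species) * rate for species, rate in percapita.items()
    )


def puffer_rate(density: GrazerDensity, rates: RateLibrary) -> float:
    """Pufferfish bioerosion AB = d_a * 365/1000 * A * feeding_fraction."""
    return (
        rates.puffer.d_a
        * GRAMS_PER_DAY_TO_KG_PER_YEAR
        * density.puffer
        * rates.puffer.feeding_fraction
    )


def total_bioerosion(components: Mapping[str, float]) -> float:
    """Total bioerosion: the sum of the component magnitudes."""
    bad = {k: v for k, v in components.items() if v < 0}
    if bad:
        raise ValueError(f"bioerosion components must be non-negative magnitudes: {bad}")
    return sum(components.values())


def component_shares(components: Mapping[str, float]) -> dict[str, float]:
    """Each component as a fraction of total bioerosion (zeros if TB=0)."""
    tb = total_bioerosion(components)
    if tb == 0:
        return {k: 0.0 for k in components}
    return {k: v / tb for k, v in components.items()}


def transect_budget(
    cover: CoverProfile,
    density: GrazerDensity,
    rates: RateLibrary,
    scale_micro_by_dead: bool = False,
) -> dict[str, float]:
    """Gross production plus every bioerosion component for one transect."""
    percapita = {s: parrotfish_percapita(rates, s) for s in rates.parrotfish}
    components = {
        "macroborer": macroborer_rate(cover, rates),
        "microborer": microborer_rate(cover, rates, scale_by_dead=scale_micro_by_dead),
        "sponge": sponge_rate(cover, rates),
        "urchin": urchin_rate(cover, density, rates),
        "parrotfish": parrotfish_rate(density, percapita),
        "puffer": puffer_rate(density, rates),
    }
    return {
        "gross": gross_production(cover, rates),
        **components,
        "total_bioerosion": total_bioerosion(components),
    }


def broadcast_fish_densities(
    grazers: pd.DataFrame, periods: Iterable[str], survey_period: str = "spring-2018"
) -> pd.DataFrame:
    """Copy fish densities surveyed in one period to every survey period.

    Belt-transect fish surveys were run once; abundances are assumed stable
    and are filled to the other periods, flagged via the ``extrapolated``
    column (False only for the period actually surveyed).
    """
    fish = grazers[grazers["taxon"] != URCHIN_TAXON]
    urchins = grazers[grazers["taxon"] == URCHIN_TAXON].copy()
    urchins["extrapolated"] = False
    base = fish[fish["period"] == survey_period]
    out = [urchins]
    for period in periods:
        block = base.copy()
        block["period"] = period
        block["extrapolated"] = period != survey_period
        out.append(block)
    return pd.concat(out, ignore_index=True)
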