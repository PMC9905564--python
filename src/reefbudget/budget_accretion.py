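"""Net carbonate production, porosity-corrected framework density, and
reef-accretion potential (RAP).

Net production per transect is gross production minus total bioerosion and
may be negative (net erosion).  To convert mass flux to vertical accretion,
net production is divided by a framework density corrected for the porosity
observed in reef cores:

    rho_x = C_x * D_f + (1 - C_x) * D_w

where C_x is the site's core compaction fraction, D_f the mean skeletal
density of the framework builder, and D_w seawater density filling the pore
space.  Accretion potential is then

    RAP = G / rho_x + S      [mm yr^-1]

with G in kg CaCO3 m^-2 yr^-1, rho_x numerically in g cm^-3, and S a
per-site sediment contribution in mm yr^-1.  (1 kg m^-2 of solid at
rho g cm^-3 is a 1/rho mm thick layer, so the quotient is already in
mm yr^-1 in these units.)  The millennial-scale variant drops the porosity
correction and uses rho = D_f, describing accretion after the open modern
framework has compacted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .io_config import Densities, RateLibrary


class KeepUp(str, Enum):
    keeps_up = "keeps_up"
    drowns = "drowns"


@dataclass(frozen=True)
class CoreSummary:
    """Per-site core compaction summary.

    ``surface_exclusion_m`` records that the uppermost interval of open,
    uncompacted modern framework was excluded when the compaction fraction
    was computed; the value here is metadata, not re-applied.
    """

    site: str
    compaction: float  # C_x, fraction of core that is solid framework
    surface_exclusion_m: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.compaction <= 1.0:
            raise ValueError(f"site {self.site}: compaction must be in [0, 1]")

    @property
    def porosity(self) -> float:
        """phi_x = 1 - C_x."""
        return 1.0 - self.compaction


@dataclass(frozen=True)
class BudgetResult:
    """Per-transect carbonate budget; components are positive magnitudes."""

    transect_id: str
    site: str
    gulf: str
    period: str
    gross: float
    components: Mapping[str, float]
    total_bioerosion: float
    net: float

    def __post_init__(self) -> None:
        if abs(self.total_bioerosion - sum(self.components.values())) > 1e-9:
            raise ValueError("components do not sum to total_bioerosion")
        if abs(self.net - (self.gross - self.total_bioerosion)) > 1e-9:
            raise ValueError("net must equal gross - total_bioerosion")


@dataclass(frozen=True)
class AccretionResult:
    transect_id: str
    rap: float  # mm yr^-1
    millennial_rap: float  # mm yr^-1
    sediment: float  # S, mm yr^-1


def net_production(gross: float, total_bioerosion: float) -> float:
    """Net carbonate production G = gross - total bioerosion (kg m^-2 yr^-1)."""
    return gross - total_bioerosion


def framework_density(
    compaction: float, framework_d: float | None = None, seawater_d: float | None = None
) -> float:
    """Porosity-corrected framework density rho_x = C*D_f + (1-C)*D_w."""
    d = Densities()
    df = d.framework if framework_d is None else framework_d
    dw = d.seawater if seawater_d is None else seawater_d
    if not 0.0 <= compaction <= 1.0:
        raise ValueError("compaction must be a fraction in [0, 1]")
    if df <= 0 or dw <= 0:
        raise ValueError("densities must be positive")
    return compaction * df + (1.0 - compaction) * dw


def reef_accretion_potential(net: float, rho: float, sediment: float = 0.0) -> float:
    """RAP = G/rho + S in mm yr^-1 (negative G gives negative RAP)."""
    if rho <= 0:
        raise ValueError("framework density must be positive")
    return net / rho + sediment


def millennial_rap(
    net: float, framework_d: float | None = None, sediment: float = 0.0
) -> float:
    """Porosity-excluded accretion potential: RAP with rho = D_f."""
    df = Densities().framework if framework_d is None else framework_d
    return reef_accretion_potential(net, df, sediment)


def classify_keepup(rap: float, scenario_rate: float) -> KeepUp:
    """A reef keeps up when its accretion potential meets or exceeds the
    sea-level-rise rate (inclusive boundary)."""
    return KeepUp.keeps_up if rap >= scenario_rate else KeepUp.drowns


def accrete(
    budget: BudgetResult,
    core: CoreSummary,
    rates: RateLibrary,
) -> AccretionResult:
    """Full and millennial accretion potential for one transect, using the
    site's core compaction and configured sediment contribution."""
    d = rates.densities
    rho = framework_density(core.compaction, d.framework, d.seawater)
    s = rates.sediment_for(budget.site)
    return AccretionResult(
        transect_id=budget.transect_id,
        rap=reef_accretion_potential(budget.net, rho, s),
        millennial_rap=millennial_rap(budget.net, d.framework, s),
        sediment=s,
    )
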