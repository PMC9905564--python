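"""End-to-end assembly: surveys + grazers + cores (+ tide gauge) -> per-
transect budgets, gulf summaries, and threshold/keep-up reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import production_bioerosion as pb
from .budget_accretion import framework_density, millennial_rap, reef_accretion_potential
from .io_config import (
    RateLibrary,
    SurveyRow,
    default_rate_library,
    read_benthic_survey,
    read_core_table,
    read_grazer_table,
    read_tide_gauge,
    survey_to_frame,
    write_budget_table,
)
from .thresholds_sealevel import (
    build_scenarios,
    fit_cover_model,
    scenario_report,
    tide_gauge_trend,
)

TRANSECT_KEY = ["site", "gulf", "period", "transect_id"]


def compute_budget(
    survey: pd.DataFrame,
    grazers: pd.DataFrame,
    rates: RateLibrary | None = None,
    scale_micro_by_dead: bool = False,
) -> pd.DataFrame:
    """Per-transect gross production, bioerosion components, total, and net.

    Fish densities (surveyed in one period only) are broadcast to every
    survey period before joining; transects without a grazer record get
    zero grazer densities.
    """
    rates = rates or default_rate_library()
    periods = list(survey["period"].unique())
    grazers = pb.broadcast_fish_densities(grazers, periods)
    dens = (
        grazers.pivot_table(
            index=TRANSECT_KEY, columns="taxon", values="density_ind_m2",
            aggfunc="mean", fill_value=0.0,
        )
        .reset_index()
    )

    records = []
    for key, block in survey.groupby(TRANSECT_KEY, sort=True):
        rows = [
            SurveyRow(r.site, r.gulf, r.period, str(r.transect_id), r.category, int(r.count))
            for r in block.itertuples(index=False)
        ]
        cover = pb.CoverProfile.from_counts(rows)
        match = dens[
            (dens["site"] == key[0])
            & (dens["period"] == key[2])
            & (dens["transect_id"] == key[3])
        ]
        fish: dict[str, float] = {}
        urchin = 0.0
        if len(match):
            row = match.iloc[0]
            for taxon in dens.columns:
                if taxon in TRANSECT_KEY:
                    continue
                if taxon == pb.URCHIN_TAXON:
                    urchin = float(row[taxon])
                else:
                    fish[taxon] = float(row[taxon])
        density = pb.GrazerDensity(transect_id=key[3], urchin=urchin, fish=fish)
        budget = pb.transect_budget(cover, density, rates, scale_micro_by_dead)
        records.append(
            {
                "site": key[0],
                "gulf": key[1],
                "period": key[2],
                "transect_id": key[3],
                "coral_cover_pct": cover.live * 100.0,
                **budget,
                "net": budget["gross"] - budget["total_bioerosion"],
            }
        )
    return pd.DataFrame(records)


def add_accretion(
    budget: pd.DataFrame, cores: pd.DataFrame, rates: RateLibrary | None = None
) -> pd.DataFrame:
    """Attach rho_x, RAP, and millennial RAP using per-site core compaction
    and sediment contribution (cores table first, rate library fallback)."""
    rates = rates or default_rate_library()
    d = rates.densities
    site_info = cores.set_index("site")
    out = budget.copy()
    rho, rap, mrap = [], [], []
    for row in out.itertuples(index=False):
        if row.site not in site_info.index:
            raise KeyError(f"no core summary for site {row.site!r}")
        info = site_info.loc[row.site]
        r = framework_density(float(info["compaction_fraction"]), d.framework, d.seawater)
        s = (
            float(info["sediment_mm_yr"])
            if "sediment_mm_yr" in site_info.columns and not np.isnan(info["sediment_mm_yr"])
            else rates.sediment_for(row.site)
        )
        rho.append(r)
        rap.append(reef_accretion_potential(row.net, r, s))
        mrap.append(millennial_rap(row.net, d.framework, s))
    out["framework_density"] = rho
    out["rap"] = rap
    out["millennial_rap"] = mrap
    return out


def gulf_summary(budget: pd.DataFrame) -> pd.DataFrame:
    """Gulf-level means of the budget terms, plus the macroborer share of
    total bioerosion."""
    cols = ["coral_cover_pct", "gross", "total_bioerosion", "net"]
    cols += [c for c in ("rap", "millennial_rap") if c in budget.columns]
    summary = budget.groupby("gulf")[cols].mean()
    shares = budget.groupby("gulf").apply(
        lambda g: g["macroborer"].sum() / g["total_bioerosion"].sum(),
        include_groups=False,
    )
    summary["macroborer_share"] = shares
    return summary.reset_index()


def run_pipeline(
    survey_path: str | Path,
    grazers_path: str | Path,
    cores_path: str | Path,
    tide_path: str | Path | None = None,
    rates: RateLibrary | None = None,
    outdir: str | Path | None = None,
    threshold_period: str = "spring-2018",
) -> dict:
    """Read inputs, compute budgets and accretion, fit threshold models on
    the most recent survey, and (optionally) write the output tables."""
    rates = rates or default_rate_library()
    survey = survey_to_frame(read_benthic_survey(survey_path))
    grazers = read_grazer_table(grazers_path)
    cores = read_core_table(cores_path)

    budget = add_accretion(compute_budget(survey, grazers, rates), cores, rates)
    summary = gulf_summary(budget)

    results: dict = {"budget": budget, "summary": summary}

    current = budget[budget["period"] == threshold_period]
    if len(current) and current["coral_cover_pct"].nunique() >= 2:
        net_model = fit_cover_model(current, response="net")
        rap_model = fit_cover_model(current, response="rap")
        results["net_model"] = net_model
        results["rap_model"] = rap_model
        observed = current.groupby("gulf")["coral_cover_pct"].mean().to_dict()
        if tide_path is not None:
            local_trend = tide_gauge_trend(read_tide_gauge(tide_path))
            results["local_trend"] = local_trend
            scenarios = build_scenarios(local_trend)
            results["scenarios"] = scenarios
            results["thresholds"] = scenario_report(rap_model, scenarios, observed)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_budget_table(budget, outdir / "budget.csv")
        summary.to_csv(outdir / "summary.csv", index=False, float_format="%.6f")
        if "thresholds" in results:
            results["thresholds"].to_csv(
                outdir / "thresholds.csv", index=False, float_format="%.6f"
            )
    return results
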