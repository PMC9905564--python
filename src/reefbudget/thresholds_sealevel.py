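"""Coral-cover thresholds and localized sea-level-rise scenarios.

Net carbonate production and accretion potential are modelled as affine
functions of coral cover (in percent) with a gulf offset and site-level
random intercepts:

    response ~ intercept + gulf_offset + slope * cover%   (+ site effects)

The cover threshold for a target response (zero for a net-positive budget,
or a sea-level-rise rate for keep-up) is the linear inversion of the fixed
effects; site variance is a nuisance component, not an offset.  Global RCP
sea-level-rise rates are localized by the ratio of the locally observed
tide-gauge trend to the global-mean observed rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Global-mean sea-level-rise rates (mm yr^-1) attached to each RCP.
RCP_GLOBAL_RATES = {"RCP2.6": 4.0, "RCP4.5": 7.0, "RCP8.5": 15.0}

#: 20th-century global-mean observed sea-level trend (mm yr^-1) used as the
#: denominator of the localization factor; configurable per call.
GLOBAL_OBSERVED_TREND = 1.7


@dataclass(frozen=True)
class SeaLevelScenario:
    label: str
    global_rate: float  # mm yr^-1
    local_rate: float  # mm yr^-1

    def __post_init__(self) -> None:
        if self.global_rate < 0 or self.local_rate < 0:
            raise ValueError("sea-level-rise rates must be non-negative")


@dataclass
class CoverModel:
    """Fitted affine cover model for one response variable.

    ``intercept`` is the prediction at 0% cover in the reference gulf;
    ``gulf_offset`` maps each gulf to its additive offset (0 for the
    reference gulf and for gulfs absent from the data); ``cover_slope`` is
    in response units per percent cover.  ``site_variance`` is the
    random-intercept variance (0 when the model reduced to OLS).
    """

    response: str
    intercept: float
    gulf_offset: dict[str, float]
    cover_slope: float
    site_variance: float = 0.0

    def predict(self, gulf: str, cover_pct: float) -> float:
        return self.intercept + self.gulf_offset.get(gulf, 0.0) + self.cover_slope * cover_pct


@dataclass(frozen=True)
class ThresholdResult:
    cover_pct: float
    unattainable: bool  # required cover exceeds 100%


def fit_cover_model(
    budget: pd.DataFrame,
    response: str = "net",
    cover_col: str = "coral_cover_pct",
) -> CoverModel:
    """Fit response ~ cover% + gulf with site random intercepts.

    Falls back to ordinary least squares when only one site per gulf is
    present, when the mixed fit fails, or when the between-site variance is
    negligible — the fixed effects are what threshold solving consumes
    either way.  Raises ``ValueError`` if cover is constant.
    """
    df = budget[[response, cover_col, "gulf", "site"]].dropna().copy()
    if df[cover_col].nunique() < 2:
        raise ValueError("coral cover is constant; cover slope is unidentifiable")
    gulfs = sorted(df["gulf"].unique())
    reference = gulfs[0]
    formula = f"{response} ~ {cover_col}" + (" + C(gulf)" if len(gulfs) > 1 else "")

    params = None
    site_variance = 0.0
    if df["site"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = smf.mixedlm(formula, df, groups=df["site"]).fit(reml=True)
            params = mixed.fe_params
            site_variance = float(np.asarray(mixed.cov_re).ravel()[0])
        except Exception:
            params = None
    if params is None:
        ols = smf.ols(formula, df).fit()
        params = ols.params

    offsets = {g: 0.0 for g in gulfs}
    for g in gulfs[1:]:
        key = f"C(gulf)[T.{g}]"
        if key in params:
            offsets[g] = float(params[key])
    return CoverModel(
        response=response,
        intercept=float(params["Intercept"]),
        gulf_offset=offsets,
        cover_slope=float(params[cover_col]),
        site_variance=site_variance,
    )


def solve_cover_threshold(model: CoverModel, gulf: str, target: float) -> ThresholdResult:
    """Coral cover (%) at which the fixed-effect prediction reaches
    ``target``; thresholds above 100% cover are flagged unattainable."""
    if model.cover_slope == 0:
        raise ZeroDivisionError("cover slope is zero; threshold undefined")
    cover = (target - model.intercept - model.gulf_offset.get(gulf, 0.0)) / model.cover_slope
    return ThresholdResult(cover_pct=cover, unattainable=cover > 100.0)


def tide_gauge_trend(
    series: pd.Series, min_months: int = 24, seasonal: bool = True
) -> float:
    """OLS trend (mm yr^-1) of a monthly mean-sea-level series indexed by
    decimal year; missing months are omitted, never interpolated.

    By default an annual sine/cosine pair is co-estimated, the standard
    practice for monthly tide-gauge records: at monthly sampling the
    seasonal cycle is not orthogonal to time, so leaving it in the
    residuals would alias part of it into the trend.
    """
    clean = series.dropna()
    if len(clean) < min_months:
        raise ValueError(f"need >= {min_months} non-missing months, have {len(clean)}")
    t = np.asarray(clean.index, dtype=float)
    columns = [t]
    if seasonal:
        columns += [np.sin(2.0 * np.pi * t), np.cos(2.0 * np.pi * t)]
    x = sm.add_constant(np.column_stack(columns))
    fit = sm.OLS(np.asarray(clean.values, dtype=float), x).fit()
    return float(fit.params[1])


def localize_projection(
    global_rate: float,
    local_obs: float,
    global_obs: float = GLOBAL_OBSERVED_TREND,
) -> float:
    """Scale a global sea-level-rise rate by the observed local/global
    trend ratio."""
    if global_obs <= 0:
        raise ValueError("global observed trend must be positive")
    return global_rate * (local_obs / global_obs)


def build_scenarios(
    local_obs: float,
    global_obs: float = GLOBAL_OBSERVED_TREND,
    labels: list[str] | None = None,
) -> list[SeaLevelScenario]:
    """The current-trend scenario plus localized RCP scenarios."""
    labels = list(RCP_GLOBAL_RATES) if labels is None else labels
    scenarios = [SeaLevelScenario("current", local_obs, local_obs)]
    for label in labels:
        g = RCP_GLOBAL_RATES[label]
        scenarios.append(SeaLevelScenario(label, g, localize_projection(g, local_obs, global_obs)))
    return scenarios


def scenario_report(
    model: CoverModel,
    scenarios: list[SeaLevelScenario],
    observed_cover: dict[str, float],
) -> pd.DataFrame:
    """Threshold/keep-up table: for each gulf x scenario, the cover
    required to keep up with the localized rate, the observed cover, and
    the verdict at observed cover."""
    from .budget_accretion import classify_keepup

    records = []
    for gulf, cover in sorted(observed_cover.items()):
        for scen in scenarios:
            threshold = solve_cover_threshold(model, gulf, scen.local_rate)
            predicted = model.predict(gulf, cover)
            records.append(
                {
                    "gulf": gulf,
                    "scenario": scen.label,
                    "local_rate": scen.local_rate,
                    "required_cover_pct": threshold.cover_pct,
                    "observed_cover_pct": cover,
                    "verdict": classify_keepup(predicted, scen.local_rate).value,
                    "unattainable": threshold.unattainable,
                }
            )
    columns = [
        "gulf", "scenario", "local_rate", "required_cover_pct",
        "observed_cover_pct", "verdict", "unattainable",
    ]
    return pd.DataFrame(records, columns=columns)
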