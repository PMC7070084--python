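"""Temporal trend estimation for foliar nutrient panels.

Concentration ~ year is fitted by REML with random intercepts nested
country/plot/species and continuous-time AR(1) residual correlation within
each tree series, the design used for the Europe-wide decline estimates.
Also provides period percent change, per-site trend sign/significance
tallies, common-mean adjustment for plotting, and the latitude-band split
at the 46 and 58 degN parallels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import MixedFit, fit_lmm
from .rates import theil_sen

__all__ = [
    "TrendEstimate",
    "TrendClassSummary",
    "region_of",
    "fit_trend_lmm",
    "fit_with_year_exclusion",
    "percent_change",
    "classify_site_trends",
    "adjust_to_common_mean",
]

NESTING = ("country", "plot", "species")


@dataclass
class TrendEstimate:
    """Slope +/- SE (units per year) of a modelled temporal trend."""

    slope: float
    se: float
    p_value: float
    n_obs: int
    element: str

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass
class TrendClassSummary:
    element: str
    frac_increasing: float
    frac_decreasing: float
    frac_zero: float
    frac_sig_increasing: float
    frac_sig_decreasing: float
    n_series: int


def region_of(latitude: float) -> str:
    """Latitude band: "south" < 46, "central" in [46, 58), "north" >= 58 degN."""
    if not np.isfinite(latitude):
        raise ValueError("latitude must be finite")
    if latitude < 46.0:
        return "south"
    if latitude < 58.0:
        return "central"
    return "north"


def _series_key(panel: pd.DataFrame) -> pd.Series:
    cols = [c for c in ("country", "plot", "species", "tree") if c in panel.columns]
    key = panel[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + "/" + panel[c].astype(str)
    return key


def _nested_factors(panel: pd.DataFrame) -> dict:
    """country, country:plot and country:plot:species intercept codes."""
    c = panel["country"].astype(str)
    cp = c + "/" + panel["plot"].astype(str)
    cps = cp + "/" + panel["species"].astype(str)
    return {"country": c.to_numpy(), "plot": cp.to_numpy(), "species": cps.to_numpy()}


def fit_trend_lmm(
    panel: pd.DataFrame,
    element: str,
    exclude_years: set | None = None,
    *,
    region: str | None = None,
    species: str | None = None,
    estimate_phi: bool = True,
    fixed_phi: float | None = None,
    fixed_lambdas: dict | None = None,
) -> tuple[MixedFit, TrendEstimate]:
    """REML fit of ``element ~ year`` with nested random intercepts and AR(1).

    ``exclude_years`` drops the listed years before fitting (the anomalous-
    year robustness check).  ``region``/``species`` restrict the panel.
    """
    df = panel
    if exclude_years:
        df = df[~df["year"].isin(set(exclude_years))]
    if region is not None and region != "all":
        df = df[df["latitude"].map(region_of) == region]
    if species is not None:
        df = df[df["species"] == species]
    if df.empty:
        raise ValueError("no observations left after filtering")
    if df["year"].nunique() < 2:
        raise ValueError("need at least two distinct years to estimate a trend")
    for k in NESTING:
        if k not in df.columns:
            raise ValueError(f"panel lacks nesting key {k!r}")

    y = df[element].to_numpy(float)
    year0 = float(df["year"].min())
    X = np.column_stack([np.ones(len(df)), df["year"].to_numpy(float) - year0])
    fit = fit_lmm(
        y,
        X,
        ["intercept", "year"],
        series=_series_key(df).to_numpy(),
        times=df["year"].to_numpy(float),
        random_factors=_nested_factors(df),
        estimate_phi=estimate_phi,
        fixed_phi=fixed_phi,
        fixed_lambdas=fixed_lambdas,
    )
    est, se = fit.fixed_effects["year"]
    trend = TrendEstimate(
        slope=est, se=se, p_value=fit.p_values["year"], n_obs=len(df), element=element
    )
    fit._state["year0"] = year0
    return fit, trend


def fit_with_year_exclusion(
    panel: pd.DataFrame,
    element: str,
    years: set = frozenset({1996, 2012}),
    **kwargs,
) -> tuple[TrendEstimate, TrendEstimate]:
    """Trend with and without the anomalous years, from one call."""
    _, full = fit_trend_lmm(panel, element, **kwargs)
    _, reduced = fit_trend_lmm(panel, element, exclude_years=set(years), **kwargs)
    return full, reduced


def percent_change(
    trend: TrendEstimate,
    panel: pd.DataFrame,
    element: str,
    fit: MixedFit | None = None,
    baseline: str = "first_year",
) -> float:
    """Period change as a percentage of the starting level.

    100 x slope x (year span) / baseline, where the baseline is the
    model-predicted value at the first observed year (default) or the
    period mean of the raw series.
    """
    span = float(panel["year"].max() - panel["year"].min())
    if baseline == "first_year":
        if fit is not None:
            b0 = fit.fixed_effects["intercept"][0]  # year is centred at first year
        else:
            b0 = float(panel[element].mean() - trend.slope * (
                panel["year"].mean() - panel["year"].min()
            ))
    elif baseline == "period_mean":
        b0 = float(panel[element].mean())
    else:
        raise ValueError("baseline must be 'first_year' or 'period_mean'")
    if b0 <= 0:
        raise ValueError(f"non-positive baseline concentration ({b0:.3g})")
    return 100.0 * trend.slope * span / b0


def classify_site_trends(
    panel: pd.DataFrame,
    element: str,
    alpha: float = 0.05,
    min_years: int = 3,
    method: str = "ols",
) -> TrendClassSummary:
    """Per-series slope sign and significance tallies.

    Each site-species(-tree) series with at least ``min_years`` distinct
    years contributes one slope; fractions of increasing/decreasing and of
    significantly (p < alpha) increasing/decreasing series are reported.
    """
    key = _series_key(panel)
    inc = dec = zer = sig_inc = sig_dec = n = 0
    for _, g in panel.groupby(key.to_numpy()):
        if g["year"].nunique() < min_years:
            continue
        t = g["year"].to_numpy(float)
        v = g[element].to_numpy(float)
        if method == "ols":
            res = stats.linregress(t, v)
            slope, p = res.slope, res.pvalue
        elif method == "theil_sen":
            slope = theil_sen(t, v)
            _, p = stats.kendalltau(t, v)[:2]
        else:
            raise ValueError("method must be 'ols' or 'theil_sen'")
        n += 1
        if slope > 0:
            inc += 1
            if p < alpha:
                sig_inc += 1
        elif slope < 0:
            dec += 1
            if p < alpha:
                sig_dec += 1
        else:
            zer += 1
    if n == 0:
        raise ValueError("no series with enough distinct years")
    return TrendClassSummary(
        element=element,
        frac_increasing=inc / n,
        frac_decreasing=dec / n,
        frac_zero=zer / n,
        frac_sig_increasing=sig_inc / n,
        frac_sig_decreasing=sig_dec / n,
        n_series=n,
    )


def adjust_to_common_mean(panel: pd.DataFrame, element: str) -> pd.DataFrame:
    """Shift each series additively so its mean equals the grand mean.

    Within-series anomalies are unchanged and the observation-weighted
    grand mean is conserved exactly.
    """
    out = panel.copy()
    key = _series_key(panel).to_numpy()
    grand = float(panel[element].mean())
    series_mean = pd.Series(panel[element].to_numpy(), index=key).groupby(level=0).mean()
    out[element] = panel[element].to_numpy() - series_mean.loc[key].to_numpy() + grand
    return out
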