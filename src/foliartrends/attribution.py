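"""Temporal-contribution attribution of foliar nutrient trends to drivers.

The observed year-trend of a nutrient is decomposed into per-driver
contributions by counterfactual predictor freezing: a driver model is
fitted on site-mean and temporal-anomaly terms (with mean x anomaly and
anomaly x anomaly interactions available), reduced by stepwise
backward-forward selection, and the year-trend of its predictions is
compared with the trend obtained when one driver's anomaly is held at its
per-site median.  The difference is that driver's temporal contribution;
whatever is left between the sum of contributions and the observed trend
is the unknown contribution.  Standard errors follow by the delta method
from the fixed-effect covariance, and the unknown term's error assumes
independence (quadrature sum).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .lmm import LmmError, MixedFit, fit_lmm, slope_weights
from .trends import TrendEstimate

__all__ = [
    "AttributionDesign",
    "ContributionEntry",
    "ContributionTable",
    "build_attribution_design",
    "fit_glmm_arma",
    "stepwise_select",
    "r2_glmm",
    "temporal_contributions",
    "attribute_element",
]

DRIVERS = ("co2", "mat", "map", "ndep_ox", "ndep_red", "sdep")


@dataclass
class AttributionDesign:
    """Observation-level design with per-site driver means and anomalies."""

    data: pd.DataFrame
    element: str
    drivers: tuple = DRIVERS
    include_growth: bool = False

    @property
    def anomaly_terms(self) -> list:
        terms = [f"{d}_anom" for d in self.drivers]
        if self.include_growth:
            terms.append("growth")
        return terms

    @property
    def mean_terms(self) -> list:
        return [f"{d}_mean" for d in self.drivers]

    @property
    def interaction_terms(self) -> list:
        mx = [f"{d}_mean_x_anom" for d in self.drivers]
        aa = [
            f"{a}_anom_x_{b}_anom"
            for a, b in itertools.combinations(self.drivers, 2)
        ]
        return mx + aa

    def full_terms(self, interactions: bool = True) -> list:
        terms = self.anomaly_terms + self.mean_terms
        if interactions:
            terms += self.interaction_terms
        return terms


@dataclass
class ContributionEntry:
    predictor: str
    contribution: float  # mg g-1 yr-1
    se: float

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass
class ContributionTable:
    entries: list
    unknown: float
    unknown_se: float
    observed_trend: TrendEstimate
    element: str
    provenance: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"predictor": e.predictor, "contribution": e.contribution, "se": e.se}
            for e in self.entries
        ]
        rows.append(
            {"predictor": "unknown", "contribution": self.unknown, "se": self.unknown_se}
        )
        return pd.DataFrame(rows)

    @property
    def total(self) -> float:
        return sum(e.contribution for e in self.entries) + self.unknown


# ---------------------------------------------------------------------------
# Design construction


def build_attribution_design(
    panel: pd.DataFrame,
    drivers: pd.DataFrame,
    element: str,
    include_growth: bool = False,
    combine_nitrogen: bool = False,
) -> AttributionDesign:
    """Join panel and drivers; add per-site means, anomalies and interactions.

    Site means are taken over the panel rows of each site, so every site's
    anomaly columns average to zero exactly.  The growth column, when
    requested, is the per-tree year-on-year dbh increment (cm yr-1); a
    tree's first observation takes its series mean increment.
    ``combine_nitrogen`` replaces the separate oxidised/reduced N
    deposition predictors with their sum (``ndep``).
    """
    df = panel.copy()
    if "site_id" not in df.columns:
        df["site_id"] = df["country"].astype(str) + "_" + df["plot"].astype(str)
    drv = drivers.set_index(["site_id", "year"])
    idx = pd.MultiIndex.from_frame(df[["site_id", "year"]])
    missing = idx[~idx.isin(drv.index)]
    if len(missing):
        raise ValueError(
            "no driver record for site-years: "
            + ", ".join(f"{s}@{y}" for s, y in missing[:10])
        )
    joined = drv.loc[idx].reset_index(drop=True)
    for d in DRIVERS:
        df[d] = joined[d].to_numpy()
    if combine_nitrogen:
        df["ndep"] = df["ndep_ox"] + df["ndep_red"]
        active = ("co2", "mat", "map", "ndep", "sdep")
    else:
        active = DRIVERS
    for d in active:
        site_mean = df.groupby("site_id")[d].transform("mean")
        df[f"{d}_mean"] = site_mean
        df[f"{d}_anom"] = df[d] - site_mean
        df[f"{d}_mean_x_anom"] = df[f"{d}_mean"] * df[f"{d}_anom"]
    for a, b in itertools.combinations(active, 2):
        df[f"{a}_anom_x_{b}_anom"] = df[f"{a}_anom"] * df[f"{b}_anom"]
    if include_growth:
        tree_key = [k for k in ("country", "plot", "species", "tree") if k in df.columns]
        df = df.sort_values(tree_key + ["year"], kind="mergesort").reset_index(drop=True)
        def _increment(g):
            inc = g["dbh"].diff() / g["year"].diff()
            return inc.fillna(inc.mean() if inc.notna().any() else 0.0)
        df["growth"] = (
            df.groupby(tree_key, group_keys=False)[["dbh", "year"]].apply(_increment)
        ).to_numpy()
    return AttributionDesign(
        data=df, element=element, drivers=active, include_growth=include_growth
    )


def _series_key(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in ("site_id", "species", "tree") if c in df.columns]
    key = df[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + "/" + df[c].astype(str)
    return key.to_numpy()


def _random_factors(df: pd.DataFrame) -> dict:
    # plot and species-within-plot intercepts
    plot = df["site_id"].astype(str)
    return {
        "plot": plot.to_numpy(),
        "species": (plot + "/" + df["species"].astype(str)).to_numpy(),
    }


def _design_matrix(df: pd.DataFrame, terms, response=None):
    names = ["intercept"] + list(terms)
    X = np.column_stack(
        [np.ones(len(df))] + [df[t].to_numpy(float) for t in terms]
    ) if terms else np.ones((len(df), 1))
    y = df[response].to_numpy(float) if response else None
    return X, names, y


def _collinear_columns(X, names, tol=1e-8):
    keep, bad = [], []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol * max(np.linalg.norm(trial), 1.0)) == len(keep) + 1:
            keep.append(j)
        else:
            bad.append(names[j])
    return bad


# ---------------------------------------------------------------------------
# Model fitting


def fit_glmm_arma(
    design: AttributionDesign | pd.DataFrame,
    terms,
    response: str | None = None,
    **lmm_kwargs,
) -> MixedFit:
    """REML fit of the element on the given design columns.

    Random intercepts for plot and species(-within-plot); AR(1) residual
    correlation within each tree series (phi**|dt|).
    """
    df = design.data if isinstance(design, AttributionDesign) else design
    response = response or (design.element if isinstance(design, AttributionDesign) else None)
    if response is None:
        raise ValueError("response column required")
    terms = list(terms)
    unknown = [t for t in terms if t not in df.columns]
    if unknown:
        raise ValueError(f"terms not in design: {unknown}")
    X, names, y = _design_matrix(df, terms, response)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise LmmError(f"rank-deficient fixed design; collinear columns: {bad}")
    return fit_lmm(
        y,
        X,
        names,
        series=_series_key(df),
        times=df["year"].to_numpy(float),
        random_factors=_random_factors(df),
        **lmm_kwargs,
    )


def _hierarchy_parents(term: str, candidates) -> list:
    """Main-effect terms that an interaction term contains."""
    if "_x_" not in term:
        return []
    parts = []
    if term.endswith("_mean_x_anom"):
        d = term[: -len("_mean_x_anom")]
        parts = [f"{d}_mean", f"{d}_anom"]
    else:
        left, right = term.split("_anom_x_")
        parts = [f"{left}_anom", f"{right.removesuffix('_anom')}_anom"]
    return [p for p in parts if p in candidates]


def stepwise_select(
    design: AttributionDesign,
    full_terms=None,
    alpha: float = 0.05,
    response: str | None = None,
    max_cycles: int = 100,
    **lmm_kwargs,
) -> MixedFit:
    """Backward-forward selection by conditional t-test p-values.

    At each cycle the least significant droppable term with p > alpha is
    removed (a main effect is droppable only once no retained interaction
    contains it), then previously dropped terms are re-offered and re-enter
    if their p <= alpha (an interaction re-entering pulls its main effects
    back in).  Deterministic given the data.  If nothing survives, an
    intercept-plus-year null model is returned with a warning.
    """
    full_terms = list(full_terms) if full_terms is not None else design.full_terms()
    current = list(full_terms)
    dropped: list = []

    def fit_terms(terms, warm=None):
        kw = dict(lmm_kwargs)
        if warm is not None and "start" not in kw:
            kw["start"] = warm
        return fit_glmm_arma(design, terms, response=response, **kw)

    fit = fit_terms(current)
    for _ in range(max_cycles):
        changed = False
        # backward: drop worst droppable insignificant term
        droppable = [
            t
            for t in current
            if not any(t in _hierarchy_parents(other, current) for other in current)
        ]
        pvals = {t: fit.p_values[t] for t in droppable}
        if pvals:
            worst = max(pvals, key=lambda t: (pvals[t], t))
            if pvals[worst] > alpha:
                current.remove(worst)
                dropped.append(worst)
                fit = fit_terms(current, warm=fit.warm_start) if current else None
                changed = True
        # forward: re-offer dropped terms.  Candidates are screened at the
        # current fit's variance parameters (a GLS t-test); the accepted
        # model is then refit with free variance parameters.
        if current:
            ws = fit.warm_start
            screen_kw = dict(lmm_kwargs)
            screen_kw.pop("start", None)
            screen_kw.update(
                fixed_phi=ws["phi"], fixed_lambdas=ws["lambdas"], estimate_phi=False
            )
            best_term, best_p = None, alpha
            for t in list(dropped):
                trial = current + [t] + [
                    p for p in _hierarchy_parents(t, full_terms) if p not in current
                ]
                try:
                    f_try = fit_glmm_arma(design, trial, response=response, **screen_kw)
                except LmmError:
                    continue
                if f_try.p_values[t] <= best_p:
                    best_term, best_p = t, f_try.p_values[t]
            if best_term is not None:
                trial = current + [best_term] + [
                    p for p in _hierarchy_parents(best_term, full_terms) if p not in current
                ]
                f_full = fit_terms(trial, warm=ws)
                if f_full.p_values[best_term] <= alpha:
                    current = trial
                    for t in current:
                        if t in dropped:
                            dropped.remove(t)
                    fit = f_full
                    changed = True
        if not current or not changed:
            break
    if not current:
        warnings.warn(
            "no term significant; returning intercept-plus-year null model",
            stacklevel=2,
        )
        df = design.data
        year0 = float(df["year"].min())
        d2 = df.copy()
        d2["_year_c"] = d2["year"] - year0
        return fit_glmm_arma(
            AttributionDesign(d2, design.element, design.drivers, design.include_growth),
            ["_year_c"],
            response=response,
            **lmm_kwargs,
        )
    return fit


def r2_glmm(fit: MixedFit) -> tuple[float, float]:
    """Marginal and conditional variance explained (Nakagawa-Schielzeth).

    marginal = var(fixed predictions) / (var_fixed + var_random + var_resid);
    conditional adds the random-intercept variances to the numerator.
    """
    var_f = float(np.var(fit.population_fitted))
    var_r = sum(
        sd**2 for nm, sd in fit.variance_components.items() if nm != "residual"
    )
    var_e = fit.variance_components["residual"] ** 2
    total = var_f + var_r + var_e
    if total <= 0:
        raise ValueError("zero total variance")
    return var_f / total, (var_f + var_r) / total


# ---------------------------------------------------------------------------
# Counterfactual freezing


def _frozen_frame(df: pd.DataFrame, drivers_def, driver: str) -> pd.DataFrame:
    """Hold one driver's anomaly at its per-site median; recompute its
    interaction columns from the frozen values."""
    out = df.copy()
    med = out.groupby("site_id")[f"{driver}_anom"].transform("median")
    out[f"{driver}_anom"] = med
    out[f"{driver}_mean_x_anom"] = out[f"{driver}_mean"] * out[f"{driver}_anom"]
    for a, b in itertools.combinations(drivers_def, 2):
        if driver in (a, b):
            out[f"{a}_anom_x_{b}_anom"] = out[f"{a}_anom"] * out[f"{b}_anom"]
    return out


def _prediction_trend_fit(df: pd.DataFrame, values: np.ndarray, **lmm_kwargs) -> MixedFit:
    """Year-only mixed model on predicted values, same grouping/correlation."""
    year0 = float(df["year"].min())
    X = np.column_stack([np.ones(len(df)), df["year"].to_numpy(float) - year0])
    return fit_lmm(
        values,
        X,
        ["intercept", "year"],
        series=_series_key(df),
        times=df["year"].to_numpy(float),
        random_factors=_random_factors(df),
        **lmm_kwargs,
    )


def temporal_contributions(
    final_fit: MixedFit,
    design: AttributionDesign,
    observed: TrendEstimate,
    *,
    per_period: bool = False,
    trend_estimator: str = "lmm",
) -> ContributionTable:
    """Decompose the observed trend into per-driver contributions.

    For each driver with a temporally varying term in the final model, the
    contribution is (year-trend of final-model predictions) minus (the same
    trend with that driver's anomaly frozen at its per-site median).  The
    trend of predictions is the year coefficient of a mixed model refit on
    the predictions with the same grouping and correlation structure
    (``trend_estimator='ols'`` uses plain least squares instead).  Because
    predictions are linear in the fixed effects, each contribution is an
    exact linear functional of beta-hat and its SE follows from
    vcov(beta-hat) by the delta method.  unknown = observed - sum, with SE
    by quadrature.  Drivers absent from the final model contribute exactly
    0 +/- 0.  ``per_period`` scales contributions by the year span.
    """
    df = design.data
    terms = [t for t in final_fit.x_names if t != "intercept"]

    def _involves(d, t):
        return (
            t == f"{d}_anom"
            or t == f"{d}_mean_x_anom"
            or t.startswith(f"{d}_anom_x_")
            or t.endswith(f"_x_{d}_anom")
        )

    model_drivers = [d for d in design.drivers if any(_involves(d, t) for t in terms)]
    scale = float(df["year"].max() - df["year"].min()) if per_period else 1.0
    if not model_drivers:
        # nothing temporally varying was selected: everything is unknown
        return ContributionTable(
            entries=[
                ContributionEntry(predictor=d, contribution=0.0, se=0.0)
                for d in design.drivers
            ],
            unknown=observed.slope * scale,
            unknown_se=observed.se * scale,
            observed_trend=observed,
            element=design.element,
            provenance={"terms": terms, "per_period": per_period},
        )

    X_full, _, _ = _design_matrix(df, terms)
    p_full = X_full @ final_fit.beta

    if trend_estimator == "lmm":
        tfit = _prediction_trend_fit(df, p_full)
        w = slope_weights(tfit, "year")
    elif trend_estimator == "ols":
        year0 = float(df["year"].min())
        Xt = np.column_stack([np.ones(len(df)), df["year"].to_numpy(float) - year0])
        H = linalg.solve(Xt.T @ Xt, Xt.T)
        w = H[1]
    else:
        raise ValueError("trend_estimator must be 'lmm' or 'ols'")

    entries = []
    sum_contrib = 0.0
    var_sum = 0.0
    for d in design.drivers:
        if d not in model_drivers:
            entries.append(ContributionEntry(predictor=d, contribution=0.0, se=0.0))
            continue
        X_froz, _, _ = _design_matrix(_frozen_frame(df, design.drivers, d), terms)
        c = (X_full - X_froz).T @ w  # contribution = c' beta
        contrib = float(c @ final_fit.beta) * scale
        se = float(np.sqrt(max(c @ final_fit.vcov_fixed @ c, 0.0))) * scale
        entries.append(ContributionEntry(predictor=d, contribution=contrib, se=se))
        sum_contrib += contrib
        var_sum += se**2
    obs_slope = observed.slope * scale
    obs_se = observed.se * scale
    unknown = obs_slope - sum_contrib
    unknown_se = float(np.sqrt(obs_se**2 + var_sum))
    return ContributionTable(
        entries=entries,
        unknown=unknown,
        unknown_se=unknown_se,
        observed_trend=observed,
        element=design.element,
        provenance={
            "terms": terms,
            "phi": final_fit.correlation.phi,
            "per_period": per_period,
            "trend_estimator": trend_estimator,
        },
    )


def attribute_element(
    panel: pd.DataFrame,
    drivers: pd.DataFrame,
    element: str,
    *,
    include_growth: bool = False,
    combine_nitrogen: bool = False,
    terms: str | list = "mains",
    stepwise: bool = True,
    alpha: float = 0.05,
    per_period: bool = False,
) -> ContributionTable:
    """End-to-end attribution: design, fit, selection, observed trend,
    temporal contributions.

    ``terms`` chooses the full model: "mains" (driver anomalies, plus
    growth when included), "full" (anomalies + site means + mean x anomaly
    and anomaly x anomaly interactions) or an explicit list of columns.
    """
    design = build_attribution_design(
        panel, drivers, element, include_growth, combine_nitrogen
    )
    if terms == "mains":
        full_terms = design.anomaly_terms
    elif terms == "full":
        full_terms = design.full_terms()
        if include_growth:
            full_terms = full_terms + ["growth"]
    else:
        full_terms = list(terms)
    if stepwise:
        final = stepwise_select(design, full_terms, alpha=alpha)
    else:
        final = fit_glmm_arma(design, full_terms)

    df = design.data
    year0 = float(df["year"].min())
    Xobs = np.column_stack([np.ones(len(df)), df["year"].to_numpy(float) - year0])
    obs_fit = fit_lmm(
        df[element].to_numpy(float),
        Xobs,
        ["intercept", "year"],
        series=_series_key(df),
        times=df["year"].to_numpy(float),
        random_factors=_random_factors(df),
    )
    observed = TrendEstimate(
        slope=obs_fit.fixed_effects["year"][0],
        se=obs_fit.fixed_effects["year"][1],
        p_value=obs_fit.p_values["year"],
        n_obs=len(df),
        element=element,
    )
    table = temporal_contributions(final, design, observed, per_period=per_period)
    marg, cond = r2_glmm(final)
    table.provenance.update(
        {
            "selected_terms": [t for t in final.x_names if t != "intercept"],
            "r2_marginal": marg,
            "r2_conditional": cond,
            "observed_phi": obs_fit.correlation.phi,
        }
    )
    return table
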