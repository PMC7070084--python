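"""Synthetic ICP-Forests-style monitoring panels with known ground truth.

Emulates the statistical structure of the European Level II foliar survey:
a nested country/plot/species sampling design observed annually over
1990-2016, driver series (atmospheric CO2, mean annual temperature and
precipitation, oxidised/reduced N and S deposition) with the period's
documented trends, nested random intercepts, and within-series AR(1)
residual correlation.  Every generated effect is retrievable, so estimator
recovery can be tested against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .rates import theil_sen
from .trends import region_of

__all__ = [
    "SimulationConfig",
    "MetaCorpusConfig",
    "ELEMENTS",
    "make_sites",
    "generate_drivers",
    "generate_panel",
    "generate_meta_corpus",
    "true_contributions",
    "default_scenario",
]

ELEMENTS = ("N", "P", "K", "S", "Ca", "Mg")
DRIVERS = ("co2", "mat", "map", "ndep_ox", "ndep_red", "sdep")

# Mean foliar concentrations (mg g-1) typical of European broadleaf/conifer
# monitoring series; N is the reference element for the noise scales.
_DEFAULT_BASELINE = {"N": 23.0, "P": 1.5, "K": 8.0, "S": 1.8, "Ca": 6.0, "Mg": 1.2}

# CO2 sensitivities (mg g-1 per ppm) sized so that a +50 ppm rise over
# 1990-2016 alone produces period declines of about -5, -11, -8, -6 and -7%
# for N, P, K, S and Mg; Ca is left unaffected.
_DEFAULT_BETA = {
    "N": {"co2": -0.023},
    "P": {"co2": -0.0033},
    "K": {"co2": -0.0128},
    "S": {"co2": -0.00216},
    "Ca": {},
    "Mg": {"co2": -0.00168},
}

# Warming rates per region (degC / yr): 0.48/0.44/0.34 degC per decade.
_DEFAULT_MAT_TREND = {"north": 0.048, "central": 0.044, "south": 0.034}
# Precipitation change: ~ +50 mm/yr in the north, ~ -100 mm/yr in the south
# accumulated over the 26-year span.
_DEFAULT_MAP_TREND = {"north": 50.0 / 26.0, "central": 0.0, "south": -100.0 / 26.0}

_MAT_BASE = {"north": 2.5, "central": 8.5, "south": 13.5}
_MAP_BASE = {"north": 900.0, "central": 800.0, "south": 620.0}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic monitoring panel.

    SD parameters are stated for the reference element N (baseline
    23 mg g-1); other elements' random-effect and residual SDs scale
    proportionally with their baselines so relative variability is uniform.
    """

    n_countries: int = 5
    plots_per_country: int = 4
    species_pool: tuple = ("Fagus sylvatica", "Pinus sylvestris", "Picea abies")
    year_start: int = 1990
    year_end: int = 2016
    co2_start: float = 355.0
    co2_total_increase: float = 50.0
    ndep_relative_decline: float = 0.25
    sdep_relative_decline: float = 0.65
    ndep_ox_start: float = 6.0
    ndep_red_start: float = 6.0
    sdep_start: float = 12.0
    mat_trend_by_region: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MAT_TREND)
    )
    map_trend_by_region: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MAP_TREND)
    )
    beta: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {e: dict(b) for e, b in _DEFAULT_BETA.items()}
    )
    sigma_country: float = 1.5
    sigma_plot: float = 1.5
    sigma_species: float = 1.0
    sigma_resid: float = 1.0
    phi: float = 0.5
    baseline: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    driver_noise_sd: Mapping[str, float] = field(default_factory=dict)
    trees_per_series: int = 1
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("year range must span at least 3 years")
        for nm in ("sigma_country", "sigma_plot", "sigma_species", "sigma_resid"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not (0.0 <= self.phi < 1.0):
            raise ValueError("phi must lie in [0, 1)")
        for d in (self.ndep_relative_decline, self.sdep_relative_decline):
            if not (0.0 <= d <= 1.0):
                raise ValueError("relative declines must lie in [0, 1]")
        if any(v <= 0 for v in self.baseline.values()):
            raise ValueError("baselines must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


def make_sites(cfg: SimulationConfig) -> pd.DataFrame:
    """Assign plots to countries and spread latitudes over 40-64 degN."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    rows = []
    n_c = cfg.n_countries
    lat_centres = np.linspace(41.0, 63.0, n_c) if n_c > 1 else np.array([50.0])
    for c in range(n_c):
        for p in range(cfg.plots_per_country):
            lat = float(np.clip(lat_centres[c] + rng.uniform(-1.5, 1.5), 34.0, 72.0))
            lon = float(rng.uniform(-8.0, 28.0))
            rows.append(
                {
                    "country": f"C{c:02d}",
                    "plot": f"P{p:02d}",
                    "site_id": f"C{c:02d}_P{p:02d}",
                    "latitude": lat,
                    "longitude": lon,
                }
            )
    return pd.DataFrame(rows)


def generate_drivers(cfg: SimulationConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """Per site-year driver records with the period's documented trends.

    CO2 is identical across sites and linear in year; N and S deposition
    decline linearly to ``(1 - decline) x start``; MAT and MAP follow
    region-specific linear trends.  Optional i.i.d. Gaussian year noise
    (``cfg.driver_noise_sd``) is added around the trend lines.
    """
    if sites.empty:
        raise ValueError("sites table is empty")
    bad = sites[~sites["latitude"].between(34.0, 72.0)]
    if not bad.empty:
        raise ValueError(
            "rejecting sites with latitude outside [34, 72] degN: "
            + ", ".join(map(str, bad["site_id"].tolist()))
        )
    years = cfg.years
    span = years[-1] - years[0]
    t = years - years[0]
    co2 = cfg.co2_start + cfg.co2_total_increase * t / span
    nd_ox = cfg.ndep_ox_start * (1.0 - cfg.ndep_relative_decline * t / span)
    nd_red = cfg.ndep_red_start * (1.0 - cfg.ndep_relative_decline * t / span)
    sd = cfg.sdep_start * (1.0 - cfg.sdep_relative_decline * t / span)
    noise = dict(cfg.driver_noise_sd)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    # CO2 is well mixed: one global series, identical across sites each year
    co2_sd = float(noise.pop("co2", 0.0))
    if co2_sd > 0:
        co2 = co2 + rng.normal(0.0, co2_sd, size=len(years))
    frames = []
    for _, s in sites.iterrows():
        reg = region_of(s["latitude"])
        mat = _MAT_BASE[reg] + cfg.mat_trend_by_region[reg] * t
        mp = _MAP_BASE[reg] + cfg.map_trend_by_region[reg] * t
        rec = pd.DataFrame(
            {
                "site_id": s["site_id"],
                "year": years,
                "co2": co2.copy(),
                "mat": mat,
                "map": mp,
                "ndep_ox": nd_ox.copy(),
                "ndep_red": nd_red.copy(),
                "sdep": sd.copy(),
            }
        )
        for drv in DRIVERS:
            sd_n = float(noise.get(drv, 0.0))
            if sd_n > 0:
                rec[drv] = rec[drv] + rng.normal(0.0, sd_n, size=len(years))
        rec["map"] = rec["map"].clip(lower=0.0)
        for c in ("ndep_ox", "ndep_red", "sdep"):
            rec[c] = rec[c].clip(lower=0.0)
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def _ar1_series(rng, n, phi, sigma):
    """Stationary AR(1) noise: var sigma^2, lag-1 correlation phi."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * math.sqrt(max(1.0 - phi * phi, 0.0))
    for i in range(1, n):
        e[i] = phi * e[i - 1] + rng.normal(0.0, innov_sd)
    return e


def generate_panel(
    cfg: SimulationConfig, drivers: pd.DataFrame, sites: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Foliar observation panel with known linear driver effects.

    concentration = baseline + sum_j beta_j * (driver_j - ref_j)
                    + country + plot + species random intercepts
                    + AR(1) residual, noise scaled per element.

    ref_j is the driver's deterministic trend-line level in the first year
    (region-specific for MAT/MAP), so the baseline is the expected
    concentration at the start of the period.
    """
    if sites is None:
        sites = make_sites(cfg)
    for elem, bmap in cfg.beta.items():
        for drv in bmap:
            if drv not in DRIVERS:
                raise ValueError(f"beta for element {elem!r} references unknown driver {drv!r}")
    drv_lookup = drivers.set_index(["site_id", "year"])
    years = cfg.years
    missing = [
        (sid, int(yr))
        for sid in sites["site_id"]
        for yr in years
        if (sid, yr) not in drv_lookup.index
    ]
    if missing:
        raise ValueError(f"drivers missing for site-years: {missing[:5]}...")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    ref = cfg.baseline["N"]
    scale = {e: cfg.baseline[e] / ref for e in cfg.baseline}

    country_eff = {}
    plot_eff = {}
    for _, s in sites.iterrows():
        key_c = s["country"]
        if key_c not in country_eff:
            country_eff[key_c] = rng.normal(0.0, 1.0)
        plot_eff[s["site_id"]] = rng.normal(0.0, 1.0)
    frames = []
    n_yr = len(years)
    for _, s in sites.iterrows():
        sid = s["site_id"]
        dr = drv_lookup.loc[sid].reindex(years)
        reg = region_of(s["latitude"])
        ref = {
            "co2": cfg.co2_start,
            "mat": _MAT_BASE[reg],
            "map": _MAP_BASE[reg],
            "ndep_ox": cfg.ndep_ox_start,
            "ndep_red": cfg.ndep_red_start,
            "sdep": cfg.sdep_start,
        }
        # fixed (driver-driven) part per element, vector over years
        fixed = {}
        for e in ELEMENTS:
            val = np.full(n_yr, cfg.baseline[e])
            for drv, b in cfg.beta.get(e, {}).items():
                val = val + b * (dr[drv].to_numpy(float) - ref[drv])
            fixed[e] = val
        for sp in cfg.species_pool:
            sp_eff = rng.normal(0.0, 1.0)  # species-within-plot intercept
            for tree_i in range(cfg.trees_per_series):
                dbh0 = rng.normal(30.0, 5.0)
                growth = max(rng.normal(0.35, 0.05), 0.05)
                keep = (
                    rng.uniform(size=n_yr) >= cfg.dropout
                    if cfg.dropout > 0
                    else np.ones(n_yr, dtype=bool)
                )
                cols = {
                    "country": s["country"],
                    "plot": s["plot"],
                    "site_id": sid,
                    "species": sp,
                    "tree": f"T{tree_i:02d}",
                    "latitude": s["latitude"],
                    "longitude": s["longitude"],
                    "year": years.astype(int),
                }
                intercepts = (
                    cfg.sigma_country * country_eff[s["country"]]
                    + cfg.sigma_plot * plot_eff[sid]
                    + cfg.sigma_species * sp_eff
                )
                conc = {}
                for e in ELEMENTS:
                    conc[e] = (
                        fixed[e]
                        + scale[e] * intercepts
                        + _ar1_series(rng, n_yr, cfg.phi, cfg.sigma_resid * scale[e])
                    )
                    cols[e] = conc[e]
                cols["np_ratio"] = conc["N"] / conc["P"]
                cols["dbh"] = dbh0 + growth * np.arange(n_yr) + rng.normal(0.0, 0.05, n_yr)
                frame = pd.DataFrame(cols)
                frames.append(frame[keep] if cfg.dropout > 0 else frame)
    return pd.concat(frames, ignore_index=True)


def true_contributions(
    cfg: SimulationConfig, drivers: pd.DataFrame, element: str
) -> pd.DataFrame:
    """Ground-truth temporal contributions: beta_j x Theil-Sen driver trend.

    Driver trends are Theil-Sen slopes of the across-site annual means.
    The unknown term is zero by construction.
    """
    if element not in cfg.beta:
        raise ValueError(f"cfg.beta has no entry for element {element!r}")
    annual = drivers.groupby("year")[list(DRIVERS)].mean()
    rows = []
    for drv in DRIVERS:
        b = float(cfg.beta[element].get(drv, 0.0))
        trend = theil_sen(annual.index.to_numpy(float), annual[drv].to_numpy())
        rows.append({"predictor": drv, "contribution": b * trend, "se": 0.0})
    out = pd.DataFrame(rows)
    out.attrs["unknown"] = 0.0
    out.attrs["element"] = element
    return out


@dataclass
class MetaCorpusConfig:
    """Generator settings for synthetic elevated-CO2 study corpora."""

    n_studies: int = 100
    true_per_ppm: float = 0.0  # true lnRR per ppm CO2 added
    ppm_range: tuple = (100.0, 360.0)
    sd_between: float = 0.0  # SD of study-level true lnRR (heterogeneity)
    cv_arm: float = 0.15  # within-arm SD as fraction of the arm mean
    n_range: tuple = (4, 12)
    control_mean: float = 20.0
    negative_policy: str = "resample"  # or "error"
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 2:
            raise ValueError("need at least 2 studies")
        if self.negative_policy not in ("resample", "error"):
            raise ValueError("negative_policy must be 'resample' or 'error'")


def generate_meta_corpus(cfg: MetaCorpusConfig) -> pd.DataFrame:
    """Study table with E[lnRR] = true_per_ppm x ppm_added per study."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 404]))
    rows = []
    for i in range(cfg.n_studies):
        ppm = float(rng.uniform(*cfg.ppm_range))
        lnrr_true = cfg.true_per_ppm * ppm
        if cfg.sd_between > 0:
            lnrr_true += rng.normal(0.0, cfg.sd_between)
        mu_n = cfg.control_mean
        mu_i = mu_n * math.exp(lnrr_true)
        ni = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        nn = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        si = cfg.cv_arm * mu_i
        sn = cfg.cv_arm * mu_n
        for _ in range(1000):
            xi = mu_i + rng.normal(0.0, si / math.sqrt(ni)) if si > 0 else mu_i
            xn = mu_n + rng.normal(0.0, sn / math.sqrt(nn)) if sn > 0 else mu_n
            if xi > 0 and xn > 0:
                break
            if cfg.negative_policy == "error":
                raise RuntimeError(f"study {i}: generated non-positive arm mean")
        rows.append(
            {
                "study_id": f"S{i:04d}",
                "variable": "N",
                "Xi": xi,
                "Xn": xn,
                "Si": si,
                "Sn": sn,
                "ni": ni,
                "nn": nn,
                "ppm_added": ppm,
            }
        )
    return pd.DataFrame(rows)


def default_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """Canonical study conditions: 5 countries x 4 plots x 3 species,
    1990-2016, paper-period driver trends, moderate nested noise, and
    realistic interannual driver variability (needed so driver anomalies
    are not mutually collinear within a region)."""
    kw = dict(
        seed=seed,
        driver_noise_sd={
            "co2": 0.3,
            "mat": 0.5,
            "map": 80.0,
            "ndep_ox": 0.5,
            "ndep_red": 0.5,
            "sdep": 0.8,
        },
    )
    kw.update(overrides)
    return SimulationConfig(**kw)
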