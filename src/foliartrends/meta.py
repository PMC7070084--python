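"""Response-ratio meta-analysis of elevated-CO2 effects on leaf chemistry.

Each study contributes a log response ratio lnRR = ln(Xi/Xn) of the
elevated over the control arm with the standard sampling variance
(1/ni)(Si/Xi)^2 + (1/nn)(Sn/Xn)^2.  Because experiments add different CO2
increments, effects are expressed per ppm and standardized to +50 ppm —
the rise observed over the 1990-2016 monitoring period — before
random-effects pooling (DerSimonian-Laird between-study variance by
default, REML optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "StudyRecord",
    "EffectSize",
    "PooledEffect",
    "ln_rr",
    "lnrr_variance",
    "standardize_effect",
    "pool_effects",
    "run_meta",
]

STUDY_COLUMNS = ["study_id", "variable", "Xi", "Xn", "Si", "Sn", "ni", "nn", "ppm_added"]


@dataclass
class StudyRecord:
    """One control/elevated comparison: means, SDs, n per arm, ppm added."""

    study_id: str
    variable: str
    Xi: float  # elevated-arm mean
    Xn: float  # control-arm mean
    Si: float
    Sn: float
    ni: int
    nn: int
    ppm_added: float

    def __post_init__(self):
        if self.Xi <= 0 or self.Xn <= 0:
            raise ValueError(f"{self.study_id}: arm means must be positive")
        if self.ni < 1 or self.nn < 1:
            raise ValueError(f"{self.study_id}: arm sizes must be >= 1")
        if self.ppm_added <= 0:
            raise ValueError(f"{self.study_id}: ppm_added must be positive")


@dataclass
class EffectSize:
    study_id: str
    lnRR: float
    variance: float
    per_ppm: float
    standardized: float  # lnRR at the target ppm increment
    std_variance: float
    percent: float  # (e^standardized - 1) x 100

    def __post_init__(self):
        if self.variance < 0 or self.std_variance < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class PooledEffect:
    variable: str
    estimate: float  # pooled lnRR on the target-ppm scale
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int
    percent: float
    percent_ci: tuple

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must contain the point estimate")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")


def ln_rr(record: StudyRecord) -> float:
    """ln(Xi) - ln(Xn); the difference form makes arm-swap antisymmetry exact."""
    if record.Xi <= 0 or record.Xn <= 0:
        raise ValueError("arm means must be positive")
    return math.log(record.Xi) - math.log(record.Xn)


def lnrr_variance(record: StudyRecord, strict_paper_formula: bool = False) -> float:
    """Sampling variance (1/ni)(Si/Xi)^2 + (1/nn)(Sn/Xn)^2.

    ``strict_paper_formula`` would wrap the sum in an outer natural log;
    that expression is negative whenever the sum is below one and cannot be
    a variance, so it is refused.
    """
    if strict_paper_formula:
        raise ValueError(
            "the outer-log variance formula yields negative variances for "
            "arguments < 1 and is treated as a typographical error; use the "
            "standard lnRR sampling variance"
        )
    if record.Xi == 0 or record.Xn == 0:
        raise ValueError("arm means must be non-zero")
    return (record.Si / record.Xi) ** 2 / record.ni + (record.Sn / record.Xn) ** 2 / record.nn


def standardize_effect(
    lnRR: float,
    variance: float,
    ppm_added: float,
    target_ppm: float = 50.0,
    study_id: str = "",
) -> EffectSize:
    """Express an effect per ppm and scale it to the target CO2 increment.

    per_ppm = lnRR / ppm_added; standardized = per_ppm x target; the
    variance scales by (target/ppm_added)^2.
    """
    if ppm_added <= 0:
        raise ValueError("ppm_added must be positive")
    per_ppm = lnRR / ppm_added
    std = per_ppm * target_ppm
    std_var = variance * (target_ppm / ppm_added) ** 2
    return EffectSize(
        study_id=study_id,
        lnRR=lnRR,
        variance=variance,
        per_ppm=per_ppm,
        standardized=std,
        std_variance=std_var,
        percent=(math.exp(std) - 1.0) * 100.0,
    )


def _tau2_dl(y, v):
    w = 1.0 / v
    yw = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - yw) ** 2))
    k = len(y)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max((q - (k - 1)) / denom, 0.0) if denom > 0 else 0.0


def _tau2_reml(y, v):
    def nll(log_tau2):
        t2 = math.exp(log_tau2)
        wi = 1.0 / (v + t2)
        mu = np.sum(wi * y) / np.sum(wi)
        return float(
            np.sum(np.log(v + t2)) + math.log(np.sum(wi)) + np.sum(wi * (y - mu) ** 2)
        )
    res = optimize.minimize_scalar(nll, bounds=(-30.0, 5.0), method="bounded")
    t2 = math.exp(res.x)
    return t2 if t2 > 1e-12 else 0.0


def pool_effects(
    effects: list,
    variable: str = "",
    tau2_method: str = "DL",
) -> PooledEffect:
    """Random-effects pooling of standardized effects.

    Inverse-variance weights 1/(v_i + tau2); tau2 by the DerSimonian-Laird
    moment estimator (default) or REML; 95% CI from the normal
    approximation; the pooled lnRR is also reported as a percent change.
    """
    if len(effects) < 2:
        raise ValueError("need at least 2 studies to pool")
    y = np.array([e.standardized for e in effects])
    v = np.array([e.std_variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive for pooling")
    if tau2_method == "DL":
        tau2 = _tau2_dl(y, v)
    elif tau2_method == "REML":
        tau2 = _tau2_reml(y, v)
    else:
        raise ValueError("tau2_method must be 'DL' or 'REML'")
    w = 1.0 / (v + tau2)
    est = float(np.sum(w * y) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    z = stats.norm.ppf(0.975)
    lo, hi = est - z * se, est + z * se
    return PooledEffect(
        variable=variable,
        estimate=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        tau2=float(tau2),
        k=len(effects),
        percent=(math.exp(est) - 1.0) * 100.0,
        percent_ci=((math.exp(lo) - 1.0) * 100.0, (math.exp(hi) - 1.0) * 100.0),
    )


def run_meta(
    studies: pd.DataFrame,
    variable: str,
    target_ppm: float = 50.0,
    tau2_method: str = "DL",
) -> tuple[PooledEffect, pd.DataFrame]:
    """Filter to one variable, derive per-study effects, pool them.

    Returns the pooled effect and the per-study effect-size table.
    """
    sub = studies[studies["variable"] == variable]
    if sub.empty:
        raise ValueError(f"no studies for variable {variable!r}")
    if len(sub) < 2:
        raise ValueError(f"need >= 2 studies for variable {variable!r}, got {len(sub)}")
    effects = []
    rows = []
    for _, r in sub.iterrows():
        rec = StudyRecord(
            study_id=str(r["study_id"]),
            variable=variable,
            Xi=float(r["Xi"]),
            Xn=float(r["Xn"]),
            Si=float(r["Si"]),
            Sn=float(r["Sn"]),
            ni=int(r["ni"]),
            nn=int(r["nn"]),
            ppm_added=float(r["ppm_added"]),
        )
        eff = standardize_effect(
            ln_rr(rec), lnrr_variance(rec), rec.ppm_added, target_ppm, rec.study_id
        )
        effects.append(eff)
        rows.append(
            {
                "study_id": eff.study_id,
                "lnRR": eff.lnRR,
                "variance": eff.variance,
                "per_ppm": eff.per_ppm,
                "standardized": eff.standardized,
                "std_variance": eff.std_variance,
                "percent": eff.percent,
            }
        )
    pooled = pool_effects(effects, variable=variable, tau2_method=tau2_method)
    return pooled, pd.DataFrame(rows)
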