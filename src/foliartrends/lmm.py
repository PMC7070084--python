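"""Linear mixed models with random intercepts and continuous-time AR(1) residuals.

This is the estimation engine shared by the trend and attribution layers.
The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),
    corr(e_i, e_j) = phi ** |t_i - t_j|   for observations in the same series,

fitted by REML.  The residual scale is profiled out; the remaining
parameters are the variance ratios lambda_k = sigma_k^2 / sigma_e^2
(optimised on the log scale) and the lag-1 correlation phi.  The marginal
covariance is inverted with the Woodbury identity, so the cost per
objective evaluation is one small Cholesky per distinct within-series
time pattern plus an (n_levels x n_levels) solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

__all__ = ["CorrelationSpec", "MixedFit", "fit_lmm", "slope_weights", "LmmError"]

# Numerical policy: variance ratios are bounded below so that boundary
# fits stay well conditioned; phi is kept inside [0, PHI_MAX].
LAMBDA_FLOOR = 1e-10
LAMBDA_CEIL = 1e8
PHI_MAX = 0.99
PHI_START = 0.3
CONV_TOL = 1e-8
_BIG = 1e30


class LmmError(RuntimeError):
    """Raised on singular designs or non-convergence."""


@dataclass
class CorrelationSpec:
    """Within-series residual correlation: ARMA(p=1, q=0), corr = phi**|dt|."""

    phi: float
    p: int = 1
    q: int = 0


@dataclass
class MixedFit:
    """Result of a REML mixed-model fit."""

    fixed_effects: dict  # name -> (estimate, se)
    vcov_fixed: np.ndarray
    variance_components: dict  # factor name -> SD (residual under 'residual')
    correlation: CorrelationSpec
    reml_loglik: float
    fitted_values: np.ndarray  # conditional (BLUP) predictions, original order
    residuals: np.ndarray  # y - fitted_values, original order
    x_names: list
    beta: np.ndarray
    t_values: np.ndarray
    p_values: dict  # name -> p
    df: dict  # name -> denominator df
    n_obs: int
    population_fitted: np.ndarray  # X beta only, original order
    boundary: bool = False  # any variance component at its floor
    converged: bool = True
    n_iter: int = 0
    # internals needed to build GLS linear functionals afterwards
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def sigma_resid(self) -> float:
        return self.variance_components["residual"]

    @property
    def warm_start(self) -> dict:
        """Variance parameters in the form accepted by ``fit_lmm(start=...)``."""
        return {"lambdas": dict(self._state.get("lambdas", {})), "phi": self.correlation.phi}


# ---------------------------------------------------------------------------
# Structure pre-processing


def _prepare(series, times):
    """Sort by (series, time); group series by identical time offsets."""
    series = np.asarray(series)
    times = np.asarray(times, dtype=float)
    codes, _ = pd.factorize(series, sort=True)
    order = np.lexsort((times, codes))
    codes_s = codes[order]
    times_s = times[order]
    # contiguous slices per series
    boundaries = np.flatnonzero(np.diff(codes_s)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [codes_s.size]))
    groups: dict = {}
    for st, sp in zip(starts, stops):
        t = times_s[st:sp]
        key = tuple(np.round(t - t[0], 9))
        groups.setdefault(key, []).append((st, sp))
    return order, times_s, groups, int(starts.size), codes_s


def _block_chol(dt_key, phi, lam_fold=0.0):
    """Cholesky of one series' covariance block: phi**|dt| + lam_fold * J.

    lam_fold is the summed variance ratio of random intercepts whose levels
    coincide with the series (they are folded into the block rather than
    carried as Woodbury columns).
    """
    t = np.asarray(dt_key, dtype=float)
    nt = len(t)
    R = phi ** np.abs(t[:, None] - t[None, :]) if phi != 0.0 else np.eye(nt)
    if lam_fold:
        R = R + lam_fold
    return linalg.cholesky(R, lower=True, check_finite=False)


def _stack_groups(B, groups):
    """Pre-stack rows of B by time-pattern group: list of (key, G, (nt,G,m))."""
    out = []
    for key, slices in groups.items():
        nt = len(key)
        Bg = np.stack([B[st:sp] for st, sp in slices], axis=1)  # (nt, G, m)
        out.append((key, len(slices), np.ascontiguousarray(Bg.reshape(nt, -1))))
    return out


def _cross_products(stacked, phi, m, lam_fold=0.0):
    """C = B' V^-1 B and log|V| over all series blocks V_s = R_s + lam*J."""
    C = np.zeros((m, m))
    logdet = 0.0
    for key, G, Bg in stacked:
        nt = len(key)
        if phi == 0.0 and lam_fold == 0.0:
            A2 = Bg.reshape(nt * G, m)
            C += A2.T @ A2
            continue
        L = _block_chol(key, phi, lam_fold)
        logdet += 2.0 * float(np.sum(np.log(np.diag(L)))) * G
        A = linalg.solve_triangular(L, Bg, lower=True, check_finite=False)
        A2 = A.reshape(nt, G, m).reshape(nt * G, m)
        C += A2.T @ A2
    return C, logdet


# ---------------------------------------------------------------------------
# REML criterion


def _criterion(stacked, m, n, p, q, dvec, phi, lam_fold=0.0, _c0_cache=None):
    """Profiled -2 REML (up to additive constant) and byproducts.

    ``stacked`` holds [y | X | Z] pre-grouped by time pattern;
    dvec = lambda per Z column; lam_fold = summed ratio of folded factors.
    """
    if phi == 0.0 and lam_fold == 0.0 and _c0_cache is not None:
        if "C0" not in _c0_cache:
            _c0_cache["C0"] = _cross_products(stacked, 0.0, m)
        C, logdetR = _c0_cache["C0"]
    else:
        C, logdetR = _cross_products(stacked, phi, m, lam_fold)
    c_yy = C[0, 0]
    C_xy = C[1 : 1 + p, 0]
    C_xx = C[1 : 1 + p, 1 : 1 + p]
    if q:
        C_zy = C[1 + p :, 0]
        C_zx = C[1 + p :, 1 : 1 + p]
        C_zz = C[1 + p :, 1 + p :]
        dh = np.sqrt(dvec)
        U = np.eye(q) + (dh[:, None] * C_zz) * dh[None, :]
        cU = linalg.cho_factor(U, lower=True, check_finite=False)
        logdetU = 2.0 * float(np.sum(np.log(np.diag(cU[0]))))
        # a' W^-1 b = C_ab - (dh*C_za)' U^-1 (dh*C_zb)
        G = np.concatenate([C_zy[:, None], C_zx], axis=1) * dh[:, None]
        GU = linalg.cho_solve(cU, G, check_finite=False)
        corr = G.T @ GU
        yWy = c_yy - corr[0, 0]
        XWy = C_xy - corr[1:, 0]
        XWX = C_xx - corr[1:, 1:]
    else:
        logdetU = 0.0
        yWy, XWy, XWX = c_yy, C_xy, C_xx
        cU = None
        dh = None
    try:
        cXX = linalg.cho_factor(XWX, lower=True, check_finite=False)
    except linalg.LinAlgError:
        raise LmmError("singular fixed-effect design under current weights")
    beta = linalg.cho_solve(cXX, XWy)
    rWr = max(float(yWy - XWy @ beta), 1e-300)
    sigma2 = rWr / (n - p)
    logdetXWX = 2.0 * float(np.sum(np.log(np.diag(cXX[0]))))
    f = (n - p) * math.log(sigma2) + logdetR + logdetU + logdetXWX
    return f, {
        "beta": beta,
        "sigma2": sigma2,
        "XWX": XWX,
        "cXX": cXX,
        "cU": cU,
        "dh": dh,
        "C": C,
        "logdetR": logdetR,
        "logdetU": logdetU,
    }


# ---------------------------------------------------------------------------
# Public fit


def fit_lmm(
    y,
    X,
    x_names: Sequence[str],
    series,
    times,
    random_factors: Mapping[str, np.ndarray] | None = None,
    *,
    estimate_phi: bool = True,
    fixed_phi: float | None = None,
    fixed_lambdas: Mapping[str, float] | None = None,
    start: Mapping | None = None,
    maxiter: int = 2000,
) -> MixedFit:
    """REML fit of ``y ~ X`` with random intercepts and AR(1) residuals.

    Parameters
    ----------
    series, times
        Define the within-series AR(1) correlation ``phi**|dt|``.
    random_factors
        Ordered mapping factor name -> per-observation level labels.
    fixed_phi, fixed_lambdas
        Constrain phi and/or variance ratios (sigma_k^2/sigma_e^2) instead
        of estimating them; used for degenerate-limit and oracle checks.
    start
        Optional warm start: ``{"lambdas": {factor: ratio}, "phi": value}``
        (e.g. from a previous fit of a nested model).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise LmmError(f"need more observations ({n}) than fixed effects ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise LmmError("rank-deficient fixed-effect design: " + ", ".join(x_names))
    random_factors = dict(random_factors or {})
    fixed_lambdas = dict(fixed_lambdas or {})

    order, times_s, groups, n_series, ser_codes = _prepare(series, times)
    inv_order = np.empty(n, dtype=int)
    inv_order[order] = np.arange(n)

    # A factor whose levels coincide one-to-one with the AR(1) series is
    # "folded": its intercept variance enters the per-series covariance
    # block as lambda*J instead of occupying Woodbury columns.
    factor_names = list(random_factors)
    factor_codes = {
        name: pd.factorize(np.asarray(random_factors[name])[order], sort=True)[0]
        for name in factor_names
    }
    fold_names = []
    z_names = []
    for name in factor_names:
        fc = factor_codes[name]
        pairs = pd.DataFrame({"s": ser_codes, "f": fc}).drop_duplicates()
        bijective = (
            pairs["s"].is_unique
            and pairs["f"].is_unique
            and len(pairs) == n_series
        )
        (fold_names if bijective else z_names).append(name)

    z_blocks = []
    z_cols: list = []
    for name in z_names:
        fc = factor_codes[name]
        nl = int(fc.max()) + 1 if len(fc) else 0
        Zk = np.zeros((n, nl))
        Zk[np.arange(n), fc] = 1.0
        z_blocks.append(Zk)
        z_cols.append(nl)
    q = int(sum(z_cols))
    Z = np.concatenate(z_blocks, axis=1) if q else np.zeros((n, 0))
    B = np.concatenate([y[order, None], X[order], Z], axis=1)
    m = B.shape[1]
    stacked = _stack_groups(B, groups)
    cache: dict = {}

    free_factors = [f for f in factor_names if f not in fixed_lambdas]
    phi_free = estimate_phi and fixed_phi is None

    def unpack(theta):
        lambdas = {}
        i = 0
        for f in free_factors:
            lambdas[f] = float(np.clip(np.exp(theta[i]), LAMBDA_FLOOR, LAMBDA_CEIL))
            i += 1
        for f, v in fixed_lambdas.items():
            lambdas[f] = max(float(v), 0.0)
        phi = (
            float(PHI_MAX * special.expit(theta[i]))
            if phi_free
            else float(fixed_phi if fixed_phi is not None else 0.0)
        )
        dvec = (
            np.concatenate(
                [np.full(z_cols[k], lambdas[z_names[k]]) for k in range(len(z_names))]
            )
            if q
            else np.zeros(0)
        )
        lam_fold = sum(lambdas[f] for f in fold_names)
        return lambdas, dvec, phi, lam_fold

    def objective(theta):
        _, dvec, phi, lam_fold = unpack(theta)
        try:
            f, _ = _criterion(stacked, m, n, p, q, dvec, phi, lam_fold, cache)
        except (LmmError, linalg.LinAlgError, FloatingPointError):
            return _BIG
        return f if np.isfinite(f) else _BIG

    n_free = len(free_factors) + (1 if phi_free else 0)
    n_iter = 0
    if n_free == 0:
        theta_hat = np.zeros(0)
    else:
        # default start: all random SDs at half the marginal SD (ratio 1),
        # phi at PHI_START; warm starts override.
        theta0 = np.zeros(n_free)
        if phi_free:
            theta0[-1] = math.log(PHI_START / (PHI_MAX - PHI_START))
        if start:
            lam0 = dict(start.get("lambdas", {}))
            for i, fct in enumerate(free_factors):
                if fct in lam0:
                    theta0[i] = math.log(
                        float(np.clip(lam0[fct], LAMBDA_FLOOR, LAMBDA_CEIL))
                    )
            if phi_free and "phi" in start:
                ph0 = float(np.clip(start["phi"], 1e-4, PHI_MAX - 1e-4))
                theta0[-1] = math.log(ph0 / (PHI_MAX - ph0))
        bounds = [(-23.0, 18.0)] * len(free_factors) + ([(-12.0, 12.0)] if phi_free else [])
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": CONV_TOL * 1e-2, "gtol": 1e-8, "maxiter": maxiter},
        )
        theta_hat, f_hat = res.x, float(res.fun)
        n_iter = int(res.nit)
        if not res.success:
            # derivative-free polish for the rare non-smooth/boundary case
            res2 = optimize.minimize(
                objective,
                theta_hat,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": CONV_TOL, "maxfev": maxiter},
            )
            n_iter += int(res2.nit)
            if float(res2.fun) <= f_hat:
                theta_hat, f_hat = res2.x, float(res2.fun)
        if f_hat >= _BIG:
            raise LmmError(
                f"REML optimisation failed after {n_iter} iterations: {res.message}"
            )

    lambdas, dvec, phi, lam_fold = unpack(theta_hat)
    f, st = _criterion(stacked, m, n, p, q, dvec, phi, lam_fold, cache)
    beta = st["beta"]
    sigma2 = st["sigma2"]
    vcov = sigma2 * linalg.cho_solve(st["cXX"], np.eye(p))
    vcov = 0.5 * (vcov + vcov.T)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))

    # conditional (BLUP) fitted values
    pop_fit = X @ beta
    cond_fit_sorted = X[order] @ beta
    if q:
        C = st["C"]
        C_zy = C[1 + p :, 0]
        C_zx = C[1 + p :, 1 : 1 + p]
        C_zz = C[1 + p :, 1 + p :]
        v = C_zy - C_zx @ beta  # Z' V^-1 r
        dh = st["dh"]
        zWr = v - (C_zz * dh[None, :]) @ linalg.cho_solve(st["cU"], dh * v)
        u_hat = dvec * zWr
        cond_fit_sorted = cond_fit_sorted + Z @ u_hat
    if lam_fold > 0:
        # folded-intercept BLUP: lam_fold * (per-series sum of W^-1 r)
        r_sorted = y[order] - X[order] @ beta
        cols = np.concatenate([r_sorted[:, None], Z], axis=1)
        VinvM = np.empty_like(cols)
        for key, slices in groups.items():
            L = _block_chol(key, phi, lam_fold)
            for stt, spp in slices:
                tmp = linalg.solve_triangular(L, cols[stt:spp], lower=True, check_finite=False)
                VinvM[stt:spp] = linalg.solve_triangular(
                    L.T, tmp, lower=False, check_finite=False
                )
        Winv_r = VinvM[:, 0]
        if q:
            dh = st["dh"]
            Winv_r = Winv_r - (VinvM[:, 1:] * dh[None, :]) @ linalg.cho_solve(
                st["cU"], dh * (Z.T @ VinvM[:, 0])
            )
        fold_blup = lam_fold * np.bincount(ser_codes, weights=Winv_r, minlength=n_series)
        cond_fit_sorted = cond_fit_sorted + fold_blup[ser_codes]
    cond_fit = cond_fit_sorted[inv_order] if (q or lam_fold > 0) else pop_fit

    # between-within denominator df: a column is "inner" if it varies
    # within at least one series.
    inner = np.zeros(p, dtype=bool)
    Xs = X[order]
    for j in range(p):
        dfm = pd.DataFrame({"s": ser_codes, "x": Xs[:, j]})
        inner[j] = bool((dfm.groupby("s")["x"].nunique() > 1).any())
    p_inner = int(inner.sum())
    p_outer = p - p_inner
    df_inner = max(n - n_series - p_inner, 1)
    df_outer = max(n_series - p_outer, 1)
    tvals = np.divide(beta, np.where(se > 0, se, np.inf))
    dfs, pvals = {}, {}
    for j, name in enumerate(x_names):
        dof = df_inner if inner[j] else df_outer
        dfs[name] = dof
        pvals[name] = float(2.0 * stats.t.sf(abs(tvals[j]), dof)) if se[j] > 0 else 0.0

    sds = {f: math.sqrt(lambdas[f] * sigma2) for f in factor_names}
    sds["residual"] = math.sqrt(sigma2)
    boundary = any(lambdas[f] <= LAMBDA_FLOOR * 1.01 for f in free_factors)
    reml_ll = -0.5 * (f + (n - p) * (1.0 + math.log(2.0 * math.pi)))

    fit = MixedFit(
        fixed_effects={nm: (float(beta[j]), float(se[j])) for j, nm in enumerate(x_names)},
        vcov_fixed=vcov,
        variance_components=sds,
        correlation=CorrelationSpec(phi=float(phi)),
        reml_loglik=float(reml_ll),
        fitted_values=cond_fit,
        residuals=y - cond_fit,
        x_names=list(x_names),
        beta=beta,
        t_values=tvals,
        p_values=pvals,
        df=dfs,
        n_obs=n,
        population_fitted=pop_fit,
        boundary=boundary,
        n_iter=n_iter,
    )
    fit._state = {
        "order": order,
        "inv_order": inv_order,
        "groups": groups,
        "phi": float(phi),
        "lambdas": dict(lambdas),
        "lam_fold": float(lam_fold),
        "dvec": dvec,
        "Z": Z,
        "X_sorted": Xs,
        "q": q,
        "n": n,
        "p": p,
    }
    return fit


def slope_weights(fit: MixedFit, coef: str) -> np.ndarray:
    """Row of the GLS hat ``(X'W^-1X)^-1 X'W^-1`` for one coefficient.

    The returned weight vector ``w`` (original observation order) gives the
    coefficient estimate as ``w @ y`` for any response fitted with the same
    design and covariance; it is the exact linear functional used for
    delta-method error propagation of prediction-trend contrasts.
    """
    st = fit._state
    j = fit.x_names.index(coef)
    order, groups, phi = st["order"], st["groups"], st["phi"]
    lam_fold = st["lam_fold"]
    X_s, Z, dvec, q, n, p = st["X_sorted"], st["Z"], st["dvec"], st["q"], st["n"], st["p"]
    B = np.concatenate([X_s, Z], axis=1)
    # V^-1 [X Z] via per-series Cholesky solves (V = AR(1) + folded J)
    VinvB = np.empty_like(B)
    for key, slices in groups.items():
        nt = len(key)
        if phi == 0.0 and lam_fold == 0.0:
            for stt, spp in slices:
                VinvB[stt:spp] = B[stt:spp]
            continue
        L = _block_chol(key, phi, lam_fold)
        for stt, spp in slices:
            tmp = linalg.solve_triangular(L, B[stt:spp], lower=True, check_finite=False)
            VinvB[stt:spp] = linalg.solve_triangular(
                L.T, tmp, lower=False, check_finite=False
            )
    VinvX = VinvB[:, :p]
    if q:
        VinvZ = VinvB[:, p:]
        dh = np.sqrt(dvec)
        U = np.eye(q) + (dh[:, None] * (Z.T @ VinvZ)) * dh[None, :]
        cU = linalg.cho_factor(U, lower=True)
        WinvX = VinvX - VinvZ * dh[None, :] @ linalg.cho_solve(cU, dh[:, None] * (Z.T @ VinvX))
    else:
        WinvX = VinvX
    XWX = X_s.T @ WinvX
    H = linalg.solve(XWX, WinvX.T)  # p x n
    w_sorted = H[j]
    w = np.empty(n)
    w[order] = w_sorted
    return w
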