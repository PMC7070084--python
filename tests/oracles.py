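"""Independent brute-force oracles used to validate the fast estimators.

Everything here deliberately uses naive dense linear algebra and generic
optimisers so that it shares no code path with the package's profiled,
Woodbury-based REML implementation.
"""

import itertools

import numpy as np
from scipy import linalg, optimize


def dense_marginal_cov(series, times, sigmas, phi, sigma_resid, factors):
    """Full n x n covariance: random intercepts + AR(1) within series."""
    series = np.asarray(series)
    times = np.asarray(times, dtype=float)
    n = len(series)
    same_series = series[:, None] == series[None, :]
    V = sigma_resid**2 * np.where(
        same_series, phi ** np.abs(times[:, None] - times[None, :]), 0.0
    )
    for name, codes in factors.items():
        codes = np.asarray(codes)
        V = V + sigmas[name] ** 2 * (codes[:, None] == codes[None, :])
    return V


def dense_gls(y, X, V):
    """Textbook GLS: beta = (X'V^-1X)^-1 X'V^-1 y."""
    Vi = linalg.inv(V)
    XtVi = X.T @ Vi
    return linalg.solve(XtVi @ X, XtVi @ y)


def dense_reml_neg2ll(y, X, V):
    n, p = X.shape
    sign, logdetV = np.linalg.slogdet(V)
    assert sign > 0
    Vi = linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    sign2, logdetXtViX = np.linalg.slogdet(XtViX)
    assert sign2 > 0
    return float(logdetV + logdetXtViX + r @ Vi @ r + (n - p) * np.log(2 * np.pi))


def brute_force_reml(y, X, series, times, factors, phi_grid=None):
    """Maximise the REML likelihood by grid search + simplex refinement.

    Parameters are the random-intercept SDs, the residual SD and phi,
    all unprofiled.  Returns (beta, params).  Only suitable for small n.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    names = list(factors)
    sd_y = float(np.std(y)) or 1.0
    phi_grid = phi_grid if phi_grid is not None else [0.0, 0.3, 0.6]
    sd_grid = [0.1 * sd_y, 0.5 * sd_y]

    def neg2ll(params):
        *log_sds, zeta = params
        sds = {nm: np.exp(ls) for nm, ls in zip(names, log_sds[:-1])}
        sigma_e = np.exp(log_sds[-1])
        phi = 0.99 / (1.0 + np.exp(-zeta))
        try:
            V = dense_marginal_cov(series, times, sds, phi, sigma_e, factors)
            return dense_reml_neg2ll(y, X, V)
        except (AssertionError, linalg.LinAlgError):
            return 1e30

    best = None
    for combo in itertools.product(sd_grid, repeat=len(names) + 1):
        for ph in phi_grid:
            zeta = np.log(max(ph, 1e-3) / (0.99 - max(ph, 1e-3)))
            x0 = np.concatenate([np.log(combo), [zeta]])
            res = optimize.minimize(
                neg2ll, x0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000, "maxfev": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
    *log_sds, zeta = best.x
    sds = {nm: float(np.exp(ls)) for nm, ls in zip(names, log_sds[:-1])}
    sigma_e = float(np.exp(log_sds[-1]))
    phi = float(0.99 / (1.0 + np.exp(-zeta)))
    V = dense_marginal_cov(series, times, sds, phi, sigma_e, factors)
    beta = dense_gls(y, X, V)
    return beta, {"sds": sds, "sigma_resid": sigma_e, "phi": phi, "neg2ll": float(best.fun)}


def exhaustive_theil_sen(times, values):
    """All-pairs slope enumeration, midpoint median convention."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    slopes = []
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t[j] != t[i]:
                slopes.append((v[j] - v[i]) / (t[j] - t[i]))
    slopes.sort()
    k = len(slopes)
    if k % 2:
        return slopes[k // 2]
    return 0.5 * (slopes[k // 2 - 1] + slopes[k // 2])


def fixed_effect_pool(effects, variances):
    """Inverse-variance weighted mean (tau^2 = 0)."""
    w = 1.0 / np.asarray(variances, float)
    return float(np.sum(w * np.asarray(effects, float)) / np.sum(w))
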