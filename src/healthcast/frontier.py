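"""Stochastic frontier linking pooled health spending to the UHC index.

The frontier model is

    log(uhc) = alpha + beta * log(pooled_pc) + v - u,

with symmetric noise ``v ~ N(0, sigma_v^2)`` and one-sided half-normal
inefficiency ``u ~ |N(0, sigma_u^2)|``.  The fitted upper envelope
``exp(alpha + beta * log(pooled_pc))`` is the attainable ("optimal") UHC index
at a given level of pooled spending; the composed residual separates
measurement noise from a country's efficiency gap.  Parameters are estimated
by maximum likelihood; per-observation inefficiency is recovered with the
conditional-mean (Jondrow et al.) estimator.

All country-years are pooled in a single frontier (no country effects), so
the envelope is set by the full range of peer countries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ComputationError, FitError
from .panel import pooled_spend_pc
from .scenarios import SCENARIOS, ScenarioSet

_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = -13.8, 5.0  # sigma in [~1e-6, ~150]


@dataclass
class FrontierFit:
    """Maximum-likelihood stochastic-frontier estimates."""

    alpha: float
    beta: float
    sigma_v: float
    sigma_u: float
    loglik: float
    u_hat: pd.Series                     # per (country, year) inefficiency, >= 0
    cov_params: np.ndarray | None = None # asymptotic covariance of (alpha, beta, log sv, log su)
    n_obs: int = 0

    def elasticity_pct_per_10pct(self) -> float:
        """Implied % increase in the UHC index per 10% more pooled spending."""
        return (1.10**self.beta - 1.0) * 100.0


@dataclass
class EfficiencyGapPath:
    """Historical and projected efficiency gaps (log-scale, >= 0)."""

    frame: pd.DataFrame  # columns: country, year, gap

    def gap(self, country: str, year: int) -> float:
        f = self.frame
        row = f[(f["country"] == country) & (f["year"] == year)]
        if row.empty:
            raise KeyError(f"no gap for ({country!r}, {year})")
        return float(row["gap"].iloc[0])


def _negloglik(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    alpha, beta, log_sv, log_su = theta
    sv, su = np.exp(log_sv), np.exp(log_su)
    sigma2 = sv * sv + su * su
    sigma = np.sqrt(sigma2)
    lam = su / sv
    eps = y - alpha - beta * x
    z = eps / sigma
    ll = (
        np.log(2.0)
        - np.log(sigma)
        + stats.norm.logpdf(z)
        + stats.norm.logcdf(-z * lam)
    )
    val = -np.sum(ll)
    return val if np.isfinite(val) else 1e12


def fit_half_normal_frontier(
    log_x: np.ndarray,
    log_y: np.ndarray,
    compute_cov: bool = True,
) -> tuple[float, float, float, float, float, np.ndarray | None]:
    """Fit the half-normal production frontier on (log x, log y) arrays.

    Returns (alpha, beta, sigma_v, sigma_u, loglik, cov) where cov is the
    asymptotic covariance of (alpha, beta, log sigma_v, log sigma_u).
    Starting values come from corrected OLS: the OLS residual skewness
    determines the initial inefficiency scale.
    """
    x = np.asarray(log_x, float)
    y = np.asarray(log_y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log_x and log_y must be 1-d arrays of equal length")
    n = len(x)
    if n < 10:
        raise FitError("too few observations for frontier estimation")

    X = np.column_stack([np.ones(n), x])
    ols_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ ols_coef
    m2 = np.mean(resid**2)
    m3 = np.mean(resid**3)
    # E[eps^3] = -sqrt(2/pi) (1 - 4/pi) sigma_u^3 for eps = v - u
    c3 = np.sqrt(2.0 / np.pi) * (1.0 - 4.0 / np.pi)
    su0 = np.cbrt(m3 / c3) if m3 < 0 else 0.1 * np.sqrt(m2)
    su0 = max(su0, 1e-4)
    sv0 = np.sqrt(max(m2 - (1.0 - 2.0 / np.pi) * su0**2, 1e-6))
    alpha0 = ols_coef[0] + su0 * np.sqrt(2.0 / np.pi)

    theta0 = np.array([alpha0, ols_coef[1], np.log(sv0), np.log(su0)])
    bounds = [(None, None), (None, None), (_LOG_SIGMA_MIN, _LOG_SIGMA_MAX), (_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    res = optimize.minimize(
        _negloglik, theta0, args=(x, y), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500},
    )
    # a second start with near-zero inefficiency guards against wrong-skew data
    theta_alt = np.array([ols_coef[0], ols_coef[1], 0.5 * np.log(max(m2, 1e-12)), _LOG_SIGMA_MIN + 1.0])
    res_alt = optimize.minimize(
        _negloglik, theta_alt, args=(x, y), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500},
    )
    if res_alt.fun < res.fun:
        res = res_alt
    if not np.isfinite(res.fun):
        raise FitError(f"frontier likelihood did not converge: {res.message}")

    alpha, beta, log_sv, log_su = res.x
    cov = None
    if compute_cov:
        try:
            from statsmodels.tools.numdiff import approx_hess1

            hess = approx_hess1(res.x, _negloglik, args=(x, y))
            cov = np.linalg.inv(hess)
        except Exception:
            cov = None
    return float(alpha), float(beta), float(np.exp(log_sv)), float(np.exp(log_su)), float(-res.fun), cov


def jlms_inefficiency(eps: np.ndarray, sigma_v: float, sigma_u: float) -> np.ndarray:
    """Conditional mean E[u | eps] for the half-normal composed error."""
    if sigma_u <= 0:
        return np.zeros_like(eps)
    sigma2 = sigma_v**2 + sigma_u**2
    mu_star = -eps * sigma_u**2 / sigma2
    s_star = sigma_u * sigma_v / np.sqrt(sigma2)
    z = mu_star / s_star
    return s_star * (stats.norm.pdf(z) / np.clip(stats.norm.cdf(z), 1e-300, None) + z)


def fit_sfa(panel: pd.DataFrame, compute_cov: bool = True) -> FrontierFit:
    """Fit the UHC frontier on all country-years of a historical panel."""
    pooled = pooled_spend_pc(panel)
    if (pooled <= 0).any():
        bad = panel.loc[pooled <= 0, ["country_id", "year"]].iloc[0]
        raise ComputationError(
            f"non-positive pooled spending for ({bad['country_id']!r}, {bad['year']})"
        )
    if (panel["uhc_index"] <= 0).any():
        raise ComputationError("UHC index must be positive for the log frontier")
    x = np.log(pooled.to_numpy())
    y = np.log(panel["uhc_index"].to_numpy())
    alpha, beta, sv, su, ll, cov = fit_half_normal_frontier(x, y, compute_cov=compute_cov)
    eps = y - alpha - beta * x
    u_hat = pd.Series(
        jlms_inefficiency(eps, sv, su),
        index=pd.MultiIndex.from_frame(panel[["country_id", "year"]]),
        name="u_hat",
    )
    return FrontierFit(
        alpha=alpha, beta=beta, sigma_v=sv, sigma_u=su, loglik=ll,
        u_hat=u_hat, cov_params=cov, n_obs=len(x),
    )


def predict_frontier(fit: FrontierFit, pooled_pc) -> np.ndarray | float:
    """Frontier (optimal) UHC index at given pooled spending per capita.

    ``exp(alpha + beta log(pooled_pc))`` capped at 100; strictly increasing in
    spending below the cap (for beta > 0).
    """
    arr = np.asarray(pooled_pc, dtype=float)
    if (arr <= 0).any():
        raise ComputationError("pooled spending must be positive")
    out = np.minimum(np.exp(fit.alpha + fit.beta * np.log(arr)), 100.0)
    return float(out) if np.isscalar(pooled_pc) or arr.ndim == 0 else out


def estimate_gap_trajectory(
    fit: FrontierFit,
    panel: pd.DataFrame,
    horizon: int,
    min_obs: int = 5,
    gap_floor: float = 1e-6,
) -> EfficiencyGapPath:
    """Project per-country efficiency gaps to ``horizon``.

    Each country's log gap is regressed on year; country slopes are shrunk
    toward the global precision-weighted mean slope (partial pooling), which
    stabilises short or noisy series.  Projections are carried out on the log
    scale, so gaps stay non-negative.  Countries with fewer than ``min_obs``
    gap observations keep their last observed gap, with a warning.
    """
    hist = fit.u_hat.rename("gap").reset_index()
    hist.columns = ["country", "year", "gap"]
    hist["gap"] = np.maximum(hist["gap"], gap_floor)

    stats_rows = []
    for country, grp in hist.groupby("country"):
        t = grp["year"].to_numpy(float)
        g = np.log(grp["gap"].to_numpy())
        if len(t) < min_obs or np.allclose(t, t[0]):
            stats_rows.append((country, np.nan, np.nan, np.inf, len(t)))
            continue
        tbar = t.mean()
        sxx = np.sum((t - tbar) ** 2)
        slope = np.sum((t - tbar) * (g - g.mean())) / sxx
        resid = g - g.mean() - slope * (t - tbar)
        dof = max(len(t) - 2, 1)
        var_slope = max(np.sum(resid**2) / dof / sxx, 1e-12)
        stats_rows.append((country, slope, g.mean() - slope * tbar, var_slope, len(t)))
    info = pd.DataFrame(
        stats_rows, columns=["country", "slope", "intercept", "var_slope", "n"]
    ).set_index("country")

    ok = info["var_slope"] < np.inf
    if ok.any():
        prec = 1.0 / info.loc[ok, "var_slope"]
        global_slope = float(np.average(info.loc[ok, "slope"], weights=prec))
        # between-country slope variance (method of moments, floored at 0)
        tau2 = max(
            float(np.average((info.loc[ok, "slope"] - global_slope) ** 2, weights=prec)
                  - np.mean(info.loc[ok, "var_slope"])),
            0.0,
        )
    else:
        global_slope, tau2 = 0.0, 0.0

    last_year = int(panel["year"].max())
    if horizon <= last_year:
        raise ComputationError("horizon must lie after the last observed year")
    future = np.arange(last_year + 1, horizon + 1)

    frames = [hist[["country", "year", "gap"]]]
    for country, row in info.iterrows():
        grp = hist[hist["country"] == country]
        last_gap = float(grp.sort_values("year")["gap"].iloc[-1])
        if not np.isfinite(row["slope"]):
            warnings.warn(f"{country}: too few gap observations; holding last gap constant")
            proj = np.full(len(future), last_gap)
        else:
            w = (1.0 / row["var_slope"]) / (1.0 / row["var_slope"] + (1.0 / tau2 if tau2 > 0 else np.inf))
            if tau2 == 0.0:
                w = 0.0 if row["var_slope"] > 0 else 1.0
            slope = w * row["slope"] + (1.0 - w) * global_slope
            log_last = np.log(last_gap)
            proj = np.exp(log_last + slope * (future - last_year))
        frames.append(pd.DataFrame({"country": country, "year": future, "gap": proj}))
    out = pd.concat(frames, ignore_index=True)
    out["gap"] = np.maximum(out["gap"], 0.0)
    return EfficiencyGapPath(out.sort_values(["country", "year"]).reset_index(drop=True))


def project_uhc_index(
    fit: FrontierFit,
    gaps: EfficiencyGapPath,
    pooled_scenarios: ScenarioSet,
) -> pd.DataFrame:
    """Scenario-conditional UHC index projections.

    ``UHC = clamp(frontier(pooled) * exp(-gap), 0, 100)`` per country-year and
    scenario.  With a common gap, more pooled spending never lowers the index,
    so the better/reference/worse ordering of spending carries over to UHC.

    Returns a frame with columns (country, year, reference, better, worse).
    """
    pooled = pooled_scenarios.frame
    pooled = pooled[pooled["component"].isin(["total", "pooled"])]
    gap_lut = gaps.frame.set_index(["country", "year"])["gap"]
    idx = pd.MultiIndex.from_frame(pooled[["country", "year"]])
    gap_vals = gap_lut.reindex(idx)
    if gap_vals.isna().any():
        missing = idx[gap_vals.isna().to_numpy()][0]
        raise ComputationError(f"no efficiency gap for {missing}; alignment error")
    out = pooled[["country", "year"]].copy()
    for col in SCENARIOS:
        frontier_val = predict_frontier(fit, pooled[col].to_numpy())
        out[col] = np.clip(frontier_val * np.exp(-gap_vals.to_numpy()), 0.0, 100.0)
    return out.reset_index(drop=True)
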