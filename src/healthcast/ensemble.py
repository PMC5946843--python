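"""Ensemble growth-model engine.

GDP and the spending shares are projected with an ensemble: a grid of
candidate regressions that differ in (a) which demographic/socioeconomic
covariates enter, (b) how strongly recent years are weighted, and (c) the
AR/MA order of the residual process.  Candidates are fitted on the growth
(log-difference, or logit-difference for shares) scale, screened by three
exclusion rules — any non-significant covariate (p > 0.10), a positive
convergence coefficient, or mean predictions outside historical growth
bounds — then ranked by out-of-sample RMSE and pooled: Monte-Carlo draws are
allocated across retained models proportionally to 1/RMSE^2, each model's
draws sampled from the asymptotic posterior of its coefficients.

The five modelled targets, in the order they feed each other:

* ``gdp_growth``            — growth of log GDP per capita;
* ``govspend_share_gdp``    — government spending as a share of GDP;
* ``ghes_share_gov``        — government health spending as a share of the
  government budget;
* ``ppp_share_gdp``         — prepaid private health spending / GDP;
* ``oop_share_gdp``         — out-of-pocket health spending / GDP.

Shares are modelled on the logit scale and back-transformed, guaranteeing
(0, 1).  The convergence term is always the 1-year lag of the
(non-differenced) dependent variable, so richer or higher-share countries can
grow more slowly.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .draws import DrawSet
from .errors import ConfigError, FitError, PoolingError
from .panel import COVARIATE_COLUMNS

#: Recency-weight profiles: exponential decay exp(-lambda * (T - t)).
WEIGHT_SCHEMES: dict[str, float] = {
    "equal": 0.0,
    "decay05": 0.05,
    "decay10": 0.10,
    "decay20": 0.20,
}

TARGETS = [
    "gdp_growth",
    "govspend_share_gdp",
    "ghes_share_gov",
    "ppp_share_gdp",
    "oop_share_gdp",
]

CONVERGENCE = "convergence_term"
_ALLOWED_COVARIATES = set(COVARIATE_COLUMNS) | {CONVERGENCE}

P_VALUE_CUTOFF = 0.10


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def target_level_frame(panel: pd.DataFrame, target: str) -> pd.DataFrame:
    """Country x year frame of the modelling-scale level for a target."""
    gdp = panel["gdp_pc"]
    if target == "gdp_growth":
        level = np.log(gdp)
    elif target == "govspend_share_gdp":
        level = _logit(panel["gov_spend"] / (gdp * panel["population"]))
    elif target == "ghes_share_gov":
        level = _logit(panel["ghes_pc"] * panel["population"] / panel["gov_spend"])
    elif target == "ppp_share_gdp":
        level = _logit(panel["ppp_pc"] / gdp)
    elif target == "oop_share_gdp":
        level = _logit(panel["oop_pc"] / gdp)
    else:
        raise ConfigError(f"unknown target {target!r}")
    work = panel[["country_id", "year"]].copy()
    work["level"] = np.asarray(level, float)
    return work.pivot(index="country_id", columns="year", values="level")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the ensemble grid."""

    target: str
    covariates: tuple[str, ...]
    weight_scheme: str = "equal"
    ar_order: int = 0
    ma_order: int = 0

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ConfigError(f"unknown target {self.target!r}")
        bad = [c for c in self.covariates if c not in _ALLOWED_COVARIATES]
        if bad:
            raise ConfigError(f"unknown covariate(s) {bad}")
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ConfigError(f"unknown weight scheme {self.weight_scheme!r}")
        if self.ar_order not in (0, 1, 2, 3) or self.ma_order not in (0, 1, 2, 3):
            raise ConfigError("ar_order and ma_order must be in {0, 1, 2, 3}")

    def stable_hash(self) -> int:
        return zlib.crc32(repr(self).encode())


@dataclass
class FittedCandidate:
    """A fitted grid cell with its diagnostics and forecasting state."""

    spec: ModelSpec
    columns: list[str]                 # const + covariates, design order
    coefficients: np.ndarray
    cov_params: np.ndarray
    p_values: np.ndarray               # aligned with columns
    convergence_coef: float | None
    phi: np.ndarray                    # AR coefficients of the residual process
    theta: np.ndarray                  # MA coefficients
    sigma2: float                      # innovation variance
    oos_rmse: float
    oos_sd_by_country: pd.Series
    pred_min: float                    # min/max of the mean forecast path
    pred_max: float
    in_bounds: bool | None = None
    drop_reason: str | None = None
    # forecasting state
    last_level: pd.Series = field(repr=False, default=None)
    last_cov: pd.DataFrame = field(repr=False, default=None)
    resid_tail: dict = field(repr=False, default_factory=dict)
    innov_tail: dict = field(repr=False, default_factory=dict)

    @property
    def covariate_p_values(self) -> pd.Series:
        """Two-sided p-values of the non-constant regressors."""
        s = pd.Series(self.p_values, index=self.columns)
        return s.drop("const")


def build_model_grid(
    covariate_subsets: Sequence[Sequence[str]],
    weight_schemes: Sequence[str],
    ar_orders: Sequence[int],
    ma_orders: Sequence[int],
    target: str,
) -> list[ModelSpec]:
    """Full factorial grid over the four specification dimensions.

    Grid size is the product of the dimension cardinalities; ordering is the
    deterministic itertools product order.
    """
    dims = {
        "covariate_subsets": list(covariate_subsets),
        "weight_schemes": list(weight_schemes),
        "ar_orders": list(ar_orders),
        "ma_orders": list(ma_orders),
    }
    for name, values in dims.items():
        if len(values) == 0:
            raise ConfigError(f"grid dimension {name!r} is empty")
    return [
        ModelSpec(
            target=target,
            covariates=tuple(subset),
            weight_scheme=w,
            ar_order=p,
            ma_order=q,
        )
        for subset, w, p, q in itertools.product(
            dims["covariate_subsets"], dims["weight_schemes"],
            dims["ar_orders"], dims["ma_orders"],
        )
    ]


def default_grid(target: str) -> list[ModelSpec]:
    """All subsets of the four demographic covariates, each with the
    convergence term, crossed with the four weight schemes and AR/MA orders
    0-3 (16 x 4 x 4 x 4 = 1024 specs per target)."""
    subsets = []
    for r in range(len(COVARIATE_COLUMNS) + 1):
        for combo in itertools.combinations(COVARIATE_COLUMNS, r):
            subsets.append(tuple(combo) + (CONVERGENCE,))
    return build_model_grid(subsets, list(WEIGHT_SCHEMES), [0, 1, 2, 3], [0, 1, 2, 3], target)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _design(panel: pd.DataFrame, spec: ModelSpec, drop_last_years: int = 0):
    """Stacked growth-scale design across countries.

    Returns (frame, columns) where frame has country, year, y, weight and one
    column per regressor (const first).
    """
    levels = target_level_frame(panel, spec.target)
    cov_wide = {
        c: panel.pivot(index="country_id", columns="year", values=c)
        for c in spec.covariates
        if c != CONVERGENCE
    }
    years = levels.columns.to_numpy()
    T_year = years[-1 - drop_last_years] if drop_last_years else years[-1]
    lam = WEIGHT_SCHEMES[spec.weight_scheme]

    rows = []
    lv = levels.to_numpy()
    for i, country in enumerate(levels.index):
        for j in range(1, len(years)):
            year = years[j]
            if drop_last_years and year > T_year:
                continue
            rec = {
                "country": country,
                "year": year,
                "y": lv[i, j] - lv[i, j - 1],
                "weight": np.exp(-lam * (T_year - year)),
                "const": 1.0,
            }
            for c in spec.covariates:
                if c == CONVERGENCE:
                    rec[c] = lv[i, j - 1]
                else:
                    rec[c] = cov_wide[c].iloc[i, j]
            rows.append(rec)
    frame = pd.DataFrame(rows)
    columns = ["const"] + list(spec.covariates)
    return frame, columns


def _wls(frame: pd.DataFrame, columns: list[str]):
    """Weighted least squares with two-sided t-test p-values."""
    X = frame[columns].to_numpy(float)
    y = frame["y"].to_numpy(float)
    w = frame["weight"].to_numpy(float)
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T) if X.shape[1] > 2 else None
        raise FitError(f"rank-deficient design; collinear covariates among {columns[1:]}")
    coef, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(np.sum(w * resid**2) / dof)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    cov = s2 * XtX_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return coef, cov, pvals, resid


def _arma_css(resid_series: list[np.ndarray], p: int, q: int):
    """Conditional-sum-of-squares ARMA(p, q) fit on stacked residual series.

    The innovations filter restarts at each country boundary, so the residual
    process is within-country only.
    """
    if p + q == 0:
        e = np.concatenate(resid_series)
        return np.zeros(0), np.zeros(0), float(np.var(e))

    def innovations(params):
        phi, theta = params[:p], params[p:]
        out = []
        for r in resid_series:
            e = np.zeros(len(r))
            for t in range(len(r)):
                acc = r[t]
                for i in range(min(p, t)):
                    acc -= phi[i] * r[t - 1 - i]
                for j in range(min(q, t)):
                    acc -= theta[j] * e[t - 1 - j]
                e[t] = acc
            out.append(e)
        return np.concatenate(out)

    res = optimize.least_squares(
        innovations, x0=np.zeros(p + q), bounds=(-0.98, 0.98), xtol=1e-8
    )
    e = innovations(res.x)
    return res.x[:p].copy(), res.x[p:].copy(), float(np.var(e))


def _forecast_growth(
    fit: "FittedCandidate", n_years: int, coef: np.ndarray | None = None
) -> pd.DataFrame:
    """Mean forecast of the growth-scale dependent variable.

    Covariates are held at their last observed values (simple continuation);
    the convergence term updates dynamically with the projected level; the
    ARMA residual forecast decays from the last observed residuals.
    Returns country x step frame of growth values.
    """
    coef = fit.coefficients if coef is None else coef
    countries = fit.last_level.index
    p, q = len(fit.phi), len(fit.theta)
    out = np.empty((len(countries), n_years))
    for i, country in enumerate(countries):
        level = float(fit.last_level.loc[country])
        r_hist = list(fit.resid_tail.get(country, []))
        e_hist = list(fit.innov_tail.get(country, []))
        x_static = {}
        for c in fit.columns:
            if c in (CONVERGENCE, "const"):
                continue
            x_static[c] = float(fit.last_cov.loc[country, c])
        for h in range(n_years):
            x = np.array(
                [
                    1.0 if c == "const" else (level if c == CONVERGENCE else x_static[c])
                    for c in fit.columns
                ]
            )
            g = float(x @ coef)
            r_hat = 0.0
            for a in range(p):
                if len(r_hist) > a:
                    r_hat += fit.phi[a] * r_hist[-1 - a]
            for b in range(q):
                if len(e_hist) > b:
                    r_hat += fit.theta[b] * e_hist[-1 - b]
            g += r_hat
            out[i, h] = g
            level += g
            r_hist.append(r_hat)
            e_hist.append(0.0)  # future innovations are zero in the mean path
    return pd.DataFrame(out, index=countries)


def fit_candidate(
    panel: pd.DataFrame,
    spec: ModelSpec,
    holdout_years: int = 5,
    forecast_horizon: int = 25,
) -> FittedCandidate:
    """Fit one candidate: WLS on the growth scale, ARMA residuals, holdout RMSE.

    The out-of-sample protocol refits the mean model with the last
    ``holdout_years`` observed years held out per country and scores one-step
    predictions on the holdout; the per-country holdout residual sd feeds the
    random-walk noise stage.
    """
    frame, columns = _design(panel, spec)
    n_params = len(columns)
    if len(frame) < n_params + 3:
        raise FitError(f"too few observations ({len(frame)}) for {n_params} parameters")
    coef, cov, pvals, resid = _wls(frame, columns)

    frame = frame.assign(resid=resid)
    resid_series = [g["resid"].to_numpy() for _, g in frame.groupby("country", sort=True)]
    phi, theta, sigma2 = _arma_css(resid_series, spec.ar_order, spec.ma_order)

    # residuals net of the ARMA one-step prediction feed the forecast state
    conv_coef = None
    if CONVERGENCE in columns:
        conv_coef = float(coef[columns.index(CONVERGENCE)])

    levels = target_level_frame(panel, spec.target)
    last_level = levels.iloc[:, -1].rename("last_level")
    cov_cols = [c for c in columns if c not in ("const", CONVERGENCE)]
    if cov_cols:
        last_cov = panel.sort_values("year").groupby("country_id")[cov_cols].last()
    else:
        last_cov = pd.DataFrame(index=last_level.index)
    tail = max(spec.ar_order, spec.ma_order, 1)
    resid_tail, innov_tail = {}, {}
    for (country, g) in frame.groupby("country", sort=True):
        r = g.sort_values("year")["resid"].to_numpy()
        resid_tail[country] = r[-tail:]
        innov_tail[country] = r[-tail:]  # CSS innovations ~ residuals at the tail

    # out-of-sample: refit without the last `holdout_years`, score one-step
    train, tcols = _design(panel, spec, drop_last_years=holdout_years)
    if len(train) < n_params + 3:
        raise FitError("holdout leaves too few training observations")
    coef_t, _, _, _ = _wls(train, tcols)
    holdout = frame[~frame.set_index(["country", "year"]).index.isin(
        train.set_index(["country", "year"]).index
    )]
    Xh = holdout[columns].to_numpy(float)
    resid_h = holdout["y"].to_numpy() - Xh @ coef_t
    oos_rmse = float(np.sqrt(np.mean(resid_h**2)))
    oos_sd = (
        holdout.assign(r2=resid_h**2).groupby("country")["r2"].mean().pow(0.5)
    )

    cand = FittedCandidate(
        spec=spec,
        columns=columns,
        coefficients=coef,
        cov_params=cov,
        p_values=pvals,
        convergence_coef=conv_coef,
        phi=phi,
        theta=theta,
        sigma2=sigma2,
        oos_rmse=oos_rmse,
        oos_sd_by_country=oos_sd,
        pred_min=np.nan,
        pred_max=np.nan,
        last_level=last_level,
        last_cov=last_cov,
        resid_tail=resid_tail,
        innov_tail=innov_tail,
    )
    path = _forecast_growth(cand, forecast_horizon)
    cand.pred_min = float(path.to_numpy().min())
    cand.pred_max = float(path.to_numpy().max())
    return cand


# ---------------------------------------------------------------------------
# exclusion, ranking, pooling
# ---------------------------------------------------------------------------

def historical_growth_bounds(panel: pd.DataFrame, target: str = "gdp_growth") -> tuple[float, float]:
    """Observed (min, max) of a target's growth/difference series in the panel."""
    levels = target_level_frame(panel, target)
    growth = np.diff(levels.to_numpy(), axis=1)
    return float(growth.min()), float(growth.max())


def apply_exclusion_rules(
    fits: Iterable[FittedCandidate],
    hist_bounds: tuple[float, float],
) -> tuple[list[FittedCandidate], pd.DataFrame]:
    """Screen candidates by the three exclusion rules, in order.

    1. ``p_value``          — any covariate with p > 0.10;
    2. ``convergence_sign`` — convergence coefficient greater than zero;
    3. ``bounds``           — mean predictions outside historical growth bounds.

    Each dropped model carries exactly one primary reason (the first rule it
    violates).  An empty retained list is a legal outcome.  Idempotent:
    re-screening the retained list changes nothing.
    """
    lo, hi = hist_bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ConfigError("historical bounds must be finite with min < max")
    retained, report = [], []
    for fit in fits:
        reason = None
        if (fit.covariate_p_values > P_VALUE_CUTOFF).any():
            reason = "p_value"
        elif fit.convergence_coef is not None and fit.convergence_coef > 0:
            reason = "convergence_sign"
        elif fit.pred_min < lo or fit.pred_max > hi:
            reason = "bounds"
        fit.in_bounds = lo <= fit.pred_min and fit.pred_max <= hi
        fit.drop_reason = reason
        report.append({"spec": repr(fit.spec), "retained": reason is None, "reason": reason})
        if reason is None:
            retained.append(fit)
    return retained, pd.DataFrame(report)


def pooling_weights(retained: Sequence[FittedCandidate]) -> np.ndarray:
    """Model weights proportional to 1 / oos_rmse^2 (perfect fits split all weight)."""
    rmse = np.array([f.oos_rmse for f in retained], float)
    if (rmse <= 1e-12).any():
        w = (rmse <= 1e-12).astype(float)
    else:
        w = 1.0 / rmse**2
    return w / w.sum()


def allocate_draws(weights: np.ndarray, n_draws: int) -> np.ndarray:
    """Largest-remainder allocation of ``n_draws`` across models."""
    weights = np.asarray(weights, float)
    ideal = weights / weights.sum() * n_draws
    counts = np.floor(ideal).astype(int)
    short = n_draws - counts.sum()
    if short > 0:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def rank_and_pool(
    retained: Sequence[FittedCandidate],
    panel: pd.DataFrame,
    n_draws: int,
    horizon: int,
    seed: int = 0,
) -> DrawSet:
    """Pool retained models into a draw-level growth forecast.

    Draws are allocated across models by ``pooling_weights`` with
    largest-remainder rounding; each model's draws are mean forecasts under
    coefficient vectors sampled from the model's asymptotic posterior
    N(coef, cov).  Output cells are (country, forecast year, target) on the
    growth/difference scale.  Both the per-model substreams and the output
    column order are keyed by a stable hash of the spec, so the pooled
    distribution does not depend on the order of the retained list.
    """
    retained = list(retained)
    if not retained:
        raise PoolingError(
            "retained set is empty; fall back to the intercept-plus-convergence model"
        )
    last_year = int(panel["year"].max())
    if horizon <= last_year:
        raise ConfigError("horizon must lie after the last observed year")
    n_years = horizon - last_year
    years = list(range(last_year + 1, horizon + 1))

    order = np.argsort([f.spec.stable_hash() for f in retained], kind="stable")
    retained = [retained[i] for i in order]
    weights = pooling_weights(retained)
    counts = allocate_draws(weights, n_draws)

    target = retained[0].spec.target
    countries = list(retained[0].last_level.index)
    blocks = []
    for fit, m in zip(retained, counts):
        if m == 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, fit.spec.stable_hash()]))
        cov = fit.cov_params
        if not np.any(cov):
            chol = np.zeros_like(cov)  # degenerate model: point predictions
        else:
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                try:
                    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
                except np.linalg.LinAlgError:
                    chol = np.zeros_like(cov)
        block = np.empty((len(countries), n_years, m))
        for d in range(m):
            coef = fit.coefficients + chol @ rng.standard_normal(len(fit.coefficients))
            block[:, :, d] = _forecast_growth(fit, n_years, coef=coef).to_numpy()
        blocks.append(block)
    values = np.concatenate(blocks, axis=2)
    return DrawSet.from_array(values, countries, years, target)


# ---------------------------------------------------------------------------
# chaining and noise
# ---------------------------------------------------------------------------

def _project_population(panel: pd.DataFrame, years: list[int]) -> pd.DataFrame:
    """Log-linear continuation of each country's population series."""
    wide = panel.pivot(index="country_id", columns="year", values="population")
    t = wide.columns.to_numpy(float)
    logp = np.log(wide.to_numpy())
    tbar = t.mean()
    slope = ((t - tbar) * (logp - logp.mean(axis=1, keepdims=True))).sum(axis=1) / np.sum(
        (t - tbar) ** 2
    )
    last = logp[:, -1]
    h = np.asarray(years, float) - t[-1]
    return pd.DataFrame(np.exp(last[:, None] + slope[:, None] * h[None, :]),
                        index=wide.index, columns=years)


def project_chain(
    panel: pd.DataFrame,
    draws_by_target: Mapping[str, DrawSet],
    horizon: int,
) -> DrawSet:
    """Turn growth-scale draws into spending-level draws, in sequence.

    GDP draws come first; the share models are then applied multiplicatively,
    so the accounting identities hold exactly within every draw:
    ``gov_spend = share x GDP``, ``ghes = share x gov_spend``,
    ``oop = share x GDP``, ``ppp = share x GDP`` and
    ``total = ghes + ppp + oop`` per capita (DAH is added downstream).
    """
    last_year = int(panel["year"].max())
    if horizon <= last_year:
        raise ConfigError("horizon must lie after the last observed year")
    missing = [t for t in TARGETS if t not in draws_by_target]
    if missing:
        raise ConfigError(f"missing draws for target(s) {missing}")
    years = list(range(last_year + 1, horizon + 1))

    def _levels(target):
        ds = draws_by_target[target]
        arr, countries, ds_years = ds.array(target)
        if ds_years[: len(years)] != years[: len(ds_years)] or len(ds_years) < len(years):
            raise ConfigError(f"draws for {target!r} do not cover the horizon")
        arr = arr[:, : len(years), :]
        levels0 = target_level_frame(panel, target).loc[countries].iloc[:, -1].to_numpy()
        return levels0[:, None, None] + np.cumsum(arr, axis=1), countries

    log_gdp, countries = _levels("gdp_growth")
    gdp_pc = np.exp(log_gdp)
    shares = {}
    for t in TARGETS[1:]:
        lv, c2 = _levels(t)
        if c2 != countries:
            raise ConfigError(f"country sets differ between gdp_growth and {t!r}")
        shares[t] = _expit(lv)

    pop = _project_population(panel, years).loc[countries].to_numpy()[:, :, None]
    gov_spend = shares["govspend_share_gdp"] * gdp_pc * pop
    ghes_pc = shares["ghes_share_gov"] * gov_spend / pop
    ppp_pc = shares["ppp_share_gdp"] * gdp_pc
    oop_pc = shares["oop_share_gdp"] * gdp_pc
    total_pc = ghes_pc + ppp_pc + oop_pc

    parts = [
        DrawSet.from_array(gdp_pc, countries, years, "gdp_pc"),
        DrawSet.from_array(gov_spend, countries, years, "gov_spend"),
        DrawSet.from_array(ghes_pc, countries, years, "ghes_pc"),
        DrawSet.from_array(ppp_pc, countries, years, "ppp_pc"),
        DrawSet.from_array(oop_pc, countries, years, "oop_pc"),
        DrawSet.from_array(total_pc, countries, years, "total_pc"),
    ]
    return DrawSet.concat(parts)


def add_random_walk_noise(
    draws: DrawSet,
    oos_residual_sd,
    seed: int = 0,
    cumulative: bool = True,
) -> DrawSet:
    """Add first-order random-walk noise to draw-level projections.

    Independent N(0, sd_c^2) increments accumulate over the forecast years, so
    the cross-draw variance contributed at horizon h is h * sd_c^2; countries
    whose sub-models fit the observed data poorly (larger holdout residual sd)
    get the widest intervals.  ``oos_residual_sd`` may be a scalar or a
    per-country mapping/Series; sd = 0 leaves the draws untouched.

    Pass ``cumulative=False`` when ``draws`` are growth *increments* that a
    later stage will cumulate into levels: the raw increments are then added
    un-cumulated, so the implied level path — not the growth path — carries
    the random walk.
    """
    if np.isscalar(oos_residual_sd):
        if oos_residual_sd < 0:
            raise ConfigError("noise sd must be non-negative")
        sd_lookup = None
        sd_scalar = float(oos_residual_sd)
    else:
        sd_series = pd.Series(oos_residual_sd, dtype=float)
        if (sd_series < 0).any():
            raise ConfigError("noise sd must be non-negative")
        sd_lookup, sd_scalar = sd_series, None

    rng = np.random.default_rng(seed)
    out_frames = []
    for quantity in draws.quantities:
        arr, countries, years = draws.sel(quantity=quantity).array(quantity)
        noisy = arr.copy()
        for i, country in enumerate(sorted(countries)):
            ci = countries.index(country)
            sd = sd_scalar if sd_lookup is None else float(sd_lookup.get(country, 0.0))
            if sd == 0.0:
                continue
            steps = rng.standard_normal((len(years), arr.shape[2])) * sd
            noisy[ci] = arr[ci] + (np.cumsum(steps, axis=0) if cumulative else steps)
        out_frames.append(DrawSet.from_array(noisy, countries, years, quantity))
    return DrawSet.concat(out_frames)


def intercept_convergence_fallback(
    panel: pd.DataFrame, target: str, holdout_years: int = 5
) -> FittedCandidate:
    """The fallback model used when every grid candidate is excluded."""
    spec = ModelSpec(target=target, covariates=(CONVERGENCE,))
    return fit_candidate(panel, spec, holdout_years=holdout_years)
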