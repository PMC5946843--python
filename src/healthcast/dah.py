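"""Development assistance for health (DAH): sources, recipients, transition.

DAH is projected in three steps.  Sources that are national treasuries
("state" sources) provide a share of their government spending, so their
future DAH inherits the government-spending projection; sources without an
associated economy (foundations, corporate donors) are forecast with ARIMA
models and no covariates.  The total provided is then allocated to recipient
countries by annual shares, and recipients whose GDP per capita crosses the
World Bank high-income threshold ($13,741 per capita, 2017 PPP) stop
receiving assistance from the crossing year onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .draws import DrawSet
from .errors import AllocationError, ConfigError, FitError

HIGH_INCOME_THRESHOLD = 13741.0


@dataclass
class DahSourceSeries:
    """Annual provided amounts for one DAH source."""

    source_id: str
    kind: str                      # "state" | "non_state"
    years: list[int]
    amounts: np.ndarray
    donor_country: str = ""
    share_of_gov: float | None = None  # state sources: share of donor gov spending


@dataclass
class DahNetwork:
    """Source series plus recipient shares.

    ``sources`` columns: source_id, kind, donor_country, share_of_gov, year,
    amount.  ``recipient_shares`` columns: country, year, share; shares lie in
    [0, 1] and sum to one over eligible recipients in every year.
    """

    sources: pd.DataFrame
    recipient_shares: pd.DataFrame
    transition_threshold: float = HIGH_INCOME_THRESHOLD

    def __post_init__(self):
        s = self.recipient_shares
        if ((s["share"] < -1e-12) | (s["share"] > 1 + 1e-12)).any():
            raise AllocationError("recipient shares must lie in [0, 1]")
        sums = s.groupby("year")["share"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)]
            raise AllocationError(f"recipient shares do not sum to 1 in year(s) {list(bad.index)}")

    def source_series(self, source_id: str) -> DahSourceSeries:
        sub = self.sources[self.sources["source_id"] == source_id].sort_values("year")
        if sub.empty:
            raise KeyError(f"unknown source {source_id!r}")
        share = sub["share_of_gov"].iloc[0]
        return DahSourceSeries(
            source_id=source_id,
            kind=sub["kind"].iloc[0],
            years=sub["year"].astype(int).tolist(),
            amounts=sub["amount"].to_numpy(float),
            donor_country=sub["donor_country"].iloc[0],
            share_of_gov=None if pd.isna(share) else float(share),
        )

    def totals_by_year(self) -> pd.Series:
        return self.sources.groupby("year")["amount"].sum()


def project_source_dah(
    source: DahSourceSeries,
    gov_spend_draws: DrawSet,
    share_draws: DrawSet | None = None,
) -> DrawSet:
    """Project a state source's DAH as a share of its government spending.

    Per draw and year, DAH = share x government spending.  The share path may
    itself carry uncertainty (``share_draws``, e.g. produced by the ensemble
    engine on the logit scale); if omitted, the source's constant
    ``share_of_gov`` is used.
    """
    if source.kind != "state":
        raise ConfigError(f"source {source.source_id!r} is not a state source")
    try:
        gov = gov_spend_draws.sel(quantity="gov_spend", country=source.donor_country)
    except KeyError as exc:
        raise ConfigError(
            f"no government-spending draws for donor {source.donor_country!r}"
        ) from exc
    values = gov.frame.to_numpy()
    if share_draws is not None:
        sh = share_draws.sel(country=source.donor_country)
        if sh.frame.shape != values.shape:
            raise ConfigError("share draws are not aligned with government-spending draws")
        values = values * sh.frame.to_numpy()
    else:
        if source.share_of_gov is None:
            raise ConfigError(f"state source {source.source_id!r} lacks a share_of_gov")
        values = values * source.share_of_gov
    index = pd.MultiIndex.from_arrays(
        [
            [source.source_id] * values.shape[0],
            gov.frame.index.get_level_values("year"),
            ["dah_provided"] * values.shape[0],
        ],
        names=["country", "year", "quantity"],
    )
    return DrawSet(pd.DataFrame(values, index=index))


def forecast_nonstate_source(
    series: np.ndarray | pd.Series,
    horizon: int,
    order: tuple[int, int, int] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    source_id: str = "nonstate",
    first_forecast_year: int | None = None,
) -> DrawSet:
    """Forecast a non-state DAH source with an ARIMA model (no covariates).

    Parameters
    ----------
    series
        Historical annual amounts (length >= 8).
    horizon
        Number of future years to forecast.
    order
        ARIMA (p, d, q).  If None, a small grid p, q <= 2, d <= 1 is searched
        by AIC.  A fit that fails to converge falls back to a (0, 1, 0)
        random walk with a warning.
    """
    from statsmodels.tsa.arima.model import ARIMA

    y = np.asarray(series, dtype=float)
    if len(y) < 8:
        raise ConfigError("non-state source series must have at least 8 observations")
    if horizon < 1:
        raise ConfigError("horizon must be at least one year")

    def _fit(o):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ARIMA(y, order=o, trend="c" if o[1] == 0 else "n")
            return model.fit(method_kwargs={"maxiter": 200})

    res = None
    if order is not None:
        try:
            res = _fit(order)
        except Exception:
            res = None
    else:
        best_aic = np.inf
        for d in (0, 1):
            for p in (0, 1, 2):
                for q in (0, 1, 2):
                    try:
                        cand = _fit((p, d, q))
                    except Exception:
                        continue
                    if np.isfinite(cand.aic) and cand.aic < best_aic:
                        best_aic, res = cand.aic, cand
    if res is None:
        warnings.warn("ARIMA fit failed; falling back to a (0,1,0) random walk")
        res = _fit((0, 1, 0))

    fc = res.get_forecast(steps=horizon)
    mean = np.asarray(fc.predicted_mean, dtype=float)
    se = np.asarray(fc.se_mean, dtype=float)
    se = np.where(np.isfinite(se), se, 0.0)
    rng = np.random.default_rng(seed)
    draws = mean[:, None] + se[:, None] * rng.standard_normal((horizon, n_draws))
    start = first_forecast_year if first_forecast_year is not None else len(y)
    years = list(range(start, start + horizon))
    return DrawSet.from_array(draws[None, :, :], [source_id], years, "dah_provided")


def allocate_recipient_dah(total_dah: DrawSet, shares: pd.DataFrame) -> DrawSet:
    """Split total provided DAH across recipients by annual shares.

    ``shares`` has columns (country, year, share); shares must sum to one per
    year to within 1e-9.  Conservation holds by construction: the per-year,
    per-draw sum over recipients equals the total provided.
    """
    sums = shares.groupby("year")["share"].sum()
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise AllocationError("recipient shares must sum to 1 each year")
    totals = total_dah.frame.groupby(level="year").sum()  # (year, draw)
    years = totals.index.to_numpy()
    sub = shares[shares["year"].isin(years)]
    share_wide = sub.pivot(index="country", columns="year", values="share").fillna(0.0)
    share_wide = share_wide.reindex(columns=years, fill_value=0.0)
    values = share_wide.to_numpy()[:, :, None] * totals.to_numpy()[None, :, :]
    return DrawSet.from_array(values, list(share_wide.index), list(years), "dah")


def apply_income_transition(
    recipient_draws: DrawSet,
    gdp_pc_draws: DrawSet,
    threshold: float = HIGH_INCOME_THRESHOLD,
    renormalize: bool = True,
) -> DrawSet:
    """Zero out DAH once a recipient's GDP per capita crosses the threshold.

    The transition is evaluated within each draw on that draw's GDP path and
    is absorbing: once GDP per capita exceeds the threshold, DAH stays zero
    even if the path later dips below.  With ``renormalize=True`` the freed
    amounts are redistributed proportionally over remaining eligible
    recipients so that conservation holds over the eligible set.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    dah, countries, years = recipient_draws.array("dah")
    gdp_all, gdp_countries, gdp_years = gdp_pc_draws.array("gdp_pc")
    gdp = pd.DataFrame(
        gdp_all.reshape(len(gdp_countries), -1),
        index=gdp_countries,
    )
    missing = [c for c in countries if c not in gdp.index]
    if missing or gdp_years != years:
        raise ConfigError(f"GDP draws not aligned with recipients (missing {missing[:3]})")
    gdp_arr = gdp.loc[countries].to_numpy().reshape(len(countries), len(years), -1)
    if gdp_arr.shape[2] != dah.shape[2]:
        raise ConfigError("GDP and DAH draw counts differ")

    crossed = np.maximum.accumulate(gdp_arr > threshold, axis=1)  # absorbing
    out = np.where(crossed, 0.0, dah)
    if renormalize:
        total_before = dah.sum(axis=0)          # (year, draw)
        total_after = out.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(total_after > 0, total_before / total_after, 0.0)
        out = out * scale[None, :, :]
    return DrawSet.from_array(out, countries, years, "dah")
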