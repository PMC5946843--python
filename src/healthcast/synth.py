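"""Synthetic country-panel and DAH-network generator.

Downstream stages (ensemble growth models, scenario construction, the
stochastic UHC frontier, DAH allocation) are all estimators with known
generative counterparts.  This module generates panels whose structure matches
the assumptions of those estimators, so that every stage can be tested by
parameter recovery without any external data:

* log GDP per capita follows growth with convergence:
  ``growth_t = mu_c + beta_convergence * log(gdp_pc)_{t-1} + noise``;
* spending-source shares are drawn on the logit scale, guaranteeing (0, 1);
* the UHC index sits below a log-log frontier of pooled spending per capita
  with symmetric noise ``v`` and one-sided half-normal inefficiency ``u``:
  ``uhc = clamp(exp(a + b*log(pooled_pc) + v - u), 0, 100)``;
* development assistance flows from a small set of sources (state sources as
  stable shares of their government spending, non-state sources as stationary
  series) to recipients whose shares sum to one each year.

A fixed seed fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dah import DahNetwork
from .errors import ConfigError, GenerationError
from .panel import validate_panel

INCOME_GROUPS = ["low", "lower_middle", "upper_middle", "high"]
SUPER_REGIONS = [
    "sub_saharan_africa",
    "north_africa_middle_east",
    "south_asia",
    "southeast_east_asia_oceania",
    "latin_america_caribbean",
    "central_europe_central_asia",
    "high_income",
]

#: Default frontier elasticity: the log-log slope for which a 10% rise in
#: pooled spending per capita raises the UHC index by 1.4%.
DEFAULT_ELASTICITY = math.log(1.014) / math.log(1.10)


@dataclass(frozen=True)
class ShareParams:
    """Logit-scale generative parameters for one spending share."""

    mean: float          # global logit-scale mean
    country_sd: float    # sd of country-level logit intercepts
    innovation_sd: float # sd of year-to-year AR(1) innovations
    ar: float = 0.85     # AR(1) coefficient of the logit path


def _default_share_params() -> dict[str, ShareParams]:
    # Centred on realistic magnitudes: government spending ~30% of GDP,
    # health ~15% of government budgets, prepaid private ~1% and
    # out-of-pocket ~2% of GDP.
    return {
        "govspend_share_gdp": ShareParams(mean=-0.85, country_sd=0.35, innovation_sd=0.03),
        "ghes_share_gov": ShareParams(mean=-1.75, country_sd=0.45, innovation_sd=0.04),
        "ppp_share_gdp": ShareParams(mean=-4.60, country_sd=0.60, innovation_sd=0.05),
        "oop_share_gdp": ShareParams(mean=-3.90, country_sd=0.60, innovation_sd=0.05),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for the synthetic world.

    Defaults encode the study conditions the estimation chain assumes:
    188 countries observed 1995-2015, convergent GDP growth, a log-log UHC
    frontier whose slope implies a 1.4% index gain per 10% more pooled
    spending, half-normal inefficiency below the frontier, and a high-income
    DAH transition at $13,741 GDP per capita.
    """

    n_countries: int = 188
    year_start: int = 1995
    year_end: int = 2015
    seed: int = 0
    beta_convergence: float = -0.01
    frontier_intercept: float = 3.2
    frontier_elasticity: float = DEFAULT_ELASTICITY
    sigma_v: float = 0.03
    sigma_u: float = 0.25
    share_params: dict[str, ShareParams] = field(default_factory=_default_share_params)
    dah_source_count: int = 6
    transition_threshold: float = 13741.0
    # growth process
    mean_growth: float = 0.02
    growth_noise_sd: float = 0.02
    country_growth_sd: float = 0.005
    log_gdp0_mean: float = 8.0
    log_gdp0_sd: float = 1.2

    def __post_init__(self):
        if self.n_countries < 2:
            raise ConfigError("need at least 2 countries for downstream regressions")
        if self.year_end - self.year_start + 1 < 3:
            raise ConfigError("need at least 3 years for downstream regressions")
        if self.sigma_v <= 0:
            raise ConfigError("sigma_v must be positive")
        if self.sigma_u < 0:
            raise ConfigError("sigma_u must be non-negative")
        if self.frontier_elasticity <= 0:
            raise ConfigError("frontier_elasticity must be positive")
        if self.beta_convergence >= 0:
            raise ConfigError("beta_convergence must be negative (growth damping)")
        if self.transition_threshold <= 0:
            raise ConfigError("transition_threshold must be positive")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _logit_share_path(rng, params: ShareParams, n_countries, n_years):
    """AR(1) logit-scale paths mapped through the logistic to (0, 1)."""
    level = params.mean + params.country_sd * rng.standard_normal(n_countries)
    stat_sd = params.innovation_sd / math.sqrt(1.0 - params.ar**2)
    x = np.empty((n_countries, n_years))
    x[:, 0] = level + stat_sd * rng.standard_normal(n_countries)
    for t in range(1, n_years):
        x[:, t] = level + params.ar * (x[:, t - 1] - level) + params.innovation_sd * rng.standard_normal(n_countries)
    return 1.0 / (1.0 + np.exp(-x))


def generate_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a validated country-year panel under ``config``."""
    rng = np.random.default_rng(config.seed)
    n_c = config.n_countries
    years = np.arange(config.year_start, config.year_end + 1)
    n_y = len(years)
    countries = [f"C{i:03d}" for i in range(n_c)]

    # GDP per capita: growth with convergence around a country-level drift.
    log_gdp = np.empty((n_c, n_y))
    log_gdp[:, 0] = config.log_gdp0_mean + config.log_gdp0_sd * rng.standard_normal(n_c)
    mu_c = (
        config.mean_growth
        - config.beta_convergence * config.log_gdp0_mean
        + config.country_growth_sd * rng.standard_normal(n_c)
    )
    for t in range(1, n_y):
        growth = (
            mu_c
            + config.beta_convergence * log_gdp[:, t - 1]
            + config.growth_noise_sd * rng.standard_normal(n_c)
        )
        log_gdp[:, t] = log_gdp[:, t - 1] + growth
    gdp_pc = np.exp(log_gdp)

    # Population: country-specific constant growth.
    log_pop0 = 15.5 + 1.5 * rng.standard_normal(n_c)
    pop_growth = 0.012 + 0.008 * rng.standard_normal(n_c)
    population = np.exp(log_pop0[:, None] + pop_growth[:, None] * np.arange(n_y)[None, :])

    shares = {
        name: _logit_share_path(rng, params, n_c, n_y)
        for name, params in config.share_params.items()
    }
    gov_spend = shares["govspend_share_gdp"] * gdp_pc * population
    ghes_pc = shares["ghes_share_gov"] * shares["govspend_share_gdp"] * gdp_pc
    ppp_pc = shares["ppp_share_gdp"] * gdp_pc
    oop_pc = shares["oop_share_gdp"] * gdp_pc

    # DAH: only countries below the high-income threshold receive assistance;
    # per-capita amounts decline with income.
    eligible = gdp_pc <= config.transition_threshold
    dah_noise = 0.3 * rng.standard_normal((n_c, n_y))
    dah_pc = np.where(eligible, np.exp(1.5 - 0.5 * (log_gdp - 7.0) + dah_noise), 0.0)

    # UHC index from the log-log frontier with composed error v - u.
    pooled_pc = ghes_pc + ppp_pc + dah_pc
    v = config.sigma_v * rng.standard_normal((n_c, n_y))
    u = np.abs(config.sigma_u * rng.standard_normal((n_c, n_y)))
    uhc = np.exp(
        config.frontier_intercept
        + config.frontier_elasticity * np.log(pooled_pc)
        + v
        - u
    )
    uhc = np.clip(uhc, 0.0, 100.0)

    # Demographic covariates: AR(1) around income-linked country means.
    z = (log_gdp[:, 0] - config.log_gdp0_mean) / config.log_gdp0_sd

    def _ar1(mean_c, sd):
        x = np.empty((n_c, n_y))
        x[:, 0] = mean_c + sd * rng.standard_normal(n_c)
        for t in range(1, n_y):
            x[:, t] = mean_c + 0.9 * (x[:, t - 1] - mean_c) + sd * rng.standard_normal(n_c)
        return x

    frac_under20 = np.clip(_ar1(0.35 - 0.08 * z, 0.01), 0.05, 0.65)
    frac_over65 = np.clip(_ar1(0.08 + 0.04 * z, 0.005), 0.01, 0.35)
    education_years = np.clip(_ar1(8.0 + 2.5 * z, 0.15), 1.0, 18.0)
    tfr = np.clip(_ar1(3.0 - 0.9 * z, 0.08), 1.0, 8.0)

    # Fixed labels: income group from baseline GDP per capita quartiles,
    # super-region assigned at random.
    quartiles = np.quantile(gdp_pc[:, 0], [0.25, 0.5, 0.75])
    group_idx = np.searchsorted(quartiles, gdp_pc[:, 0])
    income_group = np.array(INCOME_GROUPS)[group_idx]
    super_region = rng.choice(SUPER_REGIONS, size=n_c)

    rows = pd.DataFrame(
        {
            "country_id": np.repeat(countries, n_y),
            "year": np.tile(years, n_c),
            "gdp_pc": gdp_pc.ravel(),
            "gov_spend": gov_spend.ravel(),
            "ghes_pc": ghes_pc.ravel(),
            "ppp_pc": ppp_pc.ravel(),
            "oop_pc": oop_pc.ravel(),
            "dah_pc": dah_pc.ravel(),
            "population": population.ravel(),
            "uhc_index": uhc.ravel(),
            "income_group": np.repeat(income_group, n_y),
            "super_region": np.repeat(super_region, n_y),
            "frac_under20": frac_under20.ravel(),
            "frac_over65": frac_over65.ravel(),
            "education_years": education_years.ravel(),
            "tfr": tfr.ravel(),
        }
    )
    return validate_panel(rows)


def generate_dah_network(config: GeneratorConfig, panel: pd.DataFrame) -> DahNetwork:
    """Generate a source -> recipient DAH flow network consistent with ``panel``.

    State sources provide a stable share of their (donor country's) government
    spending; non-state sources (foundations, corporate donors) follow
    stationary series.  Recipient shares are positive only for countries below
    the high-income threshold and sum to one each year.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 917]))
    years = sorted(panel["year"].unique())
    wide_gdp = panel.pivot(index="country_id", columns="year", values="gdp_pc")
    wide_pop = panel.pivot(index="country_id", columns="year", values="population")
    wide_gov = panel.pivot(index="country_id", columns="year", values="gov_spend")

    eligible_any = (wide_gdp <= config.transition_threshold).any(axis=1)
    recipients = wide_gdp.index[eligible_any]
    if len(recipients) == 0:
        raise GenerationError("no eligible DAH recipients below the transition threshold")

    n_state = max(1, config.dah_source_count - 2)
    n_nonstate = config.dah_source_count - n_state
    # donors: richest countries by baseline GDP per capita
    donors = wide_gdp[years[0]].sort_values(ascending=False).index[:n_state]

    records = []
    for i, donor in enumerate(donors):
        share = rng.uniform(0.0005, 0.002)
        amounts = share * wide_gov.loc[donor, years].to_numpy()
        for y, a in zip(years, amounts):
            records.append(
                {"source_id": f"S{i:02d}", "kind": "state", "donor_country": donor,
                 "share_of_gov": share, "year": y, "amount": a}
            )
    base_total = sum(r["amount"] for r in records) / len(years) if records else 1e9
    for j in range(n_nonstate):
        level = rng.uniform(0.05, 0.2) * max(base_total, 1e6)
        path = np.empty(len(years))
        path[0] = level
        for t in range(1, len(years)):
            path[t] = level + 0.7 * (path[t - 1] - level) + 0.05 * level * rng.standard_normal()
        path = np.maximum(path, 0.0)
        for y, a in zip(years, path):
            records.append(
                {"source_id": f"N{j:02d}", "kind": "non_state", "donor_country": "",
                 "share_of_gov": np.nan, "year": y, "amount": a}
            )
    sources = pd.DataFrame.from_records(records)

    # Recipient shares: weight by population and (inverse) income among the
    # year's eligible countries, normalised to sum to one.
    weight_noise = np.exp(0.2 * rng.standard_normal(len(recipients)))
    share_rows = []
    for y in years:
        gdp_y = wide_gdp.loc[recipients, y].to_numpy()
        pop_y = wide_pop.loc[recipients, y].to_numpy()
        elig_y = gdp_y <= config.transition_threshold
        w = np.where(elig_y, pop_y / np.sqrt(gdp_y) * weight_noise, 0.0)
        if w.sum() == 0:
            raise GenerationError(f"no eligible recipients in year {y}")
        w = w / w.sum()
        for c, s in zip(recipients, w):
            share_rows.append({"country": c, "year": y, "share": s})
    recipient_shares = pd.DataFrame(share_rows)

    return DahNetwork(
        sources=sources,
        recipient_shares=recipient_shares,
        transition_threshold=config.transition_threshold,
    )
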