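"""Better and worse health-spending scenarios.

The reference projection is bracketed by two alternatives built from the
cross-country distribution of long-term spending growth.  The 20-year growth
rate of total health spending per capita is regressed on a convergence term
(the baseline log level); each country's better (worse) growth rate is its
fitted value plus the 85th (15th) percentile of the regression residuals.
Scenario paths grow from the last observed level at those constant rates, are
clipped so they always bracket the reference, and are propagated to the
spending components by proportional scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComputationError, FitError

SCENARIOS = ["reference", "better", "worse"]


@dataclass
class GrowthRegression:
    """OLS of long-term annualised growth on the baseline log level."""

    intercept: float
    convergence_slope: float
    fitted: pd.Series      # per country
    residuals: pd.Series   # per country
    percentile_better: float = 85.0
    percentile_worse: float = 15.0

    def scenario_growth(self) -> pd.DataFrame:
        """Per-country better/worse annualised growth rates.

        Residual percentiles use linear interpolation between order
        statistics (numpy's default, the 'type 7' convention).
        """
        res = self.residuals.to_numpy()
        if len(np.unique(res)) < 2:
            warnings.warn("fewer than 2 distinct residuals; percentiles are degenerate")
        q_hi = np.percentile(res, self.percentile_better)
        q_lo = np.percentile(res, self.percentile_worse)
        return pd.DataFrame(
            {"better": self.fitted + q_hi, "worse": self.fitted + q_lo}
        )


@dataclass
class ScenarioSet:
    """Reference / better / worse trajectories per (country, year, component)."""

    frame: pd.DataFrame  # columns: country, year, component, reference, better, worse

    def __post_init__(self):
        required = {"country", "year", "component", *SCENARIOS}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"ScenarioSet frame missing columns {sorted(missing)}")

    def totals(self) -> pd.DataFrame:
        return self.frame[self.frame["component"] == "total"]

    def is_ordered(self, atol: float = 1e-9) -> bool:
        f = self.frame
        return bool(
            ((f["better"] >= f["reference"] - atol) & (f["worse"] <= f["reference"] + atol)).all()
        )


def compute_longterm_growth(
    panel: pd.DataFrame,
    value_col: str | pd.Series | None = None,
    start_year: int | None = None,
    end_year: int | None = None,
) -> pd.Series:
    """Annualised log growth of a per-capita series between two endpoint years.

    ``(log(x_end) - log(x_start)) / span`` per country.  Only the endpoints
    matter; interior fluctuations do not affect the measure.
    """
    from .panel import total_spend_pc

    panel = panel.copy()
    if value_col is None:
        panel["_value"] = total_spend_pc(panel)
    elif isinstance(value_col, str):
        panel["_value"] = panel[value_col]
    else:
        panel["_value"] = np.asarray(value_col)
    start_year = start_year if start_year is not None else int(panel["year"].min())
    end_year = end_year if end_year is not None else int(panel["year"].max())
    if end_year <= start_year:
        raise ComputationError("end_year must be after start_year")
    span = end_year - start_year

    wide = panel.pivot(index="country_id", columns="year", values="_value")
    if start_year not in wide.columns or end_year not in wide.columns:
        raise ComputationError("endpoint years not observed in the panel")
    x0, x1 = wide[start_year], wide[end_year]
    if (x0 <= 0).any() or (x1 <= 0).any():
        bad = wide.index[(x0 <= 0) | (x1 <= 0)][0]
        raise ComputationError(f"non-positive spending at an endpoint for {bad!r}")
    growth = (np.log(x1) - np.log(x0)) / span
    growth.name = "annualized_growth"
    return growth


def fit_convergence_regression(
    growth: pd.Series,
    convergence_term: pd.Series,
    percentile_better: float = 85.0,
    percentile_worse: float = 15.0,
) -> GrowthRegression:
    """OLS of per-country growth on the baseline log level (convergence term)."""
    if not (0 < percentile_worse < percentile_better < 100):
        raise ValueError("percentiles must satisfy 0 < worse < better < 100")
    common = growth.index.intersection(convergence_term.index)
    if len(common) < 3:
        raise FitError("need at least 3 countries for the convergence regression")
    y = growth.loc[common].to_numpy(float)
    x = convergence_term.loc[common].to_numpy(float)
    if np.allclose(x, x[0]):
        raise FitError("all convergence terms equal; slope unidentifiable")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = pd.Series(X @ coef, index=common)
    residuals = pd.Series(y, index=common) - fitted
    return GrowthRegression(
        intercept=float(coef[0]),
        convergence_slope=float(coef[1]),
        fitted=fitted,
        residuals=residuals,
        percentile_better=percentile_better,
        percentile_worse=percentile_worse,
    )


def build_alternative_scenarios(
    reg: GrowthRegression,
    reference_totals: pd.DataFrame,
    baseline_levels: pd.Series,
    baseline_year: int,
) -> ScenarioSet:
    """Attach better/worse total-spending paths to a reference projection.

    Parameters
    ----------
    reg
        Fitted long-term growth regression.
    reference_totals
        Columns (country, year, reference): the reference total-spending
        trajectory for the forecast years.
    baseline_levels
        Observed total spending per capita per country in ``baseline_year``;
        scenario paths grow from this level at constant annualised rates.
    """
    rates = reg.scenario_growth()
    frames = []
    for country, grp in reference_totals.groupby("country"):
        if country not in rates.index or country not in baseline_levels.index:
            raise ComputationError(f"no scenario growth rate for {country!r}")
        level0 = baseline_levels.loc[country]
        years = grp["year"].to_numpy()
        h = years - baseline_year
        frames.append(
            pd.DataFrame(
                {
                    "country": country,
                    "year": years,
                    "component": "total",
                    "reference": grp["reference"].to_numpy(),
                    "better": level0 * np.exp(rates.loc[country, "better"] * h),
                    "worse": level0 * np.exp(rates.loc[country, "worse"] * h),
                }
            )
        )
    return ScenarioSet(pd.concat(frames, ignore_index=True))


def clip_to_reference(scen: ScenarioSet) -> ScenarioSet:
    """Force the ordering better >= reference >= worse, elementwise.

    Where an alternative path falls on the wrong side of the reference it is
    set to the reference value.  Idempotent.
    """
    f = scen.frame.copy()
    f["better"] = np.maximum(f["better"], f["reference"])
    f["worse"] = np.minimum(f["worse"], f["reference"])
    return ScenarioSet(f)


def scale_components(
    scen_totals: ScenarioSet,
    reference_components: pd.DataFrame,
    rtol: float = 1e-6,
) -> ScenarioSet:
    """Propagate total-spending scenarios to components by proportional scaling.

    ``reference_components`` has columns (country, year, component, reference)
    and must sum to the reference totals per country-year.  Each component is
    multiplied by (scenario total / reference total), so component sums equal
    the scenario totals exactly.
    """
    totals = scen_totals.totals().set_index(["country", "year"])
    comp_sum = reference_components.groupby(["country", "year"])["reference"].sum()
    ref_tot = totals["reference"]
    aligned = comp_sum.reindex(ref_tot.index)
    if not np.allclose(aligned.to_numpy(), ref_tot.to_numpy(), rtol=rtol, atol=1e-9):
        raise ComputationError("reference components do not sum to reference totals")

    out = reference_components.copy()
    idx = pd.MultiIndex.from_frame(out[["country", "year"]])
    ref = totals["reference"].reindex(idx).to_numpy()
    zero_ref = ref == 0
    for col in ("better", "worse"):
        scen_val = totals[col].reindex(idx).to_numpy()
        if (zero_ref & (scen_val != 0)).any():
            raise ComputationError("reference total is 0 where the scenario total is nonzero")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(zero_ref, 1.0, scen_val / ref)
        out[col] = out["reference"].to_numpy() * ratio
    return ScenarioSet(out[["country", "year", "component", "reference", "better", "worse"]])
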