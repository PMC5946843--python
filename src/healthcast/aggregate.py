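"""Lives covered, Das Gupta decomposition, grouping, and draw summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import DrawSet
from .errors import AggregationError, ComputationError


def lives_covered(uhc_index, population):
    """People covered by UHC services: (index / 100) x population.

    The UHC index (0-100) is read as a coverage proportion, so summing over
    countries gives the number of lives covered at any aggregation level.
    """
    return np.asarray(uhc_index, float) / 100.0 * np.asarray(population, float)


@dataclass
class DecompositionResult:
    """Additive split of a UHC index change into spending and efficiency parts.

    The index is written as the product UHC = F x E of the frontier value F
    (what spending alone would permit) and the efficiency multiplier
    E = UHC / F.  Averaging each factor over the other's endpoints gives the
    two-factor decomposition: the effects sum exactly to the total change and
    the formula is symmetric in the factor ordering.
    """

    delta_total: np.ndarray
    delta_spending: np.ndarray
    delta_efficiency: np.ndarray

    def shares_pct(self) -> tuple[np.ndarray, np.ndarray]:
        """Percent of the total change attributed to each factor."""
        total = self.delta_total
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(total != 0, self.delta_spending / total * 100.0, np.nan)
            e = np.where(total != 0, self.delta_efficiency / total * 100.0, np.nan)
        return s, e


def decompose_das_gupta(uhc_start, uhc_end, frontier_start, frontier_end) -> DecompositionResult:
    """Two-factor Das Gupta decomposition of a UHC index change.

    spending effect   = (E_start + E_end)/2 x (F_end - F_start)
    efficiency effect = (F_start + F_end)/2 x (E_end - E_start)
    """
    u0, u1 = np.asarray(uhc_start, float), np.asarray(uhc_end, float)
    f0, f1 = np.asarray(frontier_start, float), np.asarray(frontier_end, float)
    if (f0 <= 0).any() or (f1 <= 0).any():
        raise ComputationError("frontier values must be positive for the decomposition")
    e0, e1 = u0 / f0, u1 / f1
    spending = (e0 + e1) / 2.0 * (f1 - f0)
    efficiency = (f0 + f1) / 2.0 * (e1 - e0)
    return DecompositionResult(
        delta_total=u1 - u0, delta_spending=spending, delta_efficiency=efficiency
    )


def aggregate_groups(
    frame: pd.DataFrame,
    by: str = "income_group",
    spend_cols: tuple[str, ...] = (),
    uhc_col: str | None = "uhc_index",
    population_col: str = "population",
    year_col: str = "year",
) -> pd.DataFrame:
    """Aggregate country rows to group-level series.

    Per-capita spending aggregates as total group spending over total group
    population (not the mean of country values); the UHC index aggregates as
    the population-weighted mean.  Also reports group population and lives
    covered.
    """
    if by not in frame.columns:
        raise AggregationError(f"grouping column {by!r} absent")
    if frame[by].isna().any():
        raise AggregationError("unlabeled country rows cannot be aggregated")
    keys = [by, year_col] if year_col in frame.columns else [by]
    pop = frame[population_col]
    work = frame[keys].copy()
    work["population"] = pop
    for col in spend_cols:
        work[f"_tot_{col}"] = frame[col] * pop
    if uhc_col is not None:
        work["_uhc_pop"] = frame[uhc_col] * pop
    g = work.groupby(keys, observed=True).sum()
    out = pd.DataFrame(index=g.index)
    out["population"] = g["population"]
    for col in spend_cols:
        out[col] = g[f"_tot_{col}"] / g["population"]
    if uhc_col is not None:
        out[uhc_col] = g["_uhc_pop"] / g["population"]
        out["lives_covered"] = out[uhc_col] / 100.0 * out["population"]
    return out.reset_index()


def summarize_uncertainty(draws: DrawSet | pd.DataFrame, ci: float = 95.0) -> pd.DataFrame:
    """Mean and central uncertainty interval per cell across draws.

    The interval spans the 2.5th-97.5th percentiles (for ``ci=95``) computed
    with linear interpolation between order statistics ('type 7').
    """
    frame = draws.frame if isinstance(draws, DrawSet) else draws
    if frame.shape[1] < 2:
        raise ComputationError("need at least 2 draws to summarise uncertainty")
    vals = frame.to_numpy()
    if not np.isfinite(vals).all():
        bad = frame.index[~np.isfinite(vals).all(axis=1)].tolist()
        raise ComputationError(f"non-finite draws in cells {bad[:5]}")
    lo, hi = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    out = pd.DataFrame(index=frame.index)
    out["mean"] = vals.mean(axis=1)
    out["lower"] = np.percentile(vals, lo, axis=1)
    out["upper"] = np.percentile(vals, hi, axis=1)
    return out
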