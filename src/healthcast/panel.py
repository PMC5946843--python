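"""Country-year panel I/O and validation.

The panel is the lingua franca of the pipeline: a rectangular country x year
table holding GDP per capita, total government spending, the four mutually
exclusive health-spending sources (government, prepaid private, out-of-pocket,
development assistance), population, the UHC service-coverage index (0-100)
and fixed income-group / super-region labels.  All currency fields are
2017 PPP-adjusted dollars; no deflation is performed here.

Interchange format is comma-delimited text with one header row.  An optional
schema mapping translates arbitrary file headers to the canonical names below.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .draws import DrawSet
from .errors import PanelValidationError, SchemaError

#: Canonical column order for the interchange CSV.
PANEL_COLUMNS = [
    "country_id",
    "year",
    "gdp_pc",
    "gov_spend",
    "ghes_pc",
    "ppp_pc",
    "oop_pc",
    "dah_pc",
    "population",
    "uhc_index",
    "income_group",
    "super_region",
]

#: Demographic / socioeconomic covariates the growth models may use.  They are
#: optional panel columns: validation tolerates their absence.
COVARIATE_COLUMNS = ["frac_under20", "frac_over65", "education_years", "tfr"]

_NONNEG_COLUMNS = ["gdp_pc", "gov_spend", "ghes_pc", "ppp_pc", "oop_pc", "dah_pc", "population"]

SPEND_COMPONENTS = ["ghes_pc", "ppp_pc", "oop_pc", "dah_pc"]
#: Pooled (prepaid, risk-pooled) resources exclude out-of-pocket spending.
POOLED_COMPONENTS = ["ghes_pc", "ppp_pc", "dah_pc"]


def total_spend_pc(panel: pd.DataFrame) -> pd.Series:
    """Total health spending per capita = sum of the four source components."""
    return panel[SPEND_COMPONENTS].sum(axis=1)


def pooled_spend_pc(panel: pd.DataFrame) -> pd.Series:
    """Pooled health resources per capita (government + prepaid private + DAH)."""
    return panel[POOLED_COMPONENTS].sum(axis=1)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check all data-model invariants; return the panel sorted canonically.

    Raises
    ------
    SchemaError
        If a required column is absent.
    PanelValidationError
        On duplicate (country, year) pairs, non-contiguous year runs, negative
        currency/population values, UHC index outside [0, 100], or labels that
        vary over time within a country.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    panel = panel.copy()
    panel["year"] = panel["year"].astype(int)

    dup = panel.duplicated(subset=["country_id", "year"])
    if dup.any():
        pairs = panel.loc[dup, ["country_id", "year"]].to_records(index=False).tolist()
        raise PanelValidationError(f"duplicate (country, year) pairs: {pairs[:5]}")

    for col in _NONNEG_COLUMNS:
        bad = panel.index[panel[col] < 0]
        if len(bad):
            raise PanelValidationError(
                f"negative values in {col!r} at row index {bad[0]}"
            )
    out_of_range = panel.index[(panel["uhc_index"] < 0) | (panel["uhc_index"] > 100)]
    if len(out_of_range):
        raise PanelValidationError(
            f"uhc_index outside [0, 100] at row index {out_of_range[0]}"
        )

    for country, grp in panel.groupby("country_id", sort=False):
        years = np.sort(grp["year"].to_numpy())
        if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise PanelValidationError(f"country {country!r} has a gap in its year run")
        for label in ("income_group", "super_region"):
            if grp[label].nunique() != 1:
                raise PanelValidationError(f"country {country!r} has a time-varying {label}")

    if panel[_NONNEG_COLUMNS + ["uhc_index"]].isna().any().any():
        raise PanelValidationError("missing values are not imputed; reject countries with gaps")

    return panel.sort_values(["country_id", "year"], kind="mergesort").reset_index(drop=True)


def read_panel(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a country-year panel from delimited text.

    Parameters
    ----------
    path
        CSV file with one header row.  Lines starting with ``#`` are treated
        as a metadata block and skipped.
    schema
        Optional mapping from file header names to canonical names, for files
        whose headers differ from :data:`PANEL_COLUMNS`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, comment="#", float_precision="round_trip")
    if schema:
        unknown = [k for k in schema if k not in raw.columns]
        if unknown:
            raise SchemaError(f"schema maps absent column(s): {', '.join(unknown)}")
        raw = raw.rename(columns=dict(schema))
    return validate_panel(raw)


def write_panel(panel: pd.DataFrame, path: str | Path) -> Path:
    """Write a panel as canonical CSV (fixed column order, sorted rows)."""
    panel = validate_panel(panel)
    extras = sorted(c for c in panel.columns if c not in PANEL_COLUMNS)
    ordered = panel[PANEL_COLUMNS + extras]
    path = Path(path)
    ordered.to_csv(path, index=False)
    return path


def write_draws(draws: DrawSet, path: str | Path) -> Path:
    """Write draws as a long-format CSV (country, year, quantity, draw, value)."""
    if draws.n_cells == 0 or draws.n_draws == 0:  # defensive; DrawSet forbids this
        raise ValueError("cannot write an empty DrawSet")
    long = draws.frame.stack()
    long.index = long.index.set_names(["country", "year", "quantity", "draw"])
    long.rename("value").reset_index().to_csv(path, index=False)
    return Path(path)


def read_draws(path: str | Path) -> DrawSet:
    """Read a long-format draw CSV back into a :class:`DrawSet`."""
    long = pd.read_csv(path, comment="#", float_precision="round_trip")
    wide = long.pivot_table(
        index=["country", "year", "quantity"], columns="draw", values="value"
    )
    return DrawSet(wide)


def panel_to_csv_bytes(panel: pd.DataFrame) -> bytes:
    """Canonical CSV serialisation as bytes (used for determinism checks)."""
    buf = io.StringIO()
    extras = sorted(c for c in panel.columns if c not in PANEL_COLUMNS)
    validate_panel(panel)[PANEL_COLUMNS + extras].to_csv(buf, index=False)
    return buf.getvalue().encode()
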