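"""Monte-Carlo draw container.

All uncertainty in the pipeline is carried as draws: a matrix whose rows are
(country, year, quantity) cells and whose columns are independent Monte-Carlo
realisations.  Every stage consumes and produces :class:`DrawSet` objects so
that uncertainty propagates coherently (the same draw index refers to the same
realisation of the world throughout).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError

CELL_NAMES = ("country", "year", "quantity")


class DrawSet:
    """Draws indexed by (country, year, quantity).

    Parameters
    ----------
    frame
        DataFrame whose index is a 3-level MultiIndex named
        ``("country", "year", "quantity")`` and whose columns are the integer
        draw indices ``0 .. n_draws-1``.
    """

    def __init__(self, frame: pd.DataFrame):
        if not isinstance(frame.index, pd.MultiIndex) or frame.index.nlevels != 3:
            raise ValueError("DrawSet requires a (country, year, quantity) MultiIndex")
        frame = frame.copy()
        frame.index = frame.index.set_names(CELL_NAMES)
        frame.columns = pd.RangeIndex(frame.shape[1])
        if frame.shape[0] == 0 or frame.shape[1] == 0:
            raise ValueError("DrawSet must contain at least one cell and one draw")
        if not np.isfinite(frame.to_numpy()).all():
            raise ValueError("DrawSet values must be finite")
        self._frame = frame

    # -- construction -----------------------------------------------------
    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        countries: Sequence[str],
        years: Sequence[int],
        quantity: str,
    ) -> "DrawSet":
        """Build a DrawSet for one quantity from a (country, year, draw) array."""
        values = np.asarray(values, dtype=float)
        n_c, n_y, n_d = values.shape
        if n_c != len(countries) or n_y != len(years):
            raise ValueError("array shape does not match country/year labels")
        index = pd.MultiIndex.from_product(
            [list(countries), list(years), [quantity]], names=CELL_NAMES
        )
        return cls(pd.DataFrame(values.reshape(n_c * n_y, n_d), index=index))

    @classmethod
    def concat(cls, parts: Iterable["DrawSet"]) -> "DrawSet":
        frames = [p.frame for p in parts]
        return cls(pd.concat(frames, axis=0))

    # -- basic accessors ---------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def n_draws(self) -> int:
        return self._frame.shape[1]

    @property
    def n_cells(self) -> int:
        return self._frame.shape[0]

    @property
    def quantities(self) -> list[str]:
        return sorted(self._frame.index.get_level_values("quantity").unique())

    @property
    def countries(self) -> list[str]:
        return sorted(self._frame.index.get_level_values("country").unique())

    @property
    def years(self) -> list[int]:
        return sorted(self._frame.index.get_level_values("year").unique())

    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    def sel(self, quantity: str | None = None, country: str | None = None) -> "DrawSet":
        """Subset by quantity and/or country, keeping the draw dimension."""
        frame = self._frame
        if quantity is not None:
            frame = frame.xs(quantity, level="quantity", drop_level=False)
        if country is not None:
            frame = frame.xs(country, level="country", drop_level=False)
        if frame.shape[0] == 0:
            raise KeyError(f"no cells matching quantity={quantity!r} country={country!r}")
        return DrawSet(frame)

    def array(self, quantity: str) -> tuple[np.ndarray, list[str], list[int]]:
        """Return (country, year, draw) array plus labels for one quantity."""
        sub = self._frame.xs(quantity, level="quantity")
        countries = sorted(sub.index.get_level_values("country").unique())
        years = sorted(sub.index.get_level_values("year").unique())
        full = pd.MultiIndex.from_product([countries, years], names=["country", "year"])
        sub = sub.reindex(full)
        if sub.isna().any().any():
            raise ComputationError(f"quantity {quantity!r} is not rectangular over country x year")
        arr = sub.to_numpy().reshape(len(countries), len(years), self.n_draws)
        return arr, countries, years

    # -- summaries ---------------------------------------------------------
    def mean(self) -> pd.Series:
        return self._frame.mean(axis=1)

    def quantile(self, q: float | Sequence[float]) -> pd.DataFrame:
        """Cell-wise quantiles across draws (linear interpolation between order
        statistics, the 'type 7' convention)."""
        res = self._frame.quantile(q, axis=1, interpolation="linear").T
        if np.isscalar(q):
            res = res.to_frame()
        return res

    # -- transforms --------------------------------------------------------
    def map_values(self, fn) -> "DrawSet":
        """Apply an elementwise function to all draws."""
        return DrawSet(pd.DataFrame(fn(self._frame.to_numpy()), index=self._frame.index))

    def rename_quantity(self, mapping: Mapping[str, str]) -> "DrawSet":
        frame = self._frame.rename(index=mapping, level="quantity")
        return DrawSet(frame)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, DrawSet) and self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return (
            f"DrawSet({self.n_cells} cells x {self.n_draws} draws, "
            f"quantities={self.quantities})"
        )
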