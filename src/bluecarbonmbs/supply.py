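"""Blue-carbon sequestration supply curve over a carbon-price grid.

The curve is a step function: each record contributes its full embodied
CO2e exactly when the carbon price crosses its withdrawal price, so the
annual CO2e sequestered at price p is the cumulative CO2e of all records
with withdrawal price below p (strict, under the keep-fishing tie rule),
divided by the number of years covered. The curve saturates at the cap,
the total annual embodied CO2e of the status-quo landings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .scheme import SCENARIO_PRICES, SchemeConfig, _ensure_co2e


@dataclass
class SupplyCurve:
    """Grid of (price, sequestration, removals, value, revenue) plus the cap."""

    grid: pd.DataFrame  # columns: carbon_price, co2e_sequestered,
    #                      landings_removed, value_removed, carbon_revenue
    cap: float  # tCO2e per year

    def at(self, price: float) -> pd.Series:
        """Row of the grid at an exact price present in it."""
        match = self.grid[self.grid["carbon_price"] == price]
        if match.empty:
            raise KeyError(f"price {price} not on the grid")
        return match.iloc[0]


def default_price_grid(
    stop: float = 600.0, step: float = 1.0, scenarios=SCENARIO_PRICES
) -> np.ndarray:
    """0..stop in unit steps, with the scenario prices inserted exactly."""
    grid = np.arange(0.0, stop + step / 2, step)
    return np.unique(np.concatenate([grid, np.asarray(scenarios, float)]))


def build_supply_curve(
    records: pd.DataFrame,
    carbon: pd.DataFrame | None,
    price_grid,
    config: SchemeConfig | None = None,
) -> SupplyCurve:
    """Evaluate removal totals at every grid price (annualised means).

    Equivalent to running the per-record removal rule at each grid point;
    implemented by sorting records by withdrawal price and reading
    cumulative sums, which is exact because each record is removed on the
    half-line of prices above its withdrawal price.
    """
    if config is None:
        config = SchemeConfig()
    grid = np.asarray(price_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1:
        raise DomainError("price grid must be a nonempty 1-D sequence")
    if (np.diff(grid) <= 0).any():
        raise DomainError("price grid must be strictly ascending")
    if grid[0] < 0:
        raise DomainError("price grid must be non-negative")

    df = _ensure_co2e(records, carbon)
    n_years = max(int(df["year"].nunique()), 1)
    factors = config.factor(df["sector"].to_numpy())
    wp = factors * df["value_usd"].to_numpy() / df["co2e"].to_numpy()

    order = np.argsort(wp, kind="stable")
    wp_sorted = wp[order]
    co2e = df["co2e"].to_numpy()[order]
    tonnes = df["tonnes"].to_numpy()[order]
    value = df["value_usd"].to_numpy()[order]
    cum_co2e = np.concatenate([[0.0], np.cumsum(co2e)])
    cum_tonnes = np.concatenate([[0.0], np.cumsum(tonnes)])
    cum_value = np.concatenate([[0.0], np.cumsum(value)])

    side = "right" if config.tie_rule == "remove" else "left"
    idx = np.searchsorted(wp_sorted, grid, side=side)

    seq = cum_co2e[idx] / n_years
    out = pd.DataFrame(
        {
            "carbon_price": grid,
            "co2e_sequestered": seq,
            "landings_removed": cum_tonnes[idx] / n_years,
            "value_removed": cum_value[idx] / n_years,
            "carbon_revenue": grid * seq,
        }
    )
    cap = float(cum_co2e[-1]) / n_years
    return SupplyCurve(grid=out, cap=cap)
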