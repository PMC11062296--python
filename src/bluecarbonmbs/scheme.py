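"""Withdrawal prices and the removal decision rule.

The withdrawal price of a landings record is the carbon price at which its
owner is indifferent between landing the catch and selling the embodied
carbon as a sequestration allowance:

    withdrawal_price = factor(sector) * value_usd / co2e
                     = factor(sector) * market_price / content

in US$ per tCO2e, where ``factor`` is the sector-specific fraction of the
landed value treated as compensable return to capital (1 for artisanal
fleets, whose value added equals the landed value; 0.14 for industrial
fleets, the normal-profit share of landings value). A record is removed
(its carbon sequestered instead of landed) when its withdrawal price is
below the prevailing carbon price; removal is all-or-nothing per record.

Equivalently: removed  <=>  carbon_price * co2e > factor * value_usd.

Removal tables carry two income columns for removed records:

- ``income_usd`` (gross basis): the carbon revenue replaces the whole
  landed value — income = carbon_price * co2e.
- ``income_net_usd`` (net-of-costs basis): only the factored profit share
  of the landed value is at stake; the non-profit share (crew pay, running
  costs) is avoided cost, so income = carbon_price * co2e +
  (1 - factor) * value_usd, which is >= value_usd for every removed
  record by the removal rule itself.

Retained records have both incomes equal to the landed value. Downstream
efficiency and inequality results can be computed on either basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbon import add_co2e
from .errors import ConfigurationError, DomainError

#: Carbon-price scenarios (US$ per tCO2e): the 2022 EU ETS trading price and
#: the social cost of carbon for 2025, 2030 and 2050.
SCENARIO_PRICES = (66.0, 165.0, 203.0, 543.0)


@dataclass
class SchemeConfig:
    """Sector factors, tie handling and carbon-price scenarios."""

    factor_artisanal: float = 1.0
    factor_industrial: float = 0.14
    tie_rule: str = "keep_fishing"  # or "remove"
    carbon_prices: tuple[float, ...] = SCENARIO_PRICES

    def __post_init__(self) -> None:
        if self.factor_artisanal <= 0:
            raise ConfigurationError("factor_artisanal must be > 0")
        if self.factor_industrial <= 0:
            raise ConfigurationError("factor_industrial must be > 0")
        if self.tie_rule not in ("keep_fishing", "remove"):
            raise ConfigurationError(
                "tie_rule must be 'keep_fishing' or 'remove'"
            )
        if any(p < 0 for p in self.carbon_prices):
            raise ConfigurationError("carbon_prices must be >= 0")

    def factor(self, sector) -> float | np.ndarray:
        """Sector factor(s) for a scalar label or an array of labels."""
        if isinstance(sector, str):
            return (
                self.factor_artisanal
                if sector == "artisanal"
                else self.factor_industrial
            )
        sector = np.asarray(sector)
        return np.where(
            sector == "artisanal", self.factor_artisanal, self.factor_industrial
        )


def withdrawal_price(record, co2e: float, config: SchemeConfig) -> float:
    """Break-even carbon price (US$/tCO2e) of one landings record."""
    if co2e <= 0:
        raise DomainError("co2e must be > 0")
    return config.factor(record["sector"]) * float(record["value_usd"]) / co2e


def _ensure_co2e(records: pd.DataFrame, carbon: pd.DataFrame | None) -> pd.DataFrame:
    if "co2e" in records.columns:
        return records
    if carbon is None:
        raise ValueError("records lack a co2e column and no carbon table given")
    return add_co2e(records, carbon)


def apply_scheme(
    records: pd.DataFrame,
    carbon: pd.DataFrame | None,
    carbon_price: float,
    config: SchemeConfig | None = None,
) -> pd.DataFrame:
    """Evaluate the removal rule for every record at one carbon price.

    Returns a copy of ``records`` with columns co2e, withdrawal_price,
    removed, carbon_price and income_usd (carbon revenue if removed, landed
    value otherwise). At carbon_price 0 nothing is removed.
    """
    if config is None:
        config = SchemeConfig()
    if carbon_price < 0:
        raise DomainError("carbon_price must be >= 0")
    out = _ensure_co2e(records, carbon).copy()
    factors = config.factor(out["sector"].to_numpy())
    wp = factors * out["value_usd"].to_numpy() / out["co2e"].to_numpy()
    if config.tie_rule == "remove":
        removed = wp <= carbon_price
    else:
        removed = wp < carbon_price
    value = out["value_usd"].to_numpy()
    revenue = carbon_price * out["co2e"].to_numpy()
    out["withdrawal_price"] = wp
    out["removed"] = removed
    out["carbon_price"] = float(carbon_price)
    out["income_usd"] = np.where(removed, revenue, value)
    out["income_net_usd"] = np.where(
        removed, revenue + (1.0 - factors) * value, value
    )
    return out
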