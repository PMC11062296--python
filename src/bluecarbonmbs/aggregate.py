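"""Group summaries, opportunity cost, and the with-scheme mean price.

All operations consume the per-record removal table of a single carbon-price
scenario (the output of :func:`bluecarbonmbs.scheme.apply_scheme`).
Summaries are additive: group rows over any full partition (EEZ, FAO area,
sector, gear, country) sum exactly to the global totals.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError

DIMENSIONS = {
    "eez": "eez",
    "fao_area": "fao_area",
    "sector": "sector",
    "gear": "gear",
    "country": "country",
}


def summarize(removals: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Removal totals and fractions by one grouping dimension.

    Returns one row per group with status-quo landings and embodied CO2e,
    the removed/sequestered amounts and their fractions, landed value and
    carbon revenue. The high seas appear as their own EEZ-dimension group.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(
            f"unknown dimension {dimension!r}; expected one of {sorted(DIMENSIONS)}"
        )
    col = DIMENSIONS[dimension]
    df = removals.copy()
    rm = df["removed"].to_numpy()
    df["_t_rm"] = df["tonnes"].where(df["removed"], 0.0)
    df["_c_rm"] = df["co2e"].where(df["removed"], 0.0)
    df["_rev"] = np.where(rm, df["carbon_price"] * df["co2e"], 0.0)
    g = df.groupby(col, sort=True)
    out = pd.DataFrame(
        {
            "landings_t": g["tonnes"].sum(),
            "landings_removed_t": g["_t_rm"].sum(),
            "co2e_cap_t": g["co2e"].sum(),
            "co2e_sequestered_t": g["_c_rm"].sum(),
            "value_usd": g["value_usd"].sum(),
            "carbon_revenue_usd": g["_rev"].sum(),
        }
    )
    out["removal_fraction_landings"] = out["landings_removed_t"] / out["landings_t"]
    out["removal_fraction_co2e"] = out["co2e_sequestered_t"] / out["co2e_cap_t"]
    out.index.name = "group"
    out.insert(0, "dimension", dimension)
    return out.reset_index()


class OpportunityCost(NamedTuple):
    """Forgone gain of not running the scheme (US$ per year), three framings.

    ``net_of_costs`` treats only the factored profit share of a removed
    record's landed value as forgone (input costs are avoided when the
    vessel stays in port): sum of carbon_price * co2e - factor * value_usd,
    non-negative by the removal rule. ``signed`` is the gross framing
    (carbon revenue minus the full landed value), which can be negative for
    industrial records; ``positive_part`` sums only its positive terms.
    """

    net_of_costs: float
    signed: float
    positive_part: float


def opportunity_cost(removals: pd.DataFrame) -> OpportunityCost:
    """Annualised forgone gains over removed records, all three framings.

    Each framing equals (total with-scheme income on the matching basis)
    minus (status-quo landings value).
    """
    n_years = max(int(removals["year"].nunique()), 1)
    rm = removals[removals["removed"]]
    gross = rm["carbon_price"] * rm["co2e"] - rm["value_usd"]
    net = rm["income_net_usd"] - rm["value_usd"]
    return OpportunityCost(
        net_of_costs=float(net.sum()) / n_years,
        signed=float(gross.sum()) / n_years,
        positive_part=float(gross[gross > 0].sum()) / n_years,
    )


def _income_column(basis: str) -> str:
    if basis not in ("net", "gross"):
        raise ValueError(f"basis must be 'net' or 'gross', got {basis!r}")
    return "income_net_usd" if basis == "net" else "income_usd"


def mean_price_with_scheme(
    removals: pd.DataFrame, basis: str = "net"
) -> tuple[float, float]:
    """Status-quo and with-scheme mean ex-vessel prices (US$ per tonne).

    Both use the status-quo landed tonnage as denominator, so the relative
    uplift equals opportunity cost (on the same basis) divided by the
    status-quo landings value.
    """
    tonnes = float(removals["tonnes"].sum())
    if tonnes <= 0:
        raise DomainError("total tonnes must be > 0")
    value = float(removals["value_usd"].sum())
    income = float(removals[_income_column(basis)].sum())
    return value / tonnes, income / tonnes
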