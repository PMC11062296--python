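"""Country-level income, population-weighted Lorenz curve and Gini index.

Income from the ocean accrues to the flag state of the fleet: the landed
value of retained records plus the carbon revenue of removed records
(high-seas catches accrue to the flag state as well). Each country's income
is spread uniformly over its population, countries are ordered by income
per capita, and the Lorenz curve plots cumulative income share against
cumulative population share. The Gini coefficient is one minus twice the
trapezoid area under the piecewise-linear curve — for this block-uniform
income distribution that equals the population-weighted pairwise
mean-absolute-difference formula exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError


@dataclass
class LorenzResult:
    """Lorenz curve points ((0,0) .. (1,1)) and the Gini coefficient."""

    points: pd.DataFrame  # columns: cum_population_share, cum_income_share
    gini: float


def country_income(
    removals: pd.DataFrame, population: pd.DataFrame, basis: str = "net"
) -> pd.DataFrame:
    """Per-country fisheries income under one scenario (US$/yr, per capita).

    Income is the sum of record incomes grouped by flag state, annualised
    over the years present. ``basis`` picks the income definition for
    removed records: "net" credits carbon revenue plus the avoided-cost
    share of the landed value, "gross" credits carbon revenue alone.
    Raises a lookup error for countries missing a population.
    """
    col = {"net": "income_net_usd", "gross": "income_usd"}.get(basis)
    if col is None:
        raise ValueError(f"basis must be 'net' or 'gross', got {basis!r}")
    if col not in removals.columns and basis == "net":
        col = "income_usd"  # pre-dual-basis tables
    n_years = max(int(removals["year"].nunique()), 1)
    inc = (
        removals.groupby("country")[col].sum().rename("income_usd") / n_years
    )
    pop = population.drop_duplicates("country").set_index("country")["population"]
    missing = inc.index.difference(pop.index)
    if len(missing) > 0:
        raise KeyError(
            f"country {missing[0]!r} has landings but no population entry"
        )
    out = inc.to_frame()
    out["population"] = pop.reindex(inc.index)
    if (out["population"] <= 0).any():
        raise DomainError("populations must be > 0")
    out["income_per_capita"] = out["income_usd"] / out["population"]
    return out.reset_index()


def lorenz(incomes: pd.DataFrame) -> LorenzResult:
    """Population-weighted Lorenz curve and Gini over country income blocks.

    ``incomes`` needs columns country, population, income_usd (per-capita is
    derived). Countries are sorted ascending by income per capita; ties are
    broken stably so the curve is well defined and the Gini unaffected.
    """
    if len(incomes) < 1:
        raise DomainError("need at least one country")
    df = incomes.copy()
    total_income = float(df["income_usd"].sum())
    if total_income <= 0:
        raise DomainError("total income must be > 0")
    df["income_per_capita"] = df["income_usd"] / df["population"]
    df = df.sort_values("income_per_capita", kind="stable")
    pop = df["population"].to_numpy(dtype=float)
    inc = df["income_usd"].to_numpy(dtype=float)
    x = np.concatenate([[0.0], np.cumsum(pop) / pop.sum()])
    y = np.concatenate([[0.0], np.cumsum(inc) / total_income])
    area = float(np.trapezoid(y, x))
    points = pd.DataFrame(
        {"cum_population_share": x, "cum_income_share": y}
    )
    return LorenzResult(points=points, gini=1.0 - 2.0 * area)


def gini(incomes: pd.DataFrame) -> float:
    """Convenience: the Gini coefficient of :func:`lorenz`."""
    return lorenz(incomes).gini
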