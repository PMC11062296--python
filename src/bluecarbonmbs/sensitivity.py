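"""Factor-variant grid and year-to-year uncertainty of the scheme.

Two sensitivity axes: (i) alternative sector factors — the industrial
normal-profit share is uncertain, so the scheme is re-run with industrial
factors 0.14 / 0.33 / 1 and with artisanal fleets treated like industrial
ones (factor 0.14 for both); (ii) inter-annual variability — the cap and
the removals are means over the study years, and their standard error of
the mean (sample sd over annual totals divided by sqrt(n years)) bounds
how sensitive the headline numbers are to the averaging window.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .scheme import SchemeConfig, apply_scheme

#: (label, factor_artisanal, factor_industrial) variants re-run by default.
DEFAULT_VARIANTS = (
    ("default", 1.0, 0.14),
    ("industrial_0.33", 1.0, 0.33),
    ("industrial_1", 1.0, 1.0),
    ("artisanal_as_industrial", 0.14, 0.14),
)


def run_variants(
    records: pd.DataFrame,
    carbon: pd.DataFrame | None,
    variants=DEFAULT_VARIANTS,
    prices=None,
    config: SchemeConfig | None = None,
) -> pd.DataFrame:
    """Removal totals for every factor variant x carbon price.

    Each row is a fresh run of the removal rule under that variant's
    factors; totals are annual means with the SEM over years attached.
    """
    if config is None:
        config = SchemeConfig()
    if prices is None:
        prices = config.carbon_prices
    variants = list(variants)
    if not variants:
        raise ConfigurationError("variants must be nonempty")
    rows = []
    for label, fa, fi in variants:
        if fa <= 0 or fi <= 0:
            raise ConfigurationError(f"variant {label!r}: factors must be > 0")
        vcfg = replace(config, factor_artisanal=fa, factor_industrial=fi)
        for price in prices:
            rem = apply_scheme(records, carbon, price, vcfg)
            stats = annual_stats(rem)
            rows.append(
                {
                    "variant": label,
                    "factor_artisanal": fa,
                    "factor_industrial": fi,
                    "carbon_price": price,
                    **{
                        f"{q}_{s}": stats.loc[q, s]
                        for q in stats.index
                        for s in ("mean", "sem")
                    },
                }
            )
    return pd.DataFrame(rows)


def annual_stats(removals: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM over years of sequestration, removals, cap and value.

    SEM uses the sample standard deviation (n-1 denominator) over the
    per-year totals; a single year has no dispersion estimate and is an
    error for :func:`annual_sem` but returns SEM 0 here only when the
    totals are literally identical across >=2 years.
    """
    df = removals.copy()
    df["_c_rm"] = df["co2e"].where(df["removed"], 0.0)
    df["_t_rm"] = df["tonnes"].where(df["removed"], 0.0)
    per_year = df.groupby("year").agg(
        co2e_sequestered=("_c_rm", "sum"),
        landings_removed=("_t_rm", "sum"),
        co2e_cap=("co2e", "sum"),
        landings=("tonnes", "sum"),
        value_usd=("value_usd", "sum"),
    )
    n = len(per_year)
    mean = per_year.mean()
    if n >= 2:
        sem = per_year.std(ddof=1) / np.sqrt(n)
    else:
        sem = pd.Series(np.nan, index=per_year.columns)
    return pd.DataFrame({"mean": mean, "sem": sem})


def annual_sem(
    records: pd.DataFrame,
    carbon: pd.DataFrame | None,
    price: float,
    config: SchemeConfig | None = None,
) -> pd.DataFrame:
    """Run the scheme at one price and return per-quantity (mean, SEM).

    Requires at least two distinct years of records.
    """
    rem = apply_scheme(records, carbon, price, config)
    if rem["year"].nunique() < 2:
        raise DomainError("need at least two distinct years to estimate a SEM")
    return annual_stats(rem)
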