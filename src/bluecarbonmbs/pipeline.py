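"""End-to-end orchestration: impute -> CO2e -> scheme -> supply -> summaries
-> inequality -> sensitivity, with a JSON report plus per-stage CSVs.

Inputs come either from the three CSV paths or from the synthetic-data
generator; the report is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import aggregate, carbon, inequality, io, scheme, sensitivity, supply, synthdata
from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of (``landings_path``+``carbon_path``+``population_path``)
    or ``generator`` must provide the inputs; the generator is used when no
    paths are given.
    """

    landings_path: str | None = None
    carbon_path: str | None = None
    population_path: str | None = None
    generator: synthdata.GeneratorConfig | None = None
    scheme: scheme.SchemeConfig = field(default_factory=scheme.SchemeConfig)
    grid_stop: float = 600.0
    grid_step: float = 1.0
    outdir: str = "mbs_out"
    seed: int = 0

    def __post_init__(self) -> None:
        have_paths = all(
            p is not None
            for p in (self.landings_path, self.carbon_path, self.population_path)
        )
        if not have_paths and self.generator is None:
            self.generator = synthdata.GeneratorConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "generator" in kwargs and kwargs["generator"] is not None:
            kwargs["generator"] = synthdata.GeneratorConfig(**kwargs["generator"])
        if "scheme" in kwargs and kwargs["scheme"] is not None:
            sch = dict(kwargs["scheme"])
            if "carbon_prices" in sch:
                sch["carbon_prices"] = tuple(sch["carbon_prices"])
            kwargs["scheme"] = scheme.SchemeConfig(**sch)
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**kwargs)


def _load_inputs(config: PipelineConfig):
    if config.landings_path is not None:
        landings = io.read_landings(config.landings_path)
        carbon_tbl = io.read_carbon(config.carbon_path)
        population = io.read_population(config.population_path)
    else:
        gen = config.generator
        landings, carbon_tbl, population = synthdata.generate_all(gen)
    return landings, carbon_tbl, population


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to disk).

    Writes to ``config.outdir``: the completed carbon table, per-scenario
    removal tables and summaries, the supply curve, Lorenz curves, the
    sensitivity grid and ``report.json``. Report numbers are full
    precision; rounding happens only at display time.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landings, carbon_raw, population = _load_inputs(config)

    carbon_tbl = carbon.impute_carbon(carbon_raw)
    io.write_table(carbon_tbl, outdir / "carbon_imputed.csv")
    with_co2e = carbon.add_co2e(landings, carbon_tbl)
    n_years = int(with_co2e["year"].nunique())
    cap = carbon.annual_cap(with_co2e, n_years)

    grid = supply.default_price_grid(
        config.grid_stop, config.grid_step, config.scheme.carbon_prices
    )
    curve = supply.build_supply_curve(with_co2e, None, grid, config.scheme)
    io.write_table(curve.grid, outdir / "supply.csv")

    total_value = float(landings["value_usd"].sum()) / n_years
    total_tonnes = float(landings["tonnes"].sum()) / n_years

    report: dict = {
        "n_records": int(len(landings)),
        "n_years": n_years,
        "annual_landings_t": total_tonnes,
        "annual_value_usd": total_value,
        "cap_tco2e": cap,
        "mean_carbon_content": cap * n_years / float(landings["tonnes"].sum()),
        "scenarios": {},
    }

    status_quo_income = None
    for price in config.scheme.carbon_prices:
        rem = scheme.apply_scheme(with_co2e, None, price, config.scheme)
        io.write_table(rem, outdir / f"removals_{price:g}.csv")
        for dim in aggregate.DIMENSIONS:
            io.write_table(
                aggregate.summarize(rem, dim),
                outdir / f"summary_{dim}_{price:g}.csv",
            )
        oc = aggregate.opportunity_cost(rem)
        sq_price, mbs_price = aggregate.mean_price_with_scheme(rem, basis="net")
        _, mbs_price_gross = aggregate.mean_price_with_scheme(rem, basis="gross")
        incomes = inequality.country_income(rem, population, basis="net")
        lz = inequality.lorenz(incomes)
        io.write_table(lz.points, outdir / f"lorenz_{price:g}.csv")
        if status_quo_income is None:
            sq_rem = scheme.apply_scheme(with_co2e, None, 0.0, config.scheme)
            sq_incomes = inequality.country_income(sq_rem, population)
            status_quo_income = inequality.lorenz(sq_incomes).gini
            report["gini_status_quo"] = status_quo_income
        seq = float(curve.at(price)["co2e_sequestered"])
        report["scenarios"][f"{price:g}"] = {
            "carbon_price": price,
            "co2e_sequestered_tco2e": seq,
            "cap_fraction": seq / cap if cap > 0 else 0.0,
            "landings_removed_t": float(curve.at(price)["landings_removed"]),
            "opportunity_cost_usd": oc.net_of_costs,
            "opportunity_cost_gross_usd": oc.signed,
            "opportunity_cost_positive_usd": oc.positive_part,
            "opportunity_cost_share_of_value": oc.net_of_costs / total_value,
            "mean_price_status_quo_usd_t": sq_price,
            "mean_price_with_scheme_usd_t": mbs_price,
            "mean_price_with_scheme_gross_usd_t": mbs_price_gross,
            "gini_with_scheme": lz.gini,
        }

    sens = sensitivity.run_variants(
        with_co2e, None, config=config.scheme
    )
    io.write_table(sens, outdir / "sensitivity.csv")
    if n_years >= 2:
        sem_cap = sensitivity.annual_stats(
            scheme.apply_scheme(with_co2e, None, 0.0, config.scheme)
        )
        report["cap_sem"] = {
            "landings_mean_t": float(sem_cap.loc["landings", "mean"]),
            "landings_sem_t": float(sem_cap.loc["landings", "sem"]),
            "co2e_cap_mean_t": float(sem_cap.loc["co2e_cap", "mean"]),
            "co2e_cap_sem_t": float(sem_cap.loc["co2e_cap", "sem"]),
            "value_mean_usd": float(sem_cap.loc["value_usd", "mean"]),
            "value_sem_usd": float(sem_cap.loc["value_usd", "sem"]),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline report written to %s", outdir / "report.json")
    return report
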