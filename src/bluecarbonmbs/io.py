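"""Validated CSV input/output for the three data tables.

Column contracts (headers mandatory, UTF-8, RFC 4180):

- landings.csv: species, genus, family, year, fao_area, eez, country,
  sector, gear, tonnes, value_usd
- carbon.csv: species, genus, family, tco2e_per_tonne (blank = unmeasured);
  an imputation_level column is added on output after completion
- population.csv: country, population

Validation errors cite the first offending data row (1-based, excluding
the header).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import InputValidationError
from .synthdata import (
    CARBON_COLUMNS,
    LANDINGS_COLUMNS,
    POPULATION_COLUMNS,
    SECTORS,
)

log = logging.getLogger(__name__)


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing column(s) {missing}")


def _first_bad_row(mask: pd.Series) -> int:
    # 1-based data-row number (header excluded)
    return int(mask.to_numpy().nonzero()[0][0]) + 1


def read_landings(path) -> pd.DataFrame:
    """Read and validate a landings table."""
    df = pd.read_csv(path)
    _check_columns(df, LANDINGS_COLUMNS, path)
    for col in ("tonnes", "value_usd"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            raise InputValidationError(
                f"{path}: non-positive or non-numeric {col} in row "
                f"{_first_bad_row(bad)}"
            )
        df[col] = vals.astype(float)
    bad = ~df["sector"].isin(SECTORS)
    if bad.any():
        raise InputValidationError(
            f"{path}: unknown sector label in row {_first_bad_row(bad)}"
        )
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    log.info("read %d landings records from %s", len(df), path)
    return df[LANDINGS_COLUMNS]


def read_carbon(path) -> pd.DataFrame:
    """Read and validate a species carbon-content table (NaN allowed)."""
    df = pd.read_csv(path)
    _check_columns(df, CARBON_COLUMNS, path)
    vals = pd.to_numeric(df["tco2e_per_tonne"], errors="coerce")
    bad = df["tco2e_per_tonne"].notna() & (vals.isna() | (vals <= 0))
    if bad.any():
        raise InputValidationError(
            f"{path}: non-positive or non-numeric tco2e_per_tonne in row "
            f"{_first_bad_row(bad)}"
        )
    df["tco2e_per_tonne"] = vals
    dup = df["species"].duplicated()
    if dup.any():
        raise InputValidationError(
            f"{path}: duplicate species in row {_first_bad_row(dup)}"
        )
    log.info("read %d carbon entries from %s", len(df), path)
    cols = [c for c in df.columns if c in CARBON_COLUMNS + ["imputation_level"]]
    return df[cols]


def read_population(path) -> pd.DataFrame:
    """Read and validate a country population table."""
    df = pd.read_csv(path)
    _check_columns(df, POPULATION_COLUMNS, path)
    vals = pd.to_numeric(df["population"], errors="coerce")
    bad = vals.isna() | (vals <= 0)
    if bad.any():
        raise InputValidationError(
            f"{path}: non-positive or non-numeric population in row "
            f"{_first_bad_row(bad)}"
        )
    df["population"] = vals.astype("int64")
    log.info("read %d population rows from %s", len(df), path)
    return df[POPULATION_COLUMNS]


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as plain CSV, full precision, no index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
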