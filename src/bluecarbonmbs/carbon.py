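"""Carbon-content completion and embodied-CO2e conversion.

Species without a measured carbon content are assigned the unweighted mean
content of measured species at the lowest taxonomic level available: genus
first, then family, then the global measured mean. The provenance of each
value is recorded in an ``imputation_level`` column (measured / genus /
family / global) so the fallback chain is auditable.

Embodied CO2e of a landings record is simply tonnes landed times the
species' content in tCO2e per tonne; summed over all records and divided by
the number of years it yields the annual blue-carbon cap (the fleet's de
facto initial allowances).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError, ImputationError, SpeciesLookupError

IMPUTATION_LEVELS = ("measured", "genus", "family", "global")


def impute_carbon(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing carbon contents by taxonomic-fallback means.

    Parameters
    ----------
    table
        Frame with columns species, genus, family, tco2e_per_tonne
        (NaN where unmeasured).

    Returns
    -------
    A copy with every ``tco2e_per_tonne`` present and positive, plus an
    ``imputation_level`` column. Measured entries are returned unchanged.
    Idempotent: imputing an already-complete table is a no-op.

    Raises
    ------
    ImputationError
        If no species has a measured content.
    """
    required = {"species", "genus", "family", "tco2e_per_tonne"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"carbon table missing columns: {sorted(missing_cols)}")

    out = table.copy()
    content = out["tco2e_per_tonne"]
    measured = content.notna()
    if not measured.any():
        raise ImputationError(
            "cannot impute carbon content: no species has a measured value"
        )
    if (content[measured] <= 0).any():
        bad = out.loc[measured & (content <= 0), "species"].iloc[0]
        raise ValueError(f"non-positive carbon content for species {bad!r}")

    if "imputation_level" in out.columns:
        level = out["imputation_level"].copy()
    else:
        level = pd.Series(
            np.where(measured, "measured", ""), index=out.index, dtype=object
        )

    meas = out[measured]
    genus_mean = meas.groupby("genus")["tco2e_per_tonne"].mean()
    family_mean = meas.groupby("family")["tco2e_per_tonne"].mean()
    global_mean = float(meas["tco2e_per_tonne"].mean())

    todo = ~measured
    by_genus = out.loc[todo, "genus"].map(genus_mean)
    fill = by_genus.copy()
    level.loc[todo] = np.where(by_genus.notna(), "genus", "")

    still = todo & fill.reindex(out.index).isna()
    by_family = out.loc[still, "family"].map(family_mean)
    fill.loc[still[still].index] = by_family
    level.loc[still] = np.where(by_family.notna(), "family", "")

    final = todo & fill.reindex(out.index).isna()
    fill.loc[final[final].index] = global_mean
    level.loc[final] = "global"

    out.loc[todo, "tco2e_per_tonne"] = fill
    out["imputation_level"] = level
    return out


def co2e_of_record(record, carbon: pd.DataFrame) -> float:
    """Embodied CO2e (t) of one landings record: tonnes x content."""
    lookup = carbon.set_index("species")["tco2e_per_tonne"]
    species = record["species"]
    if species not in lookup.index or pd.isna(lookup[species]):
        raise SpeciesLookupError(
            f"species {species!r} absent from the completed carbon table"
        )
    tonnes = float(record["tonnes"])
    if tonnes <= 0:
        raise DomainError("tonnes must be > 0")
    return tonnes * float(lookup[species])


def add_co2e(landings: pd.DataFrame, carbon: pd.DataFrame) -> pd.DataFrame:
    """Attach per-record embodied CO2e to a landings table.

    ``carbon`` must be complete (post-imputation). Returns a copy of
    ``landings`` with a ``co2e`` column (tCO2e). Raises
    :class:`SpeciesLookupError` naming the first species without content.
    """
    lookup = carbon.drop_duplicates("species").set_index("species")[
        "tco2e_per_tonne"
    ]
    content = landings["species"].map(lookup)
    if content.isna().any():
        missing = landings.loc[content.isna(), "species"].iloc[0]
        raise SpeciesLookupError(
            f"species {missing!r} absent from the completed carbon table"
        )
    if (content <= 0).any():
        bad = landings.loc[content <= 0, "species"].iloc[0]
        raise ValueError(f"non-positive carbon content for species {bad!r}")
    out = landings.copy()
    out["co2e"] = landings["tonnes"].to_numpy() * content.to_numpy()
    return out


def annual_cap(landings_with_co2e: pd.DataFrame, n_years: int | None = None) -> float:
    """Total embodied CO2e divided by the number of years covered (tCO2e/yr)."""
    if n_years is None:
        n_years = landings_with_co2e["year"].nunique()
    if n_years < 1:
        raise DomainError("need at least one year of records")
    return float(landings_with_co2e["co2e"].sum()) / n_years
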