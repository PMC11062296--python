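"""Synthetic global-landings, carbon-content and population tables.

The generator emulates the record structure of reconstructed global catch
statistics: one row per species x year x FAO major fishing area x EEZ x
fishing country x sector (artisanal/industrial) x gear, carrying tonnes
landed and ex-vessel value in real US$. Defaults are calibrated to the
magnitudes of the 2011-2018 global fishery: ~0.106 Gt landed per year worth
~US$222 billion, a quarter of tonnage artisanal, ~3% caught on the high
seas, a heavy-tailed species mix in which the top species holds ~11% of
tonnage, and a mean embodied carbon content of 1.5 tCO2e per tonne landed.

The three tables close over each other: every landed species appears in the
carbon table's taxonomy, and every EEZ except "High Seas" belongs to exactly
one country present in the population table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

HIGH_SEAS = "High Seas"

#: Gear labels sampled for each record; the five named gears dominate global
#: removals summaries, "other" absorbs the long tail.
GEARS = (
    "pelagic trawl",
    "hand lines",
    "encircling nets",
    "purse seine",
    "harpoon",
    "other",
)

SECTORS = ("artisanal", "industrial")

LANDINGS_COLUMNS = [
    "species",
    "genus",
    "family",
    "year",
    "fao_area",
    "eez",
    "country",
    "sector",
    "gear",
    "tonnes",
    "value_usd",
]

CARBON_COLUMNS = ["species", "genus", "family", "tco2e_per_tonne"]

POPULATION_COLUMNS = ["country", "population"]

_N_FAO_AREAS = 8


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    Parameters
    ----------
    seed
        Master seed; identical seeds give byte-identical tables.
    n_species, n_countries, n_eez
        Taxon and spatial richness. Each EEZ belongs to one country;
        one extra zone labelled "High Seas" is always added.
    years
        Calendar years covered (the study window is 2011-2018).
    landings_concentration
        Shape of the rank-power species tonnage allocation
        (share of rank r proportional to r**-concentration); larger values
        concentrate tonnage in fewer species.
    artisanal_share
        Expected artisanal fraction of tonnage, per record drawn from a
        Beta distribution with this mean.
    carbon_mean, carbon_cv
        Mean and coefficient of variation of species carbon content
        (tCO2e per tonne landed), lognormal across species.
    price_lognormal_params
        (location, scale) of log ex-vessel price in US$/t. Prices vary by
        species x year x EEZ and are shared across sectors and gears.
    missing_carbon_fraction
        Fraction of species whose carbon content is left blank, to be
        filled later by taxonomic imputation.
    total_tonnes_per_year
        Global annual landings the species shares are scaled to.
    high_seas_share
        Fraction of each species' tonnage landed on the high seas.
    price_eez_dispersion, price_year_cv
        Within-species lognormal dispersion of price across EEZs and years.
    year_effect_cv
        Coefficient of variation of the global annual tonnage multiplier;
        drives the inter-annual dispersion of the cap (the study window's
        annual landings scatter around their mean with a CV near 0.22).
    country_capacity_sigma
        Lognormal sigma of country fishing-capacity weights (drives how
        unequal landings are across countries).
    population_sigma, population_median
        Lognormal parameters of country populations.
    """

    seed: int = 0
    n_species: int = 250
    n_countries: int = 40
    n_eez: int = 60
    years: tuple[int, ...] = tuple(range(2011, 2019))
    landings_concentration: float = 0.85
    artisanal_share: float = 0.25
    carbon_mean: float = 1.5
    carbon_cv: float = 0.3
    price_lognormal_params: tuple[float, float] = (7.33, 0.9)
    missing_carbon_fraction: float = 0.3
    total_tonnes_per_year: float = 106e6
    high_seas_share: float = 0.03
    price_eez_dispersion: float = 0.2
    price_year_cv: float = 0.05
    year_effect_cv: float = 0.22
    country_capacity_sigma: float = 0.7
    population_sigma: float = 0.85
    population_median: float = 5e6
    species_per_genus: int = 3
    genera_per_family: int = 4
    eez_per_species: int = 5

    def __post_init__(self) -> None:
        for name in ("n_species", "n_countries", "n_eez", "species_per_genus",
                     "genera_per_family", "eez_per_species"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("artisanal_share", "missing_carbon_fraction",
                     "high_seas_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("carbon_mean", "landings_concentration",
                     "total_tonnes_per_year"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("carbon_cv", "price_eez_dispersion", "price_year_cv",
                     "year_effect_cv", "country_capacity_sigma",
                     "population_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.years) < 1:
            raise ConfigurationError("years must be nonempty")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent substreams so each table is reproducible regardless of
    # which generator functions were called before it
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _species_frame(config: GeneratorConfig) -> pd.DataFrame:
    idx = np.arange(config.n_species)
    genus_idx = idx // config.species_per_genus
    family_idx = genus_idx // config.genera_per_family
    return pd.DataFrame(
        {
            "species": [f"species_{i:04d}" for i in idx],
            "genus": [f"genus_{g:04d}" for g in genus_idx],
            "family": [f"family_{f:03d}" for f in family_idx],
        }
    )


def _country_labels(config: GeneratorConfig) -> list[str]:
    return [f"C{i:03d}" for i in range(config.n_countries)]


def _eez_frame(config: GeneratorConfig) -> pd.DataFrame:
    """EEZ -> owning country and FAO area; round-robin ownership."""
    countries = _country_labels(config)
    rows = [
        {
            "eez": f"EEZ_{j:03d}",
            "country": countries[j % config.n_countries],
            "fao_area": f"FAO_{(j % _N_FAO_AREAS) + 1:02d}",
        }
        for j in range(config.n_eez)
    ]
    return pd.DataFrame(rows)


def generate_landings(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the landings table (one row per record).

    Each species is allocated a rank-power share of the global annual
    tonnage, spread over a random subset of EEZs (weighted by the owning
    country's fishing capacity) plus a high-seas slice, split per record
    into artisanal and industrial sectors, and priced with a lognormal
    ex-vessel price shared across sectors and gears.

    Returns a DataFrame with columns ``LANDINGS_COLUMNS``; tonnes and
    value_usd are strictly positive.
    """
    rng = _rng(config, 1)
    sp = _species_frame(config)
    eezs = _eez_frame(config)
    countries = _country_labels(config)

    capacity = rng.lognormal(0.0, config.country_capacity_sigma,
                             config.n_countries)
    cap_by_country = dict(zip(countries, capacity))
    eez_weight = eezs["country"].map(cap_by_country).to_numpy()

    # heavy-tailed species shares: rank-power law, ranks shuffled so rank
    # is independent of taxonomy
    ranks = rng.permutation(config.n_species) + 1
    shares = ranks.astype(float) ** (-config.landings_concentration)
    shares /= shares.sum()

    mu_p, sigma_p = config.price_lognormal_params
    base_price = rng.lognormal(mu_p, sigma_p, config.n_species)

    n_years = len(config.years)
    year_factor = rng.lognormal(0.0, config.price_year_cv,
                                (config.n_species, n_years))
    tonnage_year = rng.lognormal(0.0, config.price_year_cv,
                                 (config.n_species, n_years))
    tonnage_year /= tonnage_year.mean(axis=0, keepdims=True)
    # global year effect: annual totals scatter around the configured level
    sigma_y = np.sqrt(np.log1p(config.year_effect_cv**2))
    year_mult = rng.lognormal(-sigma_y**2 / 2.0, sigma_y, n_years)
    tonnage_year *= year_mult[np.newaxis, :]

    records: list[dict] = []
    k = min(config.eez_per_species, config.n_eez)
    for i in range(config.n_species):
        chosen = rng.choice(config.n_eez, size=k, replace=False,
                            p=eez_weight / eez_weight.sum())
        w = rng.dirichlet(np.ones(k) * 2.0)
        hs_flag = countries[rng.choice(config.n_countries,
                                       p=capacity / capacity.sum())]
        eez_rows = eezs.iloc[chosen]
        eez_price_jit = rng.lognormal(0.0, config.price_eez_dispersion, k + 1)
        gear_art, gear_ind = rng.choice(len(GEARS), size=2)
        for yi, year in enumerate(config.years):
            annual = config.total_tonnes_per_year * shares[i] * tonnage_year[i, yi]
            price_y = base_price[i] * year_factor[i, yi]
            zones = list(zip(eez_rows["eez"], eez_rows["country"],
                             eez_rows["fao_area"],
                             annual * (1 - config.high_seas_share) * w,
                             eez_price_jit[:k]))
            zones.append((HIGH_SEAS, hs_flag,
                          f"FAO_{int(rng.integers(1, _N_FAO_AREAS + 1)):02d}",
                          annual * config.high_seas_share,
                          eez_price_jit[k]))
            for eez, country, fao, tonnes, jit in zones:
                if tonnes <= 0:
                    continue
                price = price_y * jit
                # Beta with mean artisanal_share, concentration 10
                if config.artisanal_share in (0.0, 1.0):
                    art = config.artisanal_share
                else:
                    art = rng.beta(10.0 * config.artisanal_share,
                                   10.0 * (1.0 - config.artisanal_share))
                for sector, frac, gear_i in (
                    ("artisanal", art, gear_art),
                    ("industrial", 1.0 - art, gear_ind),
                ):
                    t = tonnes * frac
                    if t <= 0:
                        continue
                    records.append(
                        {
                            "species": sp["species"].iat[i],
                            "genus": sp["genus"].iat[i],
                            "family": sp["family"].iat[i],
                            "year": year,
                            "fao_area": fao,
                            "eez": eez,
                            "country": country,
                            "sector": sector,
                            "gear": GEARS[gear_i],
                            "tonnes": t,
                            "value_usd": t * price,
                        }
                    )
    return pd.DataFrame.from_records(records, columns=LANDINGS_COLUMNS)


def generate_carbon_table(
    config: GeneratorConfig, species_list: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Generate the species carbon-content table (tCO2e per tonne landed).

    ``species_list`` is a frame with species/genus/family columns (e.g. the
    landings table); defaults to the generator's own taxonomy. Contents are
    lognormal with mean ``carbon_mean`` and CV ``carbon_cv``; a fraction
    ``missing_carbon_fraction`` of species is left NaN. Within multi-species
    genera at least one member stays measured (unless everything is missing),
    so genus-level imputation has a donor.
    """
    rng = _rng(config, 2)
    if species_list is None:
        sp = _species_frame(config)
    else:
        if len(species_list) == 0:
            raise ConfigurationError("species_list must be nonempty")
        sp = (
            species_list[["species", "genus", "family"]]
            .drop_duplicates("species")
            .sort_values("species", kind="stable")
            .reset_index(drop=True)
        )
    n = len(sp)
    sigma2 = np.log1p(config.carbon_cv**2)
    mu = np.log(config.carbon_mean) - sigma2 / 2.0
    content = rng.lognormal(mu, np.sqrt(sigma2), n)

    n_missing = int(round(config.missing_carbon_fraction * n))
    missing = np.zeros(n, dtype=bool)
    missing[rng.permutation(n)[:n_missing]] = True

    if 0 < n_missing < n:
        missing = _repair_orphan_genera(sp["genus"].to_numpy(), missing, rng)

    out = sp.copy()
    out["tco2e_per_tonne"] = np.where(missing, np.nan, content)
    return out


def _repair_orphan_genera(
    genus: np.ndarray, missing: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Swap missingness so no multi-species genus is entirely unmeasured.

    Keeps the total number of missing species unchanged by un-blanking one
    member of each fully-missing multi-species genus and blanking a measured
    species from a genus that retains at least two measured members.
    """
    missing = missing.copy()
    s = pd.Series(missing, index=pd.Index(genus, name="genus"))
    grp = s.groupby(level="genus")
    sizes = grp.size()
    all_missing = grp.sum() == sizes
    orphans = sizes.index[(sizes > 1) & all_missing]
    for g in orphans:
        idx_g = np.flatnonzero((genus == g) & missing)
        # donor: genus keeping >=2 measured species after the swap
        measured_counts = (~s).groupby(level="genus").sum()
        donors = measured_counts.index[measured_counts >= 2]
        donors = [d for d in donors if d != g]
        if not donors:
            break
        d = donors[int(rng.integers(len(donors)))]
        idx_d = np.flatnonzero((genus == d) & ~missing)
        missing[idx_g[int(rng.integers(len(idx_g)))]] = False
        missing[idx_d[int(rng.integers(len(idx_d)))]] = True
        s = pd.Series(missing, index=pd.Index(genus, name="genus"))
    return missing


def generate_population(
    config: GeneratorConfig, countries: list[str] | None = None
) -> pd.DataFrame:
    """Generate heavy-tailed country populations (single reference year)."""
    rng = _rng(config, 3)
    if countries is None:
        countries = _country_labels(config)
    countries = list(countries)
    if not countries:
        raise ConfigurationError("countries must be nonempty")
    pop = rng.lognormal(np.log(config.population_median),
                        config.population_sigma, len(countries))
    return pd.DataFrame(
        {"country": countries,
         "population": np.maximum(1, np.round(pop)).astype(np.int64)}
    )


def generate_all(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the closed triple (landings, carbon, population)."""
    landings = generate_landings(config)
    carbon = generate_carbon_table(config, landings)
    population = generate_population(config)
    return landings, carbon, population
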