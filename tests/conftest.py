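import numpy as np
import pandas as pd
import pytest

from bluecarbonmbs import (
    GeneratorConfig,
    SchemeConfig,
    add_co2e,
    apply_scheme,
    generate_all,
    impute_carbon,
)


def make_record(**overrides) -> dict:
    """One landings record with sensible defaults, overridable per test."""
    rec = {
        "species": "sp1",
        "genus": "g1",
        "family": "f1",
        "year": 2011,
        "fao_area": "FAO_01",
        "eez": "E1",
        "country": "C1",
        "sector": "industrial",
        "gear": "other",
        "tonnes": 10.0,
        "value_usd": 20000.0,
    }
    rec.update(overrides)
    return rec


def landings_frame(*records) -> pd.DataFrame:
    return pd.DataFrame([make_record(**r) for r in records])


def carbon_frame(rows) -> pd.DataFrame:
    """rows: iterable of (species, genus, family, content-or-None)."""
    return pd.DataFrame(
        [
            {"species": s, "genus": g, "family": f, "tco2e_per_tonne": c}
            for s, g, f, c in rows
        ]
    )


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        seed=3,
        n_species=40,
        n_countries=8,
        n_eez=12,
        years=(2011, 2012),
        total_tonnes_per_year=1e5,
    )


@pytest.fixture(scope="session")
def small_tables(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def small_with_co2e(small_tables):
    landings, carbon, _ = small_tables
    return add_co2e(landings, impute_carbon(carbon))


@pytest.fixture(scope="session")
def small_removals(small_with_co2e):
    return apply_scheme(small_with_co2e, None, 200.0, SchemeConfig())


def random_removals(seed: int, n: int = 120, carbon_price: float = 150.0):
    """A small random removal table exercised by property tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "species": [f"sp{i % 17}" for i in range(n)],
            "genus": [f"g{i % 7}" for i in range(n)],
            "family": [f"f{i % 3}" for i in range(n)],
            "year": rng.choice([2011, 2012, 2013], n),
            "fao_area": [f"FAO_{i % 4}" for i in range(n)],
            "eez": [f"E{i % 9}" for i in range(n)],
            "country": [f"C{i % 5}" for i in range(n)],
            "sector": rng.choice(["artisanal", "industrial"], n),
            "gear": [f"gear{i % 5}" for i in range(n)],
            "tonnes": rng.lognormal(2.0, 1.0, n),
            "value_usd": rng.lognormal(9.0, 1.2, n),
            "co2e": rng.lognormal(2.3, 1.0, n),
        }
    )
    return apply_scheme(df, None, carbon_price, SchemeConfig())
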