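"""Withdrawal prices and the removal decision rule."""

import numpy as np
import pandas as pd
import pytest

from bluecarbonmbs import SchemeConfig, apply_scheme, withdrawal_price
from bluecarbonmbs.errors import ConfigurationError, DomainError
from conftest import make_record, random_removals


def test_config_rejects_nonpositive_factors_and_negative_prices():
    with pytest.raises(ConfigurationError):
        SchemeConfig(factor_industrial=0.0)
    with pytest.raises(ConfigurationError):
        SchemeConfig(factor_artisanal=-1.0)
    with pytest.raises(ConfigurationError):
        SchemeConfig(carbon_prices=(66.0, -1.0))
    with pytest.raises(ConfigurationError):
        SchemeConfig(tie_rule="flip_a_coin")


def test_withdrawal_price_industrial_example():
    """US$2000/t at 1.5 tCO2e/t and factor 0.14 -> 186.67 US$/tCO2e."""
    rec = make_record(sector="industrial", tonnes=10.0, value_usd=20000.0)
    wp = withdrawal_price(rec, co2e=15.0, config=SchemeConfig())
    assert wp == pytest.approx(0.14 * 2000.0 / 1.5, rel=1e-12)


def test_withdrawal_price_artisanal_identity():
    """Factor 1 and unit content: withdrawal price equals the market price."""
    rec = make_record(sector="artisanal", tonnes=1.0, value_usd=66.0)
    assert withdrawal_price(rec, co2e=1.0, config=SchemeConfig()) == pytest.approx(66.0)


def test_withdrawal_price_independent_of_tonnage():
    cfg = SchemeConfig()
    rec1 = make_record(tonnes=10.0, value_usd=20000.0)
    rec2 = make_record(tonnes=20.0, value_usd=40000.0)  # same price & content
    assert withdrawal_price(rec1, 15.0, cfg) == pytest.approx(
        withdrawal_price(rec2, 30.0, cfg)
    )


def test_withdrawal_price_rejects_nonpositive_co2e():
    with pytest.raises(DomainError):
        withdrawal_price(make_record(), 0.0, SchemeConfig())


def test_zero_carbon_price_removes_nothing(small_with_co2e):
    rem = apply_scheme(small_with_co2e, None, 0.0)
    assert not rem["removed"].any()
    assert rem["co2e"].where(rem["removed"], 0.0).sum() == 0.0
    assert rem["income_usd"].equals(rem["value_usd"])


def test_huge_carbon_price_removes_everything(small_with_co2e):
    rem = apply_scheme(small_with_co2e, None, 1e15)
    assert rem["removed"].all()
    assert rem["income_usd"].sum() == pytest.approx(1e15 * rem["co2e"].sum())


def test_single_record_decision_and_income():
    df = pd.DataFrame([make_record(tonnes=10.0, value_usd=20000.0)])
    df["co2e"] = 15.0  # withdrawal price 186.67
    rem = apply_scheme(df, None, 543.0)
    assert bool(rem["removed"].iloc[0])
    assert rem["income_usd"].iloc[0] == pytest.approx(543.0 * 15.0)
    # net basis credits avoided costs on top of the carbon revenue
    assert rem["income_net_usd"].iloc[0] == pytest.approx(
        543.0 * 15.0 + (1 - 0.14) * 20000.0
    )
    kept = apply_scheme(df, None, 100.0)
    assert not bool(kept["removed"].iloc[0])
    assert kept["income_usd"].iloc[0] == 20000.0


def test_tie_rule_at_exact_withdrawal_price():
    df = pd.DataFrame([make_record(sector="artisanal", tonnes=1.0, value_usd=66.0)])
    df["co2e"] = 1.0  # withdrawal price exactly 66
    keep = apply_scheme(df, None, 66.0, SchemeConfig(tie_rule="keep_fishing"))
    remove = apply_scheme(df, None, 66.0, SchemeConfig(tie_rule="remove"))
    assert not bool(keep["removed"].iloc[0])
    assert bool(remove["removed"].iloc[0])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_removal_set_monotone_in_price(seed):
    low = random_removals(seed, carbon_price=100.0)
    high = random_removals(seed, carbon_price=400.0)
    assert (low["removed"] <= high["removed"]).all()
    seq = lambda r: r["co2e"].where(r["removed"], 0.0).sum()
    assert seq(low) <= seq(high)


def test_higher_sector_factor_never_increases_removals(small_with_co2e):
    lo = apply_scheme(small_with_co2e, None, 200.0,
                      SchemeConfig(factor_industrial=0.14))
    hi = apply_scheme(small_with_co2e, None, 200.0,
                      SchemeConfig(factor_industrial=0.33))
    ind = small_with_co2e["sector"] == "industrial"
    assert (hi.loc[ind, "removed"] <= lo.loc[ind, "removed"]).all()
    # artisanal decisions untouched by the industrial factor
    assert hi.loc[~ind, "removed"].equals(lo.loc[~ind, "removed"])


@pytest.mark.parametrize("seed", [7, 8])
def test_equivalence_of_rule_framings(seed):
    """removed <=> carbon_price * co2e > factor * value (brute-force oracle)."""
    cfg = SchemeConfig()
    rem = random_removals(seed, carbon_price=150.0)
    for _, row in rem.iterrows():
        f = cfg.factor(row["sector"])
        expected = 150.0 * row["co2e"] > f * row["value_usd"]
        assert bool(row["removed"]) == expected


def test_artisanal_income_never_below_status_quo(small_with_co2e):
    rem = apply_scheme(small_with_co2e, None, 300.0)
    art = rem[(rem["sector"] == "artisanal") & rem["removed"]]
    assert (art["income_usd"] >= art["value_usd"]).all()


def test_net_income_never_below_status_quo_for_removed(small_with_co2e):
    rem = apply_scheme(small_with_co2e, None, 300.0)
    rm = rem[rem["removed"]]
    assert (rm["income_net_usd"] >= rm["value_usd"] - 1e-9).all()


def test_splitting_a_record_preserves_decision_and_totals():
    df = pd.DataFrame([make_record(tonnes=10.0, value_usd=20000.0)])
    df["co2e"] = 15.0
    halves = pd.concat([df, df], ignore_index=True)
    for col in ("tonnes", "value_usd", "co2e"):
        halves[col] = halves[col] / 2.0
    whole = apply_scheme(df, None, 543.0)
    split = apply_scheme(halves, None, 543.0)
    assert split["removed"].all() == whole["removed"].all()
    for col in ("co2e", "income_usd", "income_net_usd"):
        assert split[col].sum() == pytest.approx(whole[col].sum())


def test_negative_carbon_price_rejected(small_with_co2e):
    with pytest.raises(DomainError):
        apply_scheme(small_with_co2e, None, -1.0)
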