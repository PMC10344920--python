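"""Nutrient supply conversion, per-capita rates, and SSF contribution shares."""

import numpy as np
import pandas as pd
import pytest

from nutrisupply import (
    build_lookup,
    mean_contribution,
    nutrient_supply,
    per_capita_supply,
    ssf_contribution,
)
from nutrisupply.constants import NUTRIENTS
from nutrisupply.errors import UndefinedSupplyError

TAXONOMY = pd.DataFrame(
    {
        "scientific_name": ["A"],
        "genus": ["g"],
        "family": ["f"],
        "order": ["o"],
        "class_": ["k"],
        "commodity": ["m"],
    }
)


def profile_table(**overrides):
    row = {
        "scientific_name": "A", "genus": "g", "family": "f", "order": "o",
        "class_": "k", "commodity": "m",
        "iron": 1.0, "zinc": 1.0, "calcium": 20.0, "vitamin_a": 1.0,
        "vitamin_b12": 1.0, "dha_epa": 0.1, "protein": 20.0, "edible_fraction": 0.5,
    }
    row.update(overrides)
    return pd.DataFrame([row])


def consumption_df(rows):
    return pd.DataFrame(rows, columns=["country", "scientific_name", "sector", "tonnes"])


def test_one_tonne_unit_arithmetic():
    """1 t at edible fraction 0.5 and 20 mg calcium/100 g → 100,000 mg/yr."""
    lookup = build_lookup(profile_table())
    cons = consumption_df([("X", "A", "artisanal", 1.0)])
    supply = nutrient_supply(cons, lookup, TAXONOMY)
    cal = supply.query("nutrient == 'calcium'")["mass_per_year"].iloc[0]
    assert cal == pytest.approx(1.0 * 1e4 * 0.5 * 20.0)


def test_zero_catch_gives_zero_supply():
    lookup = build_lookup(profile_table())
    cons = consumption_df([("X", "A", "artisanal", 0.0)])
    supply = nutrient_supply(cons, lookup, TAXONOMY)
    assert (supply["mass_per_year"] == 0.0).all()


def pops(coastal, national):
    return (
        pd.DataFrame({"country": ["X"], "buffer_km": [50.0], "persons": [coastal]}),
        pd.DataFrame({"country": ["X"], "persons": [national]}),
    )


def test_per_capita_daily_rate():
    """365 g per year over one coastal resident → 1 g per day."""
    supply = pd.DataFrame(
        {"country": ["X"], "sector": ["artisanal"], "nutrient": ["protein"],
         "mass_per_year": [365.0]}
    )
    coastal, national = pops(1.0, 100.0)
    out = per_capita_supply(supply, coastal, national)
    assert out["per_capita_per_day"].iloc[0] == pytest.approx(1.0)


def test_doubling_coastal_population_halves_ssf_per_capita_supply():
    supply = pd.DataFrame(
        {"country": ["X"], "sector": ["subsistence"], "nutrient": ["iron"],
         "mass_per_year": [730.0]}
    )
    one = per_capita_supply(supply, *pops(10.0, 100.0))["per_capita_per_day"].iloc[0]
    two = per_capita_supply(supply, *pops(20.0, 100.0))["per_capita_per_day"].iloc[0]
    assert two == pytest.approx(one / 2)


def test_national_population_divides_non_ssf_sectors():
    supply = pd.DataFrame(
        {"country": ["X", "X"], "sector": ["artisanal", "industrial"],
         "nutrient": ["iron", "iron"], "mass_per_year": [365.0, 365.0]}
    )
    out = per_capita_supply(supply, *pops(10.0, 1000.0)).set_index("sector")
    assert out.loc["artisanal", "per_capita_per_day"] == pytest.approx(0.1)
    assert out.loc["industrial", "per_capita_per_day"] == pytest.approx(0.001)


def test_zero_population_with_supply_is_an_explicit_error():
    supply = pd.DataFrame(
        {"country": ["X"], "sector": ["artisanal"], "nutrient": ["iron"],
         "mass_per_year": [10.0]}
    )
    with pytest.raises(UndefinedSupplyError):
        per_capita_supply(supply, *pops(0.0, 100.0))


def percap_df(rows):
    return pd.DataFrame(
        rows, columns=["country", "sector", "nutrient", "per_capita_per_day"]
    )


def gnd_df(rows):
    return pd.DataFrame(rows, columns=["country", "food_group", "nutrient", "per_capita_per_day"])


def test_only_ssf_seafood_gives_seafood_fraction_one():
    percap = percap_df([("X", "artisanal", "iron", 2.0), ("X", "subsistence", "iron", 1.0)])
    out = ssf_contribution(percap, gnd_df([]), "seafood")
    assert out["ssf_fraction"].iloc[0] == pytest.approx(1.0)


def test_dha_epa_contribution_is_scope_invariant():
    """All DHA+EPA is assumed to come from seafood, so every scope agrees."""
    percap = percap_df(
        [("X", "artisanal", "dha_epa", 1.0), ("X", "industrial", "dha_epa", 3.0)]
    )
    gnd = gnd_df([("X", "beef", "dha_epa", 5.0), ("X", "grains", "dha_epa", 2.0)])
    fracs = [
        ssf_contribution(percap, gnd, scope)["ssf_fraction"].iloc[0]
        for scope in ("seafood", "animal_sourced", "all_foods")
    ]
    assert fracs[0] == pytest.approx(0.25)
    assert fracs[0] == fracs[1] == fracs[2]


def test_scope_denominators_nest():
    percap = percap_df([("X", "artisanal", "iron", 1.0), ("X", "imports", "iron", 1.0)])
    gnd = gnd_df([("X", "beef", "iron", 2.0), ("X", "grains", "iron", 4.0)])
    sf = ssf_contribution(percap, gnd, "seafood")["ssf_fraction"].iloc[0]
    asf = ssf_contribution(percap, gnd, "animal_sourced")["ssf_fraction"].iloc[0]
    allf = ssf_contribution(percap, gnd, "all_foods")["ssf_fraction"].iloc[0]
    assert sf == pytest.approx(0.5)
    assert asf == pytest.approx(1.0 / 4.0)
    assert allf == pytest.approx(1.0 / 8.0)
    assert allf <= asf <= sf


def test_undefined_denominator_is_missing_not_zero():
    percap = percap_df([("X", "artisanal", "iron", 0.0)])
    out = ssf_contribution(percap, gnd_df([]), "seafood")
    assert np.isnan(out["ssf_fraction"].iloc[0])


def contributions_df(country, fracs, scope="all_foods"):
    return pd.DataFrame(
        [
            {"country": country, "nutrient": nut, "denominator_scope": scope,
             "ssf_fraction": v}
            for nut, v in fracs.items()
        ]
    )


def test_mean_is_unweighted_over_six_nutrients():
    six = ["iron", "zinc", "calcium", "vitamin_a", "vitamin_b12", "dha_epa"]
    recs = contributions_df("X", {n: 0.1 for n in six})
    out = mean_contribution(recs)
    assert out["mean_ssf_contribution"].iloc[0] == pytest.approx(0.1)
    recs2 = contributions_df("X", dict(zip(six, [0, 0, 0, 0, 0, 0.6])))
    assert mean_contribution(recs2)["mean_ssf_contribution"].iloc[0] == pytest.approx(0.1)


def test_protein_is_excluded_from_the_mean():
    six = ["iron", "zinc", "calcium", "vitamin_a", "vitamin_b12", "dha_epa"]
    recs = contributions_df("X", {**{n: 0.2 for n in six}, "protein": 1.0})
    assert mean_contribution(recs)["mean_ssf_contribution"].iloc[0] == pytest.approx(0.2)


def test_missing_nutrients_are_flagged_and_mean_uses_available_ones():
    recs = contributions_df("X", {"iron": 0.3, "zinc": np.nan, "calcium": 0.1,
                                  "vitamin_a": np.nan, "vitamin_b12": 0.2,
                                  "dha_epa": np.nan})
    out = mean_contribution(recs)
    assert out["any_missing"].iloc[0]
    assert out["mean_ssf_contribution"].iloc[0] == pytest.approx(0.2)


def test_sector_fractions_sum_to_one_where_seafood_positive(small_results):
    """Across sectors, shares of the seafood denominator are complete."""
    percap = small_results.percap
    totals = percap.groupby(["country", "nutrient"])["per_capita_per_day"].sum()
    for (c, n), total in totals.items():
        if total <= 0:
            continue
        shares = percap.query("country == @c and nutrient == @n")["per_capita_per_day"] / total
        assert shares.sum() == pytest.approx(1.0, abs=1e-9)
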