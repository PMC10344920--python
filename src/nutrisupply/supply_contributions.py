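"""Nutrient supply by sector and the SSF share of it.

Consumption tonnage is converted to nutrient mass with

    mass / yr = tonnes × 10^4 (hundred-gram units per tonne)
                × edible_fraction × concentration per 100 g,

summed over taxa within country × sector × nutrient. Per-capita daily
supply divides small-scale sectors (artisanal, subsistence) by the coastal
population — their catch is assumed eaten by coastal residents — and every
other source (industrial, recreational, mariculture, imports) by the
national population.

The small-scale contribution is then the SSF per-capita supply over one of
three denominators describing a coastal resident's diet: all seafood
sources; seafood plus the non-seafood animal-sourced food groups; or
seafood plus all non-seafood food groups (national per-capita averages from
a GND-style table). DHA+EPA is assumed to come exclusively from seafood,
so non-seafood terms are zeroed from its denominators in every scope.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import (
    ANIMAL_FOOD_GROUPS,
    ASSESSED_NUTRIENTS,
    COASTAL_DENOMINATOR_SECTORS,
    COMMODITY_TAXON_PREFIX,
    DAYS_PER_YEAR,
    HG_PER_TONNE,
    NUTRIENTS,
    SEAFOOD_ONLY_NUTRIENT,
)
from .errors import DataError, UndefinedSupplyError
from .nutrient_matching import MatchResult, NutrientLookup, TaxonKey, match_nutrients

SCOPES = ("seafood", "animal_sourced", "all_foods")


def taxon_keys_for(
    taxa: Iterable[str], taxonomy: pd.DataFrame
) -> dict[str, TaxonKey]:
    """Build a TaxonKey per consumption taxon.

    ``commodity:<category>`` placeholders (import rows) key on the commodity
    alone; real taxa take their ranks from the taxonomy table.
    """
    tax = taxonomy.set_index("scientific_name")
    keys: dict[str, TaxonKey] = {}
    for t in taxa:
        if t.startswith(COMMODITY_TAXON_PREFIX):
            keys[t] = TaxonKey(commodity=t[len(COMMODITY_TAXON_PREFIX):])
        else:
            if t not in tax.index:
                raise DataError(f"taxon {t!r} missing from taxonomy table")
            row = tax.loc[t]
            keys[t] = TaxonKey(
                scientific_name=t,
                genus=row["genus"],
                family=row["family"],
                order=row["order"],
                class_=row["class_"],
                commodity=row["commodity"],
            )
    return keys


def match_consumption_taxa(
    consumption: pd.DataFrame, taxonomy: pd.DataFrame, lookup: NutrientLookup
) -> dict[str, MatchResult]:
    """Match every distinct taxon in the consumption table once."""
    keys = taxon_keys_for(consumption["scientific_name"].unique(), taxonomy)
    return {t: match_nutrients(k, lookup) for t, k in keys.items()}


def nutrient_supply(
    consumption: pd.DataFrame,
    lookup: NutrientLookup,
    taxonomy: pd.DataFrame,
    matches: Mapping[str, MatchResult] | None = None,
) -> pd.DataFrame:
    """Convert the consumption table to nutrient mass per year.

    Returns ``country, sector, nutrient, mass_per_year`` (long form), with
    each nutrient in its own concentration unit (mg, µg or g per year).
    """
    if matches is None:
        matches = match_consumption_taxa(consumption, taxonomy, lookup)
    conc = pd.DataFrame(
        {t: m.profile.as_dict() for t, m in matches.items()}
    ).T  # taxon × fields
    df = consumption.copy()
    for n in NUTRIENTS:
        df[n] = (
            df["tonnes"].to_numpy()
            * HG_PER_TONNE
            * conc["edible_fraction"].reindex(df["scientific_name"]).to_numpy()
            * conc[n].reindex(df["scientific_name"]).to_numpy()
        )
    long = df.melt(
        id_vars=["country", "sector"],
        value_vars=list(NUTRIENTS),
        var_name="nutrient",
        value_name="mass_per_year",
    )
    out = (
        long.groupby(["country", "sector", "nutrient"], as_index=False)["mass_per_year"]
        .sum()
    )
    if (out["mass_per_year"] < 0).any():
        raise DataError("negative nutrient supply")
    return out


def per_capita_supply(
    supply: pd.DataFrame,
    coastal_pop: pd.DataFrame,
    national_pop: pd.DataFrame,
) -> pd.DataFrame:
    """Fill the per-capita-per-day column of the supply table.

    Artisanal and subsistence supply is divided by the coastal population;
    all other sectors by the national population; then by 365 for a daily
    rate. A zero population under nonzero supply raises
    :class:`UndefinedSupplyError` naming the country.
    """
    cp = coastal_pop.set_index("country")["persons"]
    np_ = national_pop.set_index("country")["persons"]
    out = supply.copy()
    is_ssf = out["sector"].isin(COASTAL_DENOMINATOR_SECTORS)
    pop = np.where(
        is_ssf, cp.reindex(out["country"]).to_numpy(), np_.reindex(out["country"]).to_numpy()
    )
    bad = (pop <= 0) & (out["mass_per_year"].to_numpy() > 0)
    if bad.any():
        offenders = sorted(out.loc[bad, "country"].unique())
        raise UndefinedSupplyError(
            f"nonzero supply with zero population in {offenders}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = out["mass_per_year"].to_numpy() / (pop * DAYS_PER_YEAR)
    out["per_capita_per_day"] = np.where(out["mass_per_year"].to_numpy() == 0, 0.0, pc)
    return out


def _gnd_sums(gnd: pd.DataFrame, groups: tuple[str, ...]) -> pd.Series:
    sub = gnd[gnd["food_group"].isin(groups)]
    return sub.groupby(["country", "nutrient"])["per_capita_per_day"].sum()


def ssf_contribution(
    percap: pd.DataFrame, gnd: pd.DataFrame, scope: str
) -> pd.DataFrame:
    """Small-scale fisheries' share of per-capita nutrient supply.

    ``scope`` selects the denominator: ``seafood`` (all seafood source
    sectors), ``animal_sourced`` (seafood + non-seafood animal groups), or
    ``all_foods`` (seafood + every non-seafood group). An undefined (0/0)
    denominator yields a missing (NaN) fraction, never zero.

    Returns ``country, nutrient, denominator_scope, ssf_fraction``.
    """
    if scope not in SCOPES:
        raise DataError(f"unknown denominator scope {scope!r}")
    by_cn = percap.groupby(["country", "nutrient"])
    seafood = by_cn["per_capita_per_day"].sum()
    ssf = (
        percap[percap["sector"].isin(COASTAL_DENOMINATOR_SECTORS)]
        .groupby(["country", "nutrient"])["per_capita_per_day"]
        .sum()
        .reindex(seafood.index, fill_value=0.0)
    )
    if scope == "seafood":
        nonseafood = pd.Series(0.0, index=seafood.index)
    else:
        groups = ANIMAL_FOOD_GROUPS if scope == "animal_sourced" else tuple(
            gnd["food_group"].unique()
        )
        nonseafood = _gnd_sums(gnd, tuple(groups)).reindex(seafood.index, fill_value=0.0)
    # seafood is assumed to be the only DHA+EPA source
    idx = seafood.index.get_level_values("nutrient") == SEAFOOD_ONLY_NUTRIENT
    nonseafood = nonseafood.copy()
    nonseafood[idx] = 0.0
    denom = seafood + nonseafood
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, ssf / denom, np.nan)
    out = seafood.reset_index()[["country", "nutrient"]]
    out["denominator_scope"] = scope
    out["ssf_fraction"] = frac
    return out


def mean_contribution(
    records: pd.DataFrame, nutrients: tuple[str, ...] = ASSESSED_NUTRIENTS
) -> pd.DataFrame:
    """Unweighted per-country mean fraction over the assessed nutrients.

    Protein is excluded by default. Countries with one or more missing
    nutrient fractions are averaged over the available ones and flagged via
    ``any_missing``; a country with no available nutrient gets NaN.

    Returns ``country, mean_ssf_contribution, n_nutrients, any_missing``.
    """
    sub = records[records["nutrient"].isin(nutrients)]
    grouped = sub.groupby("country")["ssf_fraction"]
    mean = grouped.mean()  # skips NaN
    n_avail = grouped.count()
    return pd.DataFrame(
        {
            "country": mean.index,
            "mean_ssf_contribution": mean.to_numpy(),
            "n_nutrients": n_avail.to_numpy(),
            "any_missing": (n_avail < len(nutrients)).to_numpy(),
        }
    )
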