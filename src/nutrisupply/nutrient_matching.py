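"""Hierarchical assignment of nutrient profiles to taxa.

Food-composition records rarely cover every harvested species, so each taxon
is matched by walking a six-level fallback chain with sequential priority:

1. mean over records sharing the species' scientific name,
2. mean over the species' genus,
3. mean over the family,
4. mean over the order,
5. mean over the class,
6. mean over the taxon's fish commodity category (terminal; import flows,
   which are resolved only to commodity, always match here).

Means are unweighted arithmetic means over the records available at the
level. The reported match level is the first level at which at least one
record exists; when that level's mean is undefined for an individual
nutrient (every record there is missing it), only that nutrient falls
through to the next level, so a partially measured congener never blocks
the use of its measured nutrients.

Name matching is exact after case-folding and whitespace normalisation;
there is no fuzzy matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import MATCH_LEVELS, NUTRIENTS, RANK_COLUMNS
from .errors import DataError, UnmatchedTaxonError

#: profile value columns, in table order
PROFILE_FIELDS = NUTRIENTS + ("edible_fraction",)


def normalize_name(name: object) -> str:
    """Case-fold and collapse internal whitespace; '' for blank/NaN."""
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class TaxonKey:
    """Taxonomic identity of a production record.

    The commodity category is always present (it is the terminal fallback);
    ranks above the lowest resolved one may be blank.
    """

    scientific_name: str = ""
    genus: str = ""
    family: str = ""
    order: str = ""
    class_: str = ""
    commodity: str = ""

    def rank_value(self, level: str) -> str:
        return getattr(self, "class_" if level == "class" else RANK_COLUMNS[level])


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g edible raw muscle concentrations plus the edible fraction.

    Units: iron/zinc/calcium mg, vitamin_a µg RAE, vitamin_b12 µg,
    dha_epa/protein g; edible_fraction is the consumable share of live
    weight. NaN marks a value unavailable even at the commodity level.
    """

    key: TaxonKey | None = None
    iron: float = np.nan
    zinc: float = np.nan
    calcium: float = np.nan
    vitamin_a: float = np.nan
    vitamin_b12: float = np.nan
    dha_epa: float = np.nan
    protein: float = np.nan
    edible_fraction: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in PROFILE_FIELDS}


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one taxon.

    ``level`` is the highest-priority level at which any profile record
    existed; ``field_levels`` records, per nutrient, the (possibly deeper)
    level its value was actually taken from.
    """

    profile: NutrientProfile
    level: str
    field_levels: Mapping[str, str] = field(default_factory=dict)


class NutrientLookup:
    """Pre-aggregated rank means over a profile table.

    For every level and rank value, stores the arithmetic mean of each
    profile field over records carrying that value (NaN where all records
    at the level are missing the field) and the record count.
    """

    def __init__(self, means: dict[str, pd.DataFrame], n_profiles: int):
        self._means = means
        self.n_profiles = n_profiles

    def levels(self) -> tuple[str, ...]:
        return MATCH_LEVELS

    def has(self, level: str, value: str) -> bool:
        key = normalize_name(value)
        return bool(key) and key in self._means[level].index

    def mean_row(self, level: str, value: str) -> pd.Series:
        return self._means[level].loc[normalize_name(value)]

    def known_values(self, level: str) -> list[str]:
        return list(self._means[level].index)


def build_lookup(profiles: pd.DataFrame) -> NutrientLookup:
    """Index a profile table for mean-aggregation queries at every rank.

    ``profiles`` needs the rank columns (``scientific_name``, ``genus``,
    ``family``, ``order``, ``class_``, ``commodity``) and the value columns
    in :data:`PROFILE_FIELDS`; blank rank cells are allowed above the lowest
    resolved rank, but every record must carry a commodity label.
    """
    if profiles is None or len(profiles) == 0:
        raise DataError("profile table is empty; cannot build a nutrient lookup")
    df = profiles.copy()
    for level in MATCH_LEVELS:
        col = RANK_COLUMNS[level]
        if col not in df.columns:
            raise DataError(f"profile table is missing rank column {col!r}")
        df[col] = df[col].map(normalize_name)
    if (df["commodity"] == "").any():
        raise DataError("every nutrient profile must carry a commodity label")
    for f in PROFILE_FIELDS:
        if f not in df.columns:
            raise DataError(f"profile table is missing value column {f!r}")
        df[f] = pd.to_numeric(df[f], errors="coerce")

    means: dict[str, pd.DataFrame] = {}
    for level in MATCH_LEVELS:
        col = RANK_COLUMNS[level]
        sub = df[df[col] != ""]
        if len(sub) == 0:
            means[level] = pd.DataFrame(columns=list(PROFILE_FIELDS) + ["n_records"])
            continue
        grouped = sub.groupby(col)[list(PROFILE_FIELDS)].mean()
        grouped["n_records"] = sub.groupby(col).size()
        means[level] = grouped
    return NutrientLookup(means, n_profiles=len(df))


def match_nutrients(taxon: TaxonKey, lookup: NutrientLookup) -> MatchResult:
    """Match one taxon against the lookup, walking the fallback chain.

    Raises :class:`UnmatchedTaxonError` if no level matches — possible only
    when the taxon's commodity category has no profile records at all.
    """
    match_level: str | None = None
    level_rows: list[tuple[str, pd.Series]] = []
    for level in MATCH_LEVELS:
        value = taxon.rank_value(level)
        if lookup.has(level, value):
            if match_level is None:
                match_level = level
            level_rows.append((level, lookup.mean_row(level, value)))
    if match_level is None:
        raise UnmatchedTaxonError(taxon)

    values: dict[str, float] = {}
    field_levels: dict[str, str] = {}
    for f in PROFILE_FIELDS:
        values[f] = np.nan
        for level, row in level_rows:
            v = row[f]
            if not pd.isna(v):
                values[f] = float(v)
                field_levels[f] = level
                break
    return MatchResult(
        profile=NutrientProfile(key=taxon, **values),
        level=match_level,
        field_levels=field_levels,
    )


def match_statistics(results: Iterable[MatchResult]) -> dict[str, float]:
    """Per-level match fractions plus the combined species+genus+family share.

    Fractions over the six levels sum to 1; ``species_genus_family`` reports
    the share matched at family level or better.
    """
    results = list(results)
    if not results:
        raise DataError("match_statistics requires at least one result")
    n = len(results)
    counts = {level: 0 for level in MATCH_LEVELS}
    for r in results:
        counts[r.level] += 1
    stats = {level: counts[level] / n for level in MATCH_LEVELS}
    stats["species_genus_family"] = (
        (counts["species"] + counts["genus"] + counts["family"]) / n
    )
    return stats


def commodity_profile(category: str, lookup: NutrientLookup) -> NutrientProfile:
    """Mean profile over all records in one commodity category.

    Used for import flows, which the trade tables resolve only to commodity.
    """
    if not lookup.has("commodity", category):
        raise DataError(f"unknown commodity category {category!r}")
    row = lookup.mean_row("commodity", category)
    return NutrientProfile(
        key=TaxonKey(commodity=normalize_name(category)),
        **{f: float(row[f]) if not pd.isna(row[f]) else np.nan for f in PROFILE_FIELDS},
    )
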