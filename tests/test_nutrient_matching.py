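"""Hierarchical nutrient matching against brute-force scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import FIELDS, brute_force_match
from nutrisupply import TaxonKey, build_lookup, commodity_profile, match_nutrients, match_statistics
from nutrisupply.errors import DataError, UnmatchedTaxonError


def make_profiles(rows):
    base = {c: "" for c in ["scientific_name", "genus", "family", "order", "class_"]}
    base.update({f: np.nan for f in FIELDS})
    return pd.DataFrame([{**base, **r} for r in rows])


def random_profiles(rng, n, n_missing_fields=0.2):
    rows = []
    for i in range(n):
        row = {
            "scientific_name": f"sp{rng.integers(12)}",
            "genus": f"g{rng.integers(6)}",
            "family": f"f{rng.integers(4)}",
            "order": f"o{rng.integers(3)}",
            "class_": f"k{rng.integers(2)}",
            "commodity": f"m{rng.integers(2)}",
        }
        for f in FIELDS:
            row[f] = np.nan if rng.random() < n_missing_fields else float(rng.uniform(0.1, 50))
        rows.append(row)
    return pd.DataFrame(rows)


def test_rank_means_are_unweighted_arithmetic_means():
    prof = make_profiles(
        [
            {"scientific_name": "a", "genus": "g1", "commodity": "m", "calcium": 10.0},
            {"scientific_name": "b", "genus": "g1", "commodity": "m", "calcium": 30.0},
        ]
    )
    lookup = build_lookup(prof)
    assert lookup.mean_row("genus", "g1")["calcium"] == pytest.approx(20.0)


def test_single_profile_defines_every_rank_mean():
    prof = make_profiles(
        [{"scientific_name": "a", "genus": "g", "family": "f", "order": "o",
          "class_": "k", "commodity": "m", "zinc": 7.0, "edible_fraction": 0.5}]
    )
    lookup = build_lookup(prof)
    for level, value in [("species", "a"), ("genus", "g"), ("family", "f"),
                         ("order", "o"), ("class", "k"), ("commodity", "m")]:
        assert lookup.mean_row(level, value)["zinc"] == pytest.approx(7.0)


def test_randomized_rank_means_equal_groupby_oracle():
    rng = np.random.default_rng(42)
    prof = random_profiles(rng, 200)
    lookup = build_lookup(prof)
    for level, col in [("genus", "genus"), ("family", "family"), ("commodity", "commodity")]:
        for value, grp in prof.groupby(col):
            for f in FIELDS:
                expected = grp[f].dropna()
                got = lookup.mean_row(level, value)[f]
                if len(expected) == 0:
                    assert pd.isna(got)
                else:
                    assert got == pytest.approx(expected.mean())


def test_species_match_takes_priority():
    prof = make_profiles(
        [
            {"scientific_name": "a", "genus": "g", "commodity": "m", "iron": 1.0},
            {"scientific_name": "b", "genus": "g", "commodity": "m", "iron": 9.0},
        ]
    )
    res = match_nutrients(TaxonKey(scientific_name="a", genus="g", commodity="m"),
                          build_lookup(prof))
    assert res.level == "species"
    assert res.profile.iron == pytest.approx(1.0)


def test_commodity_is_the_terminal_fallback():
    prof = make_profiles([{"scientific_name": "x", "commodity": "m", "iron": 3.0}])
    res = match_nutrients(
        TaxonKey(scientific_name="unseen", genus="nog", family="nof",
                 order="noo", class_="nok", commodity="m"),
        build_lookup(prof),
    )
    assert res.level == "commodity"
    assert res.profile.iron == pytest.approx(3.0)


def test_unmatched_commodity_raises_carrying_the_taxon():
    prof = make_profiles([{"scientific_name": "x", "commodity": "m", "iron": 3.0}])
    taxon = TaxonKey(scientific_name="y", commodity="other")
    with pytest.raises(UnmatchedTaxonError) as exc:
        match_nutrients(taxon, build_lookup(prof))
    assert exc.value.taxon == taxon


def test_per_nutrient_missingness_falls_back_one_level_only():
    """A genus-level match missing one nutrient takes it from the family."""
    prof = make_profiles(
        [
            {"scientific_name": "a", "genus": "g", "family": "f", "commodity": "m",
             "iron": 2.0},  # zinc missing at genus level
            {"scientific_name": "b", "genus": "other", "family": "f", "commodity": "m",
             "iron": 10.0, "zinc": 4.0},
        ]
    )
    res = match_nutrients(TaxonKey(scientific_name="zz", genus="g", family="f",
                                   commodity="m"), build_lookup(prof))
    assert res.level == "genus"
    assert res.profile.iron == pytest.approx(2.0)
    assert res.profile.zinc == pytest.approx(4.0)
    assert res.field_levels["zinc"] == "family"


def test_randomized_matching_equals_brute_force_scan():
    rng = np.random.default_rng(7)
    for _ in range(30):
        prof = random_profiles(rng, int(rng.integers(3, 40)))
        lookup = build_lookup(prof)
        rows = prof.to_dict("records")
        for _ in range(10):
            taxon = TaxonKey(
                scientific_name=f"sp{rng.integers(14)}",
                genus=f"g{rng.integers(7)}",
                family=f"f{rng.integers(5)}",
                order=f"o{rng.integers(4)}",
                class_=f"k{rng.integers(3)}",
                commodity=f"m{rng.integers(2)}",
            )
            expected = brute_force_match(
                {"scientific_name": taxon.scientific_name, "genus": taxon.genus,
                 "family": taxon.family, "order": taxon.order, "class_": taxon.class_,
                 "commodity": taxon.commodity},
                rows,
            )
            if expected is None:
                with pytest.raises(UnmatchedTaxonError):
                    match_nutrients(taxon, lookup)
                continue
            level, fields = expected
            res = match_nutrients(taxon, lookup)
            assert res.level == level
            for f, v in fields.items():
                got = getattr(res.profile, f)
                if v is None:
                    assert pd.isna(got)
                else:
                    assert got == pytest.approx(v, rel=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_adding_a_species_profile_never_coarsens_the_match(seed):
    """Monotone specificity: new species-level data can only sharpen a match."""
    rng = np.random.default_rng(seed)
    prof = random_profiles(rng, int(rng.integers(2, 25)))
    taxon = TaxonKey(scientific_name="target sp", genus="g0", family="f0",
                     order="o0", class_="k0", commodity="m0")
    order = {lvl: i for i, lvl in enumerate(
        ["species", "genus", "family", "order", "class", "commodity"])}
    try:
        before = order[match_nutrients(taxon, build_lookup(prof)).level]
    except UnmatchedTaxonError:
        before = len(order)
    extra = prof.iloc[[0]].copy()
    extra["scientific_name"] = "target sp"
    after = match_nutrients(taxon, build_lookup(pd.concat([prof, extra]))).level
    assert order[after] <= before
    assert after == "species"


def test_match_statistics_fractions_count_levels():
    prof = make_profiles(
        [{"scientific_name": f"s{i}", "genus": "g", "family": "f", "commodity": "m",
          "iron": 1.0} for i in range(3)]
    )
    lookup = build_lookup(prof)
    results = (
        [match_nutrients(TaxonKey(scientific_name="s0", commodity="m"), lookup)] * 4
        + [match_nutrients(TaxonKey(scientific_name="q", genus="g", commodity="m"), lookup)] * 3
        + [match_nutrients(TaxonKey(scientific_name="q", commodity="m"), lookup)] * 3
    )
    stats = match_statistics(results)
    assert stats["species"] == pytest.approx(0.4)
    assert stats["genus"] == pytest.approx(0.3)
    assert stats["commodity"] == pytest.approx(0.3)
    assert stats["species_genus_family"] == pytest.approx(0.7)
    assert sum(stats[lvl] for lvl in
               ["species", "genus", "family", "order", "class", "commodity"]) == pytest.approx(1.0)


def test_commodity_profile_is_the_category_mean():
    prof = make_profiles(
        [
            {"scientific_name": "a", "commodity": "m", "zinc": 1.0},
            {"scientific_name": "b", "commodity": "m", "zinc": 3.0},
            {"scientific_name": "c", "commodity": "other", "zinc": 99.0},
        ]
    )
    lookup = build_lookup(prof)
    assert commodity_profile("m", lookup).zinc == pytest.approx(2.0)
    with pytest.raises(DataError):
        commodity_profile("unknown", lookup)


def test_empty_profile_table_is_a_data_error():
    with pytest.raises(DataError):
        build_lookup(pd.DataFrame())
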