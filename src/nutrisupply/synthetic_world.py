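"""Self-consistent miniature world with analytically known ground truth.

The generator emits every table the pipeline consumes — catch by country ×
species × sector × end use, mariculture, trade flows, food-balance-sheet
production, taxonomically keyed nutrient profiles, a gridded population with
per-country coastlines, GND-style non-seafood supply, and inadequate-intake
prevalence — and simultaneously books the expected output of every
downstream stage (apparent consumption, nutrient supply, contribution
fractions, classification flags) by direct closed-form accounting over the
records it just drew. The bookkeeping never calls the pipeline modules, so
recovering it end-to-end is a genuine test of the pipeline.

Geometry is deliberately simple: each country is a rectangle on a plane
whose western edge (x = 0) is its coastline, so a cell's distance to the
coast is exactly its x coordinate and coastal populations have closed
forms. Nutrient concentrations are drawn log-uniformly within biologically
plausible per-100 g ranges (heavy-tailed, which stresses the hierarchical
matcher), and profile records are withheld per taxonomic rank so that every
fallback level of the matcher is exercised by construction.

All accumulation in the bookkeeping uses :func:`math.fsum` (exactly rounded,
order-independent), so the independent re-derivation in
:func:`ground_truth_contributions` reproduces it bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import fsum
from typing import Mapping

import numpy as np
import pandas as pd

from .config import WorldConfig
from .constants import (
    ANIMAL_FOOD_GROUPS,
    ASSESSED_NUTRIENTS,
    CATCH_SECTORS,
    COMMERCIAL_SECTORS,
    COMMODITIES,
    COMMODITY_TAXON_PREFIX,
    CRUSTACEAN_COMMODITY,
    DAYS_PER_YEAR,
    DIRECT_HUMAN_CONSUMPTION,
    GND_FOOD_GROUPS,
    HG_PER_TONNE,
    IMPORT_SECTOR,
    MATCH_LEVELS,
    NONCOMMERCIAL_SECTORS,
    NUTRIENTS,
    PLANT_FOOD_GROUPS,
    RANK_COLUMNS,
    SEAFOOD_ONLY_NUTRIENT,
    SSF_SECTORS,
)

#: log10 ranges of per-100 g concentrations in edible raw muscle tissue
CONCENTRATION_RANGES = {
    "iron": (0.1, 10.0),        # mg
    "zinc": (0.2, 15.0),        # mg
    "calcium": (5.0, 500.0),    # mg
    "vitamin_a": (1.0, 1000.0),  # µg RAE
    "vitamin_b12": (0.5, 20.0),  # µg
    "dha_epa": (0.05, 3.0),     # g
}
PROTEIN_RANGE = (15.0, 25.0)       # g, uniform (protein varies little)
EDIBLE_FRACTION_RANGE = (0.3, 0.9)

#: per-capita daily non-seafood supply ranges per food group (same units as
#: the corresponding concentration)
GND_RANGES = {
    "iron": (0.05, 5.0),
    "zinc": (0.05, 5.0),
    "calcium": (5.0, 400.0),
    "vitamin_a": (5.0, 300.0),
    "vitamin_b12": (0.05, 2.0),   # animal groups only
    "dha_epa": (0.001, 0.05),     # animal groups only; zeroed downstream
    "protein": (1.0, 30.0),
}

#: probability an individual nutrient value is missing from a kept profile
PER_NUTRIENT_MISSINGNESS = 0.10
#: share of countries with no inadequate-intake data at all
INTAKE_MISSING_SHARE = 0.15

COUNTRY_RECT_DEPTH_KM = 300.0
COUNTRY_RECT_HEIGHT_KM = 200.0
COUNTRY_RECT_SPACING_KM = 400.0


@dataclass
class GroundTruth:
    """Expected pipeline outputs, bookkept inside the generator.

    Keys: consumption ``(country, taxon, sector)``; supply
    ``(country, sector, nutrient)``; contributions ``(country, nutrient)``
    (None = undefined denominator); flags per country with None for
    missing-data vulnerability.
    """

    expected_apparent_consumption: dict = field(default_factory=dict)
    expected_supply: dict = field(default_factory=dict)
    expected_contribution_seafood: dict = field(default_factory=dict)
    expected_contribution_asf: dict = field(default_factory=dict)
    expected_contribution_allfoods: dict = field(default_factory=dict)
    expected_mean_contribution: dict = field(default_factory=dict)
    expected_coastal_population: dict = field(default_factory=dict)
    expected_flags: dict = field(default_factory=dict)


@dataclass
class SyntheticWorld:
    """All generated tables plus the bookkept ground truth."""

    config: WorldConfig
    catch: pd.DataFrame
    mariculture: pd.DataFrame
    trade: pd.DataFrame
    fbs_production: pd.DataFrame
    profiles: pd.DataFrame
    taxonomy: pd.DataFrame
    population_cells: pd.DataFrame
    coastline: pd.DataFrame
    gnd: pd.DataFrame
    inadequate_intake: pd.DataFrame
    crustacean_fractions: pd.DataFrame
    truth: GroundTruth | None = None

    @property
    def countries(self) -> list[str]:
        return sorted(self.population_cells["country"].unique())


def _log_uniform(rng, lo, hi, size=None):
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size)


def _build_taxonomy(rng, config: WorldConfig) -> pd.DataFrame:
    shape = config.taxonomy_shape
    classes = [f"Class{i:02d}" for i in range(shape["class"])]
    orders = [f"Order{i:02d}" for i in range(shape["order"])]
    families = [f"Family{i:02d}" for i in range(shape["family"])]
    genera = [f"Genus{i:02d}" for i in range(shape["genus"])]
    order_class = {o: classes[i % len(classes)] for i, o in enumerate(orders)}
    family_order = {f: orders[i % len(orders)] for i, f in enumerate(families)}
    genus_family = {g: families[i % len(families)] for i, g in enumerate(genera)}
    # family → commodity; first families pinned so every commodity is populated
    family_commodity = {}
    for i, f in enumerate(families):
        if i < len(COMMODITIES):
            family_commodity[f] = COMMODITIES[i]
        else:
            family_commodity[f] = COMMODITIES[rng.integers(len(COMMODITIES))]
    rows = []
    for i in range(config.n_species):
        g = genera[i % len(genera)]
        fam = genus_family[g]
        rows.append(
            {
                "scientific_name": f"Species{i:03d}",
                "genus": g,
                "family": fam,
                "order": family_order[fam],
                "class_": order_class[family_order[fam]],
                "commodity": family_commodity[fam],
            }
        )
    return pd.DataFrame(rows)


def _build_profiles(rng, config: WorldConfig, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """One candidate record per species, then rank-level withholding."""
    n = len(taxonomy)
    values = {
        nut: _log_uniform(rng, *CONCENTRATION_RANGES[nut], size=n)
        for nut in CONCENTRATION_RANGES
    }
    values["protein"] = rng.uniform(*PROTEIN_RANGE, size=n)
    values["edible_fraction"] = rng.uniform(*EDIBLE_FRACTION_RANGE, size=n)

    miss = config.profile_missingness_by_rank
    withheld_rank_values: dict[str, set] = {}
    for level in ("genus", "family", "order", "class"):
        col = RANK_COLUMNS[level]
        p = miss.get(level, 0.0)
        vals = taxonomy[col].unique()
        withheld_rank_values[level] = {v for v in vals if rng.random() < p}
    p_species = miss.get("species", 0.0)

    keep = np.ones(n, dtype=bool)
    for i, row in taxonomy.iterrows():
        if rng.random() < p_species:
            keep[i] = False
        for level in ("genus", "family", "order", "class"):
            if row[RANK_COLUMNS[level]] in withheld_rank_values[level]:
                keep[i] = False

    # every commodity keeps at least one fully populated record
    forced_complete = set()
    for commodity in COMMODITIES:
        idx = taxonomy.index[taxonomy["commodity"] == commodity]
        if len(idx) == 0:
            continue
        if not keep[idx].any():
            keep[idx[0]] = True
            forced_complete.add(idx[0])
        else:
            forced_complete.add(idx[keep[idx]][0])

    prof = taxonomy.loc[keep].reset_index(drop=True).copy()
    kept_idx = np.flatnonzero(keep)
    for fieldname in list(NUTRIENTS) + ["edible_fraction"]:
        col = values[fieldname][kept_idx].copy()
        for j, orig in enumerate(kept_idx):
            if orig not in forced_complete and rng.random() < PER_NUTRIENT_MISSINGNESS:
                col[j] = np.nan
        prof[fieldname] = col
    return prof


def _build_catch(rng, config: WorldConfig, taxonomy: pd.DataFrame, countries: list[str]):
    catch_sectors = [s for s in CATCH_SECTORS if s in config.sectors_active]
    species = list(taxonomy["scientific_name"])
    presence_p = min(1.0, 40.0 / max(1, len(species)))
    rows = []
    for c in countries:
        present = [s for s in species if rng.random() < presence_p]
        if not present:
            present = [species[rng.integers(len(species))]]
        for sp in present:
            if not catch_sectors:
                break
            total = _log_uniform(rng, 10.0, 1e4)
            shares = rng.dirichlet(np.ones(len(catch_sectors)))
            for sec, share in zip(catch_sectors, shares):
                t = float(total * share)
                if t <= 0:
                    continue
                if sec in COMMERCIAL_SECTORS:
                    d = rng.uniform(*config.discard_fraction_range)
                    f = rng.uniform(*config.fmfo_fraction_range)
                    if d + f > 0.95:
                        scale = 0.95 / (d + f)
                        d, f = d * scale, f * scale
                    for end_use, frac in (
                        (DIRECT_HUMAN_CONSUMPTION, 1.0 - d - f),
                        ("fishmeal_fish_oil", f),
                        ("discard", d),
                    ):
                        if frac > 0:
                            rows.append(
                                {"country": c, "scientific_name": sp, "sector": sec,
                                 "end_use": end_use, "tonnes": t * frac}
                            )
                else:
                    rows.append(
                        {"country": c, "scientific_name": sp, "sector": sec,
                         "end_use": DIRECT_HUMAN_CONSUMPTION, "tonnes": t}
                    )
    catch = pd.DataFrame(
        rows, columns=["country", "scientific_name", "sector", "end_use", "tonnes"]
    )

    mar_rows = []
    if "mariculture" in config.sectors_active:
        for c in countries:
            for sp in species:
                if rng.random() < 0.08:
                    mar_rows.append(
                        {"country": c, "scientific_name": sp, "sector": "mariculture",
                         "end_use": DIRECT_HUMAN_CONSUMPTION,
                         "tonnes": float(_log_uniform(rng, 10.0, 10.0 ** 3.5))}
                    )
    mariculture = pd.DataFrame(
        mar_rows, columns=["country", "scientific_name", "sector", "end_use", "tonnes"]
    )
    return catch, mariculture


def _build_geography(rng, config: WorldConfig, countries: list[str]):
    cell_rows, coast_rows = [], []
    buffer = config.buffer_km_default
    inland_lo = min(buffer + 10.0, COUNTRY_RECT_DEPTH_KM - 20.0)
    for i, c in enumerate(countries):
        y0 = i * COUNTRY_RECT_SPACING_KM
        y1 = y0 + COUNTRY_RECT_HEIGHT_KM
        coast_rows.append({"country": c, "vertex": 0, "x": 0.0, "y": y0})
        coast_rows.append({"country": c, "vertex": 1, "x": 0.0, "y": y1})
        n = config.grid_cells_per_country
        n_coastal = max(1, n // 2)
        n_inland = n - n_coastal
        coastal_frac = rng.uniform(*config.coastal_fraction_range)
        total_pop = _log_uniform(rng, 1e5, 10.0 ** 7.5)
        w_c = rng.dirichlet(np.ones(n_coastal))
        xs_c = rng.uniform(0.5, max(1.0, buffer - 0.5), size=n_coastal)
        # every country keeps population in the nearest-shore band so that
        # per-capita supply stays defined down to the smallest swept buffer
        xs_c[0] = rng.uniform(0.5, 4.5)
        for x, w in zip(xs_c, w_c):
            cell_rows.append(
                {"country": c, "x": float(x), "y": float(rng.uniform(y0 + 1, y1 - 1)),
                 "persons": float(total_pop * coastal_frac * w)}
            )
        if n_inland > 0:
            w_i = rng.dirichlet(np.ones(n_inland))
            xs_i = rng.uniform(inland_lo, COUNTRY_RECT_DEPTH_KM - 10.0, size=n_inland)
            for x, w in zip(xs_i, w_i):
                cell_rows.append(
                    {"country": c, "x": float(x), "y": float(rng.uniform(y0 + 1, y1 - 1)),
                     "persons": float(total_pop * (1.0 - coastal_frac) * w)}
                )
    return pd.DataFrame(cell_rows), pd.DataFrame(coast_rows)


def _build_trade(rng, config: WorldConfig, fbs: Mapping, countries: list[str]):
    """Trade flows per country × commodity, tied to post-filter production."""
    rows = []
    positive = [v for v in fbs.values() if v > 0]
    mean_p = float(np.mean(positive)) if positive else 0.0
    for c in countries:
        for m in COMMODITIES:
            p = fbs.get((c, m), 0.0)
            exports = 0.0
            imports = 0.0
            recorded = 0.0
            if config.export_intensity > 0:
                if p > 0:
                    exports = config.export_intensity * rng.uniform(0.3, 0.9) * p
                if rng.random() < 0.7 and mean_p > 0:
                    imports = config.export_intensity * rng.uniform(0.1, 1.5) * mean_p
                if imports > 0 and config.reexport_share > 0:
                    recorded = config.reexport_share * rng.uniform(0.3, 1.0) * imports
                    exports += recorded
                if p > 0 and rng.random() < 0.3:
                    # overshoot production to trigger processed re-exports
                    exports += rng.uniform(0.1, 0.5) * (p + imports)
            if imports > 0:
                rows.append({"country": c, "commodity": m, "flow": "import", "tonnes": imports})
            if exports > 0:
                rows.append({"country": c, "commodity": m, "flow": "export", "tonnes": exports})
            if recorded > 0:
                rows.append(
                    {"country": c, "commodity": m, "flow": "reexport_recorded",
                     "tonnes": recorded}
                )
    return pd.DataFrame(rows, columns=["country", "commodity", "flow", "tonnes"])


def _build_gnd(rng, countries: list[str]) -> pd.DataFrame:
    rows = []
    for c in countries:
        for grp in GND_FOOD_GROUPS:
            for nut in NUTRIENTS:
                if grp in PLANT_FOOD_GROUPS and nut in ("vitamin_b12", SEAFOOD_ONLY_NUTRIENT):
                    v = 0.0
                else:
                    v = float(_log_uniform(rng, *GND_RANGES[nut]))
                rows.append(
                    {"country": c, "food_group": grp, "nutrient": nut,
                     "per_capita_per_day": v}
                )
    return pd.DataFrame(rows)


def _build_inadequate(rng, countries: list[str]) -> pd.DataFrame:
    rows = []
    for c in countries:
        if rng.random() < INTAKE_MISSING_SHARE:
            continue
        for nut in ASSESSED_NUTRIENTS:
            rows.append(
                {"country": c, "nutrient": nut, "prevalence": float(rng.uniform(0.05, 0.95))}
            )
    return pd.DataFrame(rows, columns=["country", "nutrient", "prevalence"])


# --------------------------------------------------------------------------
# ground-truth bookkeeping (no pipeline-module calls)
# --------------------------------------------------------------------------


def _truth_level_means(profiles: pd.DataFrame) -> dict:
    """Per-level, per-rank-value field means over available records."""
    fields = list(NUTRIENTS) + ["edible_fraction"]
    means: dict = {}
    for level in MATCH_LEVELS:
        col = RANK_COLUMNS[level]
        table: dict = {}
        for _, row in profiles.iterrows():
            v = row[col]
            if not isinstance(v, str) or not v:
                continue
            bucket = table.setdefault(v, {f: [] for f in fields})
            for f in fields:
                if not pd.isna(row[f]):
                    bucket[f].append(float(row[f]))
            bucket.setdefault("_n", 0)
            bucket["_n"] += 1
        means[level] = {
            v: {
                **{f: (fsum(vals[f]) / len(vals[f]) if vals[f] else None) for f in fields},
                "_n": vals["_n"],
            }
            for v, vals in table.items()
        }
    return means


def _truth_match(taxon_ranks: Mapping[str, str], means: dict) -> dict | None:
    """Hierarchy walk: first level with any record; per-field deeper fallback."""
    fields = list(NUTRIENTS) + ["edible_fraction"]
    chain = []
    for level in MATCH_LEVELS:
        v = taxon_ranks.get(level, "")
        if v and v in means[level]:
            chain.append(means[level][v])
    if not chain:
        return None
    out = {}
    for f in fields:
        out[f] = None
        for bucket in chain:
            if bucket[f] is not None:
                out[f] = bucket[f]
                break
    return out


def _percentile_flags(values: dict, q: float, abs_threshold: float):
    """(percentile-rule flags, absolute-rule flags) per country; None = no data."""
    with_data = {c: v for c, v in values.items() if v is not None}
    pct: dict = {}
    absolute: dict = {}
    if with_data:
        cut = float(np.quantile(np.array(list(with_data.values())), q))
    for c, v in values.items():
        if v is None:
            pct[c] = None
            absolute[c] = None
        else:
            pct[c] = v > cut
            absolute[c] = v >= abs_threshold
    return pct, absolute


def _bookkeep_truth(
    config: WorldConfig,
    catch: pd.DataFrame,
    mariculture: pd.DataFrame,
    trade: pd.DataFrame,
    fbs: dict,
    profiles: pd.DataFrame,
    taxonomy: pd.DataFrame,
    cells: pd.DataFrame,
    gnd: pd.DataFrame,
    inadequate: pd.DataFrame,
    crust_frac: dict,
) -> GroundTruth:
    truth = GroundTruth()
    commodity_of = dict(zip(taxonomy["scientific_name"], taxonomy["commodity"]))
    countries = sorted(cells["country"].unique())

    # post-filter production and non-commercial catch
    pool: dict = {}
    noncomm: dict = {}
    for _, r in catch.iterrows():
        key = (r["country"], r["scientific_name"], r["sector"])
        if r["sector"] in NONCOMMERCIAL_SECTORS:
            noncomm[key] = noncomm.get(key, 0.0) + r["tonnes"]
        elif r["end_use"] == DIRECT_HUMAN_CONSUMPTION:
            pool[key] = pool.get(key, 0.0) + r["tonnes"]
    for _, r in mariculture.iterrows():
        key = (r["country"], r["scientific_name"], "mariculture")
        pool[key] = pool.get(key, 0.0) + r["tonnes"]

    # trade accounting
    flows: dict = {}
    for _, r in trade.iterrows():
        k = (r["country"], r["commodity"], r["flow"])
        flows[k] = flows.get(k, 0.0) + r["tonnes"]
    cm_keys = sorted({(c, m) for (c, m, _) in flows} | set(fbs))
    exports_adj: dict = {}
    imports_adj: dict = {}
    for c, m in cm_keys:
        e = flows.get((c, m, "export"), 0.0)
        i = flows.get((c, m, "import"), 0.0)
        rr = flows.get((c, m, "reexport_recorded"), 0.0)
        processed = max(0.0, e - fbs.get((c, m), 0.0))
        total = min(rr + processed, e)
        exports_adj[(c, m)] = max(0.0, e - total)
        imports_adj[(c, m)] = max(0.0, i - total)
    for (c, m), e in list(exports_adj.items()):
        if m == CRUSTACEAN_COMMODITY:
            exports_adj[(c, m)] = e * (1.0 - crust_frac.get(c, 0.0))

    # proportional export allocation over the exportable pool (base case:
    # artisanal is exportable)
    pool_by_cm: dict = {}
    for (c, sp, sec), t in pool.items():
        key = (c, commodity_of[sp])
        pool_by_cm.setdefault(key, []).append(t)
    pool_tot = {k: fsum(v) for k, v in pool_by_cm.items()}
    consumption: dict = {}
    for (c, sp, sec), t in pool.items():
        m = commodity_of[sp]
        tot = pool_tot.get((c, m), 0.0)
        e = exports_adj.get((c, m), 0.0)
        ratio = min(1.0, e / tot) if tot > 0 else 0.0
        consumption[(c, sp, sec)] = t * (1.0 - ratio)
    for key, t in noncomm.items():
        consumption[key] = consumption.get(key, 0.0) + t
    for (c, m), i in imports_adj.items():
        if i > 0:
            consumption[(c, COMMODITY_TAXON_PREFIX + m, IMPORT_SECTOR)] = i
    truth.expected_apparent_consumption = dict(consumption)

    # nutrient matching + supply
    means = _truth_level_means(profiles)
    tax_ranks = {
        r["scientific_name"]: {
            "species": r["scientific_name"], "genus": r["genus"], "family": r["family"],
            "order": r["order"], "class": r["class_"], "commodity": r["commodity"],
        }
        for _, r in taxonomy.iterrows()
    }
    matched: dict = {}
    for (c, sp, sec) in consumption:
        if sp in matched:
            continue
        if sp.startswith(COMMODITY_TAXON_PREFIX):
            ranks = {"commodity": sp[len(COMMODITY_TAXON_PREFIX):]}
        else:
            ranks = tax_ranks[sp]
        matched[sp] = _truth_match(ranks, means)
    supply_terms: dict = {}
    for (c, sp, sec), t in consumption.items():
        prof = matched[sp]
        for nut in NUTRIENTS:
            ef = prof["edible_fraction"]
            conc = prof[nut]
            term = t * HG_PER_TONNE * ef * conc if (ef is not None and conc is not None) else 0.0
            supply_terms.setdefault((c, sec, nut), []).append(term)
    supply = {k: fsum(v) for k, v in supply_terms.items()}
    truth.expected_supply = dict(supply)

    # populations: in this geometry a cell's coast distance is its x coordinate
    coastal_pop = {
        c: fsum(
            r["persons"]
            for _, r in cells[cells["country"] == c].iterrows()
            if r["x"] <= config.buffer_km_default
        )
        for c in countries
    }
    national_pop = {
        c: fsum(cells.loc[cells["country"] == c, "persons"]) for c in countries
    }
    truth.expected_coastal_population = dict(coastal_pop)

    percap = {}
    for (c, sec, nut), mass in supply.items():
        popn = coastal_pop[c] if sec in SSF_SECTORS else national_pop[c]
        percap[(c, sec, nut)] = 0.0 if mass == 0 else mass / (popn * DAYS_PER_YEAR)

    gnd_animal: dict = {}
    gnd_all: dict = {}
    for _, r in gnd.iterrows():
        k = (r["country"], r["nutrient"])
        gnd_all.setdefault(k, []).append(r["per_capita_per_day"])
        if r["food_group"] in ANIMAL_FOOD_GROUPS:
            gnd_animal.setdefault(k, []).append(r["per_capita_per_day"])

    cn_keys = sorted({(c, nut) for (c, sec, nut) in percap})
    for c, nut in cn_keys:
        ssf = fsum(percap.get((c, sec, nut), 0.0) for sec in SSF_SECTORS)
        seafood = fsum(v for (cc, sec, nn), v in percap.items() if cc == c and nn == nut)
        if nut == SEAFOOD_ONLY_NUTRIENT:
            animal_extra = 0.0
            all_extra = 0.0
        else:
            animal_extra = fsum(gnd_animal.get((c, nut), []))
            all_extra = fsum(gnd_all.get((c, nut), []))
        for truth_dict, denom in (
            (truth.expected_contribution_seafood, seafood),
            (truth.expected_contribution_asf, seafood + animal_extra),
            (truth.expected_contribution_allfoods, seafood + all_extra),
        ):
            truth_dict[(c, nut)] = (ssf / denom) if denom > 0 else None

    # six-nutrient means and flags
    for c in countries:
        fracs = [
            truth.expected_contribution_allfoods[(c, nut)]
            for nut in ASSESSED_NUTRIENTS
            if (c, nut) in truth.expected_contribution_allfoods
            and truth.expected_contribution_allfoods[(c, nut)] is not None
        ]
        truth.expected_mean_contribution[c] = fsum(fracs) / len(fracs) if fracs else None

    intake_mean: dict = {c: None for c in countries}
    grouped: dict = {}
    for _, r in inadequate.iterrows():
        grouped.setdefault(r["country"], []).append(r["prevalence"])
    for c, vals in grouped.items():
        intake_mean[c] = fsum(vals) / len(vals)

    reliant_pct, reliant_abs = _percentile_flags(truth.expected_mean_contribution, 0.70, 0.15)
    vulnerable_pct, vulnerable_abs = _percentile_flags(intake_mean, 0.70, 0.50)
    for c in countries:
        truth.expected_flags[c] = {
            "reliant_percentile": reliant_pct[c],
            "vulnerable_percentile": vulnerable_pct[c],
            "reliant_absolute": reliant_abs[c],
            "vulnerable_absolute": vulnerable_abs[c],
        }
    return truth


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a world from the configured distributions and book its truth.

    Deterministic: the same config (including seed) yields a field-for-field
    identical world.
    """
    rng = np.random.default_rng(config.seed)
    countries = [f"C{i:02d}" for i in range(config.n_countries)]
    taxonomy = _build_taxonomy(rng, config)
    profiles = _build_profiles(rng, config, taxonomy)
    catch, mariculture = _build_catch(rng, config, taxonomy, countries)
    cells, coastline = _build_geography(rng, config, countries)

    # food-balance-sheet production = post-filter commercial + mariculture
    commodity_of = dict(zip(taxonomy["scientific_name"], taxonomy["commodity"]))
    fbs_terms: dict = {}
    for _, r in catch.iterrows():
        if r["sector"] in COMMERCIAL_SECTORS and r["end_use"] == DIRECT_HUMAN_CONSUMPTION:
            key = (r["country"], commodity_of[r["scientific_name"]])
            fbs_terms.setdefault(key, []).append(r["tonnes"])
    for _, r in mariculture.iterrows():
        key = (r["country"], commodity_of[r["scientific_name"]])
        fbs_terms.setdefault(key, []).append(r["tonnes"])
    fbs = {k: fsum(v) for k, v in fbs_terms.items()}
    fbs_production = pd.DataFrame(
        [{"country": c, "commodity": m, "tonnes": t} for (c, m), t in sorted(fbs.items())],
        columns=["country", "commodity", "tonnes"],
    )

    trade = _build_trade(rng, config, fbs, countries)
    gnd = _build_gnd(rng, countries)
    inadequate = _build_inadequate(rng, countries)
    crust_frac = {c: config.freshwater_crustacean_export_fraction for c in countries}
    crustacean_fractions = pd.DataFrame(
        [{"country": c, "fraction": f} for c, f in crust_frac.items()]
    )

    truth = _bookkeep_truth(
        config, catch, mariculture, trade, fbs, profiles, taxonomy,
        cells, gnd, inadequate, crust_frac,
    )
    return SyntheticWorld(
        config=config,
        catch=catch,
        mariculture=mariculture,
        trade=trade,
        fbs_production=fbs_production,
        profiles=profiles,
        taxonomy=taxonomy,
        population_cells=cells,
        coastline=coastline,
        gnd=gnd,
        inadequate_intake=inadequate,
        crustacean_fractions=crustacean_fractions,
        truth=truth,
    )


def _oracle_point_segment_km(px, py, ax, ay, bx, by) -> float:
    """Euclidean distance from point P to segment AB, from the projection formula."""
    abx, aby = bx - ax, by - ay
    denom = abx * abx + aby * aby
    if denom == 0.0:
        t = 0.0
    else:
        t = min(1.0, max(0.0, ((px - ax) * abx + (py - ay) * aby) / denom))
    qx, qy = ax + t * abx, ay + t * aby
    return float(np.hypot(px - qx, py - qy))


def _oracle_match_scan(ranks: Mapping[str, str], records: list[dict]) -> dict | None:
    """Brute-force level-by-level scan of the raw profile records.

    At each level, collects every record whose rank value matches; the
    match level is the first non-empty one, and each field takes the mean
    at the first level (from there down) where any record carries it.
    """
    fields = list(NUTRIENTS) + ["edible_fraction"]
    per_level: list[list[dict]] = []
    for level in MATCH_LEVELS:
        v = ranks.get(level, "")
        hits = [r for r in records if v and r[RANK_COLUMNS[level]] == v] if v else []
        per_level.append(hits)
    if not any(per_level):
        return None
    out: dict = {}
    for f in fields:
        out[f] = None
        for hits in per_level:
            vals = [r[f] for r in hits if r[f] is not None]
            if vals:
                out[f] = fsum(vals) / len(vals)
                break
    return out


def _oracle_quantile(values: list[float], q: float) -> float:
    """Type-7 quantile written out: interpolate between order statistics."""
    x = sorted(values)
    if len(x) == 1:
        return x[0]
    h = (len(x) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(x) - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])


def ground_truth_contributions(world: SyntheticWorld) -> GroundTruth:
    """Recompute the ground truth from the emitted tables, from scratch.

    A second, structurally independent derivation by brute-force summation
    over the world's records: profiles are matched by scanning the raw
    record list level by level (no pre-aggregation), coastal membership is
    measured by point-to-segment distance against the coastline geometry
    (the generator uses its rectangle-layout shortcut), and the percentile
    cutoff is the written-out order-statistic interpolation rather than a
    library call. All sums use exactly rounded accumulation, so the result
    must equal ``world.truth`` bit for bit.
    """
    cfg = world.config
    commodity_of = dict(zip(world.taxonomy["scientific_name"], world.taxonomy["commodity"]))
    countries = sorted(world.population_cells["country"].unique())
    crust = dict(
        zip(world.crustacean_fractions["country"], world.crustacean_fractions["fraction"])
    )
    truth = GroundTruth()

    # --- production destined for human consumption -----------------------
    pool_terms: dict = {}
    noncomm_terms: dict = {}
    for _, r in world.catch.iterrows():
        key = (r["country"], r["scientific_name"], r["sector"])
        if r["sector"] in NONCOMMERCIAL_SECTORS:
            noncomm_terms.setdefault(key, []).append(r["tonnes"])
        elif r["end_use"] == DIRECT_HUMAN_CONSUMPTION:
            pool_terms.setdefault(key, []).append(r["tonnes"])
    for _, r in world.mariculture.iterrows():
        key = (r["country"], r["scientific_name"], "mariculture")
        pool_terms.setdefault(key, []).append(r["tonnes"])
    pool = {k: fsum(v) for k, v in pool_terms.items()}
    noncomm = {k: fsum(v) for k, v in noncomm_terms.items()}

    # --- re-export estimation and trade adjustment ------------------------
    fbs = {
        (r["country"], r["commodity"]): r["tonnes"]
        for _, r in world.fbs_production.iterrows()
    }
    flow_terms: dict = {}
    for _, r in world.trade.iterrows():
        flow_terms.setdefault((r["country"], r["commodity"], r["flow"]), []).append(
            r["tonnes"]
        )
    flows = {k: fsum(v) for k, v in flow_terms.items()}
    exports_adj: dict = {}
    imports_adj: dict = {}
    for c, m in sorted({(c, m) for (c, m, _) in flows} | set(fbs)):
        e = flows.get((c, m, "export"), 0.0)
        i = flows.get((c, m, "import"), 0.0)
        rr = flows.get((c, m, "reexport_recorded"), 0.0)
        processed = max(0.0, e - fbs.get((c, m), 0.0))
        total = min(rr + processed, e)
        ea = max(0.0, e - total)
        if m == CRUSTACEAN_COMMODITY:
            ea = ea * (1.0 - crust.get(c, 0.0))
        exports_adj[(c, m)] = ea
        imports_adj[(c, m)] = max(0.0, i - total)

    # --- proportional export allocation -----------------------------------
    pool_tot = {}
    for (c, sp, sec), t in pool.items():
        pool_tot.setdefault((c, commodity_of[sp]), []).append(t)
    pool_tot = {k: fsum(v) for k, v in pool_tot.items()}
    consumption: dict = {}
    for (c, sp, sec), t in pool.items():
        m = commodity_of[sp]
        tot = pool_tot[(c, m)]
        e = exports_adj.get((c, m), 0.0)
        ratio = min(1.0, e / tot) if tot > 0 else 0.0
        consumption[(c, sp, sec)] = t * (1.0 - ratio)
    for key, t in noncomm.items():
        consumption[key] = consumption.get(key, 0.0) + t
    for (c, m), i in imports_adj.items():
        if i > 0:
            consumption[(c, COMMODITY_TAXON_PREFIX + m, IMPORT_SECTOR)] = i
    truth.expected_apparent_consumption = dict(consumption)

    # --- brute-force matching and nutrient supply --------------------------
    fields = list(NUTRIENTS) + ["edible_fraction"]
    records = [
        {
            **{RANK_COLUMNS[lvl]: r[RANK_COLUMNS[lvl]] for lvl in MATCH_LEVELS},
            **{f: (None if pd.isna(r[f]) else float(r[f])) for f in fields},
        }
        for _, r in world.profiles.iterrows()
    ]
    tax_ranks = {
        r["scientific_name"]: {
            "species": r["scientific_name"], "genus": r["genus"], "family": r["family"],
            "order": r["order"], "class": r["class_"], "commodity": r["commodity"],
        }
        for _, r in world.taxonomy.iterrows()
    }
    matched: dict = {}
    for (_, sp, _) in consumption:
        if sp not in matched:
            if sp.startswith(COMMODITY_TAXON_PREFIX):
                ranks = {"commodity": sp[len(COMMODITY_TAXON_PREFIX):]}
            else:
                ranks = tax_ranks[sp]
            matched[sp] = _oracle_match_scan(ranks, records)
    supply_terms: dict = {}
    for (c, sp, sec), t in consumption.items():
        prof = matched[sp]
        for nut in NUTRIENTS:
            ef, conc = prof["edible_fraction"], prof[nut]
            term = t * HG_PER_TONNE * ef * conc if (ef is not None and conc is not None) else 0.0
            supply_terms.setdefault((c, sec, nut), []).append(term)
    supply = {k: fsum(v) for k, v in supply_terms.items()}
    truth.expected_supply = dict(supply)

    # --- populations by measured distance to the coastline ----------------
    segments = {
        c: grp.sort_values("vertex")[["x", "y"]].to_numpy()
        for c, grp in world.coastline.groupby("country")
    }
    coastal_terms: dict = {c: [] for c in countries}
    national_terms: dict = {c: [] for c in countries}
    for _, r in world.population_cells.iterrows():
        pts = segments[r["country"]]
        d = min(
            _oracle_point_segment_km(r["x"], r["y"], a[0], a[1], b[0], b[1])
            for a, b in zip(pts[:-1], pts[1:])
        )
        national_terms[r["country"]].append(r["persons"])
        if d <= cfg.buffer_km_default:
            coastal_terms[r["country"]].append(r["persons"])
    coastal_pop = {c: fsum(v) for c, v in coastal_terms.items()}
    national_pop = {c: fsum(v) for c, v in national_terms.items()}
    truth.expected_coastal_population = dict(coastal_pop)

    # --- per-capita supply and contribution fractions ----------------------
    percap = {}
    for (c, sec, nut), mass in supply.items():
        popn = coastal_pop[c] if sec in SSF_SECTORS else national_pop[c]
        percap[(c, sec, nut)] = 0.0 if mass == 0 else mass / (popn * DAYS_PER_YEAR)

    gnd_animal: dict = {}
    gnd_all: dict = {}
    for _, r in world.gnd.iterrows():
        k = (r["country"], r["nutrient"])
        gnd_all.setdefault(k, []).append(r["per_capita_per_day"])
        if r["food_group"] in ANIMAL_FOOD_GROUPS:
            gnd_animal.setdefault(k, []).append(r["per_capita_per_day"])

    for c, nut in sorted({(c, nut) for (c, sec, nut) in percap}):
        ssf = fsum(percap.get((c, sec, nut), 0.0) for sec in SSF_SECTORS)
        seafood = fsum(v for (cc, sec, nn), v in percap.items() if cc == c and nn == nut)
        animal_extra = 0.0 if nut == SEAFOOD_ONLY_NUTRIENT else fsum(gnd_animal.get((c, nut), []))
        all_extra = 0.0 if nut == SEAFOOD_ONLY_NUTRIENT else fsum(gnd_all.get((c, nut), []))
        for out, denom in (
            (truth.expected_contribution_seafood, seafood),
            (truth.expected_contribution_asf, seafood + animal_extra),
            (truth.expected_contribution_allfoods, seafood + all_extra),
        ):
            out[(c, nut)] = (ssf / denom) if denom > 0 else None

    for c in countries:
        fracs = [
            v
            for nut in ASSESSED_NUTRIENTS
            if (v := truth.expected_contribution_allfoods.get((c, nut))) is not None
        ]
        truth.expected_mean_contribution[c] = fsum(fracs) / len(fracs) if fracs else None

    intake_terms: dict = {}
    for _, r in world.inadequate_intake.iterrows():
        intake_terms.setdefault(r["country"], []).append(r["prevalence"])
    intake_mean = {c: None for c in countries}
    for c, vals in intake_terms.items():
        intake_mean[c] = fsum(vals) / len(vals)

    contrib_data = [v for v in truth.expected_mean_contribution.values() if v is not None]
    intake_data = [v for v in intake_mean.values() if v is not None]
    c_cut = _oracle_quantile(contrib_data, 0.70) if contrib_data else None
    i_cut = _oracle_quantile(intake_data, 0.70) if intake_data else None
    for c in countries:
        mc = truth.expected_mean_contribution[c]
        mi = intake_mean[c]
        truth.expected_flags[c] = {
            "reliant_percentile": None if mc is None else mc > c_cut,
            "vulnerable_percentile": None if mi is None else mi > i_cut,
            "reliant_absolute": None if mc is None else mc >= 0.15,
            "vulnerable_absolute": None if mi is None else mi >= 0.50,
        }
    return truth
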