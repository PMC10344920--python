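"""Wires every stage into one reproducible run.

``analyze_world`` is the pure core: tables in, results out, no I/O. The
stage order is fixed: filter end uses → add mariculture → estimate
re-exports → adjust trade → remove freshwater crustaceans → convert to
live weight → subtract exports → add non-commercial catch → match
nutrients → supply → per-capita → contributions → classification.
``run_pipeline`` adds configuration, CSV output and a machine-readable
report with row counts and mass-balance residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import classify
from .coastal_population import coastal_population
from .config import RunConfig, WorldConfig
from .constants import ASSESSED_NUTRIENTS, NONCOMMERCIAL_SECTORS
from .errors import DataError
from .nutrient_matching import build_lookup, match_statistics
from .supply_contributions import (
    SCOPES,
    match_consumption_taxa,
    mean_contribution,
    nutrient_supply,
    per_capita_supply,
    ssf_contribution,
)
from .trade_accounting import (
    adjust_trade,
    apparent_consumption,
    estimate_reexports,
    filter_human_consumption,
    remove_freshwater_crustaceans,
    subtract_exports,
    to_live_weight,
)

#: mass-balance tolerance: retained + allocated exports vs post-filter production
MASS_BALANCE_RTOL = 1e-9


@dataclass
class PipelineResults:
    """All stage outputs of one pipeline run."""

    consumption: pd.DataFrame
    supply: pd.DataFrame
    percap: pd.DataFrame
    contributions: pd.DataFrame
    mean_contrib: pd.DataFrame
    intake: pd.DataFrame
    classification: pd.DataFrame
    coastal_pop: pd.DataFrame
    national_pop: pd.DataFrame
    reexports: pd.DataFrame
    surplus: pd.DataFrame
    match_stats: dict
    mass_balance_residual: float
    warnings: list = field(default_factory=list)


def _national_population(cells: pd.DataFrame) -> pd.DataFrame:
    pop = cells.groupby("country")["persons"].sum()
    return pd.DataFrame({"country": pop.index, "persons": pop.to_numpy()})


def _mass_balance_residual(
    pool: pd.DataFrame,
    retained: pd.DataFrame,
    adjusted: pd.DataFrame,
    taxonomy: pd.DataFrame,
    exportable_sectors: tuple[str, ...],
) -> float:
    """Max relative residual of: retained + allocated exports = production.

    The allocation is pre-clamp: allocated = min(adjusted exports, exportable
    pool), with any surplus accounted separately, so the identity must hold
    to rounding error for every country × commodity.
    """
    tax = taxonomy.set_index("scientific_name")["commodity"]
    p = pool.copy()
    p["commodity"] = p["scientific_name"].map(tax)
    p["_exp"] = p["sector"].isin(exportable_sectors)
    r = retained.copy()
    r["commodity"] = r["scientific_name"].map(tax)
    r["_exp"] = r["sector"].isin(exportable_sectors)
    prod_cm = p[p["_exp"]].groupby(["country", "commodity"])["tonnes"].sum()
    ret_cm = r[r["_exp"]].groupby(["country", "commodity"])["tonnes"].sum()
    exp_cm = adjusted.set_index(["country", "commodity"])["exports_adj"]
    worst = 0.0
    for key, prod in prod_cm.items():
        alloc = min(exp_cm.get(key, 0.0), prod)
        resid = abs(ret_cm.get(key, 0.0) + alloc - prod)
        if prod > 0:
            worst = max(worst, resid / prod)
    return worst


def analyze_world(
    world,
    buffer_km: float = 50.0,
    artisanal_exportable: bool = True,
    percentile: float = 0.70,
    supply_threshold: float = 0.15,
    intake_threshold: float = 0.50,
    nutrient_set: Sequence[str] = ASSESSED_NUTRIENTS,
    trade_conversion_factors: Mapping[str, float] | None = None,
    coordinate_mode: str = "planar",
) -> PipelineResults:
    """Run every analysis stage on a world's tables.

    ``world`` is any object exposing the table attributes of
    :class:`~nutrisupply.synthetic_world.SyntheticWorld` (the generator's
    output or a directory read back in tabular mode).
    """
    warnings: list[str] = []

    # trade accounting → apparent consumption
    kept = filter_human_consumption(world.catch)
    noncommercial = kept[kept["sector"].isin(NONCOMMERCIAL_SECTORS)]
    commercial = kept[~kept["sector"].isin(NONCOMMERCIAL_SECTORS)]
    parts = [df for df in (commercial, world.mariculture) if len(df)]
    pool = pd.concat(parts, ignore_index=True)[
        ["country", "scientific_name", "sector", "tonnes"]
    ] if parts else commercial[["country", "scientific_name", "sector", "tonnes"]]
    pool = pool.groupby(["country", "scientific_name", "sector"], as_index=False)["tonnes"].sum()

    reexports = estimate_reexports(world.trade, world.fbs_production)
    adjusted = adjust_trade(world.trade, reexports)
    crust = dict(
        zip(world.crustacean_fractions["country"], world.crustacean_fractions["fraction"])
    )
    adjusted = remove_freshwater_crustaceans(adjusted, crust)
    adjusted = to_live_weight(adjusted, trade_conversion_factors)

    exportable = ("artisanal", "industrial", "mariculture") if artisanal_exportable else (
        "industrial", "mariculture"
    )
    retained, surplus = subtract_exports(pool, adjusted, world.taxonomy, exportable)
    consumption = apparent_consumption(retained, adjusted, noncommercial)
    residual = _mass_balance_residual(pool, retained, adjusted, world.taxonomy, exportable)
    if residual > MASS_BALANCE_RTOL:
        raise DataError(f"mass-balance residual {residual:.3e} exceeds {MASS_BALANCE_RTOL}")

    # nutrients
    lookup = build_lookup(world.profiles)
    matches = match_consumption_taxa(consumption, world.taxonomy, lookup)
    stats = match_statistics(matches.values())
    supply = nutrient_supply(consumption, lookup, world.taxonomy, matches)

    # populations and per-capita supply
    coastal = coastal_population(
        world.population_cells, world.coastline, buffer_km, mode=coordinate_mode
    )
    national = _national_population(world.population_cells)
    zero_coastal = set(coastal.loc[coastal["persons"] <= 0, "country"])
    if zero_coastal:
        warnings.append(f"zero coastal population in {sorted(zero_coastal)}")
    percap = per_capita_supply(supply, coastal, national)

    # contributions and classification
    contributions = pd.concat(
        [ssf_contribution(percap, world.gnd, scope) for scope in SCOPES],
        ignore_index=True,
    )
    allfoods = contributions[contributions["denominator_scope"] == "all_foods"]
    mean_contrib = mean_contribution(allfoods, tuple(nutrient_set))

    intake = (
        world.inadequate_intake.groupby("country")["prevalence"].mean()
        if len(world.inadequate_intake)
        else pd.Series(dtype=float)
    )
    countries = sorted(world.population_cells["country"].unique())
    intake = intake.reindex(countries)
    intake_df = pd.DataFrame(
        {"country": intake.index, "mean_inadequate_intake": intake.to_numpy()}
    )
    classification = classify(
        mean_contrib, intake_df,
        percentile=percentile,
        supply_threshold=supply_threshold,
        intake_threshold=intake_threshold,
    )

    return PipelineResults(
        consumption=consumption,
        supply=supply,
        percap=percap,
        contributions=contributions,
        mean_contrib=mean_contrib,
        intake=intake_df,
        classification=classification,
        coastal_pop=coastal,
        national_pop=national,
        reexports=reexports,
        surplus=surplus,
        match_stats=stats,
        mass_balance_residual=residual,
        warnings=warnings,
    )


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    report: dict
    results: PipelineResults


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline from a run configuration.

    Synthetic mode generates the world from the seed; tabular mode reads a
    CSV directory (e.g. one exported by the generator). Deterministic given
    the config: the report, including every stage row count and residual,
    is byte-identical across repeated runs. If ``output_dir`` is set, all
    stage CSVs, the serialized config and ``report.json`` are written there.
    """
    from . import io as nsio
    from .synthetic_world import generate_world

    if config.mode == "synthetic":
        wc = config.world_config or WorldConfig(seed=config.seed)
        world = generate_world(wc)
    else:
        world = nsio.read_world(config.input_dir)

    results = analyze_world(
        world,
        buffer_km=config.buffer_km,
        artisanal_exportable=config.artisanal_exportable,
        percentile=config.percentile,
        supply_threshold=config.supply_threshold,
        intake_threshold=config.intake_threshold,
        nutrient_set=config.nutrient_set,
        trade_conversion_factors=config.trade_conversion_factors,
    )

    cls = results.classification
    report = {
        "config": config.to_dict(),
        "row_counts": {
            "catch": int(len(world.catch)),
            "mariculture": int(len(world.mariculture)),
            "trade": int(len(world.trade)),
            "profiles": int(len(world.profiles)),
            "consumption": int(len(results.consumption)),
            "supply": int(len(results.supply)),
            "contributions": int(len(results.contributions)),
        },
        "mass_balance_residual": results.mass_balance_residual,
        "match_statistics": {k: results.match_stats[k] for k in sorted(results.match_stats)},
        "n_countries": int(cls["country"].nunique()),
        "n_reliant_percentile": int((cls["reliant_percentile"] == True).sum()),  # noqa: E712
        "n_vulnerable_percentile": int((cls["vulnerable_percentile"] == True).sum()),  # noqa: E712
        "n_reliant_absolute": int((cls["reliant_absolute"] == True).sum()),  # noqa: E712
        "n_vulnerable_absolute": int((cls["vulnerable_absolute"] == True).sum()),  # noqa: E712
        "mean_contribution_all_countries": float(
            np.nanmean(cls["mean_ssf_contribution"].to_numpy(dtype=float))
        ),
        "warnings": results.warnings,
    }

    if config.output_dir is not None:
        nsio.write_results(results, report, config.output_dir)
    return RunReport(report=report, results=results)
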