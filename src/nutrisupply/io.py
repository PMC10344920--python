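"""CSV/JSON round-trip of worlds and pipeline results.

World directory layout (schema version 1):

* ``catch.csv``, ``mariculture.csv`` — country, scientific_name, sector, end_use, tonnes
* ``trade.csv`` — country, commodity, flow, tonnes
* ``fbs_production.csv`` — country, commodity, tonnes
* ``profiles.csv`` — scientific_name, genus, family, order, class_, commodity,
  iron, zinc, calcium, vitamin_a, vitamin_b12, dha_epa, protein, edible_fraction
* ``commodity_map.csv`` — scientific_name, genus, family, order, class_, commodity
* ``population_cells.csv`` — country, x, y, persons
* ``coastline.csv`` — country, vertex, x, y
* ``gnd.csv`` — country, food_group, nutrient, per_capita_per_day
* ``inadequate_intake.csv`` — country, nutrient, prevalence
* ``crustacean_fractions.csv`` — country, fraction
* ``truth.json`` — bookkept ground truth (optional; tuple keys joined by ``|``)

All floats are serialized with ``repr`` so a fixed seed yields
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import WorldConfig
from .synthetic_world import GroundTruth, SyntheticWorld

SCHEMA_VERSION = 1

_TABLES = {
    "catch": "catch.csv",
    "mariculture": "mariculture.csv",
    "trade": "trade.csv",
    "fbs_production": "fbs_production.csv",
    "profiles": "profiles.csv",
    "taxonomy": "commodity_map.csv",
    "population_cells": "population_cells.csv",
    "coastline": "coastline.csv",
    "gnd": "gnd.csv",
    "inadequate_intake": "inadequate_intake.csv",
    "crustacean_fractions": "crustacean_fractions.csv",
}

_TUPLE_FIELDS = (
    "expected_apparent_consumption",
    "expected_supply",
    "expected_contribution_seafood",
    "expected_contribution_asf",
    "expected_contribution_allfoods",
)


def stable_json(obj) -> str:
    """Deterministic JSON text: sorted keys, repr-based floats."""

    def default(o):
        raise TypeError(f"not JSON-serializable: {type(o)}")

    return json.dumps(obj, sort_keys=True, indent=1, allow_nan=False, default=default)


def _truth_to_jsonable(truth: GroundTruth) -> dict:
    out: dict = {"schema_version": SCHEMA_VERSION}
    for name in _TUPLE_FIELDS:
        out[name] = {"|".join(k): v for k, v in getattr(truth, name).items()}
    out["expected_mean_contribution"] = dict(truth.expected_mean_contribution)
    out["expected_coastal_population"] = dict(truth.expected_coastal_population)
    out["expected_flags"] = dict(truth.expected_flags)
    return out


def _truth_from_jsonable(data: dict) -> GroundTruth:
    truth = GroundTruth()
    for name in _TUPLE_FIELDS:
        setattr(truth, name, {tuple(k.split("|")): v for k, v in data[name].items()})
    truth.expected_mean_contribution = dict(data["expected_mean_contribution"])
    truth.expected_coastal_population = dict(data["expected_coastal_population"])
    truth.expected_flags = dict(data["expected_flags"])
    return truth


def write_world(world: SyntheticWorld, out_dir: str | Path) -> Path:
    """Export a world as a directory of CSV tables plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLES.items():
        getattr(world, attr).to_csv(out / fname, index=False)
    meta = {"schema_version": SCHEMA_VERSION, "config": world.config.to_dict()}
    (out / "world_config.json").write_text(stable_json(meta) + "\n")
    if world.truth is not None:
        (out / "truth.json").write_text(stable_json(_truth_to_jsonable(world.truth)) + "\n")
    return out


def read_world(in_dir: str | Path) -> SyntheticWorld:
    """Read a world directory back; truth.json is optional."""
    src = Path(in_dir)
    tables = {}
    for attr, fname in _TABLES.items():
        path = src / fname
        if not path.exists():
            raise FileNotFoundError(f"world directory is missing {fname}")
        tables[attr] = pd.read_csv(path)
        for col in ("scientific_name", "genus", "family", "order", "class_", "commodity"):
            if col in tables[attr].columns:
                tables[attr][col] = tables[attr][col].fillna("")
    meta_path = src / "world_config.json"
    if meta_path.exists():
        config = WorldConfig.from_dict(json.loads(meta_path.read_text())["config"])
    else:
        config = WorldConfig()
    truth = None
    truth_path = src / "truth.json"
    if truth_path.exists():
        truth = _truth_from_jsonable(json.loads(truth_path.read_text()))
    return SyntheticWorld(config=config, truth=truth, **tables)


def write_results(results, report: dict, out_dir: str | Path) -> Path:
    """Write every stage CSV plus report.json for one pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.consumption.to_csv(out / "apparent_consumption.csv", index=False)
    results.supply.to_csv(out / "nutrient_supply.csv", index=False)
    results.percap.to_csv(out / "per_capita_supply.csv", index=False)
    results.contributions.to_csv(out / "contributions.csv", index=False)
    results.mean_contrib.to_csv(out / "mean_contributions.csv", index=False)
    results.classification.to_csv(out / "classification.csv", index=False)
    results.coastal_pop.to_csv(out / "coastal_population.csv", index=False)
    results.reexports.to_csv(out / "reexports.csv", index=False)
    results.surplus.to_csv(out / "export_surplus.csv", index=False)
    (out / "report.json").write_text(stable_json(report) + "\n")
    return out
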