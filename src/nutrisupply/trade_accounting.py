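"""From raw catch and trade tables to national apparent seafood consumption.

Apparent consumption is the supply-side proxy for what a country eats:
production + imports − exports, after two corrections. First, commercial
catch that is discarded or reduced to fishmeal/fish oil is removed, keeping
only production destined for direct human consumption. Second, trade flows
are corrected for re-exports (imported seafood that leaves the country
again, unchanged or after processing) so that neither exports nor imports
are double counted. Exports are then subtracted from the commercial +
mariculture production pool proportionally to each (taxon, sector) cell's
production share within its commodity category, and non-commercial catch
(recreational and subsistence) is added in full, on the assumption that it
is entirely consumed domestically.

Tables are pandas DataFrames:

* catch / mariculture: ``country, scientific_name, sector, end_use, tonnes``
* trade: ``country, commodity, flow, tonnes`` with flow in
  {import, export, reexport_recorded}
* fbs_production: ``country, commodity, tonnes``
* taxonomy (commodity map): ``scientific_name, genus, family, order,
  class_, commodity``
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    COMMODITY_TAXON_PREFIX,
    CRUSTACEAN_COMMODITY,
    DIRECT_HUMAN_CONSUMPTION,
    END_USES,
    IMPORT_SECTOR,
    NONCOMMERCIAL_SECTORS,
)
from .errors import ConfigurationError, DataError

TRADE_FLOWS = ("import", "export", "reexport_recorded")


def filter_human_consumption(catch: pd.DataFrame) -> pd.DataFrame:
    """Keep only catch destined for direct human consumption.

    Discards and fishmeal/fish-oil reduction are removed from commercial
    sectors; non-commercial sectors (recreational, subsistence) pass through
    untouched, since that catch is assumed to be eaten regardless of its
    recorded end use.
    """
    unknown = set(catch["end_use"]) - set(END_USES)
    if unknown:
        raise DataError(f"unknown end_use values {sorted(unknown)}")
    keep = (catch["end_use"] == DIRECT_HUMAN_CONSUMPTION) | catch["sector"].isin(
        NONCOMMERCIAL_SECTORS
    )
    return catch.loc[keep].reset_index(drop=True)


def _flow_pivot(trade: pd.DataFrame) -> pd.DataFrame:
    """country × commodity table with one column per flow, zero-filled."""
    unknown = set(trade["flow"]) - set(TRADE_FLOWS)
    if unknown:
        raise DataError(f"unknown trade flow values {sorted(unknown)}")
    if len(trade) == 0:
        return pd.DataFrame(columns=["country", "commodity", *TRADE_FLOWS])
    wide = (
        trade.pivot_table(
            index=["country", "commodity"],
            columns="flow",
            values="tonnes",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=TRADE_FLOWS, fill_value=0.0)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def estimate_reexports(trade: pd.DataFrame, fbs_production: pd.DataFrame) -> pd.DataFrame:
    """Estimate re-exports per country × commodity by two routes.

    ``recorded`` sums the trade table's explicit re-export flows (seafood
    re-exported without transformation). ``processed`` infers re-exports of
    transformed imports as max(0, exports − domestic production) from the
    food-balance-sheet production table: a country exporting more of a
    commodity than it produces must be re-exporting imports. ``total`` is
    their sum, capped at recorded exports.

    Returns columns ``country, commodity, recorded, processed, total``.
    """
    wide = _flow_pivot(trade)
    prod = fbs_production.rename(columns={"tonnes": "production"})
    merged = wide.merge(prod, on=["country", "commodity"], how="left")
    merged["production"] = merged["production"].fillna(0.0)
    merged["recorded"] = merged["reexport_recorded"]
    merged["processed"] = np.maximum(0.0, merged["export"] - merged["production"])
    merged["total"] = np.minimum(merged["recorded"] + merged["processed"], merged["export"])
    return merged[["country", "commodity", "recorded", "processed", "total"]]


def adjust_trade(trade: pd.DataFrame, reexports: pd.DataFrame) -> pd.DataFrame:
    """Subtract estimated re-exports from both exports and imports.

    Re-exported tonnage neither came from domestic production (so it must
    not be subtracted from it) nor stays in the country (so it must not be
    counted as consumed imports). Both adjusted flows are clamped at zero.

    Returns columns ``country, commodity, imports_adj, exports_adj``.
    """
    wide = _flow_pivot(trade)
    merged = wide.merge(
        reexports[["country", "commodity", "total"]], on=["country", "commodity"], how="left"
    )
    merged["total"] = merged["total"].fillna(0.0)
    merged["exports_adj"] = np.maximum(0.0, merged["export"] - merged["total"])
    merged["imports_adj"] = np.maximum(0.0, merged["import"] - merged["total"])
    return merged[["country", "commodity", "imports_adj", "exports_adj"]]


def remove_freshwater_crustaceans(
    exports: pd.DataFrame,
    fraction: float | Mapping[str, float],
    commodity: str = CRUSTACEAN_COMMODITY,
) -> pd.DataFrame:
    """Scale crustacean-commodity exports by (1 − freshwater fraction).

    The analysis covers marine species only, but the crustacean trade
    category mixes in freshwater production; its estimated share is removed
    from exports before subtraction. ``fraction`` may be a scalar or a
    per-country mapping. Other commodities are untouched.
    """
    out = exports.copy()
    if isinstance(fraction, Mapping):
        frac = out["country"].map(lambda c: fraction.get(c, 0.0)).astype(float)
    else:
        frac = pd.Series(float(fraction), index=out.index)
    if ((frac < 0) | (frac > 1)).any():
        raise ConfigurationError("freshwater crustacean fraction must lie in [0, 1]")
    mask = out["commodity"] == commodity
    col = "exports_adj" if "exports_adj" in out.columns else "tonnes"
    out.loc[mask, col] = out.loc[mask, col] * (1.0 - frac[mask])
    return out


def to_live_weight(
    trade_adj: pd.DataFrame, factors: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Convert product-weight trade flows to live-weight equivalents.

    Trade statistics are in product weight while catch is live weight; a
    per-commodity factor (live tonnes per product tonne, default 1.0)
    reconciles them before exports are subtracted from production.
    """
    if not factors:
        return trade_adj
    out = trade_adj.copy()
    scale = out["commodity"].map(lambda m: factors.get(m, 1.0)).astype(float)
    for col in ("imports_adj", "exports_adj"):
        if col in out.columns:
            out[col] = out[col] * scale
    return out


def subtract_exports(
    production: pd.DataFrame,
    adjusted_exports: pd.DataFrame,
    taxonomy: pd.DataFrame,
    exportable_sectors: tuple[str, ...],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allocate exports over production cells and return what is retained.

    Within each country × commodity, the adjusted export tonnage is
    allocated across the exportable (taxon, sector) production cells
    proportionally to their production share; retained = production −
    allocation, clamped at zero (clamping only binds when exports exceed
    the entire exportable pool). Cells in non-exportable sectors are
    retained in full. Export tonnage that cannot be covered by any
    production is reported per country × commodity, never silently dropped.

    Returns ``(retained, surplus)``: retained has the production columns
    with ``tonnes`` replaced by the retained quantity; surplus has columns
    ``country, commodity, surplus_tonnes``.
    """
    tax = taxonomy.set_index("scientific_name")["commodity"]
    missing = set(production["scientific_name"]) - set(tax.index)
    if missing:
        raise DataError(f"taxa without commodity mapping: {sorted(missing)[:5]}")
    prod = production.copy()
    prod["commodity"] = prod["scientific_name"].map(tax)
    prod["_exportable"] = prod["sector"].isin(exportable_sectors)

    exp = adjusted_exports.set_index(["country", "commodity"])["exports_adj"]

    pool = (
        prod[prod["_exportable"]]
        .groupby(["country", "commodity"])["tonnes"]
        .sum()
        .rename("pool")
    )
    cells = prod.join(pool, on=["country", "commodity"])
    cells["pool"] = cells["pool"].fillna(0.0)
    cells["_exports"] = [
        exp.get((c, m), 0.0) for c, m in zip(cells["country"], cells["commodity"])
    ]
    ratio = np.where(
        cells["pool"] > 0, np.minimum(1.0, cells["_exports"] / cells["pool"].replace(0, np.nan)), 0.0
    )
    cells["retained"] = np.where(
        cells["_exportable"], cells["tonnes"] * (1.0 - ratio), cells["tonnes"]
    )

    # export surplus: demand beyond the exportable pool, incl. commodities
    # with exports but no production at all
    per_cm = (
        cells[["country", "commodity", "pool", "_exports"]]
        .drop_duplicates(["country", "commodity"])
        .set_index(["country", "commodity"])
    )
    surplus_rows = []
    for (c, m), e in exp.items():
        pool_cm = per_cm["pool"].get((c, m), 0.0)
        s = max(0.0, e - pool_cm)
        if s > 0:
            surplus_rows.append({"country": c, "commodity": m, "surplus_tonnes": s})
    surplus = pd.DataFrame(surplus_rows, columns=["country", "commodity", "surplus_tonnes"])

    retained = cells[["country", "scientific_name", "sector", "retained"]].rename(
        columns={"retained": "tonnes"}
    )
    return retained.reset_index(drop=True), surplus


def apparent_consumption(
    retained: pd.DataFrame,
    adjusted_imports: pd.DataFrame,
    noncommercial: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the national apparent-consumption table.

    Rows are country × taxon × source sector with retained tonnage:
    retained commercial/mariculture production by taxon, imports by
    commodity under the ``imports`` source sector (taxon recorded as a
    ``commodity:<category>`` placeholder, since trade has no species
    resolution), and non-commercial catch added untouched by trade.
    """
    parts = [retained[["country", "scientific_name", "sector", "tonnes"]]]
    imp = adjusted_imports[adjusted_imports["imports_adj"] > 0]
    if len(imp):
        parts.append(
            pd.DataFrame(
                {
                    "country": imp["country"],
                    "scientific_name": COMMODITY_TAXON_PREFIX + imp["commodity"],
                    "sector": IMPORT_SECTOR,
                    "tonnes": imp["imports_adj"],
                }
            )
        )
    if len(noncommercial):
        parts.append(noncommercial[["country", "scientific_name", "sector", "tonnes"]])
    nonempty = [p for p in parts if len(p)] or parts[:1]
    out = pd.concat(nonempty, ignore_index=True)
    if (out["tonnes"] < 0).any():
        raise DataError("negative tonnage in apparent consumption")
    return out
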