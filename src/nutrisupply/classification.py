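"""Country classification and sensitivity sweeps.

Countries are placed on two axes: *reliance* on small-scale fisheries
(mean SSF contribution to overall nutrient supply across the assessed
nutrients) and nutritional *vulnerability* (mean prevalence of inadequate
micronutrient intake). Two rule families are emitted side by side:

* **percentile rules** — a country is flagged iff its value is strictly
  above the interpolated 70th percentile (configurable) of the respective
  distribution over countries with data;
* **absolute rules** — reliant iff mean SSF contribution ≥ 0.15,
  vulnerable iff mean inadequate intake ≥ 0.50 (both inclusive).

The percentile cutoff uses linear interpolation between order statistics:
with the n values sorted ascending as x₁ ≤ … ≤ xₙ and h = (n−1)·q, the
cutoff is x_{⌊h⌋+1} + (h−⌊h⌋)·(x_{⌊h⌋+2} − x_{⌊h⌋+1}).

Countries lacking inadequate-intake data keep their reliance flags but get
*missing* (not False) vulnerability flags — a "reliant, vulnerability
unknown" class rather than a silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .errors import DataError

FLAG_COLUMNS = (
    "reliant_percentile",
    "vulnerable_percentile",
    "reliant_absolute",
    "vulnerable_absolute",
)


def interpolated_percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation percentile between order statistics.

    Equivalent to the common "type 7" convention: h = (n−1)·q indexes the
    sorted sample, and the cutoff interpolates linearly between the two
    bracketing order statistics. NaNs are excluded before sorting.
    """
    x = np.sort(np.asarray([v for v in values if not pd.isna(v)], dtype=float))
    if len(x) == 0:
        raise DataError("percentile of an empty (all-missing) sample")
    if len(x) == 1:
        return float(x[0])
    h = (len(x) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(x) - 1)
    return float(x[lo] + (h - lo) * (x[hi] - x[lo]))


@dataclass
class SensitivityReport:
    """Outputs of one sensitivity sweep.

    ``tables`` maps each swept level to its per-country output table;
    ``summary`` has one row per level with headline counts; ``flag_flips``
    lists countries whose flags differ from the base-case level.
    """

    axis: str
    levels: list
    base_level: object
    tables: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    flag_flips: pd.DataFrame | None = None


def classify(
    contributions: pd.DataFrame,
    inadequate: pd.DataFrame,
    percentile: float = 0.70,
    supply_threshold: float = 0.15,
    intake_threshold: float = 0.50,
) -> pd.DataFrame:
    """Assign reliant/vulnerable flags under both rule families.

    ``contributions``: ``country, mean_ssf_contribution``;
    ``inadequate``: ``country, mean_inadequate_intake`` (NaN = no data).
    Returns one row per country with both values and the four flags;
    vulnerability flags are pandas nullable booleans, NA where intake data
    is missing.
    """
    out = contributions[["country", "mean_ssf_contribution"]].merge(
        inadequate[["country", "mean_inadequate_intake"]], on="country", how="left"
    )
    if out["mean_ssf_contribution"].notna().sum() < 2:
        raise DataError("classification needs >= 2 countries with contribution data")

    contrib = out["mean_ssf_contribution"]
    intake = out["mean_inadequate_intake"]

    c_cut = interpolated_percentile(contrib, percentile)
    out["reliant_percentile"] = (contrib > c_cut).astype("boolean")
    out.loc[contrib.isna(), "reliant_percentile"] = pd.NA

    if intake.notna().any():
        i_cut = interpolated_percentile(intake, percentile)
        out["vulnerable_percentile"] = (intake > i_cut).astype("boolean")
    else:
        out["vulnerable_percentile"] = pd.NA
        out["vulnerable_percentile"] = out["vulnerable_percentile"].astype("boolean")
    out.loc[intake.isna(), "vulnerable_percentile"] = pd.NA

    out["reliant_absolute"] = (contrib >= supply_threshold).astype("boolean")
    out.loc[contrib.isna(), "reliant_absolute"] = pd.NA
    out["vulnerable_absolute"] = (intake >= intake_threshold).astype("boolean")
    out.loc[intake.isna(), "vulnerable_absolute"] = pd.NA
    return out


def _flag_counts(cls: pd.DataFrame) -> dict[str, int]:
    return {col: int((cls[col] == True).sum()) for col in FLAG_COLUMNS}  # noqa: E712


def _flips_vs_base(
    tables: Mapping, base_level, level_name: str
) -> pd.DataFrame:
    """Countries whose flags differ from the base-case level, per level."""
    base = tables[base_level].set_index("country")[list(FLAG_COLUMNS)]
    rows = []
    for level, tbl in tables.items():
        if level == base_level:
            continue
        other = tbl.set_index("country")[list(FLAG_COLUMNS)]
        for col in FLAG_COLUMNS:
            a, b = base[col], other[col].reindex(base.index)
            flipped = a.index[(a != b) & a.notna() & b.notna()]
            for country in flipped:
                rows.append(
                    {level_name: level, "country": country, "flag": col,
                     "base": bool(a[country]), "level_value": bool(b[country])}
                )
    return pd.DataFrame(rows, columns=[level_name, "country", "flag", "base", "level_value"])


def sweep_buffer(world, distances: Sequence[float], **kwargs) -> SensitivityReport:
    """Rerun the full pipeline for each coastal buffer distance.

    A wider buffer enlarges the population assumed to share the small-scale
    catch, so per-capita SSF supply (and usually its contribution) weakly
    decreases with distance. ``kwargs`` are passed to ``analyze_world``;
    the base level is the first distance unless ``buffer_km`` is supplied.
    """
    from .orchestrator import analyze_world

    distances = list(distances)
    if len(distances) < 1:
        raise DataError("sweep_buffer needs at least one distance")
    base = kwargs.pop("buffer_km", distances[0])
    tables = {}
    summary_rows = []
    for d in distances:
        res = analyze_world(world, buffer_km=d, **kwargs)
        tbl = res.classification.merge(
            res.coastal_pop[["country", "persons"]].rename(columns={"persons": "coastal_persons"}),
            on="country",
        )
        tables[d] = tbl
        summary_rows.append({"buffer_km": d, **_flag_counts(res.classification)})
    if base not in tables:
        res = analyze_world(world, buffer_km=base, **kwargs)
        tables[base] = res.classification
    return SensitivityReport(
        axis="buffer_km",
        levels=distances,
        base_level=base,
        tables=tables,
        summary=pd.DataFrame(summary_rows),
        flag_flips=_flips_vs_base(tables, base, "buffer_km"),
    )


def sweep_artisanal_trade(world, **kwargs) -> SensitivityReport:
    """Compare artisanal-catch-exportable vs entirely-retained-domestically.

    Two otherwise identical pipeline runs; retaining the artisanal catch can
    only add to domestic SSF supply, so its contributions dominate the
    exportable case country by country.
    """
    from .orchestrator import analyze_world

    kwargs.pop("artisanal_exportable", None)
    tables = {}
    summary_rows = []
    for exportable in (True, False):
        res = analyze_world(world, artisanal_exportable=exportable, **kwargs)
        tbl = res.classification.copy()
        tbl["artisanal_exportable"] = exportable
        tables[exportable] = tbl
        summary_rows.append(
            {"artisanal_exportable": exportable, **_flag_counts(res.classification)}
        )
    return SensitivityReport(
        axis="artisanal_exportable",
        levels=[True, False],
        base_level=True,
        tables=tables,
        summary=pd.DataFrame(summary_rows),
        flag_flips=_flips_vs_base(tables, True, "artisanal_exportable"),
    )


def sweep_percentile(
    contributions: pd.DataFrame,
    inadequate: pd.DataFrame,
    percentiles: Sequence[float],
    **kwargs,
) -> SensitivityReport:
    """Reclassify at each percentile threshold.

    The strictly-above rule makes flag counts a weakly decreasing step
    function of the percentile (0 flags everything with data; 1 flags
    nothing).
    """
    percentiles = list(percentiles)
    if len(percentiles) < 1:
        raise DataError("sweep_percentile needs at least one percentile")
    tables = {}
    rows = []
    for q in percentiles:
        cls = classify(contributions, inadequate, percentile=q, **kwargs)
        tables[q] = cls
        rows.append({"percentile": q, **_flag_counts(cls)})
    base = 0.70 if 0.70 in tables else percentiles[0]
    return SensitivityReport(
        axis="percentile",
        levels=percentiles,
        base_level=base,
        tables=tables,
        summary=pd.DataFrame(rows),
        flag_flips=_flips_vs_base(tables, base, "percentile"),
    )
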