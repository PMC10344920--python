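"""Population within a buffer distance of the coastline.

Small-scale catch is assumed to be eaten by the coastal population, defined
as everyone living within a configurable distance (default 50 km, swept
over 5–50 km) of the national coastline. Inputs are a table of population
cells (cell centroid coordinates + persons) and a per-country coastline
polyline; a cell is coastal iff its centroid lies within the buffer of its
own country's coastline — centroid-only, with no areal weighting.

Two coordinate modes are supported: ``planar`` (coordinates in km on a
plane; point-to-segment Euclidean distance, the synthetic world's mode) and
``geographic`` (lon/lat degrees; great-circle distance to the polyline
densified at a 1 km step).

Tables: population_cells ``country, x, y, persons``; coastline
``country, vertex, x, y`` with vertices ordered along the polyline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .errors import ConfigurationError

EARTH_RADIUS_KM = 6371.0


def _coastline_lines(coastline: pd.DataFrame) -> dict[str, LineString]:
    if coastline is None or len(coastline) == 0:
        raise ConfigurationError("coastline table is empty")
    lines: dict[str, LineString] = {}
    for country, grp in coastline.groupby("country"):
        pts = grp.sort_values("vertex")[["x", "y"]].to_numpy()
        if len(pts) < 2:
            raise ConfigurationError(f"coastline for {country} needs >= 2 vertices")
        lines[country] = LineString(pts)
    return lines


def _haversine_km(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _densify_geographic(line: LineString, step_km: float = 1.0) -> np.ndarray:
    """Insert vertices so consecutive points are <= step_km apart (great circle)."""
    coords = np.asarray(line.coords)
    out = [coords[0]]
    for a, b in zip(coords[:-1], coords[1:]):
        d = _haversine_km(a[0], a[1], b[0], b[1])
        n = max(1, int(np.ceil(d / step_km)))
        for i in range(1, n + 1):
            t = i / n
            out.append(a + t * (b - a))
    return np.asarray(out)


def distance_to_coast(
    cells: pd.DataFrame, coastline: pd.DataFrame, mode: str = "planar"
) -> pd.Series:
    """Distance (km) from each cell centroid to its country's coastline."""
    lines = _coastline_lines(coastline)
    dist = np.full(len(cells), np.inf)
    for country, grp in cells.groupby("country"):
        if country not in lines:
            continue
        idx = grp.index
        if mode == "planar":
            line = lines[country]
            dist[cells.index.get_indexer(idx)] = [
                line.distance(Point(x, y)) for x, y in zip(grp["x"], grp["y"])
            ]
        elif mode == "geographic":
            dense = _densify_geographic(lines[country])
            for pos, (x, y) in zip(cells.index.get_indexer(idx), zip(grp["x"], grp["y"])):
                dist[pos] = _haversine_km(x, y, dense[:, 0], dense[:, 1]).min()
        else:
            raise ConfigurationError(f"unknown coordinate mode {mode!r}")
    return pd.Series(dist, index=cells.index, name="distance_km")


def coastal_mask(
    cells: pd.DataFrame,
    coastline: pd.DataFrame,
    buffer_km: float,
    mode: str = "planar",
) -> pd.DataFrame:
    """Cells whose centroid lies within ``buffer_km`` of the coastline."""
    if buffer_km <= 0:
        raise ConfigurationError(f"buffer_km must be > 0, got {buffer_km}")
    d = distance_to_coast(cells, coastline, mode=mode)
    return cells.loc[d <= buffer_km]


def coastal_population(
    cells: pd.DataFrame,
    coastline: pd.DataFrame,
    buffer_km: float,
    mode: str = "planar",
) -> pd.DataFrame:
    """Sum persons over coastal cells, per country.

    Countries present in ``cells`` but with no cell inside the buffer get a
    zero row (a downstream division guard flags them if they also have
    small-scale catch). Returns ``country, buffer_km, persons``.
    """
    masked = coastal_mask(cells, coastline, buffer_km, mode=mode)
    persons = masked.groupby("country")["persons"].sum()
    persons = persons.reindex(sorted(cells["country"].unique()), fill_value=0.0)
    return pd.DataFrame(
        {"country": persons.index, "buffer_km": buffer_km, "persons": persons.to_numpy()}
    )
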