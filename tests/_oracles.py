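"""Brute-force reference implementations used only by the tests.

Deliberately naive re-derivations (plain loops, no shared code with the
package) that the implementation is checked against.
"""

import math

import numpy as np

LEVEL_COLUMNS = [
    ("species", "scientific_name"),
    ("genus", "genus"),
    ("family", "family"),
    ("order", "order"),
    ("class", "class_"),
    ("commodity", "commodity"),
]
FIELDS = [
    "iron", "zinc", "calcium", "vitamin_a", "vitamin_b12", "dha_epa", "protein",
    "edible_fraction",
]


def norm(s):
    return " ".join(str(s).split()).casefold() if s else ""


def brute_force_match(taxon: dict, profile_rows: list[dict]):
    """Level-by-level scan: (level, {field: value-or-None}) or None.

    At each level every record with the matching rank value is collected;
    the match level is the first non-empty level, and each field takes the
    unweighted mean at the first level (from the match level down) where at
    least one record carries the field.
    """
    hits_by_level = []
    for level, col in LEVEL_COLUMNS:
        v = norm(taxon.get(col, ""))
        hits = [r for r in profile_rows if v and norm(r.get(col, "")) == v]
        hits_by_level.append((level, hits))
    match_level = next((lvl for lvl, hits in hits_by_level if hits), None)
    if match_level is None:
        return None
    started = False
    profile = {}
    for f in FIELDS:
        profile[f] = None
    for level, hits in hits_by_level:
        if level == match_level:
            started = True
        if not started:
            continue
        for f in FIELDS:
            if profile[f] is not None:
                continue
            vals = [r[f] for r in hits if r.get(f) is not None and not (
                isinstance(r[f], float) and math.isnan(r[f])
            )]
            if vals:
                profile[f] = sum(vals) / len(vals)
    return match_level, profile


def rank_counting_cutoff(values: list[float], q: float) -> float:
    """Percentile by explicit order statistics with linear interpolation."""
    x = sorted(values)
    if len(x) == 1:
        return x[0]
    h = (len(x) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(x) - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])


def point_segment_distance(p, a, b) -> float:
    (px, py), (ax, ay), (bx, by) = p, a, b
    abx, aby = bx - ax, by - ay
    d2 = abx * abx + aby * aby
    t = 0.0 if d2 == 0 else max(0.0, min(1.0, ((px - ax) * abx + (py - ay) * aby) / d2))
    return math.hypot(px - (ax + t * abx), py - (ay + t * aby))
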