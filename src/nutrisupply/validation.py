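"""Comparison of pipeline results against a world's bookkept ground truth.

Used by the test suite and the reproduction script: collects, per output
family, the worst relative deviation between what the pipeline computed
and what the generator bookkept, plus any flag mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import FLAG_COLUMNS
from .synthetic_world import GroundTruth


def _rel_err(a: float, b: float) -> float:
    if a == b:
        return 0.0
    scale = max(abs(a), abs(b))
    return abs(a - b) / scale if scale > 0 else abs(a - b)


def _compare_cells(observed: dict, expected: dict) -> float:
    worst = 0.0
    for key in set(observed) | set(expected):
        worst = max(worst, _rel_err(observed.get(key, 0.0), expected.get(key, 0.0)))
    return worst


@dataclass
class TruthComparison:
    """Worst relative errors per output family and flag mismatch count."""

    consumption: float
    supply: float
    contributions: float
    mean_contribution: float
    coastal_population: float
    flag_mismatches: int

    @property
    def worst_value_error(self) -> float:
        return max(
            self.consumption,
            self.supply,
            self.contributions,
            self.mean_contribution,
            self.coastal_population,
        )


def compare_to_truth(results, truth: GroundTruth) -> TruthComparison:
    """Cell-by-cell comparison of one pipeline run against ground truth.

    Missing cells compare as zero; an undefined (None/NaN) contribution on
    one side only counts as a mismatch of size 1.
    """
    cons = {
        (r["country"], r["scientific_name"], r["sector"]): r["tonnes"]
        for _, r in results.consumption.iterrows()
    }
    e_cons = _compare_cells(cons, truth.expected_apparent_consumption)

    supply = {
        (r["country"], r["sector"], r["nutrient"]): r["mass_per_year"]
        for _, r in results.supply.iterrows()
    }
    e_supply = _compare_cells(supply, truth.expected_supply)

    expected_by_scope = {
        "seafood": truth.expected_contribution_seafood,
        "animal_sourced": truth.expected_contribution_asf,
        "all_foods": truth.expected_contribution_allfoods,
    }
    e_contrib = 0.0
    for _, r in results.contributions.iterrows():
        exp = expected_by_scope[r["denominator_scope"]].get((r["country"], r["nutrient"]))
        obs = r["ssf_fraction"]
        if exp is None or pd.isna(obs):
            if not (exp is None and pd.isna(obs)):
                e_contrib = max(e_contrib, 1.0)
        else:
            e_contrib = max(e_contrib, _rel_err(obs, exp))

    e_mean = 0.0
    for _, r in results.mean_contrib.iterrows():
        exp = truth.expected_mean_contribution.get(r["country"])
        obs = r["mean_ssf_contribution"]
        if exp is None or pd.isna(obs):
            if not (exp is None and pd.isna(obs)):
                e_mean = max(e_mean, 1.0)
        else:
            e_mean = max(e_mean, _rel_err(obs, exp))

    e_coastal = 0.0
    for _, r in results.coastal_pop.iterrows():
        exp = truth.expected_coastal_population.get(r["country"], 0.0)
        e_coastal = max(e_coastal, _rel_err(r["persons"], exp))

    mismatches = 0
    for _, r in results.classification.iterrows():
        exp_flags = truth.expected_flags.get(r["country"], {})
        for col in FLAG_COLUMNS:
            obs = r[col]
            exp = exp_flags.get(col)
            obs_val = None if pd.isna(obs) else bool(obs)
            if obs_val != exp:
                mismatches += 1

    return TruthComparison(
        consumption=e_cons,
        supply=e_supply,
        contributions=e_contrib,
        mean_contribution=e_mean,
        coastal_population=e_coastal,
        flag_mismatches=mismatches,
    )


def truth_equal(a: GroundTruth, b: GroundTruth, rtol: float = 0.0) -> tuple[bool, str]:
    """Field-by-field equality of two ground-truth objects.

    With the default rtol=0 this demands bitwise agreement (both paths use
    exactly rounded accumulation). Returns (ok, first-difference message).
    """
    for name in (
        "expected_apparent_consumption",
        "expected_supply",
        "expected_contribution_seafood",
        "expected_contribution_asf",
        "expected_contribution_allfoods",
        "expected_mean_contribution",
        "expected_coastal_population",
    ):
        da, db = getattr(a, name), getattr(b, name)
        for key in set(da) | set(db):
            va, vb = da.get(key), db.get(key)
            if va is None or vb is None:
                if va is not vb:
                    return False, f"{name}[{key}]: {va} vs {vb}"
                continue
            err = _rel_err(va, vb)
            if err > rtol:
                return False, f"{name}[{key}]: {va} vs {vb} (rel {err:.2e})"
    for country in set(a.expected_flags) | set(b.expected_flags):
        if a.expected_flags.get(country) != b.expected_flags.get(country):
            return False, (
                f"expected_flags[{country}]: {a.expected_flags.get(country)} "
                f"vs {b.expected_flags.get(country)}"
            )
    return True, ""
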