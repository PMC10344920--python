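"""Run and world configuration objects.

Both configs are plain dataclasses with eager validation; an invalid field
raises :class:`~nutrisupply.errors.ConfigurationError` naming the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from .constants import ALL_SECTORS, ASSESSED_NUTRIENTS, MATCH_LEVELS
from .errors import ConfigurationError


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


def _check_interval(name: str, interval: tuple[float, float]) -> None:
    lo, hi = interval
    _check_fraction(f"{name}[0]", lo)
    _check_fraction(f"{name}[1]", hi)
    if lo > hi:
        raise ConfigurationError(f"{name} interval is reversed: {interval!r}")


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic miniature world.

    Defaults describe a 24-country, 120-species world with all five
    production sectors active, moderate trade openness and per-rank
    nutrient-profile missingness that exercises every fallback level of
    the hierarchical matcher.
    """

    n_countries: int = 24
    n_species: int = 120
    #: number of distinct values at each rank above species
    taxonomy_shape: Mapping[str, int] = field(
        default_factory=lambda: {"class": 3, "order": 7, "family": 16, "genus": 40}
    )
    sectors_active: frozenset[str] = frozenset(ALL_SECTORS)
    #: commercial catch share discarded at sea
    discard_fraction_range: tuple[float, float] = (0.0, 0.2)
    #: commercial catch share reduced to fishmeal/fish oil
    fmfo_fraction_range: tuple[float, float] = (0.0, 0.35)
    #: scale of exports relative to post-filter production (0 = closed economy)
    export_intensity: float = 0.3
    #: share of imports that is re-exported unprocessed
    reexport_share: float = 0.1
    #: freshwater share of crustacean-commodity exports, removed before subtraction
    freshwater_crustacean_export_fraction: float = 0.2
    #: probability that profiles keyed at a rank are withheld, per rank
    profile_missingness_by_rank: Mapping[str, float] = field(
        default_factory=lambda: {
            "species": 0.45,
            "genus": 0.25,
            "family": 0.15,
            "order": 0.10,
            "class": 0.05,
        }
    )
    #: share of each country's population living in the coastal strip
    coastal_fraction_range: tuple[float, float] = (0.2, 0.8)
    grid_cells_per_country: int = 30
    buffer_km_default: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ConfigurationError(f"n_countries must be >= 2, got {self.n_countries}")
        if self.n_species < 1:
            raise ConfigurationError(f"n_species must be >= 1, got {self.n_species}")
        for rank, count in self.taxonomy_shape.items():
            if rank not in ("class", "order", "family", "genus"):
                raise ConfigurationError(f"taxonomy_shape has unknown rank {rank!r}")
            if count < 1:
                raise ConfigurationError(f"taxonomy_shape[{rank!r}] must be >= 1, got {count}")
        for rank in ("class", "order", "family", "genus"):
            if rank not in self.taxonomy_shape:
                raise ConfigurationError(f"taxonomy_shape is missing rank {rank!r}")
        unknown = set(self.sectors_active) - set(ALL_SECTORS)
        if unknown:
            raise ConfigurationError(f"sectors_active contains unknown sectors {sorted(unknown)}")
        if not self.sectors_active:
            raise ConfigurationError("sectors_active must contain at least one sector")
        _check_interval("discard_fraction_range", self.discard_fraction_range)
        _check_interval("fmfo_fraction_range", self.fmfo_fraction_range)
        _check_fraction("export_intensity", self.export_intensity)
        _check_fraction("reexport_share", self.reexport_share)
        _check_fraction(
            "freshwater_crustacean_export_fraction", self.freshwater_crustacean_export_fraction
        )
        for rank, frac in self.profile_missingness_by_rank.items():
            if rank not in MATCH_LEVELS[:-1]:
                raise ConfigurationError(f"profile_missingness_by_rank has unknown rank {rank!r}")
            _check_fraction(f"profile_missingness_by_rank[{rank!r}]", frac)
        _check_interval("coastal_fraction_range", self.coastal_fraction_range)
        if self.grid_cells_per_country < 1:
            raise ConfigurationError(
                f"grid_cells_per_country must be >= 1, got {self.grid_cells_per_country}"
            )
        if self.buffer_km_default <= 0:
            raise ConfigurationError(
                f"buffer_km_default must be > 0, got {self.buffer_km_default}"
            )
        if not isinstance(self.seed, int):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["taxonomy_shape"] = dict(self.taxonomy_shape)
        d["profile_missingness_by_rank"] = dict(self.profile_missingness_by_rank)
        d["sectors_active"] = sorted(self.sectors_active)
        d["discard_fraction_range"] = list(self.discard_fraction_range)
        d["fmfo_fraction_range"] = list(self.fmfo_fraction_range)
        d["coastal_fraction_range"] = list(self.coastal_fraction_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        d = dict(d)
        if "sectors_active" in d:
            d["sectors_active"] = frozenset(d["sectors_active"])
        for key in ("discard_fraction_range", "fmfo_fraction_range", "coastal_fraction_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run configuration.

    ``mode="synthetic"`` generates a world from ``seed``; ``mode="tabular"``
    reads CSV tables from ``input_dir``. Every default matches the base case
    of the analysis: 50 km coastal buffer, artisanal catch exportable,
    70th-percentile classification rule over the six assessed nutrients.
    """

    mode: str = "synthetic"
    input_dir: Path | None = None
    output_dir: Path | None = None
    buffer_km: float = 50.0
    artisanal_exportable: bool = True
    percentile: float = 0.70
    supply_threshold: float = 0.15
    intake_threshold: float = 0.50
    nutrient_set: Sequence[str] = ASSESSED_NUTRIENTS
    #: product-weight → live-weight conversion per commodity (default 1.0)
    trade_conversion_factors: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    world_config: WorldConfig | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "tabular"):
            raise ConfigurationError(f"mode must be 'synthetic' or 'tabular', got {self.mode!r}")
        if self.mode == "tabular" and self.input_dir is None:
            raise ConfigurationError("input_dir is required in tabular mode")
        if self.buffer_km <= 0:
            raise ConfigurationError(f"buffer_km must be > 0, got {self.buffer_km}")
        _check_fraction("percentile", self.percentile)
        _check_fraction("supply_threshold", self.supply_threshold)
        _check_fraction("intake_threshold", self.intake_threshold)
        for commodity, factor in self.trade_conversion_factors.items():
            if factor < 0:
                raise ConfigurationError(
                    f"trade_conversion_factors[{commodity!r}] must be >= 0, got {factor}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_dir"] = str(self.input_dir) if self.input_dir is not None else None
        d["output_dir"] = str(self.output_dir) if self.output_dir is not None else None
        d["nutrient_set"] = list(self.nutrient_set)
        d["trade_conversion_factors"] = dict(self.trade_conversion_factors)
        if self.world_config is not None:
            d["world_config"] = self.world_config.to_dict()
        return d
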