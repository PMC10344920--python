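"""Exception hierarchy for the pipeline."""


class NutriSupplyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NutriSupplyError):
    """A configuration value is invalid; the message names the offending field."""


class DataError(NutriSupplyError):
    """An input table violates its schema or vocabulary."""


class UnmatchedTaxonError(DataError):
    """No nutrient profile could be assigned, even at the commodity fallback level."""

    def __init__(self, taxon):
        self.taxon = taxon
        super().__init__(f"no nutrient profile found at any level for taxon {taxon!r}")


class UndefinedSupplyError(NutriSupplyError):
    """Per-capita supply is undefined: nonzero supply divided by a zero population."""
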