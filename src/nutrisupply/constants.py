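"""Closed vocabularies and unit conventions shared across the pipeline.

Units follow food-composition convention: nutrient concentrations are per
100 g of edible raw muscle tissue (iron, zinc, calcium in mg; vitamin A in
µg RAE; vitamin B12 in µg; DHA+EPA and protein in g). Production is in
tonnes live weight per year; one tonne is 10^4 hundred-gram units, so

    nutrient mass / yr = tonnes × 1e4 × edible_fraction × concentration

keeps each nutrient in its own concentration unit (mg, µg or g per year).
"""

# The seven tracked nutrients; the "assessed" six (used for country means
# and classification) exclude protein.
NUTRIENTS = ("iron", "zinc", "calcium", "vitamin_a", "vitamin_b12", "dha_epa", "protein")
ASSESSED_NUTRIENTS = ("iron", "zinc", "calcium", "vitamin_a", "vitamin_b12", "dha_epa")

# DHA+EPA is assumed to come exclusively from seafood: non-seafood terms are
# zeroed out of every contribution denominator for this nutrient.
SEAFOOD_ONLY_NUTRIENT = "dha_epa"

# Catch sectors (Sea Around Us convention) plus mariculture.
COMMERCIAL_SECTORS = ("artisanal", "industrial")
NONCOMMERCIAL_SECTORS = ("subsistence", "recreational")
CATCH_SECTORS = COMMERCIAL_SECTORS + NONCOMMERCIAL_SECTORS
ALL_SECTORS = CATCH_SECTORS + ("mariculture",)

# Small-scale fisheries = artisanal + subsistence.
SSF_SECTORS = ("artisanal", "subsistence")

# Source sectors appearing in the apparent-consumption table.
IMPORT_SECTOR = "imports"
CONSUMPTION_SECTORS = ALL_SECTORS + (IMPORT_SECTOR,)

# Sectors whose per-capita supply is divided by the *coastal* population;
# everything else uses the national population.
COASTAL_DENOMINATOR_SECTORS = SSF_SECTORS

END_USES = ("direct_human_consumption", "fishmeal_fish_oil", "discard")
DIRECT_HUMAN_CONSUMPTION = "direct_human_consumption"

# FAO-style fish commodity categories used for trade resolution.
COMMODITIES = ("pelagic_fish", "demersal_fish", "other_marine_fish", "crustaceans", "molluscs")
CRUSTACEAN_COMMODITY = "crustaceans"

# Taxonomic ranks in matching priority order; "species" keys on the
# scientific name and "commodity" is the terminal fallback.
MATCH_LEVELS = ("species", "genus", "family", "order", "class", "commodity")

# Column that holds each rank in profile / taxonomy tables.
RANK_COLUMNS = {
    "species": "scientific_name",
    "genus": "genus",
    "family": "family",
    "order": "order",
    "class": "class_",
    "commodity": "commodity",
}

# Taxon placeholder prefix for import flows, which are resolved only to
# commodity categories.
COMMODITY_TAXON_PREFIX = "commodity:"

# GND-style food groups for non-seafood supply.
ANIMAL_FOOD_GROUPS = ("beef", "pork", "poultry", "dairy", "sheep")
PLANT_FOOD_GROUPS = ("grains", "vegetables", "fruits", "oils")
GND_FOOD_GROUPS = ANIMAL_FOOD_GROUPS + PLANT_FOOD_GROUPS

# Coastal-population buffer distances (km) used in the sensitivity sweep.
BUFFER_DISTANCES_KM = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0)

# Unit conversion: hundred-gram units per tonne.
HG_PER_TONNE = 1e4

DAYS_PER_YEAR = 365.0
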