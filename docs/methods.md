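# Methods

This note records the model implemented by `nutrisupply`, the choices made
where the design was genuinely open, and what the synthetic-world tests do
and do not establish about behaviour on real data.

## The accounting procedure

The pipeline is a deterministic sequence of pure table transformations:

1. **End-use filter.** Commercial catch (artisanal, industrial) recorded as
   discarded or reduced to fishmeal/fish oil is dropped; only production
   destined for direct human consumption proceeds. Non-commercial catch
   (recreational, subsistence) passes through untouched regardless of its
   recorded end use, on the assumption that it is eaten.
2. **Mariculture** is added to the commercial pool; it is treated as
   entirely destined for human consumption (no discard/reduction split is
   applied to farmed production).
3. **Re-export estimation**, per country × commodity:
   `recorded` = explicit re-export flows in the trade table;
   `processed` = max(0, exports − food-balance-sheet production);
   `total` = min(recorded + processed, exports). The processed term uses
   the plain production–export difference; the cap at exports is what
   prevents the two routes from over-correcting in combination.
4. **Trade adjustment.** `total` is subtracted from both exports and
   imports (each clamped at zero): re-exported tonnage neither came from
   domestic production nor stays in the country.
5. **Freshwater-crustacean removal.** The crustacean trade category mixes
   freshwater production into a marine analysis; a per-country fraction
   (default 0.2 in the generator) is removed from crustacean exports.
6. **Live-weight conversion.** Trade is product weight, catch live weight.
   A per-commodity factor converts adjusted flows before subtraction. The
   default is 1.0 — deliberately exposed rather than hidden, since no
   authoritative per-commodity factor set ships with the package.
7. **Export subtraction.** Within each country × commodity, adjusted
   exports are allocated over the exportable (taxon, sector) cells
   proportionally to production; `retained = production × (1 − min(1,
   E/pool))`. Because allocation is proportional, clamping is
   all-or-nothing: cells hit zero only when exports exceed the whole pool,
   and the uncovered surplus is reported per country × commodity, never
   silently dropped. Artisanal catch is in the exportable pool in the base
   case (the conservative choice — it lowers estimated SSF supply); the
   sensitivity sweep flips it.
8. **Apparent consumption** = retained production + adjusted imports
   (commodity resolution only, under an `imports` source sector) +
   non-commercial catch.
9. **Nutrient conversion** via hierarchical matching (below);
   `mass/yr = tonnes × 10⁴ × edible_fraction × concentration per 100 g`.
10. **Per-capita supply.** Artisanal + subsistence mass is divided by the
    coastal population, every other source by the national population, then
    by 365. The modelled diet is that of a coastal resident: SSF catch per
    coastal capita plus national-average everything else. A zero population
    under nonzero supply is an explicit error, not a silent NaN.
11. **Contributions and classification** as described in the README.

Stage outputs are pure functions of their declared inputs, and a run is
byte-reproducible from (config, seed).

## Hierarchical matching

Priority order: species scientific name, genus, family, order, class,
commodity category. The reported match level is the first level with ≥ 1
record. Two refinements:

* **Per-nutrient fallback.** If every record at the match level lacks one
  nutrient, only that nutrient continues down the chain. This maximises
  the use of specific data when profiles are partially measured; the
  edible fraction follows the same rule.
* **Exact matching** after case-folding and whitespace collapsing; no
  fuzzy matching, for reproducibility.

Level means are unweighted arithmetic means over records — composition
databases report per-record sample sizes inconsistently, so no weighting
is attempted.

## The synthetic world

The generator emulates the five input schemas with known ground truth:

* **Geometry.** Each country is a planar rectangle (300 km deep, 200 km
  tall) whose western edge is its coastline, so a cell's coast distance is
  exactly its x-coordinate and coastal strip populations have closed
  forms. Each country's first coastal cell is pinned within 5 km of shore
  so per-capita SSF supply stays defined at the smallest swept buffer.
  Real-world mode accepts lon/lat cells with great-circle distances to a
  densified polyline (1 km step); no raster resampling is attempted.
* **Taxonomy** with configurable counts per rank; species are assigned to
  genera round-robin, families map to five FAO-style commodity categories
  (each category guaranteed non-empty).
* **Catch.** Per country, each species is present with probability
  ≈ 40/n_species; total tonnage per species is log-uniform on 10–10⁴ t and
  split across active sectors by a symmetric Dirichlet draw. Commercial
  records are split into end uses with discard and reduction fractions
  drawn from (0–0.2) and (0–0.35).
* **Trade** is tied to production: exports are `export_intensity` (default
  0.3) times a uniform share of post-filter commodity production; imports
  scale against mean global production; recorded re-exports are
  `reexport_share` (default 0.1) of imports; 30 % of producing cells
  overshoot production to exercise the processed-re-export route. Setting
  both intensities to zero yields a closed economy with empty trade tables.
* **Profiles.** One candidate record per species with log-uniform
  concentrations in biologically plausible per-100 g ranges (e.g. calcium
  5–500 mg, vitamin A 1–1000 µg RAE, DHA+EPA 0.05–3 g); protein and edible
  fraction are uniform (15–25 g, 0.3–0.9). Records are withheld per
  taxonomic rank (defaults 0.45/0.25/0.15/0.10/0.05 from species to class)
  so every fallback level occurs by construction, and individual nutrients
  are blanked with probability 0.1 to exercise per-nutrient fallback. One
  fully populated record per commodity is always retained, so matching is
  total.
* **Non-seafood diet.** GND-style per-capita supplies per food group, with
  vitamin B12 and DHA+EPA absent from plant groups. Inadequate-intake
  prevalence is uniform on 0.05–0.95; 15 % of countries carry no intake
  data at all, mirroring the data gaps that leave some island nations
  unclassifiable.

**Ground truth** is booked inside the generator by direct closed-form
accounting over the records just drawn, with no calls into the pipeline
modules. A second, structurally independent oracle
(`ground_truth_contributions`) re-derives it by brute-force scans —
matching by record-list traversal, coastal membership by point-to-segment
distance, percentiles by the written-out order-statistic formula. Both
paths accumulate with `math.fsum` (exactly rounded, order-independent), so
they agree bit for bit, and the pipeline must recover them to a relative
1e-9 (it lands near 1e-15; the slack absorbs pandas' pairwise summation
order).

What passing these tests shows: the accounting identities, fallback
semantics, allocation arithmetic and classification rules are implemented
exactly as specified, at any scale the generator covers. What they do not
show: realism of absolute magnitudes, behaviour under messy real-world
taxonomy strings, product-weight conversion factors, or bilateral trade
structure — real extracts must be pre-cleaned to the documented schemas.

## Numerical and rule choices

* **Percentile cutoff**: linear interpolation between order statistics —
  for sorted x₁ ≤ … ≤ xₙ and h = (n−1)q, cutoff = x_{⌊h⌋+1} +
  (h−⌊h⌋)(x_{⌊h⌋+2} − x_{⌊h⌋+1}). Flags require being *strictly above*
  the cutoff, so the 100th-percentile rule flags nobody and the rule is
  stable when a country's value coincides with an order statistic.
* **Absolute thresholds** (≥ 0.15 supply share, ≥ 0.50 inadequate intake)
  are inclusive at the boundary.
* **Undefined ratios** (zero denominators) are recorded as missing, never
  zero; country means are taken over available nutrients with an
  `any_missing` flag rather than dropping the country.
* **Coastal membership** is by cell centroid only; no areal weighting of
  boundary cells. The headline buffer is 50 km — an explicit package
  default, with 5–50 km treated as the sensitivity range.
* **Tolerances**: the mass-balance gate is a relative 1e-9 residual per
  country × commodity (observed ~1e-16); the ground-truth recovery gate is
  the same 1e-9.
* **Year basis**: the generator models a single nominal year; no attempt
  is made to reconcile catch-year and population-grid-year offsets.

## Problem sizes

Default worlds have 24 countries, 120 species across a 3/7/16/40-rank
taxonomy, 30 population cells per country. The acceptance script runs 50
such worlds (~1200 country classifications, ~7200 contribution fractions)
in well under a minute on one CPU; the unit suite uses 5–8-country worlds.

## Known limitations

* Imports are resolved only to commodity categories and carry
  category-mean nutrient profiles, and imported farmed vs wild seafood is
  not distinguished — sector contributions in heavy-importing countries
  are accordingly diluted.
* No bioavailability, cooking-retention or non-muscle-tissue adjustments;
  concentrations are raw muscle per 100 g.
* The income pathway (fish sold to buy other food) and within-country
  consumption heterogeneity are outside the model: every coastal resident
  shares the SSF catch equally.
* The inadequate-intake table is consumed as-is; the package does not
  estimate intake distributions.
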