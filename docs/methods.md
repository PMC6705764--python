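# Methods

This note documents the model implemented by `scaleaccess`, the choices made
where the construction was genuinely open, the synthetic data the tests run
on, and the limits of both.

## The model

The index is a demand-oriented accessibility score for point-located
populations. Its unit of analysis is the residential unit (a populated
building point), not an administrative centroid, which is what makes the
measure transportable across scales: any coarser value is an average of
unit values, never a re-computation on different geometry.

**Availability — theoretical pressure.** For one equipment category, the
plane is partitioned by the Voronoi tessellation of the facilities; the
population "most likely to benefit" from a facility is everyone in its cell.
We realise the tessellation as nearest-facility point assignment, which is
mathematically identical for point demand and avoids unbounded-cell polygon
clipping; equidistant ties go to the lowest facility id so runs are
reproducible. The assignment is restricted to facilities and units of the
same reference scope — EPCI for primary equipment (GP, nurse,
physiotherapist, dentist, pharmacist), region for tertiary (gynaecology-
obstetrics, ophthalmology, paediatrics, short-stay care, A&E) — reflecting
that primary care clienteles are local while specialised care draws
regionally. The pressure rate is assigned needy population divided by the
facility's professional count. Two open points are exposed as switches
rather than decided silently:

* `pressure_normalization`: `none` (population per professional, default) or
  `scope_share` (additionally divided by the scope's needy population).
* The *needy* population per category: everyone, women only
  (gynaecology-obstetrics), or under-19s (paediatrics). When a layer lacks
  the subgroup columns they are imputed from fixed national shares (women
  0.515, under-19 0.24) and the imputation is logged.

Facilities of the same category at the same site (within `merge_tol`,
default 0) are merged, capacities summed — co-located services have
identical areas of influence, so distinct records would split pressure
arbitrarily.

**Accessibility — DI, ZAP, DAP.** Per IRIS and category, the radius DI is
the maximum over the IRIS's units of the nearest-facility distance: the
smallest radius guaranteeing every resident one reachable facility. Each
unit's potential accessibility area is the disc of radius DI centred on the
unit (per-unit, not on the IRIS centroid), with an inclusive boundary so
the worst-case unit that defined DI keeps its nearest facility in scope.
The potential accessibility distance is the pressure-weighted mean distance
to the ZAP facilities, normalised by the summed pressures so it keeps
distance units and stays within [min, max] of the ZAP distances. Heavier
pressure means a larger weight — congestion on a facility drags the
expected distance toward it; the opposite reading is available as
`pressure_weighting="inverse_pressure"`. If every ZAP facility carries zero
pressure the unweighted mean is used (avoids 0/0) and logged.

**Transform, standardize, combine.** DAP distributions are heavily
right-skewed, so each category is Box-Cox transformed with a *fixed*
exponent λ (0.20 GP/physiotherapist, 0.18 nurse, 0.22 dentist, 0.21
pharmacist, 0.12 gynaecology-obstetrics and paediatrics, 0.13
ophthalmology, 0.10 short-stay, 0.04 A&E); zero distances are first
replaced by 10⁻⁷. λ is configuration, not re-estimated per run — the
transformed scale must mean the same thing everywhere — though a
maximum-likelihood estimator (`scaleaccess.index.estimate_lambda`) is
provided for exploration. Transformed values are z-standardized with the
sample standard deviation (n−1) over all units in the run, then combined as
the weighted sum Σₑ Wₑ zₑ with the equipment-frequency weights (category
count / GP count, rounded half-up to 3 decimals; `weight_from_counts`
recomputes them from raw counts). The combination operates on standardized
transformed values; combining raw DAPs instead is available as
`combine_on="raw_dap"` for comparison. Order of operations: replace zeros →
transform → standardize → combine.

**Classification, interpolation, scale change.** Deciles use linear
(type-7) quantile boundaries at 10%…90%; a value is in decile k if it
exceeds exactly k−1 boundaries, so equal values always share a decile and
decile 10 holds the worst accessibility. Classification is invariant under
any strictly increasing transform of the index. Surface interpolation is
inverse-distance weighting over the 12 nearest units with a squared-distance
weight (an exact hit returns the sample value); the default grid cell is
1/200 of the bounding-box diagonal. Scale change is the plain arithmetic
mean of member-unit values per target unit (population-weighted mean
available as an option).

**Distance metrics.** Euclidean by default. For sensitivity work a
Minkowski metric (exponent ~1.25, between the Euclidean under- and
Manhattan over-estimate of road travel) or a precomputed unit×facility
distance matrix (road-network stand-in, CSV `unit_id,facility_id,distance`)
can be plugged in. DI stays Euclidean by default (`di_metric="euclidean"`)
so the catchment definition is stable across metrics; `di_metric="provider"`
makes the radius follow the alternative metric, under which any strictly
increasing rescaling of distances preserves ZAP membership and index ranks.

## Synthetic territories

The generator produces the end product of a building-level population
projection — populated points with subgroup breakdowns — inside a nested
hierarchy (region → EPCI → municipality → IRIS → unit). Regions are
vertical strips of the extent, EPCI horizontal strips, IRIS Gaussian
clusters around centres drawn in the EPCI rectangle (tight clusters for the
urban fraction, loose for rural). Unit populations are lognormal(μ=2.0,
σ=1.5), mean ≈ 23 and median ≈ 7 inhabitants — matching the skew of real
residential-building populations — with urban populations inflated ×4 for
collective housing. Subgroup shares are drawn around women 51.5% and
under-19 24%. Facility counts per category and reference scope are
Poisson with mean density × needy/10,000 (densities derived from national
equipment counts per capita, e.g. GP 9.5 and A&E 0.10 per 10,000), never
below one per scope so every pressure table and catchment is computable;
placement prefers urban, populous IRIS. Draws come from per-purpose
sub-seeded streams, so adding a category never perturbs unit generation and
a seed reproduces layers exactly.

What the generator does **not** emulate: real French geography, road
networks, facility co-location economies, or the empirical national
distributions of the index. Tests passing on synthetic territories
demonstrate the correctness and invariances of the computation, not the
published national decile tables, which require the national registries.

Default test/validation problem sizes: 2 regions × 2 EPCI × 4 IRIS ×
12–25 units (192–400 units, ~30–60 facilities); oracle-equivalence checks
run on 50 random instances of ≤ 100 units and ≤ 20 facilities against
straight-line brute-force re-implementations at 10⁻⁹ relative tolerance.

## Numerical choices and degenerate inputs

* Ties in the nearest-facility assignment: lowest facility id.
* Equal index values always share a decile; fewer than 10 values cannot be
  classified (the model skips deciles with a warning below 10 units so the
  6-unit worked example still runs end to end; calling `classify_deciles`
  directly raises).
* A category whose transformed distances have zero variance is an error
  ("degenerate category") — standardization would be undefined.
* A reference scope containing units but no facility of a category is
  flagged and its units fall back to the globally nearest facility, logged
  as "unserved in scope"; conservation then holds globally but not per
  scope.
* Facilities without hierarchy identifiers inherit the scope of their
  nearest residential unit.
* Units with population 0 still receive a DAP and an index (surface
  completeness) but contribute nothing to pressure or population-weighted
  aggregates.
* Outputs are written atomically (temp file + rename).

## Known limitations

* Voronoi availability ignores competition between neighbouring services
  and assumes distance-optimising behaviour.
* The variable ZAP radius means the score of a unit depends on the worst
  unit of its IRIS; an isolated hamlet inflates DI for the whole IRIS.
* Straight-line (or Minkowski) distance is not travelled distance; the
  matrix provider accepts precomputed road distances but the package does
  no routing.
* The linear combination can give the same index to different accessibility
  profiles; the per-category columns of the surface table are kept for
  exactly that reason.
* GeoJSON layers are assumed planar when a `crs` member is declared;
  the package performs no datum transformations — reproject upstream.
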