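# scaleaccess

A multi-scalar, boundary-free **spatial accessibility index for health
services** (the SCALe index), for health geographers, epidemiologists and
regional planners who need one accessibility measure that works from the
residential building up to the region without being tied to administrative
divisions.

## The method

The index scores each populated residential point against a set of
health-equipment categories (GP, nurse, pharmacist, … up to A&E), combining
**spatial accessibility** (how far the supply is) with **availability** (how
loaded it is):

1. **Pressure rate** (availability). Each facility's area of influence is its
   Voronoi cell among facilities of the same category; the needy population
   of every residential unit in the cell — restricted to the facility's
   reference scope, EPCI for primary equipment and region for tertiary —
   is assigned to it, and

   *pressure* = assigned needy population / number of professionals.

2. **Potential accessibility distance** (DAP). Per IRIS the search radius
   *DI* is the largest nearest-facility distance over its units, so every
   unit is guaranteed at least one facility within *DI*. The facilities
   within *DI* of a unit form its potential accessibility area (ZAP), and

   *DAP* = Σₑ pressureₑ · dₑ / Σₑ pressureₑ  over e ∈ ZAP.

3. **Combination.** Each category's DAP vector is Box-Cox transformed,
   *t* = (DAPᵏ − 1)/λ with a fixed per-category λ (zeros replaced by 10⁻⁷),
   z-standardized, and combined as

   *index* = Σₑ Wₑ · zₑ

   with frequency weights Wₑ (the category's national equipment count over
   the GP count: 1.225 nurse, 1 GP, …, 0.010 A&E). **Low index = high
   accessibility.** Units are classed into deciles (10 = worst), the surface
   can be interpolated by inverse-distance weighting (12 neighbours,
   squared-distance weights), and the index averages up to any scale of the
   IRIS → municipality → EPCI → region hierarchy.

Distances are planar metric (provide layers in a projected CRS such as
Lambert-93); a Minkowski exponent ≈ 1.25 or a precomputed road-distance
matrix can replace the Euclidean metric for sensitivity analyses.

## Worked example

A hand-checkable territory ships with the package: 2 IRIS, 6 residential
units, 2 GP offices and 2 nurse offices.

```python
import scaleaccess as sa

example = sa.make_worked_example()
results = sa.AccessibilityModel(
    example.units, example.facilities, example.categories
).fit()
print(results.dap.round(4))
print(results.index.round(4))
```

```
         general practitioner   nurse
unit_id
u1                        1.5  1.2857
u2                        5.0  5.0000
u3                        2.0  2.0000
u4                        1.0  1.0000
u5                        1.0  1.0000
u6                        1.0  1.0000

unit_id
u1   -0.4833
u2    4.1681
u3    0.7456
u4   -1.4768
u5   -1.4768
u6   -1.4768
```

Unit u2 sits 5 m (the 3-4-5 triangle) from the only facilities it can reach,
so it carries the worst (largest) index; u1 reaches both GP offices at
distances {1, 3} whose pressures are {3, 1}, giving the pressure-weighted
DAP (3·1 + 1·3)/4 = 1.5. Units u4–u6 live next to the lightly loaded
southern site and share the best score.

## Command line

```bash
scaleaccess synth --seed 42 --out territory/          # synthetic layers
scaleaccess run --units territory/units.csv \
    --facilities territory/facilities.csv \
    --out results/ --aggregate epci --interpolate
scaleaccess sensitivity --units territory/units.csv \
    --facilities territory/facilities.csv --out sens/ \
    --compare-provider minkowski:1.25 --compare-provider minkowski:2
scaleaccess fixture --out fixture/                    # worked example
```

`run` writes the per-unit surface (DAP, transformed and standardized values,
index, decile), the pressure and DI tables, decile boundaries, optional
coarser-scale aggregates and the interpolated grid — all as CSV/JSON, and
atomically (a partial run never looks complete).

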