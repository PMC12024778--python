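# melliflow

Space-and-time modelling of **honey production potential (HPP)** within an
apiary's foraging area.

Beekeepers and landscape ecologists want to know *where* and *when* the
landscape around a hive can supply nectar. `melliflow` scores every
contiguous land-use patch (Land Use Unit, LUU) of a foraging area, week by
week over the flowering season (weeks 10–34, March–August), by combining:

- **landscape structure** — patch areas, patch densities, and Euclidean
  nearest-neighbour distances per land-use class (Land Use Station, LUS);
- **botanical surveys** — circular plots with Braun-Blanquet cover classes,
  converted to percent cover via the standard class midpoints;
- **nectariferous potentials** — published annual potentials *pnt* (kg/ha)
  per taxon, with genus-level fallbacks;
- **flowering phenology** — weekly phenophases (early / full / late) that
  spread each taxon's annual potential over its flowering window.

## The model

For a patch with area *S* (ha) whose centroid lies *D* metres from the
apiary, the weekly potential is

```
HPP = max(0, 1 − D/10 000) · S · Σ_t (R_t/100 · pnh_t)        [kg/week]
pnh_t = pnt_t / S_f,t · I_f,t(week)                           [kg/ha/week]
```

where *R_t* is the percent cover of taxon *t* on the patch, *S_f,t* its
flowering duration in weeks, and *I_f,t* the flowering intensity (1 at full
bloom, 0.5 in the early and late phases, 0 otherwise). The distance factor
is clamped at zero beyond 10 km; within a 1.5 km foraging radius the clamp
is inert. Patch-less land-use units borrow the nearest survey plot of the
same land-use class. Fragmentation indices follow the Fragstats
definitions: mean patch area `S_i = Σ_j a_ij / n_i`, patch density
`Dt_i = n_i/A · 10 000 · 100` (patches per 100 ha, *A* in m²), and
edge-to-edge nearest-neighbour distance `ENN_i`.

A seeded synthetic generator emulates a 707 ha heterogeneous foraging disc
(eight land uses, exact per-class patch counts and area shares, a
162-species pool with realistic richness contrasts, staggered flowering
windows) so the whole pipeline runs and is tested without any field data.

## Worked example

```python
from melliflow import GeneratorConfig, generate_landscape, generate_survey
from melliflow import metrics_table, assign_observations, cover_table
from melliflow import compute_surface, rank_taxa

cfg = GeneratorConfig(rng_seed=1)           # the default 707 ha mosaic
land = generate_landscape(cfg)
plots, traits, calendars = generate_survey(land, cfg)

print(metrics_table(land)[["lus", "n_luu", "si_ha", "dti_per_100ha"]].head(3))
cover = cover_table(assign_observations(land, plots))
surface = compute_surface(land, cover, traits, calendars)
print("peak week:", int(surface.total_by_week().idxmax()))
print(rank_taxa(surface, 3))
```

prints

```
         lus  n_luu     si_ha  dti_per_100ha
0     forest     40  6.416025       5.657709
1  grassland    114  1.618658      16.124470
2  wasteland     38  1.685637       5.374823
```

— 40 forest patches averaging 6.42 ha (5.66 per 100 ha) and 114 grassland
patches averaging 1.62 ha (16.1 per 100 ha): a mosaic dominated by many
small grassland and orchard parcels around fewer, larger forest blocks —
then

```
peak week: 20
      taxon       hpp_kg
0 taxon_143  5228.143192
1 taxon_019  4584.291707
2 taxon_001  4034.651994
```

i.e. the landscape-wide weekly potential peaks in late spring (week 20),
and the top taxa contribute a few tonnes each of cumulative potential over
the 25-week season.

The `melliflow` command line wraps the same pipeline:

```sh
melliflow run --config cfg.yaml --seed 1 --out out/
melliflow simulate --seed 1 --out data/
melliflow metrics --landscape data/landscape.geojson --out metrics.csv
```

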