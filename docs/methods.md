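# Methods

## Model

The quantity scored is the *honey production potential* (HPP) of one
contiguous land-use patch (LUU) in one week:

    HPP(u, w) = max(0, 1 − D_u / 10 000) · S_u · Σ_t R_{t,u}/100 · pnh_t(w)

- `D_u` — Euclidean distance (m) from the patch's area centroid to the
  apiary. "Centre of gravity" is read as the polygon area centroid, which
  is well defined for non-convex patches. The linear decay reaches zero at
  10 km and is clamped there; for a 1.5 km foraging radius the clamp never
  binds, it only guards against misuse on larger extents.
- `S_u` — patch area (ha). The formula is applied per patch, never per
  aggregated land-use class, so a class's potential is the sum over its
  patches.
- `R_{t,u}` — percent cover of taxon `t` on the patch, entering as a
  fraction (`R/100`): dimensional analysis (ha × kg/ha → kg) requires it.
- `pnh_t(w) = pnt_t / S_{f,t} · I_{f,t}(w)` — the annual nectariferous
  potential `pnt` (kg/ha) spread uniformly over the `S_f` flowering weeks
  and weighted by the phenophase intensity `I_f` (full = 1, early = late
  = 0.5, none = 0). Consequently `Σ_w pnh_t(w) ≤ pnt_t`, with equality
  exactly when every flowering week is at full bloom — this conservation
  property is tested.

Taxa with no potential at species or genus level are flagged `excluded`:
they never contribute to HPP but remain in richness summaries.

Cover comes from circular survey plots (herb stratum radius 0.56 m, shrub
4 m, tree 8 m) with Braun-Blanquet classes mapped to the conventional
midpoints r→0.1, +→0.5, 1→2.5, 2→15, 3→37.5, 4→62.5, 5→87.5 %. The method
is cited in the field without a numeric table; midpoints are the standard
quantification. When one patch holds several plots, a taxon's `R_t` is its
mean cover over those plots with absence counted as 0 — an unbiased
patch-level estimate. A plot-less patch borrows the nearest plot
(centroid-to-plot distance) *from the same land-use class* by default,
which keeps plant communities coherent within a class; a
globally-nearest-plot variant is available (`same_lus_only=False` /
`assignment: nearest`). Classes never surveyed (habitation, grass
cropfields) yield empty taxon sets and zero potential.

Phenology is per taxon (one calendar per taxon-year), not per plot: one
contiguous flowering window whose first and last weeks are early/late and
whose interior is full; a 1-week window is a single full week and a 2-week
window is early+late.

## Landscape indices

Per land-use class: patch count `n_i`; mean patch area
`S_i = Σ a_ij / n_i` (ha) with sample SD (n−1; a single patch reports 0);
patch density `Dt_i = n_i/A · 10 000 · 100` (patches per 100 ha, `A` the
total landscape area in m²); and mean Euclidean nearest-neighbour distance
`ENN_i` with `d_ij` measured **edge to edge** (minimum boundary distance),
the Fragstats definition — not centroid to centroid. Same-class patches
that touch are kept distinct (no dissolve) and contribute `d_ij = 0`;
classes with fewer than two patches report ENN as missing with a warning.
The nearest-neighbour search is STR-tree accelerated and is tested for
exact agreement with an exhaustive O(n²) scan on random landscapes.

## Synthetic foraging area

The generator emulates the data a two-year field campaign around one
apiary would produce. Defaults encode the emulated study conditions:

- **Region**: a 707 ha disc (radius ≈ 1.5 km), apiary at the centre.
- **Mosaic**: eight classes with patch counts 40 forest / 114 grassland /
  132 orchard / 49 maize / 43 cropfield / 38 wasteland / 13 riparian /
  55 habitation and area shares 36.3 / 26.1 / 6.11 / 4.04 / 4.17 / 9.06 /
  1.71 / 12.51 %. The habitation count is not part of the characterised
  table (its group tests use 7 classes), so 55 was fixed once as a
  plausible density of dispersed housing; its share is the remainder that
  closes the budget to 100 %.
- **Construction**: the disc is cut into vertical bands whose areas equal
  the per-class shares *exactly* (band edges by bisection on clipped
  areas); each class is split over several interleaved bands so its
  patches scatter across the area, and each band is tessellated into its
  patch count by a Voronoi diagram of uniformly seeded points. This yields
  exact counts, exact shares and exact tiling with irregular convex
  patches. Riparian forest uses many narrow bands (~10 m wide), which
  reproduces the stream-corridor geometry of that class without a separate
  polyline mechanism. Because same-class patches within a band touch,
  every ENN in the default mosaic is 0 — the generator reproduces
  composition and fragmentation counts, not the dispersion structure, so
  ENN behaviour is exercised on independent random-geometry fixtures
  instead.
- **Survey**: a 150 m grid anchored at the apiary (~314 candidate points);
  habitation and grass-cropfield points are never surveyed, and remaining
  points are retained with probability 0.55, emulating the reported field
  inaccessibility and reproducing the campaign's ~142 determined plots.
  Both parameters were fixed once from the emulated campaign description.
- **Flora**: a 162-species pool; per-class communities of 66 (forest), 84
  (grassland), 50 (wasteland), 69 (riparian), 45 (orchard), 25 (maize)
  species; per-plot richness Poisson with means 5.39 / 14.4 / 5.78 / 16.7
  / 6.0 / 3.0 (the orchard and maize means are not characterised in the
  emulated campaign and were set once to modest values consistent with
  managed vegetation). Grasses are simply absent from the pool. `pnt` is
  log-uniform on 0.5–800 kg/ha because published potentials span orders of
  magnitude; 8 % of taxa are `excluded` (no published value) and 5 %
  `genus-fallback`.
- **Phenology**: flowering onset drawn per taxon from a window tied to its
  primary community (orchard weeks 11–15, forest 12–24, riparian 14–26,
  grassland 16–30, wasteland 18–28, maize 20–26), duration uniform on 2–8
  weeks, clipped at week 34. This staggering produces the expected
  seasonal succession — an early orchard pulse, a forest-driven late
  spring peak, a grassland-dominated summer tail.

What the generator does **not** emulate: real parcel shapes and adjacency,
spatial autocorrelation of communities between neighbouring patches,
inter-annual phenology shifts, weather coupling, and any realized (as
opposed to potential) foraging. Passing tests therefore demonstrate the
pipeline's correctness and the recoverability of configured conditions,
not predictive skill on real landscapes.

## Statistics

Group effects of land use on patch area, nearest-neighbour distance and
per-plot richness use the Kruskal-Wallis H (rank formula with tie
correction, chi-square approximation, df = k−1), followed by Dunn's
two-by-two z tests with Holm adjustment (Bonferroni available). The
"all values identical" degenerate case is reported as H = 0, p = 1.
Letters in the compact letter display are the maximal cliques of the
non-significance graph at α = 0.05, ordered so that `a` marks the
highest-ranked groups. Habitation patches are mapped but never surveyed,
so they stay out of the group comparisons.

## Numerical choices and degenerate inputs

- Week axis fixed to weeks 10–34; weeks outside it are "not flowering".
- Seasonal period bins default to weeks 10–15, 16–19, 20–27, 28–34 and are
  configurable (`periods:`), since they are descriptive, not algorithmic.
- Per-area class potentials divide by the class's *total* area, whether or
  not every patch contributes.
- Ties in taxon rankings break alphabetically; nearest-plot ties break on
  plot id; both make reruns reproducible.
- Tessellation feasibility requires each class's share to provide at least
  100 m² per requested patch; violations fail fast naming the class.
- A survey spacing larger than the landscape extent yields zero plots with
  a warning, not a failure.
- Rasterisation assigns each cell the value of the patch containing its
  centre; boundary centres take the first patch in insertion order; cells
  outside every patch are no-data. Rasters are written as ESRI ASCII grid
  text; vector outputs as GeoJSON.
- Reruns with the same config and seed are byte-identical; stage timings
  go to the logger so the manifest stays deterministic.

## Problem sizes

The default mosaic (484 patches, ~130–150 plots, 162 taxa, 25 weeks)
builds in well under a second and the full pipeline in under a second;
property suites use 100 random ≤20-patch landscapes for nearest-neighbour
checks, 10 generator seeds for richness recovery, and 1,000 null
replicates (3 groups × 20) for the Kruskal-Wallis type-I error rate.
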