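# Methods

This note documents the models and procedures implemented in `thirty30`,
the parameter defaults and why they were chosen, what the synthetic world
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Grid and raster conventions

All computation happens on a planar equal-area grid of square cells
(default 5 km side, 25 km² cells — the planning-unit resolution of global
30×30 analyses).  Every operation in the pipeline depends only on cells
having constant area, so a planar frame is an exact stand-in for an
equal-area map projection (e.g. Mollweide); real projected rasters can be
passed through unchanged.  Cell indexing is row-major with cell (0,0) at
the origin corner; cell centers sit at origin + (index + ½)·cell_size.

Continuous and count layers use NaN as nodata; categorical layers use the
code −1.  nodata cells are excluded from every sum and mean and never count
as land.  Aggregation to coarser grids (`regrid`) offers `sum` (conserves
totals exactly; used for population counts), `mean` (used for priority
ranks and indices) and `mode` for categorical layers, with ties broken to
the lowest category code for determinism.

Buffers are discretized at cell level: the d-km buffer of a mask contains
the cells *outside* the mask whose center lies within Euclidean distance d
of some mask-cell center.  This makes buffers nested in distance and
disjoint from the mask by construction.  A vector-space buffer before
rasterization would be an equally defensible discretization; the cell-center
rule was chosen because it is exactly reproducible from the mask alone.

Coverage rasterization computes, per cell, the exact area fraction covered
by the *union* of the input polygons (never > 1 for overlapping records),
via polygon–cell intersection areas.  The protected/conserved
classification threshold is inclusive: coverage ≥ 0.5.

## Baseline network

Records carry status, category (PA/OECM), designation flag, realm, geometry
kind and an optional reported area.  Filtering applies, in order: negative
reported areas rejected; marine records dropped; proposed-status PAs
dropped; MAB-biosphere-flagged PAs dropped; point records with a reported
area A replaced by an equal-area circle (radius √(A/π)), without one
dropped.  Status and MAB exclusions apply to PAs only — OECMs are included
regardless — and the MAB rule is not extended to OECM records, since
"all OECMs included" is taken literally.

The buffer circle is a regular 64-gon whose radius is inflated by the
(n/2)·sin(2π/n) polygon-area factor so the polygon area equals the reported
area exactly (documented tolerance 0.1%; the construction is exact up to
floating point).  Marine portions of coastal areas are handled by clipping
kept geometries to the land-cell union before rasterization — the
grid-level equivalent of removing marine portions — and the network's
coverage fraction is reported relative to land.

## Minimum-shortfall solver

The biodiversity scenario minimizes

    Σ_f  w_f · max(0, t_f − h_f) / t_f

over selections S ⊇ locked cells with |S \ locked| ≤ budget, where h_f is
feature f's amount held in S.  Features with t_f = 0 are excluded from the
objective with a warning (their shortfall is undefined).

The solver is a deterministic beam search over greedy additions (default
width 10; width 1 is plain greedy): each beam state is expanded by the
candidate cells with the largest marginal objective decrease, ties broken
to the lowest row-major index, and the best partial selections are kept per
depth; the search stops early when no addition improves the objective.  A
final iterative-improvement phase — the one-out/one-in exchange step
familiar from reserve-selection software — applies the best strictly
improving swap until none exists.  Plain greedy alone provably misses the
optimum on a small fraction of instances when a cell's amount saturates a
nearly-met target (the surplus is wasted); the beam plus exchange phase
removes these artefacts while remaining deterministic and adding well under
a second at the default world scale.  `min_shortfall_exact` provides the
exhaustive-enumeration optimum for instances with ≤ 20 candidate cells and
is the solver's correctness oracle in the tests: on 500 seeded
planning-structured instances (presence/absence amounts of one cell area,
fractional targets — the structure the pipeline's habitat and ecoregion
features actually have) the solver matches the enumerated optimum exactly.

Species representation targets follow the range-size rule: 100% of habitat
for extents below 1,000 km², 10% above 250,000 km², log-linear in between.
Ecoregion targets default to 15% of ecoregion area.  KBAs are locked into
the solution rather than treated as features.  If the shortfall search
stalls before the budget is exhausted (e.g. no features), the remaining
budget is filled in row-major order so the scenario still reaches its
coverage target; this degenerate path is deterministic and documented.

## NCP scenario

Baseline cells are overridden to the highest priority; land cells are then
taken in descending rank (stable sort, row-major ties) until coverage
reaches the target.  The captured-value share — Σ rank over selected cells
divided by Σ rank over land — is computed on the original, pre-override
rank layer.  The "top 30%" is computed over the land mask; nodata fringes
are not part of the denominator.

## ITT scenario

Point ICCAs are buffered to their reported area with the same equal-area
circle used for the baseline; IPLC geometries flagged "subject to other
special rights" are dropped; ICCA + IPLC + baseline are unioned on the
grid; candidate cells (not ICCA, not baseline) with HMI > 0.1 are excluded.
The HMI filter deliberately exempts ICCA and baseline cells: removing
baseline cells would shrink the current network below its own coverage,
contradicting the scenario's construction.  If coverage still exceeds the
target, eligible cells are removed uniformly at random without replacement
until the target is met (±1 cell), with replicate r seeded `seed + r`.  The
reference mask is replicate 1; `inclusion_frequency` is the per-cell mean
over replicates, and downstream statistics for the ITT scenario are
frequency-weighted zonal sums, which equal the replicate mean exactly for
counts and areas (and the corresponding ratio of means for shares).  The
buffer ring is computed from the reference mask.  Should the raw union fall
below the target, nothing is removed and the achieved fraction is reported
as-is; if the never-removable cells alone exceed the target, the builder
raises.

For display of sensitive layers, `coarsen_frequency` mean-aggregates the
frequency and binarizes presence (> 0), mirroring the coarse presence maps
used to avoid publishing territory boundaries.

## Social profiles

* HDI classes are half-open — [0, 0.55), [0.55, 0.70), [0.70, 0.80),
  [0.80, 1] — so each value falls in exactly one class and the printed
  0.699/0.700 boundary is unambiguous.
* `mean_hdi` is population-weighted, not area-weighted.
* The wild-harvest share's denominator is the *tropical* resident
  population (|latitude| ≤ 24°), because the underlying layer is defined
  only there; the tropical resident count is reported alongside for
  transparency.  Zero tropical population flags the share as
  not-applicable rather than zero.
* Farm and rangeland statistics are area shares of the mask; when the three
  farm components tile the cell area they sum to 100%.
* Scenario profiles in the pipeline are computed on expansion areas
  (scenario mask minus baseline), with the current network profiled
  separately; buffer populations are computed independently per scenario
  with no cross-scenario de-duplication.
* Continental rows use population-weighted means within mask∩continent and
  report the whole-continent population-weighted mean as the reference;
  cells with missing continent codes appear in an `unassigned` row, so
  per-continent resident populations always sum to the global figure.
* Overlap statistics are computed on new (beyond-baseline) cells only, and
  both directional (|A∩B|/|A|) and symmetric (Jaccard) pairwise overlaps
  are reported, because a bare "X% overlap" does not identify its
  denominator.

## Synthetic world

The generator emulates the *statistical structure* of the real input
layers, not their content or totals:

* **Population** is a mixture of Gaussian clusters with log-normal masses
  (default 12 clusters, log-mass μ=12, σ=1) plus a diffuse rural background
  of 2 persons/km², generated on a 5× finer grid and aggregated by
  summation — so the regridder's conservation path is exercised on every
  world and remote cells are inhabited, as in census-disaggregated
  population surfaces.
* **HDI** is a logistic transform of ρ·z(log density) + √(1−ρ²)·(smoothed
  noise) with default ρ = 0.8, giving the empirical HDI–density correlation
  the profiling assumes.
* **HMI** saturates in smoothed population density (decay scale 25 km).
  The saturation scale is calibrated per world so that minimally modified
  cells (HMI ≤ 0.1) cover ~40% of land, emulating the global prevalence of
  low-modification lands; without this the ITT scenario's low-modification
  rule would have no domain to act on.
* **Wild harvesting** declines logistically in HDI inside the tropics band,
  capped at 75% participation outside custodian territories — the cap
  leaves headroom for the planted within-IPLC contrast, mirroring the
  empirical gap between custodian and non-custodian participation rates.
* **IPLC lands** are blobs sampled preferentially on low-HMI cells with a
  4× weight toward the tropics (mapped territories are tropics-heavy);
  ~15% are flagged with other special rights.  ICCA records mix polygons
  and point-plus-area entries.  PA records include the tricky fixtures the
  filtering rules exist for: proposed, MAB-flagged, marine, point-with-area
  and point-without-area records, in configurable counts.
* **Latitude** is a linear north–south coordinate (±57.5° by default), so
  the ±24° tropics rule is exercised without spherical geometry.
* All randomness flows from one seed through named substreams, so changing
  one component's draw count does not perturb any other component.

`plant_contrast` lowers HDI and scales wild-harvest population (capped at
the resident population) inside the IPLC footprint, recording clipping in
the world's truth record.  This implants the qualitative contrast the
profiler is expected to recover: custodian territories poorer and more
harvest-dependent than the areas a biodiversity- or NCP-driven expansion
selects.

What the synthetic world does **not** emulate: real geography, real global
totals, coastlines/islands, country borders, spatial autocorrelation of
farm systems at sub-cluster scale, or the data-quality gaps of the real
databases (e.g. national reporting restrictions).  Passing tests on
synthetic worlds therefore demonstrate the correctness and stability of the
*pipeline*, not the reproduction of published global numbers, which depend
on multi-gigabyte proprietary-versioned inputs.

Default problem sizes: the standard world is a 60×60 grid (~2,520 land
cells at 70% land), generating in well under a second; scenario
construction, 100 ITT replicates and full profiling complete in a few
seconds.  Multi-world analyses (e.g. the 50-world contrast-recovery check)
use 25 ITT replicates per world.

## Pipeline and reproducibility

The orchestrated run writes every stage's outputs (text rasters, GeoJSON,
CSV/JSON tables, a markdown report) plus a manifest listing config echo,
seeds, per-stage timings and SHA-256 hashes of every output file.  Stage
cache keys combine the stage's config with its upstream keys; a stage
recomputes when its key, its outputs, or any upstream stage changed, so
re-running an unchanged config is a no-op with byte-identical outputs and a
corrupted file is restored together with its descendants.

## Known limitations

* The solver is a heuristic; optimality is verified exhaustively only at
  desk scale.  At global scale the published analyses used ILP solvers with
  a 1% optimality gap; the beam search reproduces the objective structure
  but carries no gap certificate.
* Buffer semantics are cell-center Euclidean; at 5 km cells a 10 km buffer
  is 2 cells wide, which slightly under-represents diagonal adjacency
  relative to a vector buffer.
* The ITT frequency-weighted share statistics are ratio-of-means rather
  than mean-of-ratios across replicates; the difference is far below the
  replicate sampling noise at the default replicate counts.
* Country-level disaggregation, PADDD dynamics and the reproduction of
  specific third-party scenario layers are out of scope.
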