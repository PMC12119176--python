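# Methods

## Model and procedure

`kelpniche` characterizes a species' realized environmental niche
per marine ecoregion with a per-variable envelope rather than a fitted
model.  The underlying assumption is the classical bell-curve response:
conditions near the middle of a species' observed range are preferred,
conditions toward the observed extremes are tolerated, and conditions
beyond them are treated as unsuitable.  Under that assumption the
five-number summary (min, 25th percentile, mean, 75th percentile, max) of
the environmental values extracted at occurrence points is an
interpretable stand-in for the niche: `[min, max]` is the tolerated hull,
`[p25, p75]` the preferred band, the mean the optimum.  No probability
model is fitted — occurrence data are presence-only, and composite
habitat-suitability indices would obscure the per-variable ranges the
envelopes expose.

The pipeline stages, in order, with their bookkeeping contracts:

1. **Ingestion.**  Delimited Darwin-Core-style text, comma or tab
   autodetected from the header.  Rows failing validation (coordinates
   unparseable or outside ±90/±180, blank species) go to a rejection log
   with a reason code; `records + rejections = rows` always.  Records are
   kept raw: no deduplication by default (the envelope is defined over
   observations; an exact-duplicate drop flag exists), no date filter
   (year is provenance only), species names verbatim after whitespace
   trimming.
2. **Taxon filter.**  Case-insensitive equality on the order column
   (default `Laminariales`).  Idempotent.
3. **Land removal.**  A record is land-based iff it extracts nodata from a
   designated reference ocean layer.  A polygon land mask would be an
   alternative; the raster mask keeps the definition identical to the
   extraction semantics.
4. **Extraction.**  Containing-cell lookup, no interpolation — bilinear
   smoothing would invent values in coastal cells where no measurement
   exists.  The cell convention is half-open and used everywhere: cell
   (r, c) covers lon `[west + c·dx, west + (c+1)·dx)` and lat
   `(north − (r+1)·dy, north − r·dy]`, row 0 northmost, so every point
   belongs to at most one cell and internal boundaries are unambiguous.
   Longitudes are wrapped to `[−180, 180)` first (so +180 = −180).  Each
   variable is extracted at its native resolution independently; a point in
   a coastal nodata cell of one layer is missing for that variable only.
5. **Ecoregion assignment.**  Point-in-polygon (boundary inclusive) with
   ties on shared edges broken toward the smaller `eco_id` — deterministic
   and independent of polygon order.  `snap_tolerance` (degrees, default 0)
   optionally attaches points just outside all polygons to the nearest one,
   because occurrence coordinates often sit marginally offshore of coastal
   polygons; unassigned records have no stratum and are excluded from all
   summaries.
6. **Envelope summary.**  Per (species, ecoregion, variable), missing
   values excluded per variable, `n_obs` the non-missing count.  The
   quantile is the linear-interpolation formula (R `type 7`, NumPy
   default): `h = (n−1)p + 1` on the 1-based sorted sample, interpolate
   between `x_⌊h⌋` and `x_⌊h⌋+1`.  It is implemented directly from this
   formula (and cross-checked against `np.quantile` in the tests) so the
   envelope ordering `min ≤ p25 ≤ p75 ≤ max`, `min ≤ mean ≤ max` holds by
   construction on every emitted row.
7. **Minimum-observation filter.**  A species-ecoregion pair survives iff
   its occurrence-record count is *strictly greater* than the threshold
   (default 10, i.e. n ≥ 11): "more than 10" read literally.  The filter
   is applied to record counts before per-variable missing-value
   exclusion, so a sparse layer can report `n_obs` below the threshold —
   it is reported, not re-filtered, because the quality rule concerns
   observations, not extractions.
8. **Suitability mapping.**  Per variable, reclassify the layer to 1 on
   `lo ≤ v ≤ hi` (inclusive both ends, so a degenerate `p25 = p75` band
   still matches its one value) and 0 elsewhere.  Band modes: `iqr`
   (band `[p25, p75]`, hard exclusion outside `[min, max]`), `range`
   (band `[min, max]`), `graded` (2/1/0 tiering — full weight inside the
   IQR, half weight inside the observed hull — the discrete reading of
   "values nearer the optimum are better"; a continuous distance-to-mean
   kernel is deliberately out of scope).  Binary layers are summed with
   non-negative weights after nearest-cell resampling to a common grid
   (default: the finest input grid, consistent with containing-cell
   extraction).  Nodata propagates conjunctively — a cell missing any
   layer is missing in the score — so scores are only reported where all
   evidence exists; a `lenient` mode instead rescales by the weight sum of
   the layers present.  Zonal statistics assign each cell to the zone
   covering its center (smaller-id tie-break) and rank zones by mean
   score, ties by id.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `min_observations` | records | 10 (strict >) | envelopes from ≤10 points are dominated by sampling noise |
| `snap_tolerance` | degrees | 0 | strict containment; raise to ~0.1 for coastal GPS slack |
| band `mode` | — | `iqr` | preferred band under the bell-curve assumption |
| `weights` | — | 1 per variable | equal evidence unless the user ranks variables |
| `nodata_policy` | — | `strict` | no score without full evidence |
| `seed` | — | config-wide | single source of all randomness |

## The synthetic world

The generator emulates the three real inputs with known structure:
layers are constant fields, west-east linear ramps, or seeded smoothed
Gaussian random fields, with a seeded random `land_fraction` of cells set
to nodata; ecoregions are equal-width longitude strips tiling the grid's
bounding box exactly; occurrences are drawn (with replacement) over cell
centers with probability proportional to the product over variables of
Gaussian densities `N(μ_v, σ_v²)` evaluated at the cell's values — the
minimal realization of independent bell-curve responses.  Points sit at
cell centers so extraction is exact in tests (a jitter option exercises
boundary handling).  The default study system is a 40×40 half-degree grid
(lon −10…10, lat 35…55), 10% land, four strips, three layers (SST ramp
5–25 °C, smooth salinity field mean 34 sd 1 PSS, PAR ramp 20–50
E·m⁻²·day⁻¹), and three species with thermal optima 9/15/21 °C (σ = 2 °C)
and mild salinity preferences, sampled at 1500/900/400 points — sizes
large enough that several, but deliberately not all, species-strip pairs
clear the >10-record filter.

What the generator does *not* emulate: real kelp biogeography, spatial
autocorrelation of survey effort, covariance between variables, or
coordinate error.  Passing tests therefore demonstrate the correctness of
the bookkeeping, geometry, and statistics, not the ecological fidelity of
any envelope derived from real data.

## Numerical choices

- Quantile: hand-implemented linear-interpolation formula; `p=0`/`p=1`
  return the extremes exactly; empty samples are a domain error.
- Cell lookup: `floor((north − lat)/dy)` / `floor((lon − west)/dx)`, which
  realizes the half-open convention including the north/west edges.
- Grid sampling of niches: densities are computed in log space and shifted
  by the maximum before exponentiation; `σ = 0` degenerates to an exact
  value match, and a niche with no habitable cell is an explicit error.
- ESRI ASCII files are written with full `repr` precision so write→read
  round trips are bit-exact; GeoTIFFs store float64 with the
  ModelPixelScale/ModelTiepoint/GDAL_NODATA tags.
- Determinism: all tabular outputs are byte-reproducible for a fixed
  config + seed; nothing time-dependent enters an output file.

## Problem sizes

The test suite and the reproduction script run entirely on synthetic
inputs: the 40×40 default world (2800 records), oracle comparisons on
grids up to 50×50 with 1000 points, and a niche-recovery experiment with
n = 5000 points on a 3×1201 gradient grid — sizes at which the quantile
standard error (~0.04 at the quartiles) dominates the grid discretization
(0.0125° cells, value lattice 0.025 °C).

## Known limitations

- All inputs are assumed WGS84 geographic; there is no reprojection.
- Observation dates are not matched to layer epochs (historical records
  against climatological layers), so envelopes are historical averages.
- GeoJSON is the only vector input format; shapefiles must be converted.
- ESRI ASCII output requires square cells (the format has one `cellsize`).
- No taxonomic-backbone reconciliation: species names are taken verbatim.
- Envelopes are per-variable rectangles; interactions between variables
  are only captured multiplicatively by the suitability stack, never in
  the summaries themselves.
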