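"""Envelope-driven habitat suitability mapping.

The procedure turns envelope rows into a site-ranking raster:

1. per variable, reclassify the environmental layer to 1 inside the
   envelope band (by default the interquartile range [p25, p75]) and 0
   outside, with values beyond the observed min/max forced to 0;
2. add the binary layers, optionally weighted by variable importance;
3. rank areas by zonal statistics of the summed score.

Cells with the highest score satisfy the most (or most heavily weighted)
per-variable conditions simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .ecoregions import Ecoregion
from .errors import ConfigurationError
from .grids import EnvLayer, GridGeoref, extract_at_points

__all__ = [
    "BandRecipe",
    "SuitabilityMap",
    "recipe_from_summary",
    "reclassify_band",
    "stack_score",
    "zonal_stats",
]

#: Band-definition modes: "iqr" scores the interquartile range and excludes
#: beyond the observed extremes; "range" scores the full observed range;
#: "graded" is the three-level variant (2 inside [p25, p75], 1 inside
#: [min, max], 0 outside) for ranking values closer to the optimum higher.
BAND_MODES = ("iqr", "range", "graded")


@dataclass(frozen=True)
class BandRecipe:
    """Scoring rule for one environmental variable.

    Cells with value in ``[lo, hi]`` (inclusive) score ``weight``; cells
    outside ``[exclusion_min, exclusion_max]`` (when set) score 0 regardless.
    ``graded`` adds a half-weight middle tier between the exclusion bounds.
    """

    variable_code: str
    lo: float
    hi: float
    weight: float = 1.0
    exclusion_min: float | None = None
    exclusion_max: float | None = None
    graded: bool = False

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ConfigurationError(f"band lo {self.lo} > hi {self.hi}")
        if self.weight < 0:
            raise ConfigurationError("weight must be non-negative")
        if self.exclusion_min is not None and self.exclusion_min > self.lo:
            raise ConfigurationError("exclusion_min must be <= lo")
        if self.exclusion_max is not None and self.exclusion_max < self.hi:
            raise ConfigurationError("exclusion_max must be >= hi")


@dataclass
class SuitabilityMap:
    """An additive suitability score grid plus the recipe that produced it.

    Non-nodata scores lie in ``[0, max_score]`` with ``max_score`` the sum
    of weights; with unit weights every valid score is an integer (the
    number of satisfied conditions).  ``scores`` uses NaN for nodata.
    """

    georef: GridGeoref
    scores: np.ndarray
    recipes: list[BandRecipe] = field(default_factory=list)
    max_score: float = 0.0

    def as_layer(self, variable_code: str = "suitability") -> EnvLayer:
        """View as an EnvLayer (for GeoTIFF/ASCII export), nodata -9999."""
        vals = np.where(np.isnan(self.scores), -9999.0, self.scores)
        return EnvLayer(variable_code, "score", self.georef, vals, nodata=-9999.0)


def recipe_from_summary(row, mode: str = "iqr", weight: float = 1.0) -> BandRecipe:
    """Build a band recipe from one envelope row.

    ``row`` is a mapping (e.g. a DataFrame row) with keys ``variable_code``,
    ``min``, ``p25``, ``p75``, ``max``.  Mode ``iqr`` scores [p25, p75] and
    excludes beyond [min, max]; ``range`` scores [min, max]; ``graded``
    produces the three-level 2/1/0 recipe (realized as weight inside
    [p25, p75], weight/2 inside [min, max]).
    """
    if mode not in BAND_MODES:
        raise ConfigurationError(f"unknown band mode {mode!r}; expected one of {BAND_MODES}")
    var = row["variable_code"]
    if mode == "range":
        return BandRecipe(var, lo=float(row["min"]), hi=float(row["max"]), weight=weight)
    return BandRecipe(
        var, lo=float(row["p25"]), hi=float(row["p75"]), weight=weight,
        exclusion_min=float(row["min"]), exclusion_max=float(row["max"]),
        graded=(mode == "graded"),
    )


def reclassify_band(layer: EnvLayer, recipe: BandRecipe) -> EnvLayer:
    """Reclassify a layer to {0, 1} by band membership (nodata preserved).

    A cell maps to 1 iff ``lo <= value <= hi`` (inclusive both ends, so a
    degenerate p25 == p75 band is still non-empty); values outside the
    exclusion bounds force 0.  With ``recipe.graded``, cells inside the
    exclusion bounds but outside the band map to 0.5 instead of 0, giving
    the 2/1/0 tiering once weighted.
    """
    if layer.variable_code != recipe.variable_code:
        raise ConfigurationError(
            f"layer {layer.variable_code!r} does not match recipe {recipe.variable_code!r}")
    v = layer.values
    nod = layer.mask
    inside = (v >= recipe.lo) & (v <= recipe.hi)
    out = inside.astype(float)
    if recipe.graded:
        mid = ~inside
        if recipe.exclusion_min is not None:
            mid &= v >= recipe.exclusion_min
        if recipe.exclusion_max is not None:
            mid &= v <= recipe.exclusion_max
        out[mid] = 0.5
    if recipe.exclusion_min is not None:
        out[v < recipe.exclusion_min] = 0.0
    if recipe.exclusion_max is not None:
        out[v > recipe.exclusion_max] = 0.0
    out[nod] = layer.nodata
    return layer.with_values(out)


def _resample_nearest(layer: EnvLayer, target: GridGeoref) -> np.ndarray:
    """Sample ``layer`` at the cell centers of ``target`` (NaN = nodata)."""
    if layer.georef == target:
        return layer.masked()
    lat = np.repeat(target.lat_centers(), target.n_cols)
    lon = np.tile(target.lon_centers(), target.n_rows)
    vals = extract_at_points(layer, np.column_stack([lat, lon]))
    return vals.reshape(target.shape)


def finest_georef(layers: list[EnvLayer]) -> GridGeoref:
    """Georef of the layer with the smallest cell area (the default target)."""
    return min(layers, key=lambda l: l.georef.dx * l.georef.dy).georef


def stack_score(binary_layers: list[EnvLayer], weights: list[float],
                target_georef: GridGeoref | None = None,
                *, nodata_policy: str = "strict") -> SuitabilityMap:
    """Weighted sum of reclassified layers on a common grid.

    Layers on other grids are first resampled to ``target_georef`` (default:
    the finest input grid) by nearest-cell lookup.  Under the default
    ``strict`` nodata policy, a cell that is nodata in any layer is nodata
    in the output, so scores are only reported where all evidence exists;
    ``lenient`` instead rescales each cell by ``max_score / (sum of weights
    of layers valid there)``, keeping partial-evidence cells comparable.
    """
    if not binary_layers:
        raise ConfigurationError("stack_score needs at least one layer")
    if len(weights) != len(binary_layers):
        raise ConfigurationError("weights must align one-to-one with layers")
    if any(w < 0 for w in weights):
        raise ConfigurationError("weights must be non-negative")
    if nodata_policy not in ("strict", "lenient"):
        raise ConfigurationError(f"unknown nodata policy {nodata_policy!r}")
    target = target_georef or finest_georef(binary_layers)
    score = np.zeros(target.shape)
    valid_weight = np.zeros(target.shape)
    any_nodata = np.zeros(target.shape, dtype=bool)
    for layer, w in zip(binary_layers, weights):
        vals = _resample_nearest(layer, target)
        nod = np.isnan(vals)
        any_nodata |= nod
        score += np.where(nod, 0.0, vals) * w
        valid_weight += np.where(nod, 0.0, w)
    max_score = float(sum(weights))
    if nodata_policy == "strict":
        score[any_nodata] = np.nan
    else:
        all_missing = valid_weight == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(all_missing, np.nan, score * max_score
                             / np.where(all_missing, 1.0, valid_weight))
    return SuitabilityMap(georef=target, scores=score,
                          recipes=[], max_score=max_score)


def zonal_stats(smap: SuitabilityMap, zones: list[Ecoregion]) -> pd.DataFrame:
    """Per-zone summary of the score raster, ranking zones by mean score.

    A cell belongs to the zone containing (covering) its center; cells on a
    boundary shared by two zones go to the smaller zone id.  Statistics are
    over non-nodata cells; ``fraction_at_max`` is the fraction of those at
    the map's theoretical ``max_score``.  Zones with no cells report
    ``n_cells`` 0 and NaN statistics.  Output sorted by ``mean_score``
    descending, ties by ``zone_id`` ascending.
    """
    g = smap.georef
    lat = np.repeat(g.lat_centers(), g.n_cols)
    lon = np.tile(g.lon_centers(), g.n_rows)
    pts = shapely.points(lon, lat)
    owner = np.full(len(pts), -1, dtype=np.int64)
    for zone in sorted(zones, key=lambda z: z.eco_id):
        hit = shapely.intersects(zone.geometry, pts)
        hit &= owner == -1
        owner[hit] = zone.eco_id
    flat = smap.scores.ravel()
    rows = []
    for zone in zones:
        vals = flat[(owner == zone.eco_id)]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows.append((zone.eco_id, 0, np.nan, np.nan, np.nan))
        else:
            rows.append((
                zone.eco_id, int(vals.size), float(vals.mean()), float(vals.max()),
                float((vals == smap.max_score).mean()),
            ))
    out = pd.DataFrame(rows, columns=["zone_id", "n_cells", "mean_score",
                                      "max_score_observed", "fraction_at_max"])
    return (out.sort_values(["mean_score", "zone_id"], ascending=[False, True],
                            na_position="last")
            .reset_index(drop=True))
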