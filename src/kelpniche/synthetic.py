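"""Synthetic worlds with known structure, for testing and demonstration.

The generator emulates the three real inputs — gridded ocean layers,
rectangular ecoregions, and species occurrences — under the bell-curve
niche assumption: each species has, per variable, a Gaussian preference
(mu, sigma), and occurrence locations are sampled over ocean cells with
probability proportional to the product of the per-variable densities at
the cell's values.  Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .ecoregions import Ecoregion
from .errors import DegenerateSpecError
from .grids import DEFAULT_NODATA, EnvLayer, GridGeoref
from .occurrences import RECORD_COLUMNS, OccurrenceSet

__all__ = [
    "NicheSpec",
    "make_synthetic_layer",
    "make_synthetic_ecoregions",
    "make_synthetic_occurrences",
    "default_world",
]


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian niche of one simulated species.

    ``niche`` maps variable_code -> (mu, sigma); sigma == 0 degenerates to
    a point preference (only cells with value exactly mu are habitable).
    """

    species_name: str
    niche: dict[str, tuple[float, float]]
    n_points: int
    seed: int
    genus: str = "Synthetica"
    order: str = "Laminariales"

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        for var, (_, sigma) in self.niche.items():
            if sigma < 0:
                raise ValueError(f"sigma must be >= 0 for {var}")


def make_synthetic_layer(georef: GridGeoref, field_spec, land_fraction: float = 0.0,
                         seed: int = 0, *, variable_code: str = "synthetic",
                         units: str = "", nodata: float = DEFAULT_NODATA) -> EnvLayer:
    """Generate a layer with a known value field and seeded land cells.

    ``field_spec`` is one of:

    - ``("constant", c)`` — every cell holds c;
    - ``("gradient", a, b)`` — west-east linear ramp: column c holds
      ``a + (b - a) * c / (n_cols - 1)`` (all-``a`` on a 1-column grid);
    - ``("smooth", mean, sd, length)`` — seeded Gaussian random field,
      smoothed with a kernel of ``length`` cells then rescaled to the given
      mean and sd.

    ``floor(land_fraction * n_cells)`` cells, chosen by the seeded RNG, are
    set to nodata.  Identical seed -> bit-identical layer.
    """
    kind = field_spec[0]
    nr, nc = georef.shape
    if kind == "constant":
        values = np.full((nr, nc), float(field_spec[1]))
    elif kind == "gradient":
        a, b = float(field_spec[1]), float(field_spec[2])
        col = np.arange(nc, dtype=float)
        ramp = np.full(nc, a) if nc == 1 else a + (b - a) * col / (nc - 1)
        values = np.tile(ramp, (nr, 1))
    elif kind == "smooth":
        mean, sd, length = (float(field_spec[1]), float(field_spec[2]),
                            float(field_spec[3]))
        rng = np.random.default_rng(seed)
        raw = gaussian_filter(rng.standard_normal((nr, nc)), sigma=length,
                              mode="wrap")
        raw_sd = raw.std()
        if raw_sd > 0:
            raw = (raw - raw.mean()) / raw_sd
        values = mean + sd * raw
    else:
        raise ValueError(f"unknown field spec {kind!r}")
    if land_fraction > 0:
        rng_land = np.random.default_rng(seed + 1)
        n_land = int(np.floor(land_fraction * nr * nc))
        idx = rng_land.choice(nr * nc, size=n_land, replace=False)
        values.ravel()[idx] = nodata
    return EnvLayer(variable_code, units, georef, values, nodata=nodata,
                    provenance={"synthetic": True, "field": list(field_spec), "seed": seed})


def make_synthetic_ecoregions(georef: GridGeoref, n_regions: int) -> list[Ecoregion]:
    """Partition the grid's bounding box into equal-width west-east strips.

    Strips tile the box exactly (no gaps or overlaps) and get eco_id 1..n.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    width = (georef.east - georef.west) / n_regions
    regions = []
    for i in range(n_regions):
        w = georef.west + i * width
        e = georef.west + (i + 1) * width
        regions.append(Ecoregion(
            eco_id=i + 1, name=f"Strip {i + 1}",
            geometry=box(w, georef.south, e, georef.north)))
    return regions


def make_synthetic_occurrences(spec: NicheSpec, layers: list[EnvLayer],
                               *, jitter: float = 0.0) -> OccurrenceSet:
    """Sample occurrence records from a Gaussian niche over aligned layers.

    Cell centers are drawn with replacement with probability proportional to
    the product over the spec's variables of the Gaussian density of that
    cell's value under (mu, sigma); cells that are nodata in any layer have
    probability 0.  Records are placed at sampled cell centers (so raster
    extraction is unambiguous); ``jitter`` > 0 instead displaces each point
    uniformly within that fraction of a half-cell, for exercising boundary
    handling.  Identical spec (incl. seed) -> identical set.
    """
    if not layers:
        raise ValueError("need at least one layer")
    georef = layers[0].georef
    by_code = {}
    for layer in layers:
        if layer.georef != georef:
            raise ValueError("layers must share one grid")
        by_code[layer.variable_code] = layer
    missing = set(spec.niche) - set(by_code)
    if missing:
        raise ValueError(f"spec variables absent from layers: {sorted(missing)}")

    log_p = np.zeros(georef.shape)
    habitable = np.ones(georef.shape, dtype=bool)
    for var, (mu, sigma) in spec.niche.items():
        layer = by_code[var]
        vals = layer.masked()
        habitable &= ~np.isnan(vals)
        if sigma == 0:
            habitable &= vals == mu
        else:
            with np.errstate(invalid="ignore"):
                log_p += np.where(np.isnan(vals), 0.0, -((vals - mu) ** 2) / (2 * sigma**2))
    # any-layer nodata is uninhabitable even for variables outside the niche
    for layer in by_code.values():
        habitable &= ~layer.mask
    if not habitable.any():
        raise DegenerateSpecError(f"{spec.species_name}: no habitable cell under the niche spec")
    log_p = np.where(habitable, log_p, -np.inf)
    log_p -= log_p[habitable].max()
    prob = np.exp(log_p)
    prob /= prob.sum()

    rng = np.random.default_rng(spec.seed)
    flat = rng.choice(georef.n_rows * georef.n_cols, size=spec.n_points,
                      replace=True, p=prob.ravel())
    r, c = np.divmod(flat, georef.n_cols)
    lat = georef.north - (r + 0.5) * georef.dy
    lon = georef.west + (c + 0.5) * georef.dx
    if jitter > 0:
        lat = lat + rng.uniform(-0.5, 0.5, spec.n_points) * jitter * georef.dy
        lon = lon + rng.uniform(-0.5, 0.5, spec.n_points) * jitter * georef.dx
    years = rng.integers(1821, 2020, size=spec.n_points)
    df = pd.DataFrame({
        "species": spec.species_name,
        "genus": spec.genus,
        "order": spec.order,
        "latitude": lat,
        "longitude": lon,
        "event_year": years,
        "source_id": [f"synthetic:{spec.species_name}:{i}" for i in range(spec.n_points)],
    })[RECORD_COLUMNS]
    return OccurrenceSet(records=df, provenance=f"synthetic seed={spec.seed}")


# ---------------------------------------------------------------------------
# The default synthetic world: the fixed study conditions used by the test
# suite, the worked example, and the reproduction script.

#: Grid: 40x40 cells of 0.5 degrees, lon [-10, 10), lat [35, 55).
DEFAULT_GEOREF = GridGeoref(west=-10.0, north=55.0, dx=0.5, dy=0.5, n_rows=40, n_cols=40)

#: (variable_code, units, field spec) of the three default layers.
DEFAULT_LAYERS = [
    ("bo_sst_x", "°C", ("gradient", 5.0, 25.0)),
    ("bo_salinity", "PSS", ("smooth", 34.0, 1.0, 3.0)),
    ("bo_parmean", "Einstein/m^2/day", ("gradient", 20.0, 50.0)),
]

#: Gaussian niches of the three default species (all kelps, two genera).
DEFAULT_SPECIES = [
    ("Synthetica borealis", "Synthetica", {"bo_sst_x": (9.0, 2.0), "bo_salinity": (34.0, 1.5)}, 1500),
    ("Synthetica media", "Synthetica", {"bo_sst_x": (15.0, 2.0), "bo_salinity": (34.0, 1.5)}, 900),
    ("Pseudolaminaria australis", "Pseudolaminaria", {"bo_sst_x": (21.0, 2.0), "bo_salinity": (33.5, 1.5)}, 400),
]

DEFAULT_LAND_FRACTION = 0.1
DEFAULT_N_REGIONS = 4


def default_world(seed: int = 1):
    """Build the default synthetic study system.

    Three environmental layers (a west-east SST ramp, a smooth salinity
    field, a PAR ramp) on one 40x40 half-degree grid with 10% random land,
    four equal-width ecoregion strips, and three kelp species with distinct
    thermal optima (cool, temperate, warm) sampled at 1500/900/400 points.

    Returns
    -------
    (layers, regions, occs) : (list[EnvLayer], list[Ecoregion], OccurrenceSet)
        ``occs`` concatenates all species' records.
    """
    layers = [
        make_synthetic_layer(DEFAULT_GEOREF, fs, land_fraction=DEFAULT_LAND_FRACTION,
                             seed=seed * 1000 + i, variable_code=code, units=units)
        for i, (code, units, fs) in enumerate(DEFAULT_LAYERS)
    ]
    regions = make_synthetic_ecoregions(DEFAULT_GEOREF, DEFAULT_N_REGIONS)
    sets = []
    for j, (name, genus, niche, n) in enumerate(DEFAULT_SPECIES):
        spec = NicheSpec(species_name=name, niche=niche, n_points=n,
                         seed=seed * 100 + j, genus=genus)
        sets.append(make_synthetic_occurrences(spec, layers))
    records = pd.concat([s.records for s in sets], ignore_index=True)
    occs = OccurrenceSet(records=records, provenance=f"default synthetic world seed={seed}")
    return layers, regions, occs
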