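"""Georeferenced environmental grids: data model, file IO, and point extraction.

A grid is a north-up array of cell values in geographic (WGS84) coordinates.
The cell-membership convention used throughout the package is half-open:
cell ``(r, c)`` covers longitudes ``[west + c*dx, west + (c+1)*dx)`` and
latitudes ``(north - (r+1)*dy, north - r*dy]``, with row 0 northmost.  A
point on the grid's north edge is inside row 0; a point on the south or
east edge is outside the grid.

Supported on-disk formats are the ESRI ASCII grid (``.asc``, square cells
only) and single-band GeoTIFF (via :mod:`tifffile`, using the
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import FormatError, InputError

__all__ = [
    "GridGeoref",
    "EnvLayer",
    "read_env_layer",
    "write_env_layer",
    "extract_at_points",
    "drop_land_points",
]

#: Default nodata sentinel for files that do not declare one.
DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes used for minimal georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridGeoref:
    """Affine georeferencing of a north-up geographic grid.

    Parameters
    ----------
    west, north
        Coordinates (degrees) of the grid's north-west corner.
    dx, dy
        Cell width and height in degrees (both positive).
    n_rows, n_cols
        Grid shape; row 0 is the northmost row.
    """

    west: float
    north: float
    dx: float
    dy: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("dx and dy must be positive")
        if not (self.n_rows >= 1 and self.n_cols >= 1):
            raise ValueError("n_rows and n_cols must be >= 1")

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.dx

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.dx

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.n_rows) + 0.5) * self.dy

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell ``(r, c)``."""
        return (
            self.north - (r + 0.5) * self.dy,
            self.west + (c + 0.5) * self.dx,
        )

    def rowcol(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Containing row/col indices for point arrays; -1 where outside.

        Implements the half-open convention: the north edge belongs to row 0,
        the west edge to column 0; south and east edges fall outside.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        r = np.floor((self.north - lat) / self.dy).astype(np.int64)
        c = np.floor((lon - self.west) / self.dx).astype(np.int64)
        inside = (r >= 0) & (r < self.n_rows) & (c >= 0) & (c < self.n_cols)
        return np.where(inside, r, -1), np.where(inside, c, -1)


@dataclass
class EnvLayer:
    """One environmental variable on one grid.

    ``values`` has shape ``georef.shape``; cells with no valid measurement
    (land, out of domain) hold the ``nodata`` sentinel.  Every stored value
    is either finite or equal to ``nodata``.
    """

    variable_code: str
    units: str
    georef: GridGeoref
    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.georef.shape:
            raise ValueError(
                f"values shape {self.values.shape} != georef shape {self.georef.shape}"
            )
        bad = ~np.isfinite(self.values) & ~self._nodata_mask(self.values)
        if bad.any():
            raise ValueError("layer contains non-finite values that are not the nodata sentinel")

    def _nodata_mask(self, arr: np.ndarray) -> np.ndarray:
        if math.isnan(self.nodata):
            return np.isnan(arr)
        return arr == self.nodata

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self._nodata_mask(self.values)

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def with_values(self, values: np.ndarray, **kw) -> "EnvLayer":
        return replace(self, values=values, **kw)


def _normalize_lon(lon: np.ndarray) -> np.ndarray:
    """Wrap longitudes into [-180, 180); +180 maps to -180."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    # keep already-in-range values untouched to avoid fp drift from the modulo
    in_range = (lon >= -180.0) & (lon < 180.0)
    return np.where(in_range, lon, out)


def extract_at_points(layer: EnvLayer, points) -> np.ndarray:
    """Sample a layer at (lat, lon) points by containing-cell lookup.

    Parameters
    ----------
    layer
        The grid to sample.
    points
        Sequence or array of ``(latitude, longitude)`` pairs.

    Returns
    -------
    numpy.ndarray
        Float array aligned with the input order; NaN where the point falls
        outside the grid or in a nodata cell.  No interpolation is done:
        the value is that of the unique cell containing the point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return np.empty(0, dtype=float)
    lat, lon = pts[:, 0], _normalize_lon(pts[:, 1])
    r, c = layer.georef.rowcol(lat, lon)
    out = np.full(len(pts), np.nan)
    inside = r >= 0
    vals = layer.values[r[inside], c[inside]]
    nod = layer._nodata_mask(vals)
    vals = np.where(nod, np.nan, vals)
    out[inside] = vals
    return out


def drop_land_points(occs, reference: EnvLayer):
    """Remove occurrences that fall on nodata cells of a reference ocean layer.

    The reference layer's nodata cells are interpreted as land or
    out-of-domain.  Dropped records are appended to the rejection log with
    reason ``land_or_out_of_domain``.  Idempotent.
    """
    # imported here to avoid a module cycle (occurrences has no grid deps)
    from .occurrences import OccurrenceSet

    df = occs.records
    if len(df) == 0:
        return occs
    vals = extract_at_points(reference, df[["latitude", "longitude"]].to_numpy())
    keep = ~np.isnan(vals)
    dropped = df.loc[~keep]
    rejections = occs.rejections.copy()
    if len(dropped):
        import pandas as pd

        new = pd.DataFrame(
            {
                "row_number": dropped.index.to_numpy(),
                "reason_code": "land_or_out_of_domain",
                "raw_line": [
                    f"{r.species},{r.latitude},{r.longitude}" for r in dropped.itertuples()
                ],
            }
        )
        rejections = pd.concat([rejections, new], ignore_index=True)
    return OccurrenceSet(
        records=df.loc[keep].reset_index(drop=True),
        rejections=rejections,
        provenance=occs.provenance,
    )


# ---------------------------------------------------------------------------
# File IO


def read_env_layer(path, variable_code: str, units: str, *, nodata: float | None = None) -> EnvLayer:
    """Read a single-band georeferenced grid (ESRI ASCII or GeoTIFF).

    ``nodata`` overrides/provides the sentinel for files that do not declare
    one.  Multi-band or non-georeferenced files raise :class:`FormatError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in {".asc", ".agr", ".grd"}:
        return _read_ascii_grid(path, variable_code, units, nodata)
    if ext in {".tif", ".tiff"}:
        return _read_geotiff(path, variable_code, units, nodata)
    raise FormatError(f"unrecognised raster extension: {path}")


def write_env_layer(layer: EnvLayer, path) -> None:
    """Write a layer as ESRI ASCII grid (.asc) or GeoTIFF (.tif/.tiff)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in {".asc", ".agr", ".grd"}:
        _write_ascii_grid(layer, path)
    elif ext in {".tif", ".tiff"}:
        _write_geotiff(layer, path)
    else:
        raise FormatError(f"unrecognised raster extension: {path}")


def _read_ascii_grid(path, variable_code, units, nodata_override) -> EnvLayer:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
            "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    else:
        data_start = len(lines)
    required = {"ncols", "nrows", "cellsize"}
    if not required <= set(header) or not (
        {"xllcorner", "yllcorner"} <= set(header) or {"xllcenter", "yllcenter"} <= set(header)
    ):
        raise FormatError(f"missing georeferencing header in {path}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        west, south = header["xllcorner"], header["yllcorner"]
    else:
        west = header["xllcenter"] - cell / 2
        south = header["yllcenter"] - cell / 2
    nodata = header.get("nodata_value")
    if nodata is None:
        nodata = DEFAULT_NODATA if nodata_override is None else nodata_override
    elif nodata_override is not None:
        nodata = nodata_override
    values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path}: data block shape {values.shape} != header ({n_rows}, {n_cols})"
        )
    georef = GridGeoref(west=west, north=south + n_rows * cell, dx=cell, dy=cell,
                        n_rows=n_rows, n_cols=n_cols)
    return EnvLayer(variable_code, units, georef, values, nodata=nodata,
                    provenance={"path": path, "format": "esri_ascii"})


def _write_ascii_grid(layer: EnvLayer, path) -> None:
    g = layer.georef
    if not math.isclose(g.dx, g.dy, rel_tol=1e-12):
        raise FormatError("ESRI ASCII grids require square cells (dx == dy); write GeoTIFF instead")
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {float(g.west)!r}\n")
        fh.write(f"yllcorner {float(g.south)!r}\n")
        fh.write(f"cellsize {float(g.dx)!r}\n")
        fh.write(f"NODATA_value {float(layer.nodata)!r}\n")
        for row in layer.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path, variable_code, units, nodata_override) -> EnvLayer:
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise FormatError(f"{path}: expected a single-band raster")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise FormatError(f"{path}: expected a single-band raster")
        scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
        dx, dy = float(scale.value[0]), float(scale.value[1])
        # tiepoint maps raster (i, j) -> model (x, y); we require the NW corner
        i, j, _, x, y, _ = (float(v) for v in tiepoint.value[:6])
        west = x - i * dx
        north = y + j * dy
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        values = page.asarray().astype(float)
    if nodata_override is not None:
        nodata = nodata_override
    elif nodata_tag is not None:
        nodata = float(str(nodata_tag.value).strip("\x00 "))
    else:
        nodata = DEFAULT_NODATA
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single-band raster")
    # NaN-coded nodata in the file is mapped onto the sentinel
    if not math.isnan(nodata):
        values = np.where(np.isnan(values), nodata, values)
    n_rows, n_cols = values.shape
    georef = GridGeoref(west=west, north=north, dx=dx, dy=dy, n_rows=n_rows, n_cols=n_cols)
    return EnvLayer(variable_code, units, georef, values, nodata=nodata,
                    provenance={"path": path, "format": "geotiff"})


def _write_geotiff(layer: EnvLayer, path) -> None:
    g = layer.georef
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.dx, g.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.west, g.north, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(layer.nodata)),
    ]
    tifffile.imwrite(path, layer.values.astype(np.float64), extratags=extratags)
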