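"""Marine-ecoregion polygons and occurrence-to-ecoregion assignment.

Ecoregions follow the Marine Ecoregions of the World (MEOW) schema: an
integer id, a name, and a (multi)polygon in WGS84.  Input is GeoJSON; the
loader repairs invalid geometries by zero-width buffering and flags them.

Assignment is containment-based (a point on a boundary shared by two
regions goes to the smaller ``eco_id``), with an optional snap tolerance for
coastal points sitting just outside every polygon.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape
from shapely.strtree import STRtree

from .errors import InputError, SchemaError
from .occurrences import OccurrenceSet

__all__ = ["Ecoregion", "load_ecoregions", "write_ecoregions", "assign_ecoregions"]

log = logging.getLogger(__name__)

# Field names tried in order when the caller does not specify them; the
# first pair covers this package's own output, the rest the MEOW shapefile
# attribute table as commonly distributed in GeoJSON form.
_ID_FIELDS = ("eco_id", "ECO_CODE", "ECO_CODE_X", "ECOID")
_NAME_FIELDS = ("name", "ECOREGION", "eco_name")


@dataclass
class Ecoregion:
    """One named polygonal summarization stratum."""

    eco_id: int
    name: str
    geometry: shapely.Geometry
    repaired: bool = False


def _pick_field(props: dict, requested: str | None, candidates: tuple[str, ...], what: str) -> str:
    if requested is not None:
        if requested not in props:
            raise SchemaError(f"{what} field {requested!r} absent from feature properties")
        return requested
    for cand in candidates:
        if cand in props:
            return cand
    raise SchemaError(f"no {what} field found; tried {candidates}")


def load_ecoregions(path, *, id_field: str | None = None,
                    name_field: str | None = None) -> list[Ecoregion]:
    """Load ecoregion polygons from a GeoJSON FeatureCollection.

    Invalid geometries are repaired by zero-width buffering and flagged via
    ``Ecoregion.repaired`` (and a warning log).  Duplicate ids raise
    :class:`SchemaError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    regions: list[Ecoregion] = []
    seen: set[int] = set()
    for feat in features:
        props = feat.get("properties", {})
        idf = _pick_field(props, id_field, _ID_FIELDS, "id")
        namef = _pick_field(props, name_field, _NAME_FIELDS, "name")
        eco_id = int(props[idf])
        if eco_id in seen:
            raise SchemaError(f"duplicate eco_id {eco_id} in {path}")
        seen.add(eco_id)
        geom = shape(feat["geometry"])
        repaired = False
        if not geom.is_valid:
            geom = geom.buffer(0)
            repaired = True
            log.warning("ecoregion %s (%s): invalid geometry repaired by zero-width buffer",
                        eco_id, props[namef])
        regions.append(Ecoregion(eco_id=eco_id, name=str(props[namef]),
                                 geometry=geom, repaired=repaired))
    return regions


def write_ecoregions(regions: list[Ecoregion], path) -> None:
    """Write ecoregions as a GeoJSON FeatureCollection (eco_id + name)."""
    features = [
        {
            "type": "Feature",
            "properties": {"eco_id": r.eco_id, "name": r.name},
            "geometry": json.loads(shapely.to_geojson(r.geometry)),
        }
        for r in regions
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def assign_ecoregions(occs: OccurrenceSet, regions: list[Ecoregion],
                      snap_tolerance: float = 0.0) -> OccurrenceSet:
    """Label each record with the ecoregion containing it.

    A record gets the ``eco_id``/``eco_name`` of the region covering its
    point (boundary points count as covered; ties on shared boundaries go to
    the smaller ``eco_id``).  If no region covers the point and
    ``snap_tolerance > 0``, the nearest region within that many degrees is
    used instead.  Otherwise the record is left unassigned (``eco_id`` NA)
    and logged; unassigned records are excluded from downstream summaries.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    df = occs.records.copy()
    n = len(df)
    eco_id = np.full(n, -1, dtype=np.int64)
    if n:
        pts = shapely.points(df["longitude"].to_numpy(), df["latitude"].to_numpy())
        order = sorted(range(len(regions)), key=lambda i: regions[i].eco_id)
        geoms = [regions[i].geometry for i in order]
        ids = np.array([regions[i].eco_id for i in order], dtype=np.int64)
        tree = STRtree(geoms)
        # for points, intersects == covered-by (boundary points included);
        # taking the min eco_id over hits implements the tie-break
        cand_pt, cand_geom = tree.query(pts, predicate="intersects")
        for p, g in zip(cand_pt, cand_geom):
            if eco_id[p] == -1 or ids[g] < eco_id[p]:
                eco_id[p] = ids[g]
        if snap_tolerance > 0:
            unassigned = np.flatnonzero(eco_id == -1)
            if len(unassigned):
                near_pt, near_geom = tree.query(
                    pts[unassigned], predicate="dwithin", distance=snap_tolerance)
                dists = shapely.distance(pts[unassigned][near_pt],
                                         np.array(geoms, dtype=object)[near_geom])
                best: dict[int, tuple[float, int]] = {}
                for p, g, d in zip(near_pt, near_geom, dists):
                    key = (d, ids[g])
                    if p not in best or key < best[p]:
                        best[p] = key
                for p, (_, gid) in best.items():
                    eco_id[unassigned[p]] = gid
    names = {r.eco_id: r.name for r in regions}
    df["eco_id"] = pd.array([i if i >= 0 else pd.NA for i in eco_id], dtype="Int64")
    df["eco_name"] = [names.get(i) for i in eco_id]
    rejections = occs.rejections
    n_unassigned = int((eco_id == -1).sum())
    if n_unassigned:
        dropped = df.loc[eco_id == -1]
        new = pd.DataFrame({
            "row_number": dropped.index.to_numpy(),
            "reason_code": "unassigned_ecoregion",
            "raw_line": dropped["species"] + "|" + dropped["latitude"].astype(str)
            + "|" + dropped["longitude"].astype(str),
        })
        rejections = pd.concat([rejections, new], ignore_index=True)
        log.info("%d records outside all ecoregions left unassigned", n_unassigned)
    return OccurrenceSet(records=df, rejections=rejections, provenance=occs.provenance)
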