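"""Occurrence-record ingestion, validation, and taxonomic filtering.

Records follow the Darwin-Core-style columns of a GBIF simple download
(``species``, ``genus``, ``order``, ``decimalLatitude``, ``decimalLongitude``,
``year``).  Reading never silently drops a row: every rejected row lands in
the rejection log with a reason code, so
``records_out + rejections == rows_in`` always holds.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import pandas as pd

from .errors import InputError, SchemaError

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "read_occurrences",
    "write_occurrences",
    "filter_taxon",
    "DEFAULT_COLUMN_MAP",
]

#: Semantic field -> column name, matching GBIF simple-download headers.
DEFAULT_COLUMN_MAP = {
    "species": "species",
    "genus": "genus",
    "order": "order",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "year": "year",
}

RECORD_COLUMNS = ["species", "genus", "order", "latitude", "longitude", "event_year", "source_id"]
REJECTION_COLUMNS = ["row_number", "reason_code", "raw_line"]


@dataclass(frozen=True)
class OccurrenceRecord:
    """One cleaned species observation (WGS84 point + provenance)."""

    species: str
    genus: str
    order: str
    latitude: float
    longitude: float
    event_year: int | None = None
    source_id: str = ""


@dataclass
class OccurrenceSet:
    """Cleaned occurrence records plus the rejection log and provenance.

    ``records`` is a DataFrame with columns :data:`RECORD_COLUMNS`;
    ``rejections`` has columns :data:`REJECTION_COLUMNS`.  When the set has
    been run through ecoregion assignment, ``records`` additionally carries
    ``eco_id`` / ``eco_name`` columns.
    """

    records: pd.DataFrame
    rejections: pd.DataFrame = None  # type: ignore[assignment]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.rejections is None:
            self.rejections = pd.DataFrame(columns=REJECTION_COLUMNS)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        for row in self.records.itertuples(index=False):
            yield OccurrenceRecord(
                species=row.species, genus=row.genus, order=row.order,
                latitude=row.latitude, longitude=row.longitude,
                event_year=None if pd.isna(row.event_year) else int(row.event_year),
                source_id=row.source_id,
            )


def _sniff_delimiter(header_line: str) -> str:
    """Comma vs tab, decided from the header line."""
    return "\t" if header_line.count("\t") > header_line.count(",") else ","


def read_occurrences(path, column_map: dict | None = None, *,
                     drop_exact_duplicates: bool = False) -> OccurrenceSet:
    """Read a delimited occurrence file into a validated :class:`OccurrenceSet`.

    Parameters
    ----------
    path
        Delimited text (comma or tab, autodetected from the header), UTF-8,
        with a header row.
    column_map
        Mapping of semantic field (``species``, ``genus``, ``order``,
        ``latitude``, ``longitude``, ``year``) to column name; defaults to
        GBIF simple-download names.
    drop_exact_duplicates
        If True, rows identical in species/latitude/longitude/year after the
        first are rejected with reason ``exact_duplicate``.  Off by default:
        envelope statistics are defined over raw observations.

    Rows that cannot be parsed are routed to the rejection log with a reason
    code (``coordinate_unparseable``, ``coordinate_out_of_range``,
    ``missing_species``, ``field_count_mismatch``), never silently dropped.
    A missing or unparseable year is not a rejection; year is provenance only.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise InputError(f"empty file: {path}")
        delim = _sniff_delimiter(header_line)
        header = next(csv.reader([header_line], delimiter=delim))
        col_idx: dict[str, int] = {}
        # the semantic name itself is accepted as a fallback so files the
        # package writes with internal column names re-read cleanly
        for fieldname in ("species", "latitude", "longitude"):
            col = cmap[fieldname]
            if col in header:
                col_idx[fieldname] = header.index(col)
            elif fieldname in header:
                col_idx[fieldname] = header.index(fieldname)
            else:
                raise SchemaError(f"mapped column {col!r} for {fieldname!r} absent from header")
        for fieldname, fallback in (("genus", None), ("order", None), ("year", "event_year")):
            col = cmap.get(fieldname)
            if col is not None and col in header:
                col_idx[fieldname] = header.index(col)
            elif fallback is not None and fallback in header:
                col_idx[fieldname] = header.index(fallback)

        records: list[tuple] = []
        rejections: list[tuple] = []
        seen: set[tuple] = set()
        for row_number, line in enumerate(fh, start=2):
            raw = line.rstrip("\n")
            if not raw.strip():
                continue
            fields = next(csv.reader([raw], delimiter=delim))
            if len(fields) < len(header):
                rejections.append((row_number, "field_count_mismatch", raw))
                continue
            species = fields[col_idx["species"]].strip()
            if not species:
                rejections.append((row_number, "missing_species", raw))
                continue
            try:
                lat = float(fields[col_idx["latitude"]])
                lon = float(fields[col_idx["longitude"]])
            except ValueError:
                rejections.append((row_number, "coordinate_unparseable", raw))
                continue
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                rejections.append((row_number, "coordinate_out_of_range", raw))
                continue
            year: float | None = None
            if "year" in col_idx:
                try:
                    year = int(float(fields[col_idx["year"]]))
                except ValueError:
                    year = None
            if drop_exact_duplicates:
                key = (species, lat, lon, year)
                if key in seen:
                    rejections.append((row_number, "exact_duplicate", raw))
                    continue
                seen.add(key)
            genus = fields[col_idx["genus"]].strip() if "genus" in col_idx else ""
            order = fields[col_idx["order"]].strip() if "order" in col_idx else ""
            records.append((species, genus, order, lat, lon, year, f"{path}:{row_number}"))

    rec_df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    rej_df = pd.DataFrame(rejections, columns=REJECTION_COLUMNS)
    return OccurrenceSet(records=rec_df, rejections=rej_df, provenance=path)


def occurrences_from_frame(df: pd.DataFrame, provenance: str = "") -> OccurrenceSet:
    """Build an OccurrenceSet from an already-clean DataFrame.

    Accepts either the GBIF column names or the package's internal ones and
    keeps ``eco_id``/``eco_name`` labels when present — the entry point for
    re-reading intermediate stage files without re-validating them.
    """
    df = df.rename(columns={
        "decimalLatitude": "latitude",
        "decimalLongitude": "longitude",
        "year": "event_year",
    }).copy()
    for col in ("species", "latitude", "longitude"):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} absent from frame")
    for col, default in (("genus", ""), ("order", ""), ("event_year", pd.NA),
                         ("source_id", "")):
        if col not in df.columns:
            df[col] = default
    extra = [c for c in ("eco_id", "eco_name") if c in df.columns]
    if "eco_id" in extra:
        df["eco_id"] = df["eco_id"].astype("Int64")
    return OccurrenceSet(records=df[RECORD_COLUMNS + extra], provenance=provenance)


def write_occurrences(occs: OccurrenceSet, path, *, delimiter: str = ",") -> None:
    """Export records as delimited text re-readable by :func:`read_occurrences`."""
    df = occs.records.rename(columns={
        "latitude": "decimalLatitude",
        "longitude": "decimalLongitude",
        "event_year": "year",
    })
    df.to_csv(path, sep=delimiter, index=False)


def write_rejections(occs: OccurrenceSet, path, *, delimiter: str = ",") -> None:
    """Write the rejection log (row_number, reason_code, raw_line)."""
    occs.rejections.to_csv(path, sep=delimiter, index=False)


def filter_taxon(occs: OccurrenceSet, order_name: str) -> OccurrenceSet:
    """Keep only records whose order equals ``order_name`` (case-insensitive).

    Idempotent; dropped records are logged with reason ``taxon_filtered``.
    """
    df = occs.records
    keep = df["order"].str.strip().str.casefold() == order_name.strip().casefold()
    dropped = df.loc[~keep]
    rejections = occs.rejections
    if len(dropped):
        new = pd.DataFrame({
            "row_number": dropped.index.to_numpy(),
            "reason_code": "taxon_filtered",
            "raw_line": dropped["species"] + "|" + dropped["order"],
        })
        rejections = pd.concat([rejections, new], ignore_index=True)
    return OccurrenceSet(records=df.loc[keep].reset_index(drop=True),
                         rejections=rejections, provenance=occs.provenance)
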