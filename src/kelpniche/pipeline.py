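"""End-to-end pipeline driver, configuration, and diagnostic reports.

``run_pipeline`` chains the stages: read -> taxon filter -> land removal ->
extraction -> ecoregion assignment -> minimum-observation filter -> envelope
summary -> optional suitability map + zonal ranking.  Every stage's
input/output counts are logged and returned, so record bookkeeping is
conservative at each step; identical config + seed reproduces bit-identical
tabular outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecoregions import assign_ecoregions, load_ecoregions
from .envelope import filter_min_observations, pair_counts, summarize_niche
from .errors import ConfigurationError, KelpNicheError
from .grids import drop_land_points, extract_at_points, read_env_layer, write_env_layer
from .occurrences import filter_taxon, read_occurrences, write_occurrences, write_rejections
from .suitability import recipe_from_summary, reclassify_band, stack_score, zonal_stats

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "LayerSpec", "SuitabilitySpec", "run_pipeline",
           "report_record_distribution", "extract_all_layers"]


@dataclass(frozen=True)
class LayerSpec:
    path: str
    variable_code: str
    units: str = ""


@dataclass(frozen=True)
class SuitabilitySpec:
    """Which envelope row drives the suitability map, and how."""

    species: str
    eco_id: int
    mode: str = "iqr"                       # iqr | range | graded
    weights: dict = field(default_factory=dict)  # variable_code -> weight, default 1
    nodata_policy: str = "strict"


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    All randomness in a run flows from ``seed``; paths must be distinct.
    """

    occurrences: str
    layers: list[LayerSpec]
    ecoregions: str
    out_dir: str
    order_name: str = "Laminariales"
    min_observations: int = 10
    snap_tolerance: float = 0.0
    land_reference: str | None = None       # variable_code of the ocean mask layer
    suitability: SuitabilitySpec | None = None
    drop_exact_duplicates: bool = False
    top_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_observations < 0:
            raise ConfigurationError("min_observations must be >= 0")
        if self.suitability and any(w < 0 for w in self.suitability.weights.values()):
            raise ConfigurationError("weights must be non-negative")
        paths = [self.occurrences, self.ecoregions] + [l.path for l in self.layers]
        if len(set(paths)) != len(paths):
            raise ConfigurationError("input paths must be distinct")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        layers = [LayerSpec(**l) for l in raw.pop("layers")]
        suit = raw.pop("suitability", None)
        if suit is not None:
            suit = SuitabilitySpec(**suit)
        return cls(layers=layers, suitability=suit, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        if raw["suitability"] is None:
            raw.pop("suitability")
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def extract_all_layers(occs, layers) -> pd.DataFrame:
    """Long-format extraction table: one row per (record, variable).

    Each variable is extracted independently at native resolution; a point
    in a nodata cell of one layer yields NaN for that variable only.
    """
    df = occs.records
    pts = df[["latitude", "longitude"]].to_numpy()
    frames = []
    for layer in layers:
        vals = extract_at_points(layer, pts)
        frame = df[["species", "genus"]].copy()
        if "eco_id" in df.columns:
            frame["eco_id"] = df["eco_id"]
            frame["eco_name"] = df["eco_name"]
        frame["variable_code"] = layer.variable_code
        frame["units"] = layer.units
        frame["value"] = vals
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def report_record_distribution(labelled_records: pd.DataFrame, k: int = 1):
    """Per-ecoregion and per-genus record counts, plus the top-k share.

    Returns ``(per_ecoregion, per_genus, top_k_share_pct)``.  Count tables
    carry a log10(count) column (matching how heavily skewed occurrence
    data is usually displayed); the share is the percentage of all records
    held by the k most record-rich ecoregions.
    """
    if len(labelled_records) == 0:
        empty_eco = pd.DataFrame(columns=["eco_id", "eco_name", "n_records", "log10_n"])
        empty_gen = pd.DataFrame(columns=["genus", "n_records", "log10_n"])
        return empty_eco, empty_gen, float("nan")
    df = labelled_records
    per_eco = (df.dropna(subset=["eco_id"])
               .groupby(["eco_id", "eco_name"], dropna=False).size()
               .rename("n_records").reset_index()
               .sort_values(["n_records", "eco_id"], ascending=[False, True])
               .reset_index(drop=True))
    per_eco["log10_n"] = np.log10(per_eco["n_records"].astype(float))
    per_gen = (df.groupby("genus").size().rename("n_records").reset_index()
               .sort_values(["n_records", "genus"], ascending=[False, True])
               .reset_index(drop=True))
    per_gen["log10_n"] = np.log10(per_gen["n_records"].astype(float))
    total = per_eco["n_records"].sum()
    top_share = float(per_eco["n_records"].head(k).sum() / total * 100.0) if total else float("nan")
    return per_eco, per_gen, top_share


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a run summary.

    The summary maps stage names to record counts and ``outputs`` to the
    files written under ``config.out_dir``:

    - ``occurrences_clean.csv`` / ``rejections.csv``
    - ``labelled_occurrences.csv`` (with eco_id/eco_name)
    - ``extractions.csv`` (long format, one row per record x variable)
    - ``niche_summary.csv`` + ``niche_summary.meta.json`` sidecar
    - ``report_by_ecoregion.csv`` / ``report_by_genus.csv``
    - ``suitability.tif`` + ``zonal_ranking.csv`` when configured

    Any stage error aborts the run and removes partial outputs.
    """
    t0 = time.monotonic()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    written: list[str] = []
    counts: dict[str, int] = {}

    def emit(name, writer):
        path = os.path.join(out, name)
        writer(path)
        written.append(path)

    try:
        occs = read_occurrences(config.occurrences,
                                drop_exact_duplicates=config.drop_exact_duplicates)
        counts["rows_read"] = len(occs) + len(occs.rejections)
        counts["records_valid"] = len(occs)
        if len(occs) == 0:
            log.warning("no parseable occurrence rows in %s", config.occurrences)
        occs = filter_taxon(occs, config.order_name)
        counts["records_in_taxon"] = len(occs)

        layers = [read_env_layer(l.path, l.variable_code, l.units) for l in config.layers]
        by_code = {l.variable_code: l for l in layers}
        ref_code = config.land_reference or config.layers[0].variable_code
        if ref_code not in by_code:
            raise ConfigurationError(f"land_reference {ref_code!r} not among layer codes")
        occs = drop_land_points(occs, by_code[ref_code])
        counts["records_in_ocean"] = len(occs)

        regions = load_ecoregions(config.ecoregions)
        occs = assign_ecoregions(occs, regions, snap_tolerance=config.snap_tolerance)
        counts["records_assigned"] = int(occs.records["eco_id"].notna().sum())

        extractions = extract_all_layers(occs, layers)
        summary = summarize_niche(extractions)
        basis = pair_counts(occs.records)
        counts["species_ecoregion_pairs"] = int(len(basis))
        summary = filter_min_observations(summary, config.min_observations, basis)
        surviving = summary[["species", "eco_id"]].drop_duplicates()
        counts["pairs_surviving_filter"] = int(len(surviving))
        counts["summary_rows"] = int(len(summary))
        if len(summary) == 0:
            log.warning("no species-ecoregion pair exceeds %d observations",
                        config.min_observations)

        emit("occurrences_clean.csv", lambda p: write_occurrences(occs, p))
        emit("rejections.csv", lambda p: write_rejections(occs, p))
        emit("labelled_occurrences.csv", lambda p: _write_csv(occs.records, p))
        emit("extractions.csv", lambda p: _write_csv(extractions, p))
        emit("niche_summary.csv", lambda p: _write_csv(summary, p))
        meta = {
            "tool": f"kelpniche {__version__}",
            "occurrence_source": config.occurrences,
            "layers": [dataclasses.asdict(l) for l in config.layers],
            "ecoregions": config.ecoregions,
            "order_filter": config.order_name,
            "min_observations_strictly_greater_than": config.min_observations,
            "snap_tolerance_deg": config.snap_tolerance,
            "seed": config.seed,
        }
        emit("niche_summary.meta.json",
             lambda p: open(p, "w").write(json.dumps(meta, indent=2)))

        per_eco, per_gen, top_share = report_record_distribution(occs.records, k=config.top_k)
        counts["top_k_share_pct"] = top_share
        emit("report_by_ecoregion.csv", lambda p: _write_csv(per_eco, p))
        emit("report_by_genus.csv", lambda p: _write_csv(per_gen, p))

        if config.suitability is not None:
            spec = config.suitability
            rows = summary[(summary["species"] == spec.species)
                           & (summary["eco_id"] == spec.eco_id)]
            if len(rows) == 0:
                raise ConfigurationError(
                    f"no envelope rows for {spec.species!r} in ecoregion {spec.eco_id}")
            binary, weights, recipes = [], [], []
            for _, row in rows.iterrows():
                if row["variable_code"] not in by_code:
                    continue
                w = float(spec.weights.get(row["variable_code"], 1.0))
                recipe = recipe_from_summary(row, mode=spec.mode, weight=1.0)
                binary.append(reclassify_band(by_code[row["variable_code"]], recipe))
                weights.append(w)
                recipes.append(dataclasses.replace(recipe, weight=w))
            smap = stack_score(binary, weights, nodata_policy=spec.nodata_policy)
            smap.recipes = recipes
            zonal = zonal_stats(smap, regions)
            emit("suitability.tif", lambda p: write_env_layer(smap.as_layer(), p))
            emit("zonal_ranking.csv", lambda p: _write_csv(zonal, p))
    except Exception as exc:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        stage = counts and list(counts)[-1] or "read"
        raise KelpNicheError(f"pipeline aborted after stage {stage!r}: {exc}") from exc

    counts["elapsed_s"] = round(time.monotonic() - t0, 3)
    for k, v in counts.items():
        log.info("pipeline %s = %s", k, v)
    return {"counts": counts, "outputs": written}
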