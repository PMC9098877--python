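"""End-to-end pipeline: simulate -> reconcile -> clean -> grid -> regions.

A single structured configuration (JSON) drives the whole analysis; every
stage writes its outputs under the run directory and the run closes with
a machine-readable manifest (package version, seed, input hashes,
per-stage counts, output hashes). Reruns with the same seed and inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd
from shapely.geometry import Point

from . import io as eio
from . import __version__
from .checklist import (
    flag_nus,
    reconcile_names,
    summarize_catalogue,
)
from .cleaning import FilterConfig, clean_pipeline
from .grid import GridSpec, compute_grid_metrics, metrics_to_geojson
from .io import ConfigError, DataError
from .regions import (
    breadth_distribution,
    richness_records_regression,
    summarize_regions,
)
from .synthetic import ScenarioConfig, simulate_scenario


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_scenario(artifacts: dict, answer_key, out_dir) -> dict:
    """Emit a simulated scenario as plain files; returns the path map."""
    out_dir = Path(out_dir)
    geo_dir = out_dir / "geometry"
    geo_dir.mkdir(parents=True, exist_ok=True)
    geometry = artifacts["geometry"]
    grid: GridSpec = artifacts["grid"]

    paths = {
        "checklist": out_dir / "checklist.csv",
        "backbone": out_dir / "backbone.csv",
        "crops": out_dir / "crops.csv",
        "occurrences": out_dir / "occurrences.csv",
        "land": geo_dir / "land.geojson",
        "urban": geo_dir / "urban.geojson",
        "institutions": geo_dir / "institutions.geojson",
        "departments": geo_dir / "departments.geojson",
        "bioregions": geo_dir / "bioregions.geojson",
        "answer_key": out_dir / "answer_key.json",
    }
    eio.write_checklist(artifacts["entries"], paths["checklist"])
    eio.write_backbone(artifacts["backbone"], paths["backbone"])
    eio.write_crops(artifacts["crops"], paths["crops"])
    eio.write_occurrences(artifacts["records"], paths["occurrences"])
    eio.write_single_geometry(geometry.land, paths["land"], name="land")
    eio.write_single_geometry(geometry.urban, paths["urban"], name="urban")
    eio.write_geojson(
        eio.geometry_to_feature_collection(
            [
                ({"name": f"institution_{k}"}, Point(p))
                for k, p in enumerate(geometry.institutions)
            ]
        ),
        paths["institutions"],
    )
    eio.write_region_set(geometry.departments, paths["departments"])
    eio.write_region_set(geometry.bioregions, paths["bioregions"])
    eio.write_json(answer_key.to_json_dict(), paths["answer_key"])

    config = {
        "paths": {k: str(v) for k, v in paths.items() if k != "answer_key"},
        "filters": {
            "min_decimals": 3,
            "centroid": list(geometry.centroid),
            "centroid_radius_km": 5.0,
            "institution_buffer_m": 100.0,
        },
        "grid": {"cell_size": grid.cell_size, "extent": list(grid.extent)},
    }
    eio.write_json(config, out_dir / "pipeline_config.json")
    paths["pipeline_config"] = out_dir / "pipeline_config.json"
    return {k: str(v) for k, v in paths.items()}


def load_filter_config(config: dict) -> FilterConfig:
    paths = config.get("paths", {})
    filters = config.get("filters", {})
    try:
        land = eio.read_single_geometry(paths["land"]) if "land" in paths else None
        urban = eio.read_single_geometry(paths["urban"]) if "urban" in paths else None
        institutions = (
            eio.read_points(paths["institutions"]) if "institutions" in paths else ()
        )
    except FileNotFoundError as exc:
        raise ConfigError(f"geometry file missing: {exc}") from exc
    centroid = filters.get("centroid")
    fc = FilterConfig(
        min_decimals=int(filters.get("min_decimals", 3)),
        centroid=tuple(centroid) if centroid else None,
        centroid_radius_km=float(filters.get("centroid_radius_km", 5.0)),
        institution_points=institutions,
        institution_buffer_m=float(filters.get("institution_buffer_m", 100.0)),
        urban_polygons=urban,
        land_polygon=land,
    )
    try:
        fc.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return fc


def run_all(config: dict, out_dir, seed: Optional[int] = None) -> dict:
    """Execute every stage in order and write the run manifest.

    Returns the manifest dict. Raises :class:`ConfigError` (exit code 2)
    for configuration problems and :class:`DataError` (exit code 3) for
    malformed data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "edibleflora",
        "version": __version__,
        "seed": seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        if seed is not None:
            sim_kwargs["seed"] = seed
        try:
            scenario_cfg = ScenarioConfig(**sim_kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad simulate config: {exc}") from exc
        artifacts, _key = simulate_scenario(scenario_cfg)
        paths = write_scenario(artifacts, _key, out_dir / "inputs")
        config = dict(config)
        config.update(eio.read_json(paths["pipeline_config"]))
        manifest["stages"]["simulate"] = {
            "n_species": scenario_cfg.n_species,
            "n_records": len(artifacts["records"]),
        }

    paths = config.get("paths", {})
    for required in ("checklist", "backbone", "crops", "occurrences"):
        if required not in paths:
            raise ConfigError(f"config missing path for {required!r}")
        if not Path(paths[required]).exists():
            raise ConfigError(f"input file not found: {paths[required]}")
    for key in ("land", "urban", "institutions", "departments", "bioregions"):
        if key in paths and not Path(paths[key]).exists():
            raise ConfigError(f"input file not found: {paths[key]}")
    for key, p in paths.items():
        manifest["inputs"][key] = sha256_file(p)

    # --- reconcile ---------------------------------------------------
    entries = eio.read_checklist(paths["checklist"])
    backbone = eio.read_backbone(paths["backbone"])
    crops = eio.read_crops(paths["crops"])
    raw = eio.read_occurrences(paths["occurrences"])
    names = sorted({r.taxon_name for r in raw})
    mapping, unmatched = reconcile_names(names, backbone)
    taxon_map = {name: taxon_id for name, (_, taxon_id) in mapping.items()}
    matched_raw = [r for r in raw if r.taxon_name in taxon_map]
    manifest["stages"]["reconcile"] = {
        "n_names": len(names),
        "n_unmatched_names": len(unmatched),
        "n_records_dropped_unmatched": len(raw) - len(matched_raw),
    }

    # --- catalogue summary -------------------------------------------
    entries = flag_nus(entries, crops)
    summary = summarize_catalogue(entries)
    eio.write_json(summary.to_dict(), out_dir / "catalogue_summary.json")
    pd.DataFrame([summary.to_dict()]).to_csv(
        out_dir / "catalogue_summary.csv", index=False
    )
    manifest["stages"]["summary"] = {"n_species": summary.n_species}

    # --- clean --------------------------------------------------------
    fc = load_filter_config(config)
    cleaned, report = clean_pipeline(matched_raw, fc, taxon_map=taxon_map)
    eio.write_clean_occurrences(cleaned, out_dir / "occurrences_clean.csv")
    eio.write_json(report.to_dict(), out_dir / "cleaning_report.json")
    manifest["stages"]["clean"] = report.to_dict()

    # --- grid ----------------------------------------------------------
    grid_cfg = config.get("grid", {})
    grid = GridSpec(
        cell_size=float(grid_cfg.get("cell_size", 0.1)),
        extent=tuple(grid_cfg["extent"]) if "extent" in grid_cfg else None,
    )
    metrics = compute_grid_metrics(cleaned, grid)
    metrics.to_csv(out_dir / "grid_metrics.csv", index=False)
    eio.write_geojson(metrics_to_geojson(metrics), out_dir / "grid_metrics.geojson")
    manifest["stages"]["grid"] = {
        "n_cells": len(metrics),
        "n_gridded_species": len({c.taxon_id for c in cleaned}),
    }

    # --- regions -------------------------------------------------------
    for kind in ("departments", "bioregions"):
        if kind not in paths:
            continue
        rs = eio.read_region_set(paths[kind])
        summaries = summarize_regions(cleaned, entries, rs)
        summaries.to_csv(out_dir / f"region_summary_{kind}.csv", index=False)
        breadth, headline = breadth_distribution(cleaned, rs)
        breadth.rename("breadth").to_csv(out_dir / f"breadth_{kind}.csv")
        result: dict = {"headline": headline}
        try:
            reg = richness_records_regression(summaries)
            result["regression"] = asdict(reg)
        except ValueError as exc:
            result["regression"] = {"error": str(exc)}
        eio.write_json(result, out_dir / f"regions_{kind}.json")
        manifest["stages"][f"regions_{kind}"] = {
            "n_regions": len(rs.regions),
            "n_unassigned": summaries.attrs.get("__unassigned__", 0),
        }

    for p in sorted(out_dir.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = sha256_file(p)
    eio.write_json(manifest, out_dir / "manifest.json")
    return manifest
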