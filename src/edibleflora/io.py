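"""File readers and writers: Darwin-Core CSV, GeoJSON geometry, reports.

CSV dialect is fixed (comma delimiter, UTF-8, ``.`` decimal separator,
case-sensitive Darwin Core headers). Coordinate columns are read as
verbatim text and parsed alongside, so precision filtering can operate on
what the source actually shipped. GeoJSON is handled with ``json`` plus
``shapely.geometry.shape``/``mapping``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .checklist import BackboneRecord, ChecklistEntry, entries_from_frame, entries_to_frame
from .cleaning import CleanOccurrence, RawOccurrence
from .regions import RegionSet

REQUIRED_OCCURRENCE_COLUMNS = ("scientificName", "decimalLatitude", "decimalLongitude")


class ConfigError(ValueError):
    """Bad configuration or missing/invalid input file (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed data content (CLI exit code 3)."""


def read_occurrences(path) -> list[RawOccurrence]:
    """Read a Darwin-Core-style occurrence CSV, preserving coordinate text.

    Row numbers (1-based, excluding the header) become ``source_id``
    unless an ``occurrenceID`` column is present. A missing required
    column is a hard error naming it; rows that later fail to parse are
    kept (the cleaning pipeline counts them), so no row is lost here.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if len(header) == 1 and ";" in header[0]:
            raise DataError(
                f"{path}: expected comma-delimited CSV, header looks "
                f"semicolon-delimited: {header[0]!r}"
            )
        missing = [c for c in REQUIRED_OCCURRENCE_COLUMNS if c not in header]
        if missing:
            raise DataError(f"{path}: missing required column(s) {missing}")
        records = []
        for idx, row in enumerate(reader, start=1):
            sid = row.get("occurrenceID") or f"row{idx}"
            records.append(
                RawOccurrence.from_text(
                    taxon_name=(row["scientificName"] or "").strip(),
                    lat_text=row["decimalLatitude"],
                    lon_text=row["decimalLongitude"],
                    source_id=sid,
                )
            )
    return records


def write_occurrences(records: Sequence[RawOccurrence], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["occurrenceID", *REQUIRED_OCCURRENCE_COLUMNS])
        for r in records:
            writer.writerow([r.source_id, r.taxon_name, r.lat_text, r.lon_text])


def write_clean_occurrences(records: Sequence[CleanOccurrence], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon_id", "decimalLongitude", "decimalLatitude"])
        for r in records:
            writer.writerow([r.taxon_id, repr(r.lon), repr(r.lat)])


def read_clean_occurrences(path) -> list[CleanOccurrence]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CleanOccurrence(
                    taxon_id=row["taxon_id"],
                    lon=float(row["decimalLongitude"]),
                    lat=float(row["decimalLatitude"]),
                )
            )
    return out


def write_checklist(entries: Sequence[ChecklistEntry], path) -> None:
    entries_to_frame(entries).to_csv(path, index=False)


def read_checklist(path) -> list[ChecklistEntry]:
    import pandas as pd

    return entries_from_frame(pd.read_csv(path))


def write_backbone(records: Sequence[BackboneRecord], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["input_name", "accepted_name", "taxon_id", "match_status"])
        for r in records:
            writer.writerow([r.input_name, r.accepted_name, r.taxon_id, r.match_status])


def read_backbone(path) -> list[BackboneRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(BackboneRecord(**row))
    return out


def write_crops(names: Iterable[str], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accepted_name"])
        for n in names:
            writer.writerow([n])


def read_crops(path) -> list[str]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return [row["accepted_name"] for row in csv.DictReader(fh)]


def write_geojson(obj: dict, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, separators=(",", ":"))


def read_geojson(path) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)


def geometry_to_feature_collection(
    geoms: Sequence[tuple[dict, BaseGeometry]]
) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
            for props, geom in geoms
        ],
    }


def write_region_set(region_set: RegionSet, path) -> None:
    fc = geometry_to_feature_collection(
        [
            ({"region_name": name, "kind": region_set.kind}, geom)
            for name, geom in region_set.regions
        ]
    )
    write_geojson(fc, path)


def read_region_set(path, name: Optional[str] = None) -> RegionSet:
    """Load a RegionSet from a GeoJSON FeatureCollection.

    Features need ``region_name`` and ``kind`` properties; geometry
    validity is checked here (hard error at load, not per point).
    """
    fc = read_geojson(path)
    regions = []
    kinds = set()
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        if "region_name" not in props:
            raise DataError(f"{path}: feature missing region_name property")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise DataError(f"{path}: invalid geometry for {props['region_name']!r}")
        regions.append((props["region_name"], geom))
        kinds.add(props.get("kind", "region"))
    if not regions:
        raise DataError(f"{path}: no region features")
    kind = kinds.pop() if len(kinds) == 1 else "region"
    rs = RegionSet(name=name or Path(path).stem, kind=kind, regions=regions)
    rs.validate_tiling()
    return rs


def write_single_geometry(geom: BaseGeometry, path, **props) -> None:
    write_geojson(geometry_to_feature_collection([(props, geom)]), path)


def read_single_geometry(path) -> BaseGeometry:
    fc = read_geojson(path)
    feats = fc.get("features", [])
    if not feats:
        raise DataError(f"{path}: no features")
    geoms = [shape(f["geometry"]) for f in feats]
    for g in geoms:
        if not g.is_valid:
            raise DataError(f"{path}: invalid geometry")
    if len(geoms) == 1:
        return geoms[0]
    from shapely.ops import unary_union

    return unary_union(geoms)


def read_points(path) -> list[tuple[float, float]]:
    fc = read_geojson(path)
    pts = []
    for feat in fc.get("features", []):
        geom = feat["geometry"]
        if geom["type"] != "Point":
            raise DataError(f"{path}: expected Point features, got {geom['type']}")
        pts.append(tuple(geom["coordinates"][:2]))
    return pts


def write_json(obj: dict, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)
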