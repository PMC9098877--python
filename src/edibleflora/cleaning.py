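"""Record-level and spatial filters for raw occurrence tables.

Raw biodiversity occurrence downloads are contaminated in well-known ways:
records georeferenced to a country centroid, to the coordinates of the
holding institution, to urban centres, truncated to coarse coordinate
precision, with transposition artefacts (latitude equal to longitude) or
placeholder zeros, falling in the sea, or duplicated. Each contamination
type gets a pure per-record predicate; :func:`clean_pipeline` composes
them in a fixed order, attributes every removal to the first failing
filter, deduplicates exact (taxon, lat, lon) triples, and emits an
auditable report whose counts always reconcile with the input size.

Coordinate precision is judged on the verbatim coordinate *strings*
(occurrence archives ship coordinates as text); a shortest-round-trip
float rendering is the documented fallback when only parsed values exist.
All distances use the haversine great-circle formula on a sphere of
radius 6371.0088 km.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from shapely.geometry.base import BaseGeometry
from shapely.geometry import Point

EARTH_RADIUS_KM = 6371.0088

#: Fixed application order; removals are attributed to the first failure.
FILTER_ORDER = (
    "parse",
    "range",
    "nonzero",
    "equal_coords",
    "precision",
    "centroid",
    "sea",
    "urban",
    "institution",
)

_DECIMAL_RE = re.compile(r"^[+-]?(\d+)(?:\.(\d*))?$")


@dataclass(frozen=True)
class RawOccurrence:
    """One raw occurrence row; coordinates kept as verbatim text."""

    taxon_name: str
    lat_text: Optional[str]
    lon_text: Optional[str]
    source_id: str
    lat: Optional[float] = None
    lon: Optional[float] = None

    @classmethod
    def from_text(
        cls, taxon_name: str, lat_text: str, lon_text: str, source_id: str
    ) -> "RawOccurrence":
        """Build a record, parsing the coordinate strings when possible."""
        return cls(
            taxon_name=taxon_name,
            lat_text=lat_text,
            lon_text=lon_text,
            source_id=source_id,
            lat=_try_parse(lat_text),
            lon=_try_parse(lon_text),
        )


@dataclass(frozen=True)
class CleanOccurrence:
    """One deduplicated georeferenced record surviving every filter."""

    taxon_id: str
    lon: float
    lat: float


@dataclass
class FilterConfig:
    """Configuration of the cleaning filters.

    Filters whose geometry/point inputs are ``None`` are skipped. The sea
    filter retains points on the land-polygon boundary; urban and
    institution filters remove boundary/exact-coordinate points.
    """

    min_decimals: int = 3
    centroid: Optional[tuple[float, float]] = None  # (lon, lat)
    centroid_radius_km: float = 5.0
    institution_points: Sequence[tuple[float, float]] = ()
    institution_buffer_m: float = 100.0
    urban_polygons: Optional[BaseGeometry] = None
    land_polygon: Optional[BaseGeometry] = None

    def validate(self) -> None:
        if self.min_decimals < 0:
            raise ValueError("min_decimals must be >= 0")
        if self.centroid_radius_km < 0 or self.institution_buffer_m < 0:
            raise ValueError("radii and buffers must be >= 0")
        for geom, name in (
            (self.urban_polygons, "urban_polygons"),
            (self.land_polygon, "land_polygon"),
        ):
            if geom is not None:
                if geom.is_empty:
                    raise ValueError(f"{name} is empty")
                if not geom.is_valid:
                    raise ValueError(f"{name} is not a valid geometry")


@dataclass
class CleaningReport:
    """Audit trail: per-filter removal counts plus the dedup count.

    Invariant: ``n_input - sum(removals) - n_duplicates_collapsed ==
    n_output``.
    """

    n_input: int = 0
    removals: dict = field(default_factory=dict)
    n_duplicates_collapsed: int = 0
    n_output: int = 0

    def check(self) -> None:
        total = sum(self.removals.values())
        if self.n_input - total - self.n_duplicates_collapsed != self.n_output:
            raise AssertionError("cleaning report counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removals": dict(self.removals),
            "n_duplicates_collapsed": self.n_duplicates_collapsed,
            "n_output": self.n_output,
        }


def _try_parse(text: Optional[str]) -> Optional[float]:
    if text is None:
        return None
    try:
        v = float(text)
    except ValueError:
        return None
    if math.isnan(v) or math.isinf(v):
        return None
    return v


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def decimal_places(coordinate_text: str) -> int:
    """Count decimal digits in a verbatim coordinate string.

    Trailing zeros count ("4.50" has two decimals). Scientific notation
    and other non-plain-decimal text raise ``ValueError``.
    """
    m = _DECIMAL_RE.match(coordinate_text.strip())
    if m is None:
        raise ValueError(f"not a plain decimal number: {coordinate_text!r}")
    return len(m.group(2) or "")


def decimal_places_float(value: float) -> int:
    """Fallback decimal count from the shortest round-trip rendering."""
    return decimal_places(repr(float(value)))


def _decimals_of(rec: RawOccurrence, which: str) -> int:
    text = rec.lat_text if which == "lat" else rec.lon_text
    if text is not None:
        return decimal_places(text)
    value = rec.lat if which == "lat" else rec.lon
    if value is None:
        raise ValueError("record has neither text nor parsed coordinate")
    return decimal_places_float(value)


def passes_parse(rec: RawOccurrence) -> bool:
    return rec.lat is not None and rec.lon is not None


def passes_range(rec: RawOccurrence) -> bool:
    return -90 <= rec.lat <= 90 and -180 <= rec.lon <= 180


def passes_nonzero(rec: RawOccurrence) -> bool:
    """False iff latitude or longitude is exactly zero."""
    return rec.lat != 0 and rec.lon != 0


def passes_equal_coords(rec: RawOccurrence) -> bool:
    """False iff parsed latitude equals parsed longitude exactly."""
    return rec.lat != rec.lon


def passes_precision(rec: RawOccurrence, min_decimals: int) -> bool:
    """True iff both coordinates carry at least ``min_decimals`` decimals.

    Judged on the verbatim strings; records whose strings are not plain
    decimals (e.g. scientific notation) fail this filter.
    """
    try:
        return (
            _decimals_of(rec, "lat") >= min_decimals
            and _decimals_of(rec, "lon") >= min_decimals
        )
    except ValueError:
        return False


def passes_centroid(
    rec: RawOccurrence, centroid: tuple[float, float], radius_km: float
) -> bool:
    """False iff the record lies within ``radius_km`` of the country centroid."""
    return haversine_km(rec.lon, rec.lat, centroid[0], centroid[1]) > radius_km


def passes_spatial(rec: RawOccurrence, geometry, mode: str, buffer_m: float = 100.0) -> bool:
    """Spatial predicates: ``sea``, ``urban`` or ``institution`` mode.

    sea: fails iff the point is outside the land polygon (boundary counts
    as land, i.e. retained). urban: fails iff the point is inside any
    urban polygon (boundary removed). institution: fails iff the point is
    within ``buffer_m`` metres of any institution point.
    """
    if mode == "sea":
        return geometry.covers(Point(rec.lon, rec.lat))
    if mode == "urban":
        return not geometry.covers(Point(rec.lon, rec.lat))
    if mode == "institution":
        limit_km = buffer_m / 1000.0
        return all(
            haversine_km(rec.lon, rec.lat, px, py) > limit_km for px, py in geometry
        )
    raise ValueError(f"unknown spatial mode {mode!r}")


def deduplicate(
    records: Sequence[CleanOccurrence],
) -> tuple[list[CleanOccurrence], int]:
    """Keep the first record per exact (taxon_id, lat, lon) triple."""
    seen: set = set()
    kept: list[CleanOccurrence] = []
    for rec in records:
        key = (rec.taxon_id, rec.lat, rec.lon)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return kept, len(records) - len(kept)


def clean_pipeline(
    records: Sequence[RawOccurrence],
    config: FilterConfig,
    taxon_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[CleanOccurrence], CleaningReport]:
    """Apply every enabled filter in the fixed order and deduplicate.

    ``taxon_map`` optionally maps verbatim taxon names to reconciled
    taxon ids; unmapped names pass through verbatim. Each removal is
    attributed to the first failing filter, so per-filter counts are
    exclusive and the report identity holds by construction.
    """
    config.validate()
    report = CleaningReport(
        n_input=len(records), removals={name: 0 for name in FILTER_ORDER}
    )

    def first_failure(rec: RawOccurrence) -> Optional[str]:
        if not passes_parse(rec):
            return "parse"
        if not passes_range(rec):
            return "range"
        if not passes_nonzero(rec):
            return "nonzero"
        if not passes_equal_coords(rec):
            return "equal_coords"
        if not passes_precision(rec, config.min_decimals):
            return "precision"
        if config.centroid is not None and not passes_centroid(
            rec, config.centroid, config.centroid_radius_km
        ):
            return "centroid"
        if config.land_polygon is not None and not passes_spatial(
            rec, config.land_polygon, "sea"
        ):
            return "sea"
        if config.urban_polygons is not None and not passes_spatial(
            rec, config.urban_polygons, "urban"
        ):
            return "urban"
        if config.institution_points and not passes_spatial(
            rec,
            config.institution_points,
            "institution",
            config.institution_buffer_m,
        ):
            return "institution"
        return None

    survivors: list[CleanOccurrence] = []
    for rec in records:
        reason = first_failure(rec)
        if reason is not None:
            report.removals[reason] += 1
        else:
            taxon = rec.taxon_name if taxon_map is None else taxon_map.get(
                rec.taxon_name, rec.taxon_name
            )
            survivors.append(CleanOccurrence(taxon_id=taxon, lon=rec.lon, lat=rec.lat))

    unique, collapsed = deduplicate(survivors)
    report.n_duplicates_collapsed = collapsed
    report.n_output = len(unique)
    report.check()
    return unique, report
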