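"""Synthetic checklist, occurrence and geometry scenarios with ground truth.

The generator emulates the statistical structure of a national
edible-plant occurrence compilation without any external download:

* heavy-tailed per-species record counts (a handful of widespread,
  heavily collected species dominate the record total) via a truncated
  discrete power law;
* range-size heterogeneity from single-cell endemics to near
  country-wide species, with ranges grown as contiguous cell blobs;
* spatially clustered hotspots (range seeds concentrate around a few
  hotspot centres);
* a georeferencing gap — a configurable fraction of catalogued species
  has no records at all;
* contamination of every type the cleaning filters target, injected at
  stated rates with each contaminated record violating exactly one
  filter, so per-filter removal attribution is testable against the
  recorded labels.

Every scenario carries an :class:`AnswerKey` with the true synonym map,
per-species range cells, per-record region membership, per-species
regional breadth and per-record contamination labels. The same seed and
configuration always reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Point, box

from .checklist import BackboneRecord, ChecklistEntry, flag_nus
from .cleaning import RawOccurrence
from .grid import GridSpec, assign_cell
from .regions import RegionSet

_HABITS = ("tree", "herb", "shrub", "climber", "other")
_HABIT_WEIGHTS = (0.40, 0.27, 0.20, 0.10, 0.03)

#: Contamination label -> cleaning filter that must catch it.
CONTAMINATION_FILTER = {
    "zero_coord": "nonzero",
    "equal_coords": "equal_coords",
    "low_precision": "precision",
    "centroid": "centroid",
    "sea": "sea",
    "urban": "urban",
    "institution": "institution",
}


@dataclass
class ScenarioConfig:
    """Full parameterisation of one synthetic scenario.

    Flag frequencies default to the composition of the Colombian edible
    flora (native 73.8%, endemic 3.8%, naturalised 11.9%, cultivated
    17.4%, locally reported 64.6%, crop-census members 3.1%, species with
    at least one georeferenced record 82.3%). Distribution shapes are
    truncated power laws; exponents and truncation points are
    configuration, not constants.
    """

    seed: int = 0
    n_species: int = 250
    extent: tuple[float, float, float, float] = (-75.0, 2.0, -71.0, 6.0)
    cell_size: float = 0.1
    sea_margin: float = 0.3  # degrees of "sea" between extent and land
    n_regions: int = 6  # department-like vertical strips
    n_bioregions: int = 4  # bioregion-like horizontal strips
    n_urban: int = 2
    n_institutions: int = 3
    n_hotspots: int = 3
    hotspot_concentration: float = 0.7
    range_exponent: float = 2.0
    max_range_cells: int = 100
    fixed_range_sizes: Optional[Sequence[int]] = None
    records_exponent: float = 1.6
    max_records_per_species: int = 400
    p_native: float = 0.738
    p_endemic: float = 0.038
    p_naturalised: float = 0.119
    p_cultivated: float = 0.174
    p_locally_reported: float = 0.646
    p_georeferenced: float = 0.823
    crop_census_fraction: float = 0.031
    synonym_rate: float = 0.10
    contamination_rates: dict = field(
        default_factory=lambda: {label: 0.01 for label in CONTAMINATION_FILTER}
        | {"duplicate": 0.01}
    )

    def __post_init__(self) -> None:
        if self.n_species <= 0:
            raise ValueError("n_species must be positive")
        x0, y0, x1, y1 = self.extent
        if x1 - x0 < self.cell_size or y1 - y0 < self.cell_size:
            raise ValueError("extent smaller than one grid cell")
        for name in (
            "p_native",
            "p_endemic",
            "p_naturalised",
            "p_cultivated",
            "p_locally_reported",
            "p_georeferenced",
            "crop_census_fraction",
            "synonym_rate",
            "hotspot_concentration",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        bad = [k for k, v in self.contamination_rates.items() if not 0 <= v <= 1]
        if bad:
            raise ValueError(f"contamination rates outside [0, 1]: {bad}")
        if sum(self.contamination_rates.values()) > 1:
            raise ValueError("contamination rates sum above 1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(cell_size=self.cell_size, extent=self.extent)


@dataclass
class GeometrySet:
    """Toy geometry: rectangular land, strip regions, urban, institutions."""

    land: object
    departments: RegionSet
    bioregions: RegionSet
    urban: object  # MultiPolygon
    institutions: list  # [(lon, lat)]
    centroid: tuple[float, float]


@dataclass
class AnswerKey:
    """Ground truth emitted alongside every synthetic scenario."""

    synonym_map: dict = field(default_factory=dict)
    crop_names: list = field(default_factory=list)
    checklist_counts: dict = field(default_factory=dict)
    range_cells: dict = field(default_factory=dict)  # taxon_id -> [[i, j], ...]
    record_regions: dict = field(default_factory=dict)  # source_id -> region|None
    breadth: dict = field(default_factory=dict)  # taxon_id -> int
    contamination: dict = field(default_factory=dict)  # source_id -> label
    n_base_records: int = 0

    @property
    def range_sizes(self) -> dict:
        return {t: len(cells) for t, cells in self.range_cells.items()}

    @property
    def contamination_counts(self) -> dict:
        counts: dict = {}
        for label in self.contamination.values():
            counts[label] = counts.get(label, 0) + 1
        return counts

    def to_json_dict(self) -> dict:
        return {
            "synonym_map": self.synonym_map,
            "crop_names": self.crop_names,
            "checklist_counts": self.checklist_counts,
            "range_cells": {t: sorted(map(list, c)) for t, c in self.range_cells.items()},
            "record_regions": self.record_regions,
            "breadth": self.breadth,
            "contamination": self.contamination,
            "n_base_records": self.n_base_records,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "AnswerKey":
        key = cls(**{k: d[k] for k in d})
        key.range_cells = {
            t: {tuple(c) for c in cells} for t, cells in d["range_cells"].items()
        }
        return key


def _truncated_power_law(
    rng: np.random.Generator, exponent: float, k_max: int, size: int
) -> np.ndarray:
    """Draw integers in [1, k_max] with P(k) proportional to k**-exponent."""
    ks = np.arange(1, k_max + 1, dtype=float)
    p = ks**-exponent
    p /= p.sum()
    return rng.choice(np.arange(1, k_max + 1), size=size, p=p)


def make_toy_geometry(
    extent: tuple[float, float, float, float],
    n_regions: int,
    n_bioregions: int = 1,
    sea_margin: float = 0.3,
    n_urban: int = 2,
    n_institutions: int = 3,
) -> GeometrySet:
    """Deterministic toy geometry over a rectangular extent.

    The land polygon is the extent inset by ``sea_margin`` on every side;
    department strips tile it vertically and bioregion strips
    horizontally, exactly (no gaps, no overlaps). Urban squares and
    institution points sit at fixed relative positions inside land.
    """
    if n_regions < 1 or n_bioregions < 1:
        raise ValueError("need at least one region per set")
    x0, y0, x1, y1 = extent
    lx0, ly0 = x0 + sea_margin, y0 + sea_margin
    lx1, ly1 = x1 - sea_margin, y1 - sea_margin
    if not (lx1 > lx0 and ly1 > ly0):
        raise ValueError("sea margin leaves no land")
    land = box(lx0, ly0, lx1, ly1)

    def strips(n: int, vertical: bool, kind: str) -> RegionSet:
        regions = []
        for k in range(n):
            if vertical:
                a = lx0 + (lx1 - lx0) * k / n
                b = lx0 + (lx1 - lx0) * (k + 1) / n
                geom = box(a, ly0, b, ly1)
            else:
                a = ly0 + (ly1 - ly0) * k / n
                b = ly0 + (ly1 - ly0) * (k + 1) / n
                geom = box(lx0, a, lx1, b)
            regions.append((f"{kind}_{k:02d}", geom))
        return RegionSet(name=kind, kind=kind, regions=regions)

    w, h = lx1 - lx0, ly1 - ly0
    urban_side = 0.06
    urban_anchors = [(0.22, 0.72), (0.72, 0.22), (0.15, 0.40), (0.60, 0.85)]
    urban = MultiPolygon(
        [
            box(
                lx0 + fx * w,
                ly0 + fy * h,
                lx0 + fx * w + urban_side,
                ly0 + fy * h + urban_side,
            )
            for fx, fy in urban_anchors[:n_urban]
        ]
    )
    inst_anchors = [(0.12, 0.12), (0.86, 0.86), (0.50, 0.88), (0.88, 0.12)]
    institutions = [
        (round(lx0 + fx * w, 5), round(ly0 + fy * h, 5))
        for fx, fy in inst_anchors[:n_institutions]
    ]
    centroid = (round((lx0 + lx1) / 2, 3), round((ly0 + ly1) / 2, 3))
    return GeometrySet(
        land=land,
        departments=strips(n_regions, True, "department"),
        bioregions=strips(n_bioregions, False, "bioregion"),
        urban=urban,
        institutions=institutions,
        centroid=centroid,
    )


def simulate_checklist(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[list[ChecklistEntry], list[BackboneRecord], list[str], AnswerKey]:
    """Checklist entries, backbone (with synonyms), crop census, answers."""
    n = config.n_species
    n_families = max(3, n // 12)
    n_genera = max(4, n // 4)
    genus_family = {
        f"Genus{g:04d}": f"Family{int(rng.integers(n_families)):03d}"
        for g in range(n_genera)
    }
    genus_names = sorted(genus_family)

    entries: list[ChecklistEntry] = []
    backbone: list[BackboneRecord] = []
    key = AnswerKey()
    for k in range(n):
        genus = genus_names[int(rng.integers(n_genera))]
        accepted = f"{genus} species{k:05d}"
        taxon_id = f"T{k:05d}"
        native = bool(rng.random() < config.p_native)
        endemic = native and bool(
            rng.random() < config.p_endemic / max(config.p_native, 1e-12)
        )
        naturalised = (not native) and bool(
            rng.random() < config.p_naturalised / max(1 - config.p_native, 1e-12)
        )
        habits = {_HABITS[int(rng.choice(len(_HABITS), p=_HABIT_WEIGHTS))]}
        if rng.random() < 0.10:
            habits.add(_HABITS[int(rng.choice(len(_HABITS), p=_HABIT_WEIGHTS))])
        entries.append(
            ChecklistEntry(
                taxon_id=taxon_id,
                accepted_name=accepted,
                family=genus_family[genus],
                genus=genus,
                native=native,
                endemic=endemic,
                naturalised=naturalised,
                cultivated=bool(rng.random() < config.p_cultivated),
                locally_reported=bool(rng.random() < config.p_locally_reported),
                growth_habits=frozenset(habits),
            )
        )
        backbone.append(
            BackboneRecord(
                input_name=accepted,
                accepted_name=accepted,
                taxon_id=taxon_id,
                match_status="accepted",
            )
        )
        if rng.random() < config.synonym_rate:
            synonym = f"{genus} oldspecies{k:05d}"
            backbone.append(
                BackboneRecord(
                    input_name=synonym,
                    accepted_name=accepted,
                    taxon_id=taxon_id,
                    match_status="synonym",
                )
            )
            key.synonym_map[synonym] = accepted

    n_crops = int(round(config.crop_census_fraction * n))
    crop_idx = rng.choice(n, size=n_crops, replace=False) if n_crops else []
    crops = sorted(entries[i].accepted_name for i in crop_idx)
    entries = flag_nus(entries, crops)

    key.crop_names = crops
    key.checklist_counts = {
        "n_species": n,
        "n_native": sum(e.native for e in entries),
        "n_endemic": sum(e.endemic for e in entries),
        "n_naturalised": sum(e.naturalised for e in entries),
        "n_cultivated": sum(e.cultivated for e in entries),
        "n_locally_reported": sum(e.locally_reported for e in entries),
        "n_in_census": sum(e.in_crop_census for e in entries),
        "n_nus": sum(e.is_nus for e in entries),
    }
    return entries, backbone, crops, key


def _eligible_cells(config: ScenarioConfig, geometry: GeometrySet) -> list:
    """Grid cells whose full square is safe for base records.

    A cell qualifies when it lies inside land and clear of the centroid
    disk, urban squares and institution buffers (with a safety margin),
    so any point sampled inside it passes every spatial filter.
    """
    grid = config.grid
    exclusion = geometry.urban.union(
        Point(geometry.centroid).buffer(0.06)
    )
    for px, py in geometry.institutions:
        exclusion = exclusion.union(Point(px, py).buffer(0.002))
    x0, y0, x1, y1 = config.extent
    cells = []
    i0, j0 = assign_cell(x0, y0, grid)
    ni = int(round((x1 - x0) / grid.cell_size))
    nj = int(round((y1 - y0) / grid.cell_size))
    for i in range(i0, i0 + ni):
        for j in range(j0, j0 + nj):
            cell_box = box(*grid.cell_bounds((i, j)))
            if geometry.land.contains(cell_box) and not cell_box.intersects(
                exclusion
            ):
                cells.append((i, j))
    return cells


def _grow_range(
    seed_cell: tuple, size: int, eligible: set, rng: np.random.Generator
) -> set:
    """Grow a contiguous blob of ``size`` cells from a seed, clipped to
    the eligible set (falls back to random fill if the blob is walled in)."""
    blob = {seed_cell}
    frontier = [seed_cell]
    while len(blob) < size and frontier:
        idx = int(rng.integers(len(frontier)))
        ci, cj = frontier[idx]
        neighbours = [
            c
            for c in ((ci + 1, cj), (ci - 1, cj), (ci, cj + 1), (ci, cj - 1))
            if c in eligible and c not in blob
        ]
        if not neighbours:
            frontier.pop(idx)
            continue
        new = neighbours[int(rng.integers(len(neighbours)))]
        blob.add(new)
        frontier.append(new)
    if len(blob) < size:  # walled in: top up with random eligible cells
        pool = sorted(eligible - blob)
        extra = rng.choice(len(pool), size=min(size - len(blob), len(pool)), replace=False)
        blob |= {pool[i] for i in extra}
    return blob


def simulate_occurrences(
    checklist: Sequence[ChecklistEntry],
    config: ScenarioConfig,
    geometry: GeometrySet,
    rng: np.random.Generator,
    answer_key: AnswerKey,
) -> list[RawOccurrence]:
    """Clean base records for a georeferenced subset of the checklist.

    Each georeferenced species receives a contiguous range of grid cells
    (seeded near a hotspot centre with probability
    ``hotspot_concentration``) and a heavy-tailed number of records, at
    least one per range cell so realized range size equals the drawn one.
    Coordinates are serialized with five decimals; every base record
    passes every cleaning filter by construction.
    """
    grid = config.grid
    eligible = _eligible_cells(config, geometry)
    if not eligible:
        raise ValueError("no eligible cells: extent/margin leave no safe land")
    eligible_set = set(eligible)
    hotspots = [
        eligible[int(rng.integers(len(eligible)))] for _ in range(config.n_hotspots)
    ]

    geo_mask = rng.random(len(checklist)) < config.p_georeferenced
    geo_species = [e for e, m in zip(checklist, geo_mask) if m]
    if config.fixed_range_sizes is not None:
        if len(config.fixed_range_sizes) != len(geo_species):
            raise ValueError(
                "fixed_range_sizes length must equal number of georeferenced "
                f"species ({len(geo_species)})"
            )
        sizes = np.asarray(config.fixed_range_sizes, dtype=int)
    else:
        sizes = _truncated_power_law(
            rng,
            config.range_exponent,
            min(config.max_range_cells, len(eligible)),
            len(geo_species),
        )
    counts = _truncated_power_law(
        rng, config.records_exponent, config.max_records_per_species, len(geo_species)
    )
    counts = np.maximum(counts, sizes)  # every range cell gets >= 1 record

    records: list[RawOccurrence] = []
    seen: set = set()
    for entry, size, n_rec in zip(geo_species, sizes, counts):
        if rng.random() < config.hotspot_concentration and hotspots:
            centre = hotspots[int(rng.integers(len(hotspots)))]
            # seed at an eligible cell near the hotspot centre
            order = sorted(
                eligible, key=lambda c: (abs(c[0] - centre[0]) + abs(c[1] - centre[1]))
            )
            seed_cell = order[int(rng.integers(min(25, len(order))))]
        else:
            seed_cell = eligible[int(rng.integers(len(eligible)))]
        blob = _grow_range(seed_cell, int(size), eligible_set, rng)
        cells = sorted(blob)
        answer_key.range_cells[entry.taxon_id] = set(cells)
        # one record per range cell, remainder spread at random
        draws = list(cells)
        draws += [cells[int(rng.integers(len(cells)))] for _ in range(int(n_rec) - len(cells))]
        for cell in draws:
            cx0, cy0, cx1, cy1 = grid.cell_bounds(cell)
            for _ in range(200):
                lon = cx0 + (cx1 - cx0) * (0.01 + 0.98 * rng.random())
                lat = cy0 + (cy1 - cy0) * (0.01 + 0.98 * rng.random())
                lon_text, lat_text = f"{lon:.5f}", f"{lat:.5f}"
                dup_key = (entry.taxon_id, lat_text, lon_text)
                if dup_key not in seen:
                    seen.add(dup_key)
                    break
            else:  # pragma: no cover - 200 collisions in one cell
                raise RuntimeError("could not place a unique record")
            source_id = f"r{len(records):06d}"
            records.append(
                RawOccurrence.from_text(
                    taxon_name=entry.accepted_name,
                    lat_text=lat_text,
                    lon_text=lon_text,
                    source_id=source_id,
                )
            )

    answer_key.n_base_records = len(records)
    name_to_id = {e.accepted_name: e.taxon_id for e in checklist}
    _record_region_truth(records, geometry, name_to_id, answer_key)
    return records


def _record_region_truth(
    records: Sequence[RawOccurrence],
    geometry: GeometrySet,
    name_to_id: dict,
    key: AnswerKey,
) -> None:
    from .regions import assign_regions_bulk

    lons = np.array([r.lon for r in records])
    lats = np.array([r.lat for r in records])
    assigned = assign_regions_bulk(lons, lats, geometry.departments)
    per_species: dict = {}
    for rec, region in zip(records, assigned):
        key.record_regions[rec.source_id] = region
        if region is not None:
            per_species.setdefault(name_to_id[rec.taxon_name], set()).add(region)
    key.breadth = {tid: len(regions) for tid, regions in per_species.items()}


def inject_contamination(
    records: Sequence[RawOccurrence],
    config: ScenarioConfig,
    geometry: GeometrySet,
    rng: np.random.Generator,
    answer_key: AnswerKey,
) -> list[RawOccurrence]:
    """Append records each violating exactly one cleaning filter.

    Counts per type are ``round(rate * n_base)``. Violations are disjoint
    by construction: the injected coordinates fail their targeted filter
    and no earlier one, so the cleaning report's per-filter counts must
    equal the label counts exactly.
    """
    if not records:
        return list(records)
    x0, y0, x1, y1 = config.extent
    lx0, ly0, lx1, ly1 = geometry.land.bounds
    out = list(records)
    names = sorted({r.taxon_name for r in records})
    next_id = len(records)

    def add(label: str, lat_text: str, lon_text: str) -> None:
        nonlocal next_id
        sid = f"c{next_id:06d}"
        next_id += 1
        out.append(
            RawOccurrence.from_text(
                taxon_name=names[int(rng.integers(len(names)))],
                lat_text=lat_text,
                lon_text=lon_text,
                source_id=sid,
            )
        )
        answer_key.contamination[sid] = label

    def rand_lon() -> float:
        return lx0 + (lx1 - lx0) * rng.random()

    def rand_lat() -> float:
        return ly0 + (ly1 - ly0) * rng.random()

    n_base = len(records)
    for label, rate in sorted(config.contamination_rates.items()):
        k = int(round(rate * n_base))
        for _ in range(k):
            if label == "zero_coord":
                add(label, "0.00000", f"{rand_lon():.5f}")
            elif label == "equal_coords":
                v = f"{rand_lat():.5f}"
                add(label, v, v)
            elif label == "low_precision":
                add(label, f"{rand_lat():.2f}", f"{rand_lon():.2f}")
            elif label == "centroid":
                cx, cy = geometry.centroid
                add(label, f"{cy:.5f}", f"{cx:.5f}")
            elif label == "sea":
                lat = y0 + (config.sea_margin * 0.5) * (0.1 + 0.8 * rng.random())
                add(label, f"{lat:.5f}", f"{rand_lon():.5f}")
            elif label == "urban":
                poly = geometry.urban.geoms[int(rng.integers(len(geometry.urban.geoms)))]
                ux0, uy0, ux1, uy1 = poly.bounds
                lon = ux0 + (ux1 - ux0) * (0.1 + 0.8 * rng.random())
                lat = uy0 + (uy1 - uy0) * (0.1 + 0.8 * rng.random())
                add(label, f"{lat:.5f}", f"{lon:.5f}")
            elif label == "institution":
                px, py = geometry.institutions[
                    int(rng.integers(len(geometry.institutions)))
                ]
                add(label, f"{py:.5f}", f"{px:.5f}")
            elif label == "duplicate":
                base = records[int(rng.integers(n_base))]
                sid = f"c{next_id:06d}"
                next_id += 1
                out.append(dataclasses.replace(base, source_id=sid))
                answer_key.contamination[sid] = label
            else:
                raise ValueError(f"unknown contamination label {label!r}")
    return out


def simulate_scenario(
    config: ScenarioConfig,
) -> tuple[dict, AnswerKey]:
    """Run the full generator; returns in-memory artefacts and the key.

    The returned dict holds ``entries``, ``backbone``, ``crops``,
    ``records`` (contaminated raw occurrences), ``geometry`` and
    ``grid``. File emission lives in :mod:`edibleflora.io`.
    """
    rng = np.random.default_rng(config.seed)
    geometry = make_toy_geometry(
        config.extent,
        config.n_regions,
        config.n_bioregions,
        config.sea_margin,
        config.n_urban,
        config.n_institutions,
    )
    entries, backbone, crops, key = simulate_checklist(config, rng)
    base = simulate_occurrences(entries, config, geometry, rng, key)
    records = inject_contamination(base, config, geometry, rng, key)
    return (
        {
            "entries": entries,
            "backbone": backbone,
            "crops": crops,
            "records": records,
            "geometry": geometry,
            "grid": config.grid,
        },
        key,
    )
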