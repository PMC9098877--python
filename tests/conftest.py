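import math
from fractions import Fraction

import numpy as np
import pytest

from edibleflora.checklist import ChecklistEntry
from edibleflora.cleaning import FilterConfig
from edibleflora.synthetic import ScenarioConfig, simulate_scenario


def make_entry(
    taxon_id="T1",
    accepted_name="Genus one",
    family="Fam",
    genus="Genus",
    native=True,
    endemic=False,
    naturalised=False,
    cultivated=False,
    locally_reported=False,
    growth_habits=("tree",),
    in_crop_census=False,
):
    return ChecklistEntry(
        taxon_id=taxon_id,
        accepted_name=accepted_name,
        family=family,
        genus=genus,
        native=native,
        endemic=endemic,
        naturalised=naturalised,
        cultivated=cultivated,
        locally_reported=locally_reported,
        growth_habits=frozenset(growth_habits),
        in_crop_census=in_crop_census,
        is_nus=not in_crop_census,
    )


def point_in_polygon(x, y, ring):
    """Even-odd ray-casting oracle; ring is a list of (x, y) vertices."""
    inside = False
    n = len(ring)
    for k in range(n):
        x1, y1 = ring[k]
        x2, y2 = ring[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside


def haversine_oracle_km(lon1, lat1, lon2, lat2, radius=6371.0088):
    """Independent great-circle distance via the spherical law of cosines
    on unit vectors (numerically distinct from the haversine route)."""
    def unit(lon, lat):
        lon, lat = math.radians(lon), math.radians(lat)
        return np.array(
            [math.cos(lat) * math.cos(lon), math.cos(lat) * math.sin(lon), math.sin(lat)]
        )
    u, v = unit(lon1, lat1), unit(lon2, lat2)
    return radius * math.atan2(np.linalg.norm(np.cross(u, v)), float(u @ v))


def destination_point(lon, lat, bearing_deg, distance_km, radius=6371.0088):
    """Spherical direct problem: point at given bearing and distance."""
    d = distance_km / radius
    b = math.radians(bearing_deg)
    p1, l1 = math.radians(lat), math.radians(lon)
    p2 = math.asin(math.sin(p1) * math.cos(d) + math.cos(p1) * math.sin(d) * math.cos(b))
    l2 = l1 + math.atan2(
        math.sin(b) * math.sin(d) * math.cos(p1),
        math.cos(d) - math.sin(p1) * math.sin(p2),
    )
    return math.degrees(l2), math.degrees(p2)


def brute_force_metrics(cells_by_species):
    """Exact-rational SR/WE/CWE per occupied cell from presence sets."""
    occupied = set()
    for cells in cells_by_species.values():
        occupied |= set(cells)
    out = {}
    for cell in occupied:
        present = [s for s, cells in cells_by_species.items() if cell in cells]
        we = sum(Fraction(1, len(cells_by_species[s])) for s in present)
        out[cell] = (len(present), we, we / len(present))
    return out


@pytest.fixture(scope="session")
def demo_scenario():
    """One mid-size synthetic scenario shared across the suite."""
    config = ScenarioConfig(n_species=150, seed=42)
    artifacts, key = simulate_scenario(config)
    return config, artifacts, key


@pytest.fixture(scope="session")
def demo_filter_config(demo_scenario):
    _, artifacts, _ = demo_scenario
    g = artifacts["geometry"]
    return FilterConfig(
        centroid=g.centroid,
        institution_points=g.institutions,
        urban_polygons=g.urban,
        land_polygon=g.land,
    )
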