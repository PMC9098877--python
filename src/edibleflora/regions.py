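"""Point-in-polygon regional aggregation and sampling-effort regression.

Cleaned records are assigned to a tiling set of region polygons
(administrative departments or ecological bioregions). Per region the
module counts records and the distinct species, genera and families among
them; per species it measures breadth (distinct regions occupied); and it
fits the ordinary-least-squares regression of regional species richness on
regional record counts, the standard check that apparent richness
differences track sampling effort.

Boundary points are assigned to the alphabetically first matching region —
a documented stable tie-break, since tiling polygons share edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .checklist import ChecklistEntry
from .cleaning import CleanOccurrence


@dataclass
class RegionSet:
    """Named set of region polygons of one kind (department/bioregion)."""

    name: str
    kind: str  # department | bioregion
    regions: list  # [(region_name, shapely geometry)], unique names

    def __post_init__(self) -> None:
        names = [n for n, _ in self.regions]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")
        # deterministic assignment order for boundary tie-breaks
        self.regions = sorted(self.regions, key=lambda r: r[0])

    def validate_tiling(self) -> None:
        """Hard error if any two region interiors overlap."""
        for a in range(len(self.regions)):
            na, ga = self.regions[a]
            for b in range(a + 1, len(self.regions)):
                nb, gb = self.regions[b]
                if ga.relate_pattern(gb, "2********"):
                    raise ValueError(
                        f"region interiors overlap: {na!r} and {nb!r}"
                    )

    @property
    def names(self) -> list:
        return [n for n, _ in self.regions]


@dataclass(frozen=True)
class RegionSummary:
    """Record/species/genus/family counts for one region."""

    region_name: str
    n_records: int
    n_species: int
    n_genera: int
    n_families: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of species richness on record count across regions."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def assign_region(lon: float, lat: float, region_set: RegionSet) -> Optional[str]:
    """Name of the region containing the point, or None.

    Boundary points go to the alphabetically first covering region.
    """
    pt = Point(lon, lat)
    for name, geom in region_set.regions:
        if geom.covers(pt):
            return name
    return None


def assign_regions_bulk(
    lons: np.ndarray, lats: np.ndarray, region_set: RegionSet
) -> np.ndarray:
    """Vectorised region assignment; unassigned points get None."""
    pts = shapely.points(np.asarray(lons, float), np.asarray(lats, float))
    out = np.full(len(pts), None, dtype=object)
    unassigned = np.ones(len(pts), dtype=bool)
    for name, geom in region_set.regions:  # alphabetical: first wins
        if not unassigned.any():
            break
        hit = shapely.covers(geom, pts) & unassigned
        out[hit] = name
        unassigned &= ~hit
    return out


def _occurrence_frame(occurrences: Sequence[CleanOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.taxon_id, o.lon, o.lat) for o in occurrences],
        columns=["taxon_id", "lon", "lat"],
    )


def summarize_regions(
    occurrences: Sequence[CleanOccurrence],
    checklist: Sequence[ChecklistEntry],
    region_set: RegionSet,
) -> pd.DataFrame:
    """Per-region record, species, genus and family counts.

    Regions with no records are emitted with zeros; records outside every
    region are counted in the ``__unassigned__`` attribute of the returned
    frame, never silently dropped. Records whose taxon_id is missing from
    the checklist are a hard error.
    """
    lookup = {e.taxon_id: e for e in checklist}
    df = _occurrence_frame(occurrences)
    if len(df):
        orphans = sorted(set(df["taxon_id"]) - set(lookup))
        if orphans:
            raise ValueError(f"taxon_ids missing from checklist: {orphans}")
        df["region"] = assign_regions_bulk(
            df["lon"].to_numpy(), df["lat"].to_numpy(), region_set
        )
        df["genus"] = df["taxon_id"].map(lambda t: lookup[t].genus)
        df["family"] = df["taxon_id"].map(lambda t: lookup[t].family)
    else:
        df = df.assign(region=pd.Series(dtype=object), genus="", family="")

    rows = []
    for name in region_set.names:
        sub = df[df["region"] == name]
        rows.append(
            {
                "region_name": name,
                "n_records": len(sub),
                "n_species": sub["taxon_id"].nunique(),
                "n_genera": sub["genus"].nunique(),
                "n_families": sub["family"].nunique(),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["region_name", "n_records", "n_species", "n_genera", "n_families"],
    )
    out.attrs["__unassigned__"] = int(df["region"].isna().sum()) if len(df) else 0
    return out


def breadth_distribution(
    occurrences: Sequence[CleanOccurrence],
    region_set: RegionSet,
    thresholds: tuple[int, int, int, int] = (20, 30, 1, 5),
) -> tuple[pd.Series, dict]:
    """Per-species regional breadth plus headline counts.

    Breadth is the number of distinct regions holding at least one record
    of the species (unassigned records contribute nothing). Headline
    counts use the threshold parameters ``(gt_a, gt_b, eq_low, le_c)``:
    species in more than ``gt_a`` regions, more than ``gt_b`` regions,
    exactly ``eq_low`` region, at most ``le_c`` regions, and in every
    region of the set.
    """
    gt_a, gt_b, eq_low, le_c = thresholds
    df = _occurrence_frame(occurrences)
    if len(df):
        df["region"] = assign_regions_bulk(
            df["lon"].to_numpy(), df["lat"].to_numpy(), region_set
        )
        df = df.dropna(subset=["region"])
        breadth = df.groupby("taxon_id")["region"].nunique().astype(int)
    else:
        breadth = pd.Series(dtype=int, name="region")
    n_regions = len(region_set.regions)
    headline = {
        f"gt_{gt_a}": int((breadth > gt_a).sum()),
        f"gt_{gt_b}": int((breadth > gt_b).sum()),
        f"eq_{eq_low}": int((breadth == eq_low).sum()),
        f"le_{le_c}": int((breadth <= le_c).sum()),
        "all_regions": int((breadth == n_regions).sum()),
    }
    return breadth, headline


def richness_records_regression(
    summaries: pd.DataFrame, log: bool = False
) -> RegressionResult:
    """OLS of regional species richness on record count.

    Regions with zero records are excluded. With ``log=True`` both axes
    are log10-transformed (an option, not the default). The slope's
    two-sided t-test uses n - 2 degrees of freedom. Requires at least 3
    regions with records and non-constant record counts.
    """
    sub = summaries[summaries["n_records"] > 0]
    if len(sub) < 3:
        raise ValueError("need at least 3 regions with records")
    x = sub["n_records"].to_numpy(dtype=float)
    y = sub["n_species"].to_numpy(dtype=float)
    if log:
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0:
        raise ValueError("record counts have zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(sub),
    )
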