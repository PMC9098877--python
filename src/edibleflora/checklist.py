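"""Checklist curation and catalogue-level summary statistics.

A national edible-plant checklist is a table of taxa with accepted names,
higher taxonomy (family, genus) and status flags (native, endemic,
naturalised, cultivated, locally reported in food use). This module
reconciles verbatim names against a taxonomic backbone table, flags
neglected-and-underutilized species (NUS) by absence from a crop-census
list, and computes the headline counts and percentage shares of the
catalogue.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled vocabulary for growth habits.
GROWTH_HABITS = frozenset({"tree", "shrub", "herb", "climber", "other"})


@dataclass(frozen=True)
class BackboneRecord:
    """One row of the taxonomic backbone used for name reconciliation."""

    input_name: str
    accepted_name: str
    taxon_id: str
    match_status: str  # accepted | synonym | unmatched

    def __post_init__(self) -> None:
        if self.match_status not in {"accepted", "synonym", "unmatched"}:
            raise ValueError(f"unknown match_status {self.match_status!r}")
        if self.match_status != "unmatched" and not self.accepted_name:
            raise ValueError(
                f"backbone row {self.input_name!r}: accepted_name required "
                f"for status {self.match_status!r}"
            )


@dataclass(frozen=True)
class ChecklistEntry:
    """One curated taxon with taxonomy, status flags, habit and NUS flag.

    Invariants: ``endemic`` implies ``native``; ``is_nus`` is the negation
    of ``in_crop_census``; ``genus`` is the first epithet of
    ``accepted_name``.
    """

    taxon_id: str
    accepted_name: str
    family: str
    genus: str
    native: bool
    endemic: bool
    naturalised: bool
    cultivated: bool
    locally_reported: bool
    growth_habits: frozenset = field(default_factory=frozenset)
    in_crop_census: bool = False
    is_nus: bool = True

    def __post_init__(self) -> None:
        if self.endemic and not self.native:
            raise ValueError(f"{self.accepted_name}: endemic implies native")
        if self.is_nus == self.in_crop_census:
            raise ValueError(
                f"{self.accepted_name}: is_nus must be NOT in_crop_census"
            )
        bad = set(self.growth_habits) - GROWTH_HABITS
        if bad:
            raise ValueError(f"{self.accepted_name}: unknown habits {sorted(bad)}")


@dataclass(frozen=True)
class CatalogueSummary:
    """Totals and one-decimal percentage shares for a curated checklist."""

    n_species: int
    n_families: int
    n_genera: int
    n_native: int
    n_endemic: int
    n_naturalised: int
    n_cultivated: int
    n_locally_reported: int
    n_nus: int

    @property
    def shares(self) -> dict:
        """Percentage of n_species for every count, one decimal."""
        return {
            name: compute_share(getattr(self, name), self.n_species)
            for name in (
                "n_native",
                "n_endemic",
                "n_naturalised",
                "n_cultivated",
                "n_locally_reported",
                "n_nus",
            )
        }

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out.update({f"pct{k[1:]}": v for k, v in self.shares.items()})
        return out


def normalize_name(name: str) -> str:
    """Matching key for a taxon name: trim, collapse internal whitespace,
    case-fold. No fuzzy matching — that would silently merge taxa."""
    return " ".join(name.split()).casefold()


def coerce_habit(habit: str) -> str:
    """Map a habit string to the fixed vocabulary, warning on unknowns."""
    h = habit.strip().lower()
    if h not in GROWTH_HABITS:
        logger.warning("unknown growth habit %r mapped to 'other'", habit)
        return "other"
    return h


def reconcile_names(
    names: Sequence[str], backbone: Sequence[BackboneRecord]
) -> tuple[dict, list]:
    """Resolve verbatim names against the backbone.

    Returns ``(mapping, unmatched)`` where ``mapping`` maps each resolvable
    verbatim name to ``(accepted_name, taxon_id)`` and ``unmatched`` lists
    names (in input order, deduplicated) with no backbone match. Matching is
    exact after :func:`normalize_name`; synonyms resolve to their accepted
    taxon, so two verbatim names sharing an accepted name collapse to one
    taxon_id.

    Raises ``ValueError`` if the backbone holds the same input name twice
    with conflicting accepted names.
    """
    index: dict[str, BackboneRecord] = {}
    for rec in backbone:
        key = normalize_name(rec.input_name)
        prior = index.get(key)
        if prior is not None:
            if (prior.accepted_name, prior.taxon_id) != (
                rec.accepted_name,
                rec.taxon_id,
            ):
                raise ValueError(
                    f"backbone input_name {rec.input_name!r} duplicated with "
                    f"conflicting targets {prior.accepted_name!r} / "
                    f"{rec.accepted_name!r}"
                )
            continue
        index[key] = rec

    mapping: dict[str, tuple[str, str]] = {}
    unmatched: list[str] = []
    seen_unmatched: set[str] = set()
    for name in names:
        rec = index.get(normalize_name(name))
        if rec is None or rec.match_status == "unmatched":
            if name not in seen_unmatched:
                unmatched.append(name)
                seen_unmatched.add(name)
        else:
            mapping[name] = (rec.accepted_name, rec.taxon_id)
    return mapping, unmatched


def flag_nus(
    entries: Iterable[ChecklistEntry], crop_names: Iterable[str]
) -> list[ChecklistEntry]:
    """Set ``in_crop_census``/``is_nus`` by membership in the crop census.

    A taxon is NUS exactly when its accepted name is absent from the
    census; the partition is exhaustive and exclusive. An empty census
    makes every species NUS.
    """
    crops = {normalize_name(c) for c in crop_names}
    out = []
    for e in entries:
        in_census = normalize_name(e.accepted_name) in crops
        out.append(replace(e, in_crop_census=in_census, is_nus=not in_census))
    return out


def compute_share(k: int, n: int) -> float:
    """Percentage 100*k/n rounded half-away-from-zero to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    pct = Decimal(100 * k) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_catalogue(entries: Sequence[ChecklistEntry]) -> CatalogueSummary:
    """Catalogue totals over distinct taxa, families and genera."""
    if not entries:
        raise ValueError("empty checklist")
    by_id = {e.taxon_id: e for e in entries}
    taxa = list(by_id.values())
    return CatalogueSummary(
        n_species=len(taxa),
        n_families=len({e.family for e in taxa}),
        n_genera=len({e.genus for e in taxa}),
        n_native=sum(e.native for e in taxa),
        n_endemic=sum(e.endemic for e in taxa),
        n_naturalised=sum(e.naturalised for e in taxa),
        n_cultivated=sum(e.cultivated for e in taxa),
        n_locally_reported=sum(e.locally_reported for e in taxa),
        n_nus=sum(e.is_nus for e in taxa),
    )


def rank_families(
    entries: Sequence[ChecklistEntry],
    n: int,
    native_only: bool = False,
) -> pd.DataFrame:
    """Top-``n`` families by genus count.

    Ties break by species count then family name. With ``native_only`` the
    counts are recomputed over native taxa only. If ``n`` exceeds the
    number of families, all families are returned.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pool = [e for e in entries if e.native] if native_only else list(entries)
    genera: dict[str, set] = defaultdict(set)
    species: dict[str, set] = defaultdict(set)
    for e in pool:
        genera[e.family].add(e.genus)
        species[e.family].add(e.taxon_id)
    rows = [
        {"family": fam, "n_genera": len(genera[fam]), "n_species": len(species[fam])}
        for fam in genera
    ]
    df = pd.DataFrame(rows, columns=["family", "n_genera", "n_species"])
    df = df.sort_values(
        ["n_genera", "n_species", "family"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df.head(n)


def rank_genera_by_habit(
    entries: Sequence[ChecklistEntry], habit: str, n: int
) -> pd.DataFrame:
    """Top-``n`` genera by species count within one growth habit.

    A species with several habits counts once under each of them.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    habit = coerce_habit(habit)
    species: dict[str, set] = defaultdict(set)
    for e in entries:
        if habit in e.growth_habits:
            species[e.genus].add(e.taxon_id)
    rows = [{"genus": g, "n_species": len(s)} for g, s in species.items()]
    df = pd.DataFrame(rows, columns=["genus", "n_species"])
    df = df.sort_values(
        ["n_species", "genus"], ascending=[False, True]
    ).reset_index(drop=True)
    return df.head(n)


def entries_to_frame(entries: Sequence[ChecklistEntry]) -> pd.DataFrame:
    """Checklist as a DataFrame (growth habits pipe-joined, sorted)."""
    rows = []
    for e in entries:
        d = {k: getattr(e, k) for k in e.__dataclass_fields__}
        d["growth_habits"] = "|".join(sorted(e.growth_habits))
        rows.append(d)
    return pd.DataFrame(rows)


def entries_from_frame(df: pd.DataFrame) -> list[ChecklistEntry]:
    """Inverse of :func:`entries_to_frame`."""
    bool_cols = [
        "native",
        "endemic",
        "naturalised",
        "cultivated",
        "locally_reported",
        "in_crop_census",
        "is_nus",
    ]
    out = []
    for row in df.to_dict("records"):
        habits = frozenset(
            coerce_habit(h) for h in str(row["growth_habits"]).split("|") if h
        )
        kwargs: dict = {
            "taxon_id": str(row["taxon_id"]),
            "accepted_name": str(row["accepted_name"]),
            "family": str(row["family"]),
            "genus": str(row["genus"]),
            "growth_habits": habits,
        }
        for c in bool_cols:
            if c in df.columns:
                v = row[c]
                kwargs[c] = bool(v) if not isinstance(v, str) else v.lower() in {
                    "true",
                    "1",
                    "t",
                    "yes",
                }
        out.append(ChecklistEntry(**kwargs))
    return out
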