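"""Checklist curation: reconciliation, NUS flagging, summaries, rankings."""

from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edibleflora.checklist import (
    BackboneRecord,
    ChecklistEntry,
    compute_share,
    flag_nus,
    rank_families,
    rank_genera_by_habit,
    reconcile_names,
    summarize_catalogue,
)
from edibleflora.synthetic import ScenarioConfig, simulate_checklist

from conftest import make_entry


def bb(input_name, accepted, taxon_id, status="accepted"):
    return BackboneRecord(input_name, accepted, taxon_id, status)


class TestReconcileNames:
    def test_whitespace_and_case_normalization_collapse_to_one_taxon(self):
        backbone = [bb("Inga edulis", "Inga edulis Mart.", "T1")]
        mapping, unmatched = reconcile_names(
            ["Inga edulis", "Inga  edulis ", "INGA EDULIS"], backbone
        )
        assert unmatched == []
        assert {v for v in mapping.values()} == {("Inga edulis Mart.", "T1")}

    def test_unknown_name_goes_to_unmatched(self):
        mapping, unmatched = reconcile_names(
            ["Xyzus fakeus"], [bb("Inga edulis", "Inga edulis", "T1")]
        )
        assert mapping == {}
        assert unmatched == ["Xyzus fakeus"]

    def test_synonyms_collapse_to_accepted_taxon_count(self):
        # 50 names: 40 accepted species plus 10 synonyms of 5 of them
        backbone, names = [], []
        for k in range(45):
            backbone.append(bb(f"Genus sp{k}", f"Genus sp{k}", f"T{k}"))
        for k in range(40):
            names.append(f"Genus sp{k}")
        for j in range(10):
            syn = f"Genus oldsp{j}"
            backbone.append(bb(syn, f"Genus sp{j % 5}", f"T{j % 5}", "synonym"))
            names.append(syn)
        mapping, unmatched = reconcile_names(names, backbone)
        assert unmatched == []
        assert len(names) == 50
        assert len({tid for _, tid in mapping.values()}) == 40

    def test_conflicting_duplicate_backbone_rows_raise(self):
        backbone = [
            bb("Inga edulis", "Inga edulis", "T1"),
            bb("Inga edulis", "Inga vera", "T2"),
        ]
        with pytest.raises(ValueError, match="Inga edulis"):
            reconcile_names(["Inga edulis"], backbone)

    def test_idempotent_on_accepted_names(self):
        backbone = [bb(f"G sp{k}", f"G sp{k}", f"T{k}") for k in range(20)]
        names = [r.accepted_name for r in backbone]
        mapping, unmatched = reconcile_names(names, backbone)
        assert unmatched == []
        assert all(mapping[n][0] == n for n in names)

    def test_generator_synonym_map_round_trips(self):
        config = ScenarioConfig(n_species=200, seed=11, synonym_rate=0.25)
        entries, backbone, _, key = simulate_checklist(
            config, np.random.default_rng(11)
        )
        names = [e.accepted_name for e in entries] + sorted(key.synonym_map)
        mapping, unmatched = reconcile_names(names, backbone)
        assert unmatched == []
        # every synonym resolves to its recorded accepted name
        for syn, accepted in key.synonym_map.items():
            assert mapping[syn][0] == accepted
        assert len({tid for _, tid in mapping.values()}) == len(entries)


class TestFlagNus:
    def test_partition_is_exhaustive_and_exclusive(self):
        entries = [make_entry(taxon_id=f"T{k}", accepted_name=f"G sp{k}") for k in range(5)]
        flagged = flag_nus(entries, {"G sp0", "G sp3"})
        assert sum(e.is_nus for e in flagged) == 3
        assert all(e.is_nus != e.in_crop_census for e in flagged)

    def test_empty_census_makes_everything_nus(self):
        entries = [make_entry(taxon_id=f"T{k}", accepted_name=f"G sp{k}") for k in range(4)]
        assert all(e.is_nus for e in flag_nus(entries, set()))

    def test_generator_census_answer_key(self):
        config = ScenarioConfig(n_species=200, seed=5, crop_census_fraction=0.085)
        entries, _, crops, key = simulate_checklist(config, np.random.default_rng(5))
        assert len(crops) == 17
        assert sum(e.is_nus for e in entries) == 183
        assert key.checklist_counts["n_nus"] == 183


class TestComputeShare:
    # Worked examples whose inputs are published counts. Several published
    # one-decimal shares (e.g. 17.6, 20.8, 0.3, 11.9, 17.3) are not
    # consistent with their own printed numerators under any standard
    # rounding; only internally consistent pairs are asserted here.
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (3132, 3805, 82.3),  # species with georeferenced records
            (146, 3805, 3.8),  # endemics
            (2272, 3805, 59.7),  # species with <= 20 records
            # 1806/3805 = 47.46%: the published table truncates this one to
            # 47.4; consistent half-away-from-zero rounding gives 47.5
            (1806, 3805, 47.5),
            (172, 3805, 4.5),  # species in > 20 departments
            (0, 3805, 0.0),
        ],
    )
    def test_published_count_examples(self, k, n, expected):
        assert compute_share(k, n) == expected

    def test_round_half_away_from_zero(self):
        assert compute_share(1, 800) == 0.1  # 0.125 -> 0.1
        assert compute_share(3, 2000) == 0.2  # 0.15 -> 0.2, not banker's 0.1

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            compute_share(0, 0)

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_endpoints(self, k, n):
        k = min(k, n)
        share = compute_share(k, n)
        assert 0.0 <= share <= 100.0
        assert compute_share(n, n) == 100.0

    @given(st.integers(1, 5000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_numerator(self, n):
        shares = [compute_share(k, n) for k in range(0, n + 1, max(1, n // 17))]
        assert shares == sorted(shares)


class TestSummarizeCatalogue:
    def test_toy_counts(self):
        entries = [
            make_entry(taxon_id="T1", native=True, endemic=True),
            make_entry(taxon_id="T2", native=True),
            make_entry(taxon_id="T3", native=False, naturalised=True),
        ]
        s = summarize_catalogue(entries)
        assert (s.n_native, s.n_endemic, s.n_naturalised) == (2, 1, 1)
        assert s.n_species == 3

    def test_species_without_local_reports_from_published_totals(self):
        # 3805 catalogued species of which 2457 carry local use reports
        entries = [
            make_entry(taxon_id=f"T{k}", locally_reported=(k < 2457))
            for k in range(3805)
        ]
        s = summarize_catalogue(entries)
        assert s.n_species - s.n_locally_reported == 1348

    def test_empty_checklist_rejected(self):
        with pytest.raises(ValueError):
            summarize_catalogue([])

    def test_generator_flag_counts_match_answer_key(self):
        config = ScenarioConfig(n_species=400, seed=9)
        entries, _, _, key = simulate_checklist(config, np.random.default_rng(9))
        s = summarize_catalogue(entries)
        for field, expected in key.checklist_counts.items():
            if field == "n_in_census":
                continue
            assert getattr(s, field) == expected
        assert s.n_nus + key.checklist_counts["n_in_census"] == s.n_species


class TestRankings:
    def _toy(self):
        return [
            make_entry("T1", "A one", family="FamA", genus="Aone"),
            make_entry("T2", "A two", family="FamA", genus="Atwo"),
            make_entry("T3", "A three", family="FamA", genus="Atwo", native=False),
            make_entry("T4", "B one", family="FamB", genus="Bone"),
            make_entry("T5", "B two", family="FamB", genus="Btwo"),
            make_entry("T6", "C one", family="FamC", genus="Cone"),
        ]

    def test_rank_families_hand_counted(self):
        df = rank_families(self._toy(), n=3)
        assert list(df["family"]) == ["FamA", "FamB", "FamC"]
        assert list(df["n_genera"]) == [2, 2, 1]
        assert list(df["n_species"]) == [3, 2, 1]

    def test_native_restriction_recomputes_counts(self):
        df = rank_families(self._toy(), n=10, native_only=True)
        fam_a = df[df["family"] == "FamA"].iloc[0]
        assert fam_a["n_species"] == 2

    def test_n_larger_than_family_count_returns_all(self):
        assert len(rank_families(self._toy(), n=99)) == 3

    def test_totals_conserved_against_recount_oracle(self):
        config = ScenarioConfig(n_species=300, seed=21)
        entries, _, _, _ = simulate_checklist(config, np.random.default_rng(21))
        df = rank_families(entries, n=10**6)
        assert df["n_species"].sum() == len(entries)
        oracle = defaultdict(lambda: [set(), set()])
        for e in entries:
            oracle[e.family][0].add(e.genus)
            oracle[e.family][1].add(e.taxon_id)
        for row in df.to_dict("records"):
            gset, sset = oracle[row["family"]]
            assert (row["n_genera"], row["n_species"]) == (len(gset), len(sset))

    def test_rank_genera_by_habit_order_and_set_semantics(self):
        entries = [
            make_entry("T1", genus="Ga", growth_habits=("tree",)),
            make_entry("T2", genus="Ga", growth_habits=("tree", "shrub")),
            make_entry("T3", genus="Ga", growth_habits=("tree",)),
            make_entry("T4", genus="Gb", growth_habits=("tree",)),
        ]
        df = rank_genera_by_habit(entries, "tree", n=5)
        assert list(df["genus"]) == ["Ga", "Gb"]
        assert list(df["n_species"]) == [3, 1]
        # the dual-habit species counts once under each habit
        shrub = rank_genera_by_habit(entries, "shrub", n=5)
        assert list(shrub["n_species"]) == [1]

    def test_rank_genera_matches_recount_oracle(self):
        config = ScenarioConfig(n_species=300, seed=22)
        entries, _, _, _ = simulate_checklist(config, np.random.default_rng(22))
        for habit in ("tree", "herb"):
            df = rank_genera_by_habit(entries, habit, n=10**6)
            oracle = defaultdict(set)
            for e in entries:
                if habit in e.growth_habits:
                    oracle[e.genus].add(e.taxon_id)
            assert df["n_species"].sum() == sum(len(v) for v in oracle.values())


class TestEntryInvariants:
    def test_endemic_requires_native(self):
        with pytest.raises(ValueError, match="endemic"):
            make_entry(native=False, endemic=True)

    def test_nus_must_negate_census_flag(self):
        with pytest.raises(ValueError, match="is_nus"):
            ChecklistEntry(
                taxon_id="T1",
                accepted_name="G s",
                family="F",
                genus="G",
                native=True,
                endemic=False,
                naturalised=False,
                cultivated=False,
                locally_reported=False,
                in_crop_census=True,
                is_nus=True,
            )
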