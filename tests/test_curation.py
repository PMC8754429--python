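"""Curation funnel: normalization, matching, median aggregation, subsets."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldcomp.curation import (
    build_reactions,
    curate,
    filter_wild_type,
    match_t_growth,
    normalize_organism_name,
    reactions_from_frame,
    reactions_to_frame,
    subset_reactions,
)
from coldcomp.io import ValueType, VariantStatus

from conftest import make_entry


class TestNormalizeOrganismName:
    def test_trims_collapses_and_lowercases(self):
        assert normalize_organism_name("Escherichia  coli ") == "escherichia coli"

    def test_idempotent(self):
        once = normalize_organism_name("Escherichia coli")
        assert normalize_organism_name(once) == once == "escherichia coli"

    def test_strain_stripping_mode(self):
        assert (
            normalize_organism_name("Pseudomonas putida KT2440", strip_strain=True)
            == "pseudomonas putida"
        )
        assert (
            normalize_organism_name("Pseudomonas putida KT2440")
            == "pseudomonas putida kt2440"
        )

    def test_empty_name_is_error(self):
        with pytest.raises(ValueError):
            normalize_organism_name("   ")

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=st.characters(whitelist_categories=["Lu", "Ll"]), min_size=1))
    def test_idempotence_property(self, name):
        once = normalize_organism_name(name)
        assert normalize_organism_name(once) == once


class TestFilterWildType:
    def test_keeps_wild_type_in_order(self):
        wt1 = make_entry(entry_id="1")
        mut = make_entry(entry_id="2", status=VariantStatus.MUTANT)
        wt2 = make_entry(entry_id="3")
        assert filter_wild_type([wt1, mut, wt2]) == [wt1, wt2]

    def test_all_mutant_gives_empty(self):
        assert filter_wild_type([make_entry(status=VariantStatus.MUTANT)] * 3) == []

    def test_idempotent(self):
        entries = [make_entry(), make_entry(status=VariantStatus.MUTANT)]
        once = filter_wild_type(entries)
        assert filter_wild_type(once) == once


class TestMatchTGrowth:
    TABLE = {"org alpha": 10.0, "org beta": 37.0}

    def test_matched_and_unmatched_counts(self):
        entries = [
            make_entry(organism="Org alpha"),
            make_entry(organism="Org beta"),
            make_entry(organism="Org gamma"),
        ]
        matched, unmatched = match_t_growth(entries, self.TABLE)
        assert len(matched) == 2 and unmatched == 1
        assert matched[0].t_growth_C == 10.0

    def test_empty_entries(self):
        matched, unmatched = match_t_growth([], self.TABLE)
        assert matched == [] and unmatched == 0

    def test_matching_invariant_to_case_and_whitespace(self):
        entries = [make_entry(organism="  ORG   Alpha ")]
        matched, unmatched = match_t_growth(entries, {"Org  alpha": 10.0})
        assert unmatched == 0
        assert matched[0].organism == "org alpha"


class TestBuildReactions:
    def test_median_aggregation_per_organism(self):
        entries = [
            make_entry(organism="Org a", value=v, entry_id=f"a{v}") for v in (1.0, 2.0, 9.0)
        ] + [make_entry(organism="Org b", value=4.0, entry_id="b")]
        matched, _ = match_t_growth(entries, {"org a": 5.0, "org b": 40.0})
        reactions, report = build_reactions(matched)
        (reaction,) = reactions
        ks = {m.organism: m.k for m in reaction.measurements}
        assert ks == {"org a": 2.0, "org b": 4.0}
        assert report.n_values_in_reactions == 4
        assert report.n_organisms == 2

    def test_even_count_median_is_midpoint(self):
        entries = [
            make_entry(organism="Org a", value=v) for v in (1.0, 3.0)
        ] + [make_entry(organism="Org b", value=4.0)]
        matched, _ = match_t_growth(entries, {"org a": 5.0, "org b": 40.0})
        reactions, _ = build_reactions(matched)
        assert {m.k for m in reactions[0].measurements} == {2.0, 4.0}

    def test_single_organism_reaction_dropped(self):
        entries = [make_entry(organism="Org a"), make_entry(organism="Org a", value=2.0)]
        matched, _ = match_t_growth(entries, {"org a": 5.0})
        reactions, report = build_reactions(matched)
        assert reactions == []
        assert report.n_reactions == 0
        assert report.n_values_in_reactions == 0

    def test_two_organisms_one_value_each(self):
        entries = [make_entry(organism="Org a"), make_entry(organism="Org b", value=2.0)]
        matched, _ = match_t_growth(entries, {"org a": 5.0, "org b": 40.0})
        reactions, report = build_reactions(matched)
        assert len(reactions[0].measurements) == 2
        assert report.n_values_in_reactions == 2

    def test_permutation_invariance(self):
        entries = [
            make_entry(organism=o, value=v, substrate=s, entry_id=f"{o}{v}{s}")
            for o, v, s in [
                ("Org a", 1.0, "s1"), ("Org b", 2.0, "s1"), ("Org a", 5.0, "s1"),
                ("Org a", 3.0, "s2"), ("Org c", 7.0, "s2"),
            ]
        ]
        table = {"org a": 5.0, "org b": 40.0, "org c": 20.0}
        matched_fwd, _ = match_t_growth(entries, table)
        matched_rev, _ = match_t_growth(entries[::-1], table)
        fwd, _ = build_reactions(matched_fwd)
        rev, _ = build_reactions(matched_rev)
        assert [
            (r.reaction_key, [(m.organism, m.k) for m in r.measurements]) for r in fwd
        ] == [
            (r.reaction_key, [(m.organism, m.k) for m in r.measurements]) for r in rev
        ]

    def test_funnel_monotone(self):
        entries = [
            make_entry(organism="Org a"),
            make_entry(organism="Org a", status=VariantStatus.MUTANT),
            make_entry(organism="Org nowhere"),
            make_entry(organism="Org b", value=2.0),
            make_entry(organism="Org lonely", substrate="other"),
        ]
        reactions, report = curate(entries, {"org a": 5.0, "org b": 40.0, "org lonely": 10.0})
        assert report.n_input == 5
        assert report.n_wild_type == 4
        assert report.n_t_growth_matched == 3
        assert report.n_values_in_reactions == 2  # lonely's reaction has 1 organism
        assert (
            report.n_input >= report.n_wild_type >= report.n_t_growth_matched
            >= report.n_values_in_reactions
        )
        assert len(reactions) == 1


class TestSubsetReactions:
    def _reactions(self):
        entries = [
            make_entry(organism="Org a", value=1.0, assay_temperature_C=25.0),
            make_entry(organism="Org b", value=2.0, assay_temperature_C=25.0),
            make_entry(organism="Org c", value=3.0, assay_temperature_C=37.0),
        ]
        matched, _ = match_t_growth(
            entries, {"org a": 5.0, "org b": 20.0, "org c": 45.0}
        )
        reactions, _ = build_reactions(matched)
        return reactions

    def test_span_filter_is_strict(self):
        reactions = self._reactions()  # span 40
        assert subset_reactions(reactions, min_t_growth_span_C=20.0) == reactions
        assert subset_reactions(reactions, min_t_growth_span_C=40.0) == []

    def test_span_filter_keeps_wide_reaction(self):
        assert len(subset_reactions(self._reactions(), min_t_growth_span_C=39.9)) == 1

    def test_assay_filter_reaggregates_and_drops_small_reactions(self):
        reactions = self._reactions()
        at_25 = subset_reactions(reactions, assay_temperature_C=25.0)
        assert len(at_25) == 1
        assert {m.organism for m in at_25[0].measurements} == {"org a", "org b"}
        # only one organism measured at 37 C -> below two organisms -> dropped
        assert subset_reactions(reactions, assay_temperature_C=37.0) == []


class TestReactionFrameRoundTrip:
    def test_round_trip(self):
        entries = [
            make_entry(organism="Org a", value=1.0),
            make_entry(organism="Org b", value=2.0),
        ]
        matched, _ = match_t_growth(entries, {"org a": 5.0, "org b": 40.0})
        reactions, _ = build_reactions(matched)
        frame = reactions_to_frame(reactions)
        back = reactions_from_frame(frame)
        assert len(back) == 1
        assert [(m.organism, m.t_growth_C, m.k) for m in back[0].measurements] == [
            (m.organism, m.t_growth_C, m.k) for m in reactions[0].measurements
        ]
        assert back[0].value_type is ValueType.KCAT
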