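"""MDC core: site scan semantics, classification, event merging, profiles."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastomdc import (MultipleAlignment, SpeciesPartition, StateSet,
                       classify_site, column_states, find_diagnostic_sites,
                       from_species_dict, merge_events, species_mdc_profile)
from plastomdc.mdc import DiagnosticSite, genus_profiles

from conftest import oracle_sites, random_alignment, scanner_sites_as_tuples


def sites_of(species_seqs, query, policy="ignore"):
    aln = from_species_dict("G", species_seqs)
    part = SpeciesPartition.for_query(aln, query)
    return find_diagnostic_sites(aln, part, policy=policy)


class TestColumnStates:
    def test_iupac_expansion_and_gap(self):
        aln = from_species_dict("G", {"a": ["R-N"], "b": ["ACG"]})
        r, gap, n = (column_states(aln, c, "a")[0] for c in range(3))
        assert r.states == {"A", "G"} and not r.missing
        assert gap.states == {"-"}
        assert n.missing and n.states == frozenset()

    def test_strict_policy_expands_n(self):
        aln = from_species_dict("G", {"a": ["N"], "b": ["A"]})
        s = column_states(aln, 0, "a", policy="strict")[0]
        assert s.states == {"A", "C", "G", "T"} and not s.missing

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="invalid symbol"):
            from_species_dict("G", {"a": ["AXG"], "b": ["ACG"]})


class TestFindDiagnosticSites:
    def test_single_substitution_site(self):
        sites = sites_of({"q": ["ACGT", "ACGT"],
                          "r1": ["ACCT"], "r2": ["ACTT"]}, "q")
        assert len(sites) == 1
        s = sites[0]
        assert (s.column, s.category) == (2, "substitution")
        assert s.query_state.states == {"G"}
        assert s.reference_union.states == {"C", "T"}

    def test_query_polymorphic_column_excluded(self):
        assert sites_of({"q": ["ACGT", "ACTT"], "r": ["ACCT"]}, "q") == []

    def test_shared_state_not_diagnostic(self):
        assert sites_of({"q": ["ACGT"], "r": ["ACGT", "ACGA"]}, "q") == []

    def test_gap_is_a_character_state(self):
        sites = sites_of({"q": ["A-GT"], "r": ["ACGT"]}, "q")
        assert [(s.column, s.category) for s in sites] == [(1, "deletion")]
        assert sites[0].query_state.states == {"-"}

    def test_missing_query_specimen_ignored(self):
        # the N specimen contributes nothing; the remaining one is monomorphic
        sites = sites_of({"q": ["ACGT", "ACNT"], "r": ["ACCT"]}, "q")
        assert [s.column for s in sites] == [2]

    def test_all_missing_column_skipped(self):
        assert sites_of({"q": ["N"], "r": ["A"]}, "q") == []
        assert sites_of({"q": ["A"], "r": ["N"]}, "q") == []

    def test_strict_policy_lets_n_erase_sites(self):
        seqs = {"q": ["ACGT"], "r1": ["ACCT"], "r2": ["ACNT"]}
        assert [s.column for s in sites_of(seqs, "q")] == [2]
        assert sites_of(seqs, "q", policy="strict") == []

    def test_ambiguity_monomorphism_requires_identical_sets(self):
        # {R, R} is monomorphic, {R, A} is not
        assert [s.column for s in
                sites_of({"q": ["R", "R"], "r": ["C"]}, "q")] == [0]
        assert sites_of({"q": ["R", "A"], "r": ["C"]}, "q") == []

    def test_ambiguity_overlap_blocks_disjointness(self):
        # query {A,G} shares A with the reference
        assert sites_of({"q": ["R"], "r": ["A"]}, "q") == []

    def test_unknown_query_species_raises(self):
        aln = from_species_dict("G", {"a": ["AC"], "b": ["AC"]})
        with pytest.raises(KeyError):
            SpeciesPartition.for_query(aln, "zz")


class TestClassifySite:
    @pytest.mark.parametrize("q, r, expected", [
        ({"A"}, {"C", "T"}, "substitution"),
        ({"-"}, {"A", "C"}, "deletion"),
        ({"G"}, {"-"}, "insertion"),
        ({"T"}, {"C", "-"}, "mixed"),
        ({"-"}, {"A", "-"}, None),  # non-disjoint -> contract violation
    ])
    def test_categories(self, q, r, expected):
        qs, rs = StateSet(frozenset(q)), StateSet(frozenset(r))
        if expected is None:
            with pytest.raises(ValueError):
                classify_site(qs, rs)
        else:
            assert classify_site(qs, rs) == expected


def _site(col, cat):
    return DiagnosticSite(col, StateSet(frozenset("A")),
                          StateSet(frozenset("C")), cat)


class TestMergeEvents:
    def test_consecutive_deletions_merge(self):
        evs = merge_events([_site(c, "deletion") for c in (5, 6, 7)])
        assert [(e.start, e.end, e.event_type) for e in evs] == \
            [(5, 8, "multi_deletion")]
        assert evs[0].length == 3

    def test_non_adjacent_stay_single(self):
        evs = merge_events([_site(5, "substitution"), _site(7, "substitution")])
        assert [(e.start, e.end, e.event_type) for e in evs] == \
            [(5, 6, "substitution"), (7, 8, "substitution")]

    def test_heterogeneous_run_is_multi_mixed(self):
        evs = merge_events([_site(5, "substitution"), _site(6, "deletion")])
        assert [(e.start, e.end, e.event_type) for e in evs] == \
            [(5, 7, "multi_mixed")]

    def test_run_containing_mixed_site_is_multi_mixed(self):
        evs = merge_events([_site(5, "mixed"), _site(6, "mixed")])
        assert evs[0].event_type == "multi_mixed"

    def test_single_mixed_keeps_category(self):
        assert merge_events([_site(3, "mixed")])[0].event_type == "mixed"

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            merge_events([_site(6, "deletion"), _site(5, "deletion")])


class TestSpeciesProfile:
    def test_twin_species_have_zero_mdcs(self):
        aln = from_species_dict("G", {
            "a": ["ACGT"], "b": ["ACGT"], "c": ["AGGT"]})
        assert species_mdc_profile(aln, "a").mdc_count == 0
        assert species_mdc_profile(aln, "b").mdc_count == 0

    def test_every_column_diagnostic_for_disjoint_pair(self):
        aln = from_species_dict("G", {"a": ["ACGT"], "b": ["TGCA"]})
        assert species_mdc_profile(aln, "a").mdc_count == 4

    def test_tally_partitions_sites(self, toy_alignment):
        for sp in toy_alignment.species:
            p = species_mdc_profile(toy_alignment, sp)
            assert sum(p.type_tally.values()) == p.mdc_count
            assert sum(e.length for e in p.events) == p.mdc_count

    def test_inclusion_rule_enforced(self):
        aln = from_species_dict("G", {"a": ["AC"], "b": ["AG"]})
        with pytest.raises(ValueError, match="at least 3"):
            genus_profiles(aln)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(20240917)
        for _ in range(60):
            aln = random_alignment(rng, max_columns=80)
            records = [(r.species, r.sequence) for r in aln.records]
            for sp in aln.species:
                assert scanner_sites_as_tuples(aln, sp) == \
                    oracle_sites(records, sp)

    def test_matches_brute_force_under_strict_policy(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            aln = random_alignment(rng, max_columns=60)
            records = [(r.species, r.sequence) for r in aln.records]
            for sp in aln.species:
                assert scanner_sites_as_tuples(aln, sp, policy="strict") == \
                    oracle_sites(records, sp, policy="strict")


@st.composite
def alignment_strategy(draw):
    n_species = draw(st.integers(2, 4))
    n_spec = draw(st.integers(1, 3))
    n_cols = draw(st.integers(1, 30))
    sym = st.sampled_from("ACGT-N")
    species_seqs = {
        f"sp{i}": [
            "".join(draw(st.lists(sym, min_size=n_cols, max_size=n_cols)))
            for _ in range(n_spec)]
        for i in range(n_species)
    }
    return from_species_dict("G", species_seqs)


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(alignment_strategy(), st.randoms(use_true_random=False))
    def test_order_permutation_invariance(self, aln, rnd):
        """Shuffling specimen/species record order never changes the sites."""
        order = list(range(aln.n_records))
        rnd.shuffle(order)
        shuffled = MultipleAlignment([aln.records[i] for i in order])
        for sp in aln.species:
            assert scanner_sites_as_tuples(aln, sp) == \
                scanner_sites_as_tuples(shuffled, sp)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(alignment_strategy())
    def test_reference_monotonicity(self, aln):
        """Adding a reference specimen never enlarges the diagnostic set."""
        query = aln.species[0]
        before = {t[0] for t in scanner_sites_as_tuples(aln, query)}
        extra = aln.records[-1]
        if extra.species == query:
            return
        grown = MultipleAlignment(aln.records + [extra])
        after = {t[0] for t in scanner_sites_as_tuples(grown, query)}
        assert after <= before

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(alignment_strategy())
    def test_query_duplication_invariance(self, aln):
        """Duplicating an existing query specimen changes nothing."""
        query = aln.species[0]
        dup = aln.records[aln.rows_of(query)[0]]
        grown = MultipleAlignment(aln.records + [dup])
        assert scanner_sites_as_tuples(aln, query) == \
            scanner_sites_as_tuples(grown, query)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(alignment_strategy())
    def test_all_n_reference_specimen_is_inert(self, aln):
        """Under the ignore policy an all-N specimen contributes nothing."""
        query = aln.species[0]
        other = aln.species[-1]
        if other == query:
            return
        blank = type(aln.records[0])(aln.genus, other, "blank",
                                     "N" * aln.n_columns)
        grown = MultipleAlignment(aln.records + [blank])
        assert scanner_sites_as_tuples(aln, query) == \
            scanner_sites_as_tuples(grown, query)

    def test_two_species_symmetry(self):
        """Monomorphic 2-species genus: both species share one site set."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            a = "".join(rng.choice(list("ACGT-"), size=n))
            b = "".join(rng.choice(list("ACGT-"), size=n))
            aln = from_species_dict("G", {"a": [a, a], "b": [b, b]})
            sa = {t[0] for t in scanner_sites_as_tuples(aln, "a")}
            sb = {t[0] for t in scanner_sites_as_tuples(aln, "b")}
            assert sa == sb

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(alignment_strategy())
    def test_events_conserve_sites_and_are_maximal(self, aln):
        for sp in aln.species:
            p = species_mdc_profile(aln, sp)
            cols = sorted(s.column for s in p.sites)
            assert sum(e.length for e in p.events) == len(cols)
            covered = sorted(c for e in p.events
                             for c in range(e.start, e.end))
            assert covered == cols
            # maximality: neighbouring columns of each event are not sites
            colset = set(cols)
            for e in p.events:
                assert e.start - 1 not in colset
                assert e.end not in colset
            # events non-overlapping and sorted
            for e1, e2 in zip(p.events, p.events[1:]):
                assert e1.end < e2.start

    def test_tally_counter_is_consistent_with_events(self, toy_alignment):
        p = species_mdc_profile(toy_alignment, "sp1")
        recomputed = Counter()
        for e in p.events:
            recomputed[e.event_type] += e.length
        assert recomputed == p.type_tally
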