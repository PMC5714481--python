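"""Proportional allocation of shared reads among paralogous genes."""


import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqplus.allocation import (
    AllocationParams,
    FamilyState,
    allocate_all,
    allocate_bitscore,
    allocate_evalue,
    progressive_allocate,
    proportion_two,
)
from seqplus.matcher import Hit, MatchEntry, MatchTable


class TestProportionTwo:
    def test_cold_shock_pair_proportion(self):
        assert round(proportion_two(291, 86), 4) == 0.7719

    def test_symmetry(self):
        assert proportion_two(5, 5) == 0.5

    def test_degenerate_equal_split(self):
        # identical paralogs: both unique counts zero
        assert proportion_two(0, 0) == 0.5

    def test_pseudocount_variant(self):
        params = AllocationParams(pseudocount_eps=0.01)
        assert proportion_two(7, 38, params) == pytest.approx(7.01 / 45.02)
        assert proportion_two(0, 0, params) == 0.5

    def test_length_normalization(self):
        # per-kb rates: 1000*10/500 = 20 vs 1000*10/2000 = 5
        p = proportion_two(10, 10, lengths=(500, 2000))
        assert p == pytest.approx(20 / 25)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_two(-1, 3)


class TestProgressiveAllocate:
    def test_three_gene_worked_example(self, three_gene_family):
        state, shared = three_gene_family
        res = progressive_allocate(state, shared)
        assert res.counts["A"] == pytest.approx(10.57778, abs=5e-6)
        assert res.counts["B"] == pytest.approx(19.14074, abs=5e-6)
        assert res.counts["C"] == pytest.approx(38.28148, abs=5e-6)
        props = res.proportions[frozenset("ABC")]
        assert props["A"] == pytest.approx(0.15556, abs=5e-6)
        assert props["B"] == pytest.approx(0.28148, abs=5e-6)
        assert props["C"] == pytest.approx(0.56296, abs=5e-6)

    def test_pairwise_stage_intermediate(self, three_gene_family):
        state, shared = three_gene_family
        res = progressive_allocate(state, shared)
        after_pairs = res.stage_states[2]
        assert after_pairs["B"] == pytest.approx(12.66667, abs=5e-6)
        assert after_pairs["C"] == pytest.approx(25.33333, abs=5e-6)
        assert after_pairs["A"] == 7.0

    def test_identical_paralogs_split_equally(self):
        res = progressive_allocate(
            FamilyState({"A": 0.0, "B": 0.0}), {frozenset("AB"): 10.0}
        )
        assert res.counts == {"A": 5.0, "B": 5.0}

    def test_reduces_to_two_member_formula(self):
        """With F=2 and a single pairwise set the progressive algorithm IS the
        two-member proportional formula."""
        nu1, nu2, shared = 37.0, 11.0, 29.0
        p1 = proportion_two(nu1, nu2)
        res = progressive_allocate(
            FamilyState({"g1": nu1, "g2": nu2}), {frozenset(["g1", "g2"]): shared}
        )
        assert res.counts["g1"] == pytest.approx(nu1 + shared * p1, abs=1e-12)
        assert res.counts["g2"] == pytest.approx(nu2 + shared * (1 - p1), abs=1e-12)

    def test_same_size_set_order_invariance(self):
        state = {"A": 3.0, "B": 5.0, "C": 9.0}
        sets_fwd = {frozenset("AB"): 10.0, frozenset("BC"): 12.0, frozenset("ABC"): 7.0}
        sets_rev = dict(reversed(list(sets_fwd.items())))
        a = progressive_allocate(FamilyState(dict(state)), sets_fwd).counts
        b = progressive_allocate(FamilyState(dict(state)), sets_rev).counts
        assert a == b

    def test_conservation_and_normalization_properties(self):
        state = {"A": 1.0, "B": 0.0, "C": 4.5, "D": 2.0}
        shared = {
            frozenset("AB"): 6.0,
            frozenset("CD"): 3.0,
            frozenset("ABC"): 11.0,
            frozenset("ABCD"): 9.0,
        }
        res = progressive_allocate(FamilyState(dict(state)), shared)
        total_in = sum(state.values()) + sum(shared.values())
        assert sum(res.counts.values()) == pytest.approx(total_in, abs=1e-9)
        for props in res.proportions.values():
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_singleton_set_rejected(self):
        with pytest.raises(ValueError):
            progressive_allocate(FamilyState({"A": 1.0}), {frozenset("A"): 2.0})

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            progressive_allocate(FamilyState({"A": 1.0}), {frozenset("AZ"): 2.0})

    @given(
        uniques=st.lists(st.floats(0, 100), min_size=3, max_size=3),
        c2=st.floats(0, 50),
        c3=st.floats(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_holds_for_arbitrary_counts(self, uniques, c2, c3):
        state = {g: v for g, v in zip("ABC", uniques)}
        shared = {frozenset("BC"): c2, frozenset("ABC"): c3}
        res = progressive_allocate(FamilyState(dict(state)), shared)
        expected = sum(uniques) + c2 + c3
        assert sum(res.counts.values()) == pytest.approx(expected, abs=1e-7)


class TestScoreWeightedSchemes:
    def test_equal_bitscores_split_equally(self):
        assert allocate_bitscore({"a": 100.0, "b": 100.0}) == {"a": 0.5, "b": 0.5}

    def test_bitscore_direct_formula(self):
        props = allocate_bitscore({"a": 100.0, "b": 50.0})
        assert props["a"] == pytest.approx(2 / 3)
        assert props["b"] == pytest.approx(1 / 3)

    def test_bitscore_normalizes_random_vector(self):
        import numpy as np

        rng = np.random.default_rng(3)
        scores = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(1, 500, 10))}
        assert sum(allocate_bitscore(scores).values()) == pytest.approx(1.0)

    def test_nonpositive_bitscore_rejected(self):
        with pytest.raises(ValueError):
            allocate_bitscore({"a": 0.0, "b": 1.0})

    def test_equal_evalues_split_equally(self):
        props = allocate_evalue({"a": 1e-5, "b": 1e-5})
        assert props == {"a": 0.5, "b": 0.5}

    def test_evalue_direct_formula(self):
        props = allocate_evalue({"a": 1e-10, "b": 1e-5})
        assert props["a"] == pytest.approx(1 / (1 + 1e-5))
        assert props["b"] == pytest.approx(1e-5 / (1 + 1e-5))

    def test_zero_evalue_clamped(self):
        props = allocate_evalue({"a": 0.0, "b": 1e-50})
        assert props["a"] > props["b"]
        assert sum(props.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "bitscores,evalues",
        [
            ({"a": 100.0, "b": 80.0}, {"a": 1e-20, "b": 1e-12}),
            ({"a": 60.0, "b": 50.0, "c": 40.0}, {"a": 1e-9, "b": 1e-6, "c": 1e-3}),
        ],
    )
    def test_evalue_scheme_more_biased_toward_best_hit(self, bitscores, evalues):
        """Inverse e-value weighting concentrates the read on the best match
        far more sharply than bit-score weighting, which stays near equal."""
        best = max(bitscores, key=bitscores.get)
        assert min(evalues, key=evalues.get) == best
        p_bit = allocate_bitscore(bitscores)[best]
        p_ev = allocate_evalue(evalues)[best]
        assert p_ev > p_bit


class TestAllocateAll:
    def test_cold_shock_paralog_pair(self, csp_match_table):
        """264/58 unique + 27/28 better-matching + 12 exact ties →
        300.2626 / 88.7374 final counts."""
        res = allocate_all(csp_match_table, {"cspF": 210, "cspH": 210})
        assert res.counts["cspF"] == pytest.approx(300.2626, abs=5e-5)
        assert res.counts["cspH"] == pytest.approx(88.7374, abs=5e-5)
        assert res.unmapped == 0

    def test_unique_only_table_is_identity(self):
        table = MatchTable(
            [
                MatchEntry("a", 10, [Hit("g1", 50.0)]),
                MatchEntry("b", 4, [Hit("g2", 50.0)]),
            ]
        )
        res = allocate_all(table)
        assert res.counts == {"g1": 10.0, "g2": 4.0}

    def test_unmapped_reads_counted(self):
        table = MatchTable(
            [MatchEntry("a", 3, [Hit("g1", 50.0)]), MatchEntry("b", 2, [])]
        )
        res = allocate_all(table)
        assert res.unmapped == 2
        assert res.total_mapped + res.unmapped == table.total_reads

    def test_families_are_cobesthit_components(self):
        table = MatchTable(
            [
                MatchEntry("a", 1, [Hit("g1", 50.0), Hit("g2", 50.0)]),
                MatchEntry("b", 1, [Hit("g2", 40.0), Hit("g3", 40.0)]),
                MatchEntry("c", 1, [Hit("g4", 40.0)]),
            ]
        )
        res = allocate_all(table)
        assert frozenset({"g1", "g2", "g3"}) in res.families
        assert frozenset({"g4"}) in res.families

    def test_gene_permutation_invariance(self, csp_match_table):
        flipped = MatchTable(
            [
                MatchEntry(e.read_id, e.copy_number, list(reversed(e.best_hits)))
                for e in csp_match_table.entries
            ]
        )
        a = allocate_all(csp_match_table, {"cspF": 210, "cspH": 210}).counts
        b = allocate_all(flipped, {"cspF": 210, "cspH": 210}).counts
        assert a == pytest.approx(b)

    def test_bitscore_scheme_on_shared_reads(self):
        table = MatchTable(
            [
                MatchEntry("u", 6, [Hit("g1", 50.0)]),
                MatchEntry("s", 9, [Hit("g1", 60.0), Hit("g2", 30.0)]),
            ]
        )
        res = allocate_all(table, params=AllocationParams(scheme="bitscore"))
        assert res.counts["g1"] == pytest.approx(6 + 9 * 2 / 3)
        assert res.counts["g2"] == pytest.approx(9 * 1 / 3)
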