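"""Assembly planning: first tier, gene plans, chain recovery, growth."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from splintstore.assembly_planner import (
    JoinSpec,
    Piece,
    TopologyError,
    brute_force_order,
    growth_stats,
    order_from_joins,
    plan_data_gene,
    plan_first_tier,
)
from splintstore.library_design import design_symbol_oligo
from splintstore.sequence_core import Oligo, S1_ENDS, TerminalChemistry


def make_piece(symbol: str, index: int) -> Piece:
    oligo = Oligo("G" + "ACGT" * 3 + "AGC", ends=S1_ENDS)
    return Piece(oligo, left_linker_index=index, right_linker_index=index,
                 tier=2, symbol_name=symbol)


class TestFirstTier:
    def test_three_pieces_two_catalytic_strands(self, demo_libs):
        symbol = design_symbol_oligo(demo_libs.symbols.payload("A"))
        left, right = demo_libs.linkers.pairs[0]
        tier = plan_first_tier(symbol, left, right, demo_libs.linkers.params)
        assert len(tier.pieces) == 3
        assert len(tier.catalytic_strands) == 2

    def test_roles_left_and_symbol_activated_right_is_s2(self, demo_libs):
        symbol = design_symbol_oligo(demo_libs.symbols.payload("B"))
        left, right = demo_libs.linkers.pairs[1]
        tier = plan_first_tier(symbol, left, right, demo_libs.linkers.params)
        assert tier.activated_pieces == [0, 1]  # left linker + symbol
        assert tier.s2_piece == 2  # right linker
        assert tier.pieces[0].oligo.seq == left.seq
        assert tier.pieces[2].oligo.seq == right.seq

    def test_symbol_without_phosphate_rejected(self, demo_libs):
        bare = Oligo("GACGTACGTAGC", ends=TerminalChemistry())
        left, right = demo_libs.linkers.pairs[0]
        with pytest.raises(ValueError, match="phosphate"):
            plan_first_tier(bare, left, right)


class TestDataGenePlans:
    def test_gene1_pairings_and_joins(self, demo_libs):
        plan = plan_data_gene(list("ABCBA"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        tier2 = plan.final_tier
        assert [(p.symbol_name, p.left_linker_index) for p in tier2.pieces] == [
            ("A", 1), ("B", 2), ("C", 3), ("B", 4), ("A", 5)
        ]
        assert [(j.upstream_right_linker_index, j.downstream_left_linker_index)
                for j in tier2.joins] == [(1, 2), (2, 3), (3, 4), (4, 5)]

    def test_gene3_join_redesign_reuses_gene2_pairing(self, demo_libs):
        plan = plan_data_gene(list("CBCAB"), "design_joins",
                              demo_libs.symbols, demo_libs.linkers,
                              reference_order=list("BCACB"))
        tier2 = plan.final_tier
        assert {(j.upstream_right_linker_index, j.downstream_left_linker_index)
                for j in tier2.joins} == {(2, 1), (1, 4), (4, 3), (3, 5)}
        assert order_from_joins(tier2.pieces, tier2.joins) == list("CBCAB")

    def test_five_pieces_four_catalytic_strands(self, demo_libs):
        plan = plan_data_gene(list("BCACB"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        assert len(plan.final_tier.catalytic_strands) == 4
        assert len(plan.final_tier.pieces) == 5

    def test_both_modes_realise_the_same_order(self, demo_libs):
        order = list("CABCA")
        a = plan_data_gene(order, "pair_linkers", demo_libs.symbols, demo_libs.linkers)
        b = plan_data_gene(order, "design_joins", demo_libs.symbols,
                           demo_libs.linkers, reference_order=list("AABCC"))
        assert order_from_joins(a.final_tier.pieces, a.final_tier.joins) == order
        assert order_from_joins(b.final_tier.pieces, b.final_tier.joins) == order
        assert a.final_tier.joins != b.final_tier.joins

    def test_unknown_symbol_rejected(self, demo_libs):
        with pytest.raises(KeyError, match="unknown symbol"):
            plan_data_gene(list("ABZ"), "pair_linkers",
                           demo_libs.symbols, demo_libs.linkers)

    def test_too_many_symbols_for_library(self, demo_libs):
        with pytest.raises(ValueError, match="linker pairs"):
            plan_data_gene(list("ABCABC"), "pair_linkers",
                           demo_libs.symbols, demo_libs.linkers)

    def test_activation_accounting(self, demo_libs):
        plan = plan_data_gene(list("ABCBA"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        tier2 = plan.final_tier
        assert len(tier2.activated_pieces) == len(tier2.pieces) - 1
        assert tier2.s2_piece not in tier2.activated_pieces


class TestOrderFromJoins:
    def test_published_gene1_chain(self):
        pieces = [make_piece(s, i) for s, i in
                  [("A", 1), ("B", 2), ("C", 3), ("B", 4), ("A", 5)]]
        joins = [JoinSpec(1, 2), JoinSpec(2, 3), JoinSpec(3, 4), JoinSpec(4, 5)]
        assert order_from_joins(pieces, joins) == list("ABCBA")

    def test_published_gene3_chain(self):
        pieces = [make_piece(s, i) for s, i in
                  [("B", 1), ("C", 2), ("A", 3), ("C", 4), ("B", 5)]]
        joins = [JoinSpec(2, 1), JoinSpec(1, 4), JoinSpec(4, 3), JoinSpec(3, 5)]
        assert order_from_joins(pieces, joins) == list("CBCAB")

    def test_cycle_rejected(self):
        pieces = [make_piece("A", 1), make_piece("B", 2)]
        with pytest.raises(TopologyError):
            order_from_joins(pieces, [JoinSpec(1, 2), JoinSpec(2, 1)])

    def test_disconnected_rejected(self):
        pieces = [make_piece(s, i) for s, i in
                  [("A", 1), ("B", 2), ("C", 3), ("D", 4)]]
        with pytest.raises(TopologyError):
            order_from_joins(pieces, [JoinSpec(1, 2), JoinSpec(3, 4), JoinSpec(4, 3)])

    def test_reused_linker_rejected(self):
        pieces = [make_piece(s, i) for s, i in [("A", 1), ("B", 2), ("C", 3)]]
        with pytest.raises(TopologyError, match="two joins"):
            order_from_joins(pieces, [JoinSpec(1, 2), JoinSpec(1, 3)])

    @given(st.permutations(list(range(6))))
    def test_matches_permutation_enumeration_oracle(self, perm):
        names = "ABCDEF"
        pieces = [make_piece(names[i], i + 1) for i in range(6)]
        joins = [
            JoinSpec(pieces[a].right_linker_index, pieces[b].left_linker_index)
            for a, b in zip(perm, perm[1:])
        ]
        expected = brute_force_order(pieces, joins)
        assert order_from_joins(pieces, joins) == expected
        assert expected == [names[i] for i in perm]


class TestGrowthStats:
    @pytest.mark.parametrize(
        "k,m,symbols,bits",
        [(5, 1, 5, 80), (5, 2, 25, 400), (5, 3, 125, 2000), (2, 0, 1, 16),
         (3, 4, 81, 1296)],
    )
    def test_geometric_growth(self, k, m, symbols, bits):
        s = growth_stats(k, m, 16)
        assert (s.symbols, s.bits) == (symbols, bits)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            growth_stats(1, 3)
        with pytest.raises(ValueError):
            growth_stats(5, -1)
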