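"""Activation chemistry, junction gates, motif table, stochastic yields."""

import numpy as np
import pytest

from splintstore.assembly_planner import plan_data_gene
from splintstore.library_design import (
    LibraryDesignParams,
    design_catalytic_strand,
)
from splintstore.ligation_simulator import (
    ChemistryError,
    ReactionConditions,
    activate,
    junction_efficiency,
    junction_report,
    simulate_assembly,
    simulate_plan,
    simulate_two_component,
)
from splintstore.sequence_core import EndState, Oligo, S1_ENDS, TerminalChemistry


@pytest.fixture()
def junction():
    """A canonical activated junction: substrates, splint, clean conditions."""
    up = Oligo("G" + "ATCCTGAACTGGATTC" + "AGC", ends=S1_ENDS)
    down = Oligo("G" + "TTGACCAGTATCGGAT" + "AGC", ends=S1_ENDS)
    splint = design_catalytic_strand(up, down)
    return activate(up), down, splint


class TestActivation:
    def test_phosphate_becomes_phosphorimidazolide(self):
        o = Oligo("GACGTAGC", ends=S1_ENDS)
        a = activate(o, 20.0, 100.0)
        assert a.ends.three_prime == EndState.PHOSPHORIMIDAZOLIDE

    def test_hydroxyl_cannot_be_activated(self):
        o = Oligo("GACGTAGC", ends=TerminalChemistry())
        with pytest.raises(ChemistryError, match="3' phosphate"):
            activate(o)

    def test_zero_reagent_rejected(self):
        o = Oligo("GACGTAGC", ends=S1_ENDS)
        with pytest.raises(ValueError, match="positive"):
            activate(o, 0.0, 100.0)

    def test_reactivation_is_noop_with_warning(self):
        o = activate(Oligo("GACGTAGC", ends=S1_ENDS))
        with pytest.warns(UserWarning, match="already activated"):
            assert activate(o) == o

    def test_carryover_recorded(self):
        cond = ReactionConditions()
        activate(Oligo("GACGTAGC", ends=S1_ENDS), 100.0, 100.0, cond=cond)
        assert cond.imidazole_carryover_mM == 100.0
        assert cond.edc_carryover_mM == 100.0


class TestJunctionEfficiency:
    def test_canonical_junction_is_fully_efficient(self, junction):
        assert junction_efficiency(*junction) == 1.0

    @pytest.mark.parametrize("motif,expected", [("CGCA", 0.16), ("CGCC", 0.50)])
    def test_reduced_activity_motifs(self, junction, motif, expected):
        import contextlib

        up, down, splint = junction
        ctx = (pytest.warns(UserWarning, match="side")
               if motif == "CGCC" else contextlib.nullcontext())
        with ctx:
            eff = junction_efficiency(up, down, splint.with_motif(motif))
        assert eff == expected

    @pytest.mark.parametrize(
        "motif", ["GGCT", "TGCT", "CCCT", "CACT", "CGGT", "CGTT"]
    )
    def test_six_single_base_mutants_are_dead(self, junction, motif):
        up, down, splint = junction
        assert junction_efficiency(up, down, splint.with_motif(motif)) == 0.0

    def test_no_zinc_no_ligation(self, junction):
        up, down, splint = junction
        rep = junction_report(up, down, splint, ReactionConditions(zinc_present=False))
        assert rep.efficiency == 0.0 and rep.reason == "no_zinc_cofactor"

    def test_unactivated_upstream_no_ligation(self, junction):
        _, down, splint = junction
        raw = Oligo("G" + "ATCCTGAACTGGATTC" + "AGC", ends=S1_ENDS)
        rep = junction_report(raw, down, splint)
        assert rep.efficiency == 0.0 and rep.reason == "upstream_not_activated"

    def test_arm_mismatch_no_ligation(self, junction):
        up, down, _ = junction
        other_up = Oligo("G" + "CCCCTGAACTGGCCCC" + "AGC", ends=S1_ENDS)
        wrong = design_catalytic_strand(other_up, down)
        rep = junction_report(up, down, wrong)
        assert rep.efficiency == 0.0 and rep.reason == "arm_s1_hybridization_failure"

    def test_imidazole_inhibition_is_monotone(self, junction):
        up, down, splint = junction
        effs = [
            junction_efficiency(up, down, splint,
                                ReactionConditions(imidazole_carryover_mM=c))
            for c in (0.0, 5.0, 20.0, 100.0)
        ]
        assert all(a > b for a, b in zip(effs, effs[1:]))
        assert effs[2] == 0.5  # c == K halves the efficiency

    def test_edc_carryover_has_no_effect(self, junction):
        up, down, splint = junction
        assert junction_efficiency(
            up, down, splint, ReactionConditions(edc_carryover_mM=500.0)
        ) == 1.0


class TestSimulateAssembly:
    def test_deterministic_full_length_is_exact_concatenation(self, demo_libs):
        plan = plan_data_gene(list("ABCBA"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        mix = simulate_plan(plan)
        assert len(mix.products) == 1
        tier2 = plan.final_tier
        expected = "".join(p.oligo.seq for p in tier2.pieces)
        assert mix.products[0].seq == expected
        assert len(mix.products[0].seq) == sum(len(p.oligo.seq) for p in tier2.pieces)

    def test_single_dead_junction_splits_chain(self, demo_libs):
        import dataclasses

        plan = plan_data_gene(list("ABCBA"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        tier2 = plan.final_tier
        j = tier2.junctions[2]
        tier2.junctions[2] = dataclasses.replace(
            j, catalytic_strand=j.catalytic_strand.with_motif("GGCT")
        )
        mix = simulate_assembly(tier2)
        spans = {p.span for p in mix.products}
        assert spans == {(0, 3), (3, 5)}
        assert mix.full_length_fraction == 0.0

    def test_stochastic_full_length_yield_matches_q_to_the_n_minus_1(self, demo_libs):
        plan = plan_data_gene(list("ABCBA"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        cond = ReactionConditions(p_base=0.5)
        n = 10_000
        mix = simulate_assembly(plan, cond, mode="stochastic",
                                n_molecules=n, seed=123)
        expected = 0.5**4  # four junctions
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(mix.full_length_fraction - expected) < 3 * se

    def test_stochastic_nucleotide_conservation(self, demo_libs):
        plan = plan_data_gene(list("ABC"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        tier2 = plan.final_tier
        n = 2_000
        mix = simulate_assembly(tier2, ReactionConditions(p_base=0.3),
                                mode="stochastic", n_molecules=n, seed=9)
        piece_total = sum(len(p.oligo.seq) for p in tier2.pieces)
        assert mix.total_nucleotides() == n * piece_total
        assert abs(sum(p.abundance for p in mix.products) - 1.0) < 1e-12

    def test_stochastic_reproducible_under_seed(self, demo_libs):
        plan = plan_data_gene(list("ABC"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        kwargs = dict(cond=ReactionConditions(p_base=0.4), mode="stochastic",
                      n_molecules=500, seed=77)
        a = simulate_assembly(plan, **kwargs)
        b = simulate_assembly(plan, **kwargs)
        assert [(p.span, p.count) for p in a.products] == \
               [(p.span, p.count) for p in b.products]

    def test_stochastic_requires_seed(self, demo_libs):
        plan = plan_data_gene(list("ABC"), "pair_linkers",
                              demo_libs.symbols, demo_libs.linkers)
        with pytest.raises(ValueError, match="seed"):
            simulate_assembly(plan, mode="stochastic", n_molecules=10)


class TestTwoComponent:
    @pytest.fixture()
    def self_substrate(self):
        sub = Oligo("G" + "TCAGGATCCTGAACTGGATTCCAGGATCCTGAACTGGATT" + "AGC",
                    ends=S1_ENDS)
        splint = design_catalytic_strand(sub, sub)
        return sub, splint

    def test_q_zero_gives_all_monomers(self, self_substrate):
        sub, splint = self_substrate
        d = simulate_two_component(sub, splint,
                                   ReactionConditions(zinc_present=False),
                                   n_molecules=500, seed=1)
        assert d.q == 0.0
        assert set(d.size_counts()) == {1}

    def test_mean_size_matches_geometric(self, self_substrate):
        sub, splint = self_substrate
        n = 10_000
        d = simulate_two_component(sub, splint, ReactionConditions(p_base=0.5),
                                   n_molecules=n, seed=11)
        # geometric mean 1/(1-q) = 2, var q/(1-q)^2 = 2
        se = np.sqrt(2.0 / n)
        assert abs(d.mean_size - 2.0) < 3 * se

    def test_high_q_reaches_eight_piece_assemblies(self, self_substrate):
        sub, splint = self_substrate
        d = simulate_two_component(sub, splint, ReactionConditions(p_base=0.8),
                                   n_molecules=10_000, seed=2)
        assert d.max_size >= 8  # P(size >= 8) = 0.8^7 ~ 0.21

    def test_bad_substrate_rejected(self, self_substrate):
        _, splint = self_substrate
        bad = Oligo("TTCAGGATCCTGAACAGC", ends=S1_ENDS)  # no 5' G
        with pytest.raises(ValueError, match="end constraints"):
            simulate_two_component(bad, splint)
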