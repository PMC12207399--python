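"""Symbol-oligo layout, linker generation, splint geometry, orthogonality."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from splintstore.library_design import (
    CANONICAL_MOTIF,
    DesignFailureError,
    LibraryDesignParams,
    design_catalytic_strand,
    design_linker_pairs,
    design_symbol_oligo,
    orthogonality_report,
)
from splintstore.sequence_core import (
    EndState,
    Oligo,
    S1_ENDS,
    hamming_distance,
    longest_complementary_run,
    reverse_complement,
)

payload8 = st.text(alphabet="ACGT", min_size=8, max_size=8)


def canonical_substrates():
    """A long S1/S2 pair satisfying the junction grammar."""
    up = Oligo("G" + "ATCCTGAACTGGATTC" + "AGC", ends=S1_ENDS)
    down = Oligo("G" + "TTGACCAGTATCGGAT" + "AGC", ends=S1_ENDS)
    return up, down


class TestSymbolOligo:
    def test_layout_and_chemistry(self):
        o = design_symbol_oligo("AAAAAAAA")
        assert o.seq == "GAAAAAAAAAGC"
        assert len(o.seq) == 12
        assert o.ends.three_prime == EndState.PHOSPHATE
        assert o.ends.five_prime == EndState.HYDROXYL

    @given(payload8)
    def test_junction_motif_rule_holds_for_any_payload(self, payload):
        o = design_symbol_oligo(payload)
        assert o.seq.startswith("G") and o.seq.endswith("AGC")

    def test_wrong_payload_length_rejected(self):
        with pytest.raises(ValueError):
            design_symbol_oligo("AAAAAAA")


class TestLinkerDesign:
    def test_deterministic_under_seed(self):
        params = LibraryDesignParams(n_linker_pairs=5, seed=42)
        a = design_linker_pairs(params)
        b = design_linker_pairs(params)
        assert [(l.seq, r.seq) for l, r in a.pairs] == [
            (l.seq, r.seq) for l, r in b.pairs
        ]

    def test_every_linker_obeys_junction_grammar(self, small_linker_library):
        for lk in small_linker_library.all_linkers():
            assert lk.seq.startswith("G") and lk.seq.endswith("AGC")
            assert lk.ends.three_prime == EndState.PHOSPHATE

    def test_symbol_connecting_region_constant_per_side(self, small_linker_library):
        lefts = {l.symbol_connecting_seq for l, _ in small_linker_library.pairs}
        rights = {r.symbol_connecting_seq for _, r in small_linker_library.pairs}
        assert len(lefts) == 1 and len(rights) == 1

    def test_linker_connecting_regions_distinct(self, small_linker_library):
        lcs = [lk.linker_connecting_seq for lk in small_linker_library.all_linkers()]
        assert len(set(lcs)) == len(lcs)

    def test_design_output_passes_its_own_screen(self, small_linker_library):
        report = orthogonality_report(small_linker_library)
        assert report.ok
        assert report.max_cross_run <= small_linker_library.params.max_cross_run
        assert report.min_hamming >= small_linker_library.params.min_hamming

    def test_impossible_constraints_fail_loudly(self):
        # 20-nt regions cannot all be 20 apart once more than a handful exist
        params = LibraryDesignParams(
            n_linker_pairs=8, min_hamming=20, max_retries=200, seed=0
        )
        with pytest.raises(DesignFailureError, match="binding constraint"):
            design_linker_pairs(params)


class TestCatalyticStrand:
    def test_default_geometry_13_24_10(self):
        up, down = canonical_substrates()
        cs = design_catalytic_strand(up, down)
        assert len(cs.arm_s2) == 13
        assert len(cs.core) == 24
        assert len(cs.arm_s1) == 10
        assert len(cs.seq) == 47

    def test_arms_are_reverse_complements_of_substrate_ends(self):
        up, down = canonical_substrates()
        cs = design_catalytic_strand(up, down)
        assert cs.arm_s1 == reverse_complement(up.seq[-10:])
        assert cs.arm_s2 == reverse_complement(down.seq[:13])

    def test_canonical_motif_is_cgct(self):
        up, down = canonical_substrates()
        cs = design_catalytic_strand(up, down)
        assert cs.motif == "CGCT" == CANONICAL_MOTIF
        assert cs.motif == reverse_complement(up.seq[-3:] + down.seq[0])
        assert cs.motif in cs.core

    def test_short_substrate_errors_unless_clamped(self):
        up, _ = canonical_substrates()
        short_down = design_symbol_oligo("ACGTACGT")  # 12 nt < 13-nt arm
        with pytest.raises(ValueError, match="too short"):
            design_catalytic_strand(up, short_down)
        cs = design_catalytic_strand(
            up, short_down, LibraryDesignParams(clamp_arms=True)
        )
        assert len(cs.arm_s2) == 12  # clamped to the substrate
        assert cs.arm_s2 == reverse_complement(short_down.seq)

    def test_missing_chemistry_rejected(self):
        from splintstore.sequence_core import TerminalChemistry

        up, down = canonical_substrates()
        blunt = up.with_ends(TerminalChemistry())  # 3'-OH: not ligatable
        with pytest.raises(ValueError, match="phosphate"):
            design_catalytic_strand(blunt, down)
        bad_down = Oligo("TTGACCTAGCTAGCAGC", ends=S1_ENDS)  # no leading G
        with pytest.raises(ValueError, match="start with G"):
            design_catalytic_strand(up, bad_down)

    def test_motif_mutation_helper(self):
        up, down = canonical_substrates()
        cs = design_catalytic_strand(up, down)
        mut = cs.with_motif("CGCA")
        assert mut.motif == "CGCA" and "CGCA" in mut.core
        assert mut.arm_s1 == cs.arm_s1 and mut.arm_s2 == cs.arm_s2


class TestOrthogonalityReport:
    def test_single_pair_library_clean(self):
        lib = design_linker_pairs(LibraryDesignParams(n_linker_pairs=1, seed=3))
        assert orthogonality_report(lib).ok

    def test_planted_reverse_complement_flagged(self):
        lib = design_linker_pairs(LibraryDesignParams(n_linker_pairs=2, seed=3))
        evil = Oligo(reverse_complement(lib.pairs[0][0].seq), label="evil")
        honest = Oligo(lib.pairs[0][0].seq, label="honest")
        report = orthogonality_report([honest, evil])
        assert not report.ok
        assert report.max_cross_run == len(evil.seq)
        assert any(v[0] == "cross_complementary_run" for v in report.violations)

    def test_metrics_equal_brute_force(self, small_linker_library):
        report = orthogonality_report(small_linker_library)
        seqs = [lk.seq for lk in small_linker_library.all_linkers()]
        brute_max = max(
            longest_complementary_run(a, b)
            for i, a in enumerate(seqs)
            for b in seqs[i:]
        )
        lcs = [lk.linker_connecting_seq for lk in small_linker_library.all_linkers()]
        brute_ham = min(
            hamming_distance(a, b)
            for i, a in enumerate(lcs)
            for b in lcs[i + 1 :]
        )
        assert report.max_cross_run == brute_max
        assert report.min_hamming == brute_ham

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            orthogonality_report([])
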