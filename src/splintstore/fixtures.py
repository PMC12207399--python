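"""Seeded demo fixtures: a three-symbol library, five linker pairs, and the
three five-symbol demonstration genes.

The published study assembled three data storage genes from symbols A, B, C
with five linker pairs; genes 1 and 2 set their order via the symbol-linker
pairing, gene 3 reused gene 2's complexes and reordered them by redesigning
the splint joins. The actual oligo sequences live in unpublished
supplementary data, so a seeded generator produces stand-in libraries
obeying all stated constraints; the symbol orders themselves are the
published ones.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .assembly_planner import AssemblyPlan, plan_data_gene
from .codec import SymbolLibrary
from .decoder import decode_assembly
from .library_design import LibraryDesignParams, LinkerLibrary, design_linker_pairs
from .ligation_simulator import ReactionConditions, simulate_plan

__all__ = ["DEMO_GENE_ORDERS", "DemoLibraries", "make_demo_libraries",
           "plan_demo_gene", "run_demo"]

#: The three demonstrated five-symbol gene orders and how each was realised.
DEMO_GENE_ORDERS: dict[str, dict] = {
    "gene1": {"order": list("ABCBA"), "mode": "pair_linkers"},
    "gene2": {"order": list("BCACB"), "mode": "pair_linkers"},
    # gene 3 reuses gene 2's symbol-linker complexes, reordered via the joins
    "gene3": {"order": list("CBCAB"), "mode": "design_joins",
              "reference": list("BCACB")},
}


@dataclass
class DemoLibraries:
    symbols: SymbolLibrary
    linkers: LinkerLibrary
    seed: int = 0


def _random_payloads(rng: random.Random, n: int, L: int) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        p = "".join(rng.choice("ACGT") for _ in range(L))
        # keep payloads at pairwise Hamming distance >= 3 so noisy-read
        # payload calls stay well separated
        if all(sum(a != b for a, b in zip(p, q)) >= 3 for q in out):
            out.add(p)
    return sorted(out)


def make_demo_libraries(seed: int = 0, n_pairs: int = 5) -> DemoLibraries:
    """Three distinct 8-nt symbol payloads (A, B, C) plus ``n_pairs`` linker
    pairs, all from one seed."""
    rng = random.Random(seed)
    payloads = _random_payloads(rng, 3, 8)
    symbols = SymbolLibrary(entries=dict(zip("ABC", payloads)))
    params = LibraryDesignParams(n_linker_pairs=n_pairs, seed=rng.randrange(2**31))
    linkers = design_linker_pairs(params, payloads=payloads)
    return DemoLibraries(symbols=symbols, linkers=linkers, seed=seed)


def plan_demo_gene(gene: str, libs: DemoLibraries) -> AssemblyPlan:
    spec = DEMO_GENE_ORDERS[gene]
    return plan_data_gene(
        spec["order"], spec["mode"], libs.symbols, libs.linkers,
        reference_order=spec.get("reference"),
    )


@dataclass
class DemoGeneResult:
    gene: str
    expected_order: list[str]
    decoded_order: list[str]
    bits_roundtrip_ok: bool

    @property
    def ok(self) -> bool:
        return self.decoded_order == self.expected_order and self.bits_roundtrip_ok


@dataclass
class DemoReport:
    seed: int
    genes: list[DemoGeneResult] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return sum(g.ok for g in self.genes)

    @property
    def all_ok(self) -> bool:
        return self.n_ok == len(self.genes)


def run_demo(seed: int = 42) -> DemoReport:
    """Full reproduction of the three demonstration genes: design libraries,
    plan each gene (two via symbol-linker pairing, one via join redesign),
    simulate the ligations deterministically, decode, and compare orders."""
    from .codec import symbols_to_bits

    libs = make_demo_libraries(seed)
    report = DemoReport(seed=seed)
    cond = ReactionConditions()
    for gene, spec in DEMO_GENE_ORDERS.items():
        plan = plan_demo_gene(gene, libs)
        mix = simulate_plan(plan, cond)
        assert len(mix.products) == 1, "deterministic demo assembly must go to completion"
        decoded = decode_assembly(mix.products[0].seq, libs.symbols, libs.linkers)
        expected_bits = symbols_to_bits(
            [libs.symbols.payload(n) for n in spec["order"]], libs.symbols
        )
        report.genes.append(
            DemoGeneResult(
                gene=gene,
                expected_order=spec["order"],
                decoded_order=decoded.symbol_order,
                bits_roundtrip_ok=decoded.bits == expected_bits,
            )
        )
    return report
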