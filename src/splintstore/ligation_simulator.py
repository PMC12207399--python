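"""Rule-level simulation of activation and catalytic-splint ligation.

The chemistry is modelled as gates and multipliers, not kinetics:

* a junction ligates only if Zn2+ is present, the upstream substrate has
  been activated to a 3' phosphorimidazolide and ends ...AGC, the
  downstream substrate starts with G on a 5' hydroxyl, and both splint arms
  are fully complementary to their targets;
* if all gates pass, the efficiency is the catalytic motif's relative
  activity (CGCT 100%, CGCA 16%, CGCC 50%, every single-base mutant of the
  other three positions inactive) scaled by imidazole inhibition
  ``1 / (1 + c / K)`` -- a monotone one-parameter model standing in for
  dose-response data that are not available numerically;
* stochastic mode treats each junction of each molecule as an independent
  Bernoulli trial with probability ``efficiency * p_base``; there is no
  diffusion, competition, or kinetic modelling. EDC carryover is tracked
  but has no effect on ligation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .assembly_planner import AssemblyPlan, AssemblyTier
from .library_design import CatalyticStrand, S1_SUFFIX, S2_PREFIX
from .sequence_core import EndState, Oligo

__all__ = [
    "DEFAULT_MOTIF_ACTIVITY",
    "ReactionConditions",
    "ChemistryError",
    "JunctionAssessment",
    "Product",
    "ProductMixture",
    "MultimerDistribution",
    "activate",
    "junction_efficiency",
    "junction_report",
    "simulate_assembly",
    "simulate_plan",
    "simulate_two_component",
]

#: Relative ligation activity of catalytic 4-mer motifs (fraction of the
#: unmutated CGCT motif's activity). Single-base mutants of the first three
#: positions (GGCT, TGCT, CCCT, CACT, CGGT, CGTT) show no activity and are
#: simply absent (lookup default 0). CGCC additionally produced unexpected
#: side products experimentally; those are not modelled structurally, only
#: the 50% main-product activity is kept (a warning is raised when used).
DEFAULT_MOTIF_ACTIVITY: Mapping[str, float] = {
    "CGCT": 1.00,
    "CGCA": 0.16,
    "CGCC": 0.50,
}

#: Wet-lab yields measured for the one- and two-tier assemblies; offered as
#: presets for calibrating p_base, never produced as predictions.
MEASURED_YIELD_PRESETS = {"three_piece": 0.40, "five_piece": 0.00082}


class ChemistryError(ValueError):
    """An oligo is in the wrong chemical state for the requested step."""


@dataclass
class ReactionConditions:
    """Rule-level reaction state.

    ``imidazole_carryover_mM`` is un-purified activation imidazole carried
    into the ligation; it inhibits ligation as ``1/(1 + c/K)`` with
    ``K = imidazole_inhibition_K_mM`` (default 20 mM, a model parameter).
    EDC carryover is tracked for reporting but does not inhibit.
    ``p_base`` is the per-junction baseline success probability used by the
    stochastic mode.
    """

    zinc_present: bool = True
    imidazole_carryover_mM: float = 0.0
    edc_carryover_mM: float = 0.0
    imidazole_inhibition_K_mM: float = 20.0
    p_base: float = 1.0
    activation_imidazole_mM: float = 20.0
    activation_edc_mM: float = 100.0
    motif_activity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_ACTIVITY)
    )

    def __post_init__(self) -> None:
        for name in ("imidazole_carryover_mM", "edc_carryover_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.imidazole_inhibition_K_mM <= 0:
            raise ValueError("imidazole_inhibition_K_mM must be > 0")
        if not 0.0 <= self.p_base <= 1.0:
            raise ValueError("p_base must lie in [0, 1]")
        for motif, v in self.motif_activity.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"motif activity for {motif} outside [0, 1]")
        best = max(self.motif_activity.values(), default=0.0)
        if self.motif_activity.get("CGCT", 0.0) != best:
            raise ValueError("CGCT must map to the maximum motif activity")

    @property
    def inhibition_factor(self) -> float:
        return 1.0 / (1.0 + self.imidazole_carryover_mM / self.imidazole_inhibition_K_mM)


def activate(
    o: Oligo,
    imidazole_mM: float = 20.0,
    edc_mM: float = 100.0,
    cond: ReactionConditions | None = None,
) -> Oligo:
    """Activate a 3'-phosphate oligo to the reactive phosphorimidazolide.

    Requires positive imidazole and EDC concentrations; a 3'-hydroxyl oligo
    cannot be activated (a 3' phosphate group is required on the S1
    substrate). Re-activating an already activated oligo is a no-op with a
    warning. If ``cond`` is given, the concentrations are recorded there as
    carryover for downstream inhibition accounting.
    """
    if imidazole_mM <= 0 or edc_mM <= 0:
        raise ValueError("activation needs positive imidazole and EDC concentrations")
    if o.ends.three_prime == EndState.PHOSPHORIMIDAZOLIDE:
        warnings.warn(f"oligo {o.label or o.seq[:10]} is already activated; no-op")
        return o
    if o.ends.three_prime != EndState.PHOSPHATE:
        raise ChemistryError(
            "cannot activate a 3'-hydroxyl oligo: a 3' phosphate group is required"
        )
    if cond is not None:
        cond.imidazole_carryover_mM = imidazole_mM
        cond.edc_carryover_mM = edc_mM
    return o.with_ends(replace(o.ends, three_prime=EndState.PHOSPHORIMIDAZOLIDE))


@dataclass(frozen=True)
class JunctionAssessment:
    efficiency: float
    reason: str  # "ok" or the gate that failed


def junction_report(
    upstream: Oligo,
    downstream: Oligo,
    splint: CatalyticStrand,
    cond: ReactionConditions | None = None,
) -> JunctionAssessment:
    """Assess one junction; efficiency 0 carries the failing gate's name."""
    cond = cond or ReactionConditions()
    if not cond.zinc_present:
        return JunctionAssessment(0.0, "no_zinc_cofactor")
    if upstream.ends.three_prime != EndState.PHOSPHORIMIDAZOLIDE:
        return JunctionAssessment(0.0, "upstream_not_activated")
    if not upstream.seq.endswith(S1_SUFFIX):
        return JunctionAssessment(0.0, "upstream_missing_3prime_AGC")
    if not downstream.seq.startswith(S2_PREFIX):
        return JunctionAssessment(0.0, "downstream_missing_5prime_G")
    if downstream.ends.five_prime != EndState.HYDROXYL:
        return JunctionAssessment(0.0, "downstream_not_5prime_hydroxyl")
    from .sequence_core import reverse_complement

    k1, k2 = len(splint.arm_s1), len(splint.arm_s2)
    if len(upstream.seq) < k1 or splint.arm_s1 != reverse_complement(upstream.seq[-k1:]):
        return JunctionAssessment(0.0, "arm_s1_hybridization_failure")
    if len(downstream.seq) < k2 or splint.arm_s2 != reverse_complement(downstream.seq[:k2]):
        return JunctionAssessment(0.0, "arm_s2_hybridization_failure")
    activity = cond.motif_activity.get(splint.motif, 0.0)
    if activity == 0.0:
        return JunctionAssessment(0.0, f"inactive_motif_{splint.motif}")
    if splint.motif == "CGCC":
        warnings.warn(
            "motif CGCC ligates at ~50% but also formed unexpected side "
            "products experimentally; side products are not modelled"
        )
    return JunctionAssessment(activity * cond.inhibition_factor, "ok")


def junction_efficiency(
    upstream: Oligo,
    downstream: Oligo,
    splint: CatalyticStrand,
    cond: ReactionConditions | None = None,
) -> float:
    """Relative ligation efficiency of one junction in [0, 1] (deterministic;
    all failure modes return 0 -- see :func:`junction_report` for reasons)."""
    return junction_report(upstream, downstream, splint, cond).efficiency


@dataclass(frozen=True)
class Product:
    """One (partial) assembly product: contiguous piece span, sequence, and
    how often it occurred."""

    span: tuple[int, int]  # half-open piece positions in chain order
    seq: str
    count: int
    abundance: float  # fraction of all product molecules in the mixture
    molecule_fraction: float  # count / number of simulated molecules


@dataclass
class ProductMixture:
    products: list[Product]
    mode: str  # "deterministic" | "stochastic"
    n_pieces: int
    n_molecules: int
    seed: int | None = None

    @property
    def full_length_fraction(self) -> float:
        """Fraction of simulated molecules assembled end-to-end."""
        for p in self.products:
            if p.span == (0, self.n_pieces):
                return p.molecule_fraction
        return 0.0

    def total_nucleotides(self) -> int:
        return sum(len(p.seq) * p.count for p in self.products)


def _activated_tier_oligos(tier: AssemblyTier, cond: ReactionConditions) -> list[Oligo]:
    """Activate the pieces the plan marks for activation (all but the
    3'-terminal S2)."""
    oligos = [p.oligo for p in tier.pieces]
    for i in tier.activated_pieces:
        if oligos[i].ends.three_prime != EndState.PHOSPHORIMIDAZOLIDE:
            oligos[i] = activate(
                oligos[i], cond.activation_imidazole_mM, cond.activation_edc_mM
            )
    return oligos


def _junction_probs(tier: AssemblyTier, cond: ReactionConditions) -> np.ndarray:
    oligos = _activated_tier_oligos(tier, cond)
    effs = []
    for j in tier.junctions:
        effs.append(
            junction_efficiency(
                oligos[j.upstream_piece], oligos[j.downstream_piece],
                j.catalytic_strand, cond,
            )
        )
    return np.asarray(effs, dtype=float)


def _fragments_from_pattern(ok: tuple[bool, ...]) -> list[tuple[int, int]]:
    """Maximal contiguous piece spans given per-junction success flags."""
    spans = []
    start = 0
    for i, success in enumerate(ok):
        if not success:
            spans.append((start, i + 1))
            start = i + 1
    spans.append((start, len(ok) + 1))
    return spans


def simulate_assembly(
    plan: AssemblyTier | AssemblyPlan,
    cond: ReactionConditions | None = None,
    mode: str = "deterministic",
    n_molecules: int = 1,
    seed: int | None = None,
) -> ProductMixture:
    """Simulate one tier's ligation reaction.

    Deterministic mode: a single full-length product (the exact
    concatenation of piece sequences in chain order) iff every junction has
    efficiency > 0; otherwise the chain splits into maximal fragments at the
    dead junctions. Stochastic mode: each of ``n_molecules`` molecules
    succeeds independently at junction j with probability
    ``efficiency_j * p_base``; the mixture lists every contiguous fragment
    species with empirical abundances (reproducible under a fixed seed).
    """
    tier = plan.final_tier if isinstance(plan, AssemblyPlan) else plan
    cond = cond or ReactionConditions()
    probs = _junction_probs(tier, cond)
    seqs = [p.oligo.seq for p in tier.pieces]
    n_pieces = len(seqs)

    def product(span: tuple[int, int], count: int, total_frags: int, n_mol: int) -> Product:
        return Product(
            span=span,
            seq="".join(seqs[span[0] : span[1]]),
            count=count,
            abundance=count / total_frags,
            molecule_fraction=count / n_mol,
        )

    if mode == "deterministic":
        spans = _fragments_from_pattern(tuple(probs > 0))
        return ProductMixture(
            products=[product(s, 1, len(spans), 1) for s in spans],
            mode=mode, n_pieces=n_pieces, n_molecules=1,
        )
    if mode != "stochastic":
        raise ValueError(f"mode must be 'deterministic' or 'stochastic', got {mode!r}")
    if n_molecules < 1:
        raise ValueError("stochastic mode needs n_molecules >= 1")
    if seed is None:
        raise ValueError("stochastic mode needs a seed")

    rng = np.random.default_rng(seed)
    success = rng.random((n_molecules, len(probs))) < (probs * cond.p_base)
    patterns, counts = np.unique(success, axis=0, return_counts=True)
    span_counts: dict[tuple[int, int], int] = {}
    for pattern, c in zip(patterns, counts):
        for span in _fragments_from_pattern(tuple(bool(x) for x in pattern)):
            span_counts[span] = span_counts.get(span, 0) + int(c)
    total = sum(span_counts.values())
    products = [
        product(span, c, total, n_molecules)
        for span, c in sorted(span_counts.items())
    ]
    return ProductMixture(products=products, mode=mode, n_pieces=n_pieces,
                          n_molecules=n_molecules, seed=seed)


def simulate_plan(
    plan: AssemblyPlan, cond: ReactionConditions | None = None
) -> ProductMixture:
    """Deterministically run every tier of a plan in order and return the
    final tier's mixture (tier-1 products are by construction the tier-2
    piece sequences; this verifies that invariant as it goes)."""
    cond = cond or ReactionConditions()
    for i, sub in enumerate(plan.first_tier):
        mix = simulate_assembly(sub, cond, mode="deterministic")
        if len(mix.products) != 1:
            raise ChemistryError(f"tier-1 assembly {i} failed to go to completion")
    return simulate_assembly(plan.final_tier, cond, mode="deterministic")


@dataclass
class MultimerDistribution:
    """Per-molecule chain lengths from the two-component (self-S1/S2)
    concatemer regime; sizes follow Geometric(1 - q)."""

    sizes: np.ndarray
    q: float
    seed: int

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes))

    @property
    def max_size(self) -> int:
        return int(np.max(self.sizes))

    def size_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.sizes, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def simulate_two_component(
    substrate: Oligo,
    splint: CatalyticStrand,
    cond: ReactionConditions | None = None,
    n_molecules: int = 10_000,
    seed: int = 0,
) -> MultimerDistribution:
    """Simulate the unbounded concatemer regime in which a single substrate
    serves as both S1 and S2 (its splint clamps the substrate's own ends),
    so chain growth is limited only by per-junction success.

    Each molecule's chain extends while successive junctions succeed with
    probability ``q = junction efficiency * p_base``; sizes are therefore
    geometric with parameter ``1 - q`` (mean ``1/(1-q)``).
    """
    cond = cond or ReactionConditions()
    if not substrate.seq.startswith(S2_PREFIX) or not substrate.seq.endswith(S1_SUFFIX):
        raise ValueError(
            "two-component substrate must satisfy both end constraints "
            f"(start {S2_PREFIX}, end {S1_SUFFIX})"
        )
    if substrate.ends.five_prime != EndState.HYDROXYL:
        raise ValueError("two-component substrate needs a 5' hydroxyl")
    upstream = substrate
    if upstream.ends.three_prime == EndState.PHOSPHATE:
        upstream = activate(upstream, cond.activation_imidazole_mM,
                            cond.activation_edc_mM)
    elif upstream.ends.three_prime != EndState.PHOSPHORIMIDAZOLIDE:
        raise ValueError("two-component substrate needs an activatable 3' phosphate")

    q = junction_efficiency(upstream, substrate, splint, cond) * cond.p_base
    rng = np.random.default_rng(seed)
    if q >= 1.0:
        raise ValueError("q = 1 gives unbounded chains; reduce p_base or efficiency")
    if q == 0.0:
        sizes = np.ones(n_molecules, dtype=np.int64)
    else:
        sizes = rng.geometric(1.0 - q, size=n_molecules)
    return MultimerDistribution(sizes=sizes, q=q, seed=seed)
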