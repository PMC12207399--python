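"""Design of symbol oligos, linker pairs, and catalytic (splint) strands.

The E47 ligating DNAzyme imposes a hard junction grammar: the upstream (S1)
substrate of every junction must end 5'-...AGC-3' and carry a 3' phosphate,
and the downstream (S2) substrate must begin with G carrying a 5' hydroxyl.
The reverse complement of the four junction bases (AGC|G) is the splint's
catalytic motif, canonically 5'-CGCT-3'. Everything designed here obeys that
grammar:

* a symbol oligo is ``G + payload + AGC`` (the motif bases sit outside the
  encoding region);
* a left linker is ``linker_connecting + symbol_connecting`` and a right
  linker is the mirror image, so every piece of an assembly starts with G
  and ends with AGC;
* a catalytic strand is ``arm_S2 + core + arm_S1`` where the arms are the
  reverse complements of the substrate ends they clamp (13 and 10 nt by
  default) and the core is a 24-nt catalytic region carrying the motif.

The symbol-connecting region is shared by all linkers of a side, so any
linker attaches to any symbol with the same pair of splints; the
linker-connecting regions are unique per linker and dictate which neighbour
a piece joins. Linker-connecting regions are screened for mutual Hamming
distance and all designed strands for cross-complementary runs
(rejection sampling under a fixed seed; design is bit-identical across runs).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .sequence_core import (
    EndState,
    Oligo,
    OligoRole,
    S1_ENDS,
    S2_ENDS,
    TerminalChemistry,
    clean_sequence,
    hamming_distance,
    longest_complementary_run,
    reverse_complement,
)

__all__ = [
    "S1_SUFFIX",
    "S2_PREFIX",
    "CANONICAL_MOTIF",
    "DEFAULT_CORE_TEMPLATE",
    "DesignFailureError",
    "LibraryDesignParams",
    "Linker",
    "LinkerLibrary",
    "CatalyticStrand",
    "OrthogonalityReport",
    "design_symbol_oligo",
    "design_linker_pairs",
    "design_catalytic_strand",
    "orthogonality_report",
]

#: Required 3'-terminal motif of every upstream (S1) substrate.
S1_SUFFIX = "AGC"
#: Required 5'-terminal base of every downstream (S2) substrate.
S2_PREFIX = "G"
#: reverse_complement(S1_SUFFIX + S2_PREFIX): the active catalytic motif.
CANONICAL_MOTIF = reverse_complement(S1_SUFFIX + S2_PREFIX)  # "CGCT"

# The true E47 catalytic core is figure-only in the source literature; the
# simulation depends only on the 4-nt motif, so the core outside the motif is
# an arbitrary fixed 24-mer (configurable via LibraryDesignParams).
DEFAULT_CORE_TEMPLATE = "TTACGAGTCG" + CANONICAL_MOTIF + "AGGTCACTAA"
DEFAULT_MOTIF_OFFSET = 10


class DesignFailureError(RuntimeError):
    """Rejection sampling exhausted its retry budget; names the binding constraint."""


@dataclass
class LibraryDesignParams:
    """Knobs for library generation.

    Arm lengths follow the E47 architecture (24-nt catalytic core, 13-nt arm
    clamping the downstream/S2 substrate, 10-nt arm clamping the upstream/S1
    substrate; which arm is which is configurable). Region lengths default to
    20 nt (linker-connecting) and 13 nt (symbol-connecting) so that a full
    arm always lands inside a single region. Orthogonality thresholds are
    standard barcode-design heuristics.
    """

    n_linker_pairs: int = 5
    arm_s1_len: int = 10  # k1: clamps the upstream substrate's 3' end
    arm_s2_len: int = 13  # k2: clamps the downstream substrate's 5' end
    linker_connecting_len: int = 20
    symbol_connecting_len: int = 13
    min_hamming: int = 8
    max_cross_run: int = 6
    seed: int = 0
    core_template: str = DEFAULT_CORE_TEMPLATE
    motif_offset: int = DEFAULT_MOTIF_OFFSET
    max_retries: int = 10_000
    # Allow arms shorter than k when the substrate itself is shorter (a
    # 12-nt symbol oligo cannot host a 13-nt arm). Off by default; the
    # planners enable it for symbol-adjacent junctions.
    clamp_arms: bool = False

    def __post_init__(self) -> None:
        if self.n_linker_pairs < 1:
            raise ValueError("n_linker_pairs must be >= 1")
        for name in ("arm_s1_len", "arm_s2_len", "min_hamming", "max_cross_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        longest_arm = max(self.arm_s1_len, self.arm_s2_len)
        if self.symbol_connecting_len < longest_arm:
            raise ValueError(
                "symbol_connecting_len must be >= the longer arm so a full arm "
                "lands inside one region"
            )
        if self.linker_connecting_len < longest_arm:
            raise ValueError("linker_connecting_len must be >= the longer arm")
        if len(self.core_template) != 24:
            raise ValueError("catalytic core template must be 24 nt")
        if not 0 <= self.motif_offset <= 20:
            raise ValueError("motif_offset must place the 4-mer inside the core")


@dataclass(frozen=True)
class Linker:
    """A left or right linker: one constant symbol-connecting region and one
    unique linker-connecting region, with the junction grammar at both ends."""

    side: str  # "left" | "right"
    index: int
    seq: str
    symbol_connecting_region: tuple[int, int]  # half-open interval on seq
    linker_connecting_region: tuple[int, int]
    ends: TerminalChemistry = S1_ENDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq, allow_empty=False))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.index < 1:
            raise ValueError("linker index must be a positive integer")
        if not self.seq.startswith(S2_PREFIX) or not self.seq.endswith(S1_SUFFIX):
            raise ValueError(
                f"linker must start with {S2_PREFIX} and end with {S1_SUFFIX}"
            )
        if self.ends.three_prime == EndState.HYDROXYL:
            raise ValueError("linker 3' terminus must be a phosphate (ligatable)")

    @property
    def symbol_connecting_seq(self) -> str:
        a, b = self.symbol_connecting_region
        return self.seq[a:b]

    @property
    def linker_connecting_seq(self) -> str:
        a, b = self.linker_connecting_region
        return self.seq[a:b]

    def to_oligo(self) -> Oligo:
        role = OligoRole.LEFT_LINKER if self.side == "left" else OligoRole.RIGHT_LINKER
        return Oligo(self.seq, self.ends, label=f"{self.side}_linker_{self.index}", role=role)


@dataclass
class LinkerLibrary:
    """Paired left/right linkers sharing per-side symbol-connecting regions."""

    pairs: list[tuple[Linker, Linker]]
    params: LibraryDesignParams
    sc_left: str = ""
    sc_right: str = ""

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("library must contain at least one linker pair")
        if not self.sc_left:
            self.sc_left = self.pairs[0][0].symbol_connecting_seq
        if not self.sc_right:
            self.sc_right = self.pairs[0][1].symbol_connecting_seq

    def left(self, index: int) -> Linker:
        return self._get("left", index)

    def right(self, index: int) -> Linker:
        return self._get("right", index)

    def _get(self, side: str, index: int) -> Linker:
        pos = 0 if side == "left" else 1
        for pair in self.pairs:
            if pair[pos].index == index:
                return pair[pos]
        raise KeyError(f"no {side} linker with index {index}")

    def all_linkers(self) -> list[Linker]:
        return [lk for pair in self.pairs for lk in pair]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class CatalyticStrand:
    """An E47-style catalytic splint: arm_S2 + 24-nt core + arm_S1 (5'->3').

    ``arm_S2`` is the reverse complement of the first ``len(arm_S2)`` nt of
    the downstream substrate and ``arm_S1`` the reverse complement of the
    last ``len(arm_S1)`` nt of the upstream substrate. ``motif`` is the 4-mer
    at the core's junction-facing position; only it (plus zinc and substrate
    chemistry) determines simulated ligation activity.
    """

    arm_s2: str
    core: str
    arm_s1: str
    motif: str
    label: str = ""
    intended_upstream: str = ""  # substrate sequences the arms were built for
    intended_downstream: str = ""

    def __post_init__(self) -> None:
        for name in ("arm_s2", "core", "arm_s1", "motif"):
            object.__setattr__(self, name, clean_sequence(getattr(self, name)))
        if len(self.core) != 24:
            raise ValueError("catalytic core must be 24 nt")
        if len(self.motif) != 4 or self.motif not in self.core:
            raise ValueError("motif must be a 4-mer present in the core")

    @property
    def seq(self) -> str:
        return self.arm_s2 + self.core + self.arm_s1

    def __len__(self) -> int:
        return len(self.seq)

    def with_motif(self, motif: str) -> "CatalyticStrand":
        """Return a copy whose core carries ``motif`` at the junction position
        (used to probe motif mutants)."""
        motif = clean_sequence(motif)
        if len(motif) != 4:
            raise ValueError("catalytic motif must be 4 nt")
        i = self.core.index(self.motif)
        core = self.core[:i] + motif + self.core[i + 4 :]
        return replace(self, core=core, motif=motif)

    def to_oligo(self) -> Oligo:
        return Oligo(self.seq, label=self.label or "catalytic_strand",
                     role=OligoRole.CATALYTIC_STRAND)


def design_symbol_oligo(payload: str, L_sym: int = 8) -> Oligo:
    """Wrap a payload in the junction grammar: ``G + payload + AGC``,
    5'-hydroxyl / 3'-phosphate, so the symbol can act as S2 on its left
    junction and (after activation) as S1 on its right junction."""
    payload = clean_sequence(payload)
    if len(payload) != L_sym:
        raise ValueError(f"payload must be {L_sym} nt, got {len(payload)}")
    return Oligo(
        S2_PREFIX + payload + S1_SUFFIX,
        ends=S1_ENDS,
        label=f"symbol:{payload}",
        role=OligoRole.SYMBOL,
    )


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _cross_run_ok(candidate: str, accepted: Iterable[str], limit: int) -> bool:
    if longest_complementary_run(candidate, candidate) > limit:
        return False
    return all(longest_complementary_run(candidate, s) <= limit for s in accepted)


def _sample(
    rng: random.Random,
    make: "callable",
    checks: "list[tuple[str, callable]]",
    max_retries: int,
    what: str,
) -> str:
    fail_counts: dict[str, int] = {}
    for _ in range(max_retries):
        cand = make()
        for name, ok in checks:
            if not ok(cand):
                fail_counts[name] = fail_counts.get(name, 0) + 1
                break
        else:
            return cand
    worst = max(fail_counts, key=fail_counts.get) if fail_counts else "unknown"
    raise DesignFailureError(
        f"could not design {what} after {max_retries} attempts; "
        f"binding constraint: {worst} ({fail_counts})"
    )


def design_linker_pairs(
    params: LibraryDesignParams,
    payloads: Sequence[str] = (),
) -> LinkerLibrary:
    """Generate ``n_linker_pairs`` left/right linker pairs by seeded rejection
    sampling.

    All linkers obey the junction grammar; the two per-side symbol-connecting
    regions are designed once and shared; every linker-connecting region is
    unique with pairwise Hamming distance >= ``min_hamming``; no two designed
    strands (nor any strand against the symbol oligos implied by
    ``payloads``) share a complementary run longer than ``max_cross_run``.
    Pure function of the seed. Raises :class:`DesignFailureError` when the
    constraint space is exhausted.
    """
    rng = random.Random(params.seed)
    limit = params.max_cross_run
    accepted: list[str] = [
        design_symbol_oligo(p, L_sym=len(clean_sequence(p))).seq for p in payloads
    ]

    sc_len = params.symbol_connecting_len
    sc_left = _sample(
        rng,
        lambda: _random_seq(rng, sc_len - len(S1_SUFFIX)) + S1_SUFFIX,
        [("cross_complementary_run", lambda c: _cross_run_ok(c, accepted, limit))],
        params.max_retries,
        "left symbol-connecting region",
    )
    accepted.append(sc_left)
    sc_right = _sample(
        rng,
        lambda: S2_PREFIX + _random_seq(rng, sc_len - len(S2_PREFIX)),
        [("cross_complementary_run", lambda c: _cross_run_ok(c, accepted, limit))],
        params.max_retries,
        "right symbol-connecting region",
    )
    accepted.append(sc_right)

    lc_len = params.linker_connecting_len
    lc_regions: list[str] = []
    pairs: list[tuple[Linker, Linker]] = []
    for index in range(1, params.n_linker_pairs + 1):
        lc_left = _sample(
            rng,
            lambda: S2_PREFIX + _random_seq(rng, lc_len - len(S2_PREFIX)),
            [
                ("min_hamming_distance",
                 lambda c: all(hamming_distance(c, x) >= params.min_hamming for x in lc_regions)),
                ("cross_complementary_run",
                 lambda c: _cross_run_ok(c + sc_left, accepted, limit)),
            ],
            params.max_retries,
            f"left linker-connecting region {index}",
        )
        left_seq = lc_left + sc_left
        lc_regions.append(lc_left)
        accepted.append(left_seq)
        left = Linker(
            side="left", index=index, seq=left_seq,
            linker_connecting_region=(0, lc_len),
            symbol_connecting_region=(lc_len, lc_len + sc_len),
        )

        lc_right = _sample(
            rng,
            lambda: _random_seq(rng, lc_len - len(S1_SUFFIX)) + S1_SUFFIX,
            [
                ("min_hamming_distance",
                 lambda c: all(hamming_distance(c, x) >= params.min_hamming for x in lc_regions)),
                ("cross_complementary_run",
                 lambda c: _cross_run_ok(sc_right + c, accepted, limit)),
            ],
            params.max_retries,
            f"right linker-connecting region {index}",
        )
        right_seq = sc_right + lc_right
        lc_regions.append(lc_right)
        accepted.append(right_seq)
        right = Linker(
            side="right", index=index, seq=right_seq,
            symbol_connecting_region=(0, sc_len),
            linker_connecting_region=(sc_len, sc_len + lc_len),
        )
        pairs.append((left, right))

    return LinkerLibrary(pairs=pairs, params=params, sc_left=sc_left, sc_right=sc_right)


def design_catalytic_strand(
    upstream: Oligo,
    downstream: Oligo,
    params: LibraryDesignParams | None = None,
    label: str = "",
) -> CatalyticStrand:
    """Build the splint for one junction from its two substrates.

    The arms are reverse complements of the substrate ends (13 nt on the
    downstream/S2 side, 10 nt on the upstream/S1 side by default); the motif
    is the reverse complement of the four junction bases, substituted into
    the core template. With canonical substrates the motif is CGCT and the
    strand is 47 nt.
    """
    params = params or LibraryDesignParams()
    if not upstream.seq.endswith(S1_SUFFIX):
        raise ValueError(f"upstream substrate must end with {S1_SUFFIX}")
    if upstream.ends.three_prime not in (EndState.PHOSPHATE, EndState.PHOSPHORIMIDAZOLIDE):
        raise ValueError("upstream substrate needs a 3' phosphate (or activated) terminus")
    if not downstream.seq.startswith(S2_PREFIX):
        raise ValueError(f"downstream substrate must start with {S2_PREFIX}")
    if downstream.ends.five_prime != EndState.HYDROXYL:
        raise ValueError("downstream substrate needs a 5' hydroxyl")

    k1, k2 = params.arm_s1_len, params.arm_s2_len
    if len(upstream.seq) < k1 or len(downstream.seq) < k2:
        if params.clamp_arms:
            k1 = min(k1, len(upstream.seq))
            k2 = min(k2, len(downstream.seq))
        else:
            raise ValueError(
                f"substrate too short for arm (need {k1}/{k2} nt, have "
                f"{len(upstream.seq)}/{len(downstream.seq)}); "
                "set clamp_arms=True to shorten arms to the substrate"
            )

    motif = reverse_complement(upstream.seq[-3:] + downstream.seq[0])
    core = (
        params.core_template[: params.motif_offset]
        + motif
        + params.core_template[params.motif_offset + 4 :]
    )
    return CatalyticStrand(
        arm_s2=reverse_complement(downstream.seq[:k2]),
        core=core,
        arm_s1=reverse_complement(upstream.seq[-k1:]),
        motif=motif,
        label=label,
        intended_upstream=upstream.seq,
        intended_downstream=downstream.seq,
    )


@dataclass
class OrthogonalityReport:
    """Deterministic screening summary for a designed library."""

    max_cross_run: int
    min_hamming: int | None
    violations: list[tuple[str, str, str, int]] = field(default_factory=list)
    # each violation: (kind, name_a, name_b, observed value)

    @property
    def ok(self) -> bool:
        return not self.violations


def orthogonality_report(
    lib: LinkerLibrary | Sequence[Oligo],
    payloads: Sequence[str] = (),
    catalytic_strands: Sequence[CatalyticStrand] = (),
    params: LibraryDesignParams | None = None,
) -> OrthogonalityReport:
    """Re-screen a library from scratch: pairwise cross-complementary runs
    over all strands (including each against itself), pairwise Hamming
    distance over linker-connecting regions, and splint-arm specificity
    (no arm may complement any substrate other than its intended target
    beyond the threshold). Reports; never mutates."""
    if isinstance(lib, LinkerLibrary):
        params = params or lib.params
        named: list[tuple[str, str]] = [
            (f"{lk.side}_linker_{lk.index}", lk.seq) for lk in lib.all_linkers()
        ]
        lc_named = [
            (f"{lk.side}_lc_{lk.index}", lk.linker_connecting_seq)
            for lk in lib.all_linkers()
        ]
    else:
        params = params or LibraryDesignParams()
        named = [(o.label or f"oligo_{i}", o.seq) for i, o in enumerate(lib)]
        lc_named = []
    if not named:
        raise ValueError("cannot screen an empty library")
    named += [
        (f"symbol_oligo:{p}", design_symbol_oligo(p, L_sym=len(p)).seq) for p in payloads
    ]

    violations: list[tuple[str, str, str, int]] = []
    max_run = 0
    for i, (na, sa) in enumerate(named):
        for nb, sb in named[i:]:
            run = longest_complementary_run(sa, sb)
            max_run = max(max_run, run)
            if run > params.max_cross_run:
                violations.append(("cross_complementary_run", na, nb, run))

    min_ham: int | None = None
    for i, (na, sa) in enumerate(lc_named):
        for nb, sb in lc_named[i + 1 :]:
            d = hamming_distance(sa, sb)
            min_ham = d if min_ham is None else min(min_ham, d)
            if d < params.min_hamming:
                violations.append(("hamming_distance", na, nb, d))

    for cs in catalytic_strands:
        for arm_name, arm in (("arm_s1", cs.arm_s1), ("arm_s2", cs.arm_s2)):
            for nb, sb in named:
                if sb in (cs.intended_upstream, cs.intended_downstream):
                    continue
                run = longest_complementary_run(arm, sb)
                if run > params.max_cross_run:
                    violations.append(
                        (f"splint_{arm_name}_off_target", cs.label or cs.seq[:10], nb, run)
                    )

    return OrthogonalityReport(max_cross_run=max_run, min_hamming=min_ham,
                               violations=violations)
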