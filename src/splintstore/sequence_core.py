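"""Nucleotide-sequence primitives and terminal chemistry.

Every strand in the package is a plain uppercase string over ``{A, C, G, T}``
read 5'->3'. Ligation chemistry is tracked per oligo as the state of its two
termini: the upstream (S1) substrate of a junction needs a 3' phosphate that
is activated to a phosphorimidazolide, while the downstream (S2) substrate
needs a free 5' hydroxyl. No IUPAC ambiguity codes are accepted anywhere --
the scheme works with fully specified synthetic oligos.

All positions are 0-based and intervals half-open on the 5'->3' string.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "ALPHABET",
    "AlphabetError",
    "EndState",
    "TerminalChemistry",
    "OligoRole",
    "Oligo",
    "clean_sequence",
    "reverse_complement",
    "longest_complementary_run",
    "hamming_distance",
]

ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


class EndState(str, enum.Enum):
    """Chemical state of an oligo terminus."""

    HYDROXYL = "hydroxyl"
    PHOSPHATE = "phosphate"
    # Reactive leaving-group species formed by treating a 3' phosphate with
    # imidazole and EDC; reachable only via ligation_simulator.activate.
    PHOSPHORIMIDAZOLIDE = "phosphorimidazolide"


@dataclass(frozen=True)
class TerminalChemistry:
    """End chemistry of an oligo: 5' is OH or phosphate; 3' may also be activated."""

    five_prime: EndState = EndState.HYDROXYL
    three_prime: EndState = EndState.HYDROXYL

    def __post_init__(self) -> None:
        if self.five_prime == EndState.PHOSPHORIMIDAZOLIDE:
            raise ValueError("a 5' terminus cannot be a phosphorimidazolide")


#: Chemistry of a ligation-ready upstream (S1) substrate before activation.
S1_ENDS = TerminalChemistry(EndState.HYDROXYL, EndState.PHOSPHATE)
#: Chemistry of a downstream (S2) substrate.
S2_ENDS = TerminalChemistry(EndState.HYDROXYL, EndState.HYDROXYL)


class OligoRole(str, enum.Enum):
    SYMBOL = "symbol"
    LEFT_LINKER = "left_linker"
    RIGHT_LINKER = "right_linker"
    CATALYTIC_STRAND = "catalytic_strand"
    ASSEMBLY_PRODUCT = "assembly_product"
    GENERIC = "generic"


@dataclass(frozen=True)
class Oligo:
    """A single-stranded oligo: sequence, end chemistry, and a role label."""

    seq: str
    ends: TerminalChemistry = field(default_factory=TerminalChemistry)
    label: str = ""
    role: OligoRole = OligoRole.GENERIC

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq))
        if self.role == OligoRole.CATALYTIC_STRAND and self.ends != TerminalChemistry():
            raise ValueError("catalytic strands carry plain hydroxyl termini")

    def __len__(self) -> int:
        return len(self.seq)

    def with_ends(self, ends: TerminalChemistry) -> "Oligo":
        return replace(self, ends=ends)


def clean_sequence(s: str, allow_empty: bool = True) -> str:
    """Validate and normalize a nucleotide string.

    Lowercase input is accepted and upper-cased with a warning (FASTA
    dialects vary); anything outside {A, C, G, T} raises
    :class:`AlphabetError`.
    """
    if not isinstance(s, str):
        raise TypeError(f"expected str, got {type(s).__name__}")
    if s != s.upper():
        warnings.warn("lowercase bases normalized to uppercase", stacklevel=2)
        s = s.upper()
    if not allow_empty and not s:
        raise ValueError("empty sequence not allowed here")
    bad = set(s) - ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)} (only A/C/G/T allowed)")
    return s


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement of a 5'->3' sequence (still 5'->3')."""
    return clean_sequence(s).translate(_COMPLEMENT)[::-1]


def longest_complementary_run(a: str, b: str) -> int:
    """Length of the longest contiguous stretch of ``a`` whose reverse
    complement occurs in ``b``.

    This is the cross-hybridization proxy used for orthogonality screening:
    a long run means the two strands can form a stable duplex. Symmetric in
    its arguments. Equivalent to the longest common substring of ``a`` and
    ``reverse_complement(b)``, computed by dynamic programming.
    """
    a = clean_sequence(a, allow_empty=False)
    b = clean_sequence(b, allow_empty=False)
    rb = reverse_complement(b)
    # classic O(len(a)*len(b)) longest-common-substring DP, rolling row
    best = 0
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0] * (len(rb) + 1)
        for j, cb in enumerate(rb, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def hamming_distance(a: str, b: str) -> int:
    """Positionwise mismatch count between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))
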