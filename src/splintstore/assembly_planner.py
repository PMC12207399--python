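"""Turn a desired symbol order into a tiered assembly plan.

Tier 1 attaches a left and a right linker to each symbol (a three-piece
ligation: three substrates, two splints). Tier 2 chains the resulting
symbol-linker complexes (a five-piece ligation for five symbols: five
substrates, four splints). Two mechanisms realise an order:

* ``pair_linkers`` -- assign linker pair i to the i-th symbol of the
  requested order and join consecutively (right i -> left i+1);
* ``design_joins`` -- keep a fixed canonical symbol/linker pairing and
  compute the splint joins so the chain visits the pieces in the requested
  order.

In every tier the chain's 3'-terminal piece is the lone S2 subunit; all
other pieces are upstream of some junction and are marked for activation.
The geometric growth accounting (k pieces per step, m steps -> k^m symbols)
lives in :func:`growth_stats`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

from .codec import SymbolLibrary
from .library_design import (
    CatalyticStrand,
    Linker,
    LibraryDesignParams,
    LinkerLibrary,
    S1_SUFFIX,
    S2_PREFIX,
    design_catalytic_strand,
    design_symbol_oligo,
)
from .sequence_core import EndState, Oligo, OligoRole, S1_ENDS

__all__ = [
    "Piece",
    "JoinSpec",
    "Junction",
    "AssemblyTier",
    "AssemblyPlan",
    "TierStats",
    "TopologyError",
    "plan_first_tier",
    "plan_data_gene",
    "order_from_joins",
    "growth_stats",
]


class TopologyError(ValueError):
    """The join graph is not a single simple path over all pieces."""


@dataclass(frozen=True)
class Piece:
    """One substrate of a tier: a bare oligo (tier 1) or a symbol-linker
    complex (tier 2+), flanked by linker indices when applicable."""

    oligo: Oligo
    left_linker_index: int | None = None
    right_linker_index: int | None = None
    tier: int = 1
    symbol_name: str = ""

    def __post_init__(self) -> None:
        if not self.oligo.seq.startswith(S2_PREFIX) or not self.oligo.seq.endswith(S1_SUFFIX):
            raise ValueError(
                f"piece sequence must start with {S2_PREFIX} and end with {S1_SUFFIX}"
            )


@dataclass(frozen=True)
class JoinSpec:
    """One splint-mediated join: which right linker meets which left linker."""

    upstream_right_linker_index: int
    downstream_left_linker_index: int


@dataclass(frozen=True)
class Junction:
    """A junction between two adjacent pieces of a tier's chain."""

    upstream_piece: int  # positions in the tier's chain-ordered piece list
    downstream_piece: int
    catalytic_strand: CatalyticStrand
    join: JoinSpec | None = None  # linker-mediated joins only (tier 2+)


@dataclass
class AssemblyTier:
    """Pieces in chain order, their junctions, and the role assignment."""

    pieces: list[Piece]
    junctions: list[Junction]
    tier: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pieces)
        if len(self.junctions) != n - 1:
            raise TopologyError(
                f"a tier with {n} pieces needs exactly {n - 1} junctions, "
                f"got {len(self.junctions)}"
            )

    @property
    def joins(self) -> list[JoinSpec]:
        return [j.join for j in self.junctions if j.join is not None]

    @property
    def catalytic_strands(self) -> list[CatalyticStrand]:
        return [j.catalytic_strand for j in self.junctions]

    @property
    def activated_pieces(self) -> list[int]:
        """Chain positions that must be activated (every piece but the
        3'-terminal one, which is the tier's lone S2 subunit)."""
        return list(range(len(self.pieces) - 1))

    @property
    def s2_piece(self) -> int:
        return len(self.pieces) - 1

    @property
    def product_seq(self) -> str:
        return "".join(p.oligo.seq for p in self.pieces)


@dataclass
class AssemblyPlan:
    """Ordered tiers realising a symbol order; tier 1 is a list of
    three-piece sub-assemblies, later tiers chain their products."""

    first_tier: list[AssemblyTier]
    later_tiers: list[AssemblyTier]
    symbol_order: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def final_tier(self) -> AssemblyTier:
        return self.later_tiers[-1] if self.later_tiers else self.first_tier[-1]


@dataclass(frozen=True)
class TierStats:
    """Geometric growth accounting: m k-piece steps hold k^m symbols."""

    k: int
    m: int
    symbols: int
    bits: int


def growth_stats(k: int, m: int, bits_per_symbol: int = 16) -> TierStats:
    """Symbols and bits after ``m`` assembly steps joining ``k`` pieces each
    (exact integer arithmetic). One 8-nt symbol holds 16 bits; five-piece
    steps give 5, 25, 125 symbols = 80, 400, 2000 bits."""
    if k < 2:
        raise ValueError("k (pieces per step) must be >= 2")
    if m < 0:
        raise ValueError("m (step count) must be >= 0")
    symbols = k**m
    return TierStats(k=k, m=m, symbols=symbols, bits=bits_per_symbol * symbols)


def _require_activatable(o: Oligo, what: str) -> None:
    if o.ends.three_prime not in (EndState.PHOSPHATE, EndState.PHOSPHORIMIDAZOLIDE):
        raise ValueError(f"{what} lacks the 3' phosphate required of an S1 substrate")


def plan_first_tier(
    symbol: Oligo,
    left: Linker,
    right: Linker,
    params: LibraryDesignParams | None = None,
    symbol_name: str = "",
) -> AssemblyTier:
    """Plan the three-piece symbol-linker attachment: chain
    left linker -> symbol -> right linker, two junctions, two splints.

    The left linker and the symbol are the activated S1 subunits; the right
    linker is the S2. Splint arms clamping the short symbol oligo are
    clamped to its length.
    """
    params = params or LibraryDesignParams()
    _require_activatable(symbol, "symbol oligo")
    _require_activatable(left.to_oligo(), "left linker")
    if right.to_oligo().ends.five_prime != EndState.HYDROXYL:
        raise ValueError("right linker needs a 5' hydroxyl to serve as S2")

    clamped = dataclasses.replace(params, clamp_arms=True)
    left_o, right_o = left.to_oligo(), right.to_oligo()
    cs_a = design_catalytic_strand(left_o, symbol, clamped,
                                   label=f"join:left{left.index}|symbol")
    cs_b = design_catalytic_strand(symbol, right_o, clamped,
                                   label=f"join:symbol|right{right.index}")
    pieces = [
        Piece(left_o, tier=1),
        Piece(symbol, tier=1, symbol_name=symbol_name),
        Piece(right_o, tier=1),
    ]
    junctions = [
        Junction(0, 1, cs_a),
        Junction(1, 2, cs_b),
    ]
    return AssemblyTier(pieces=pieces, junctions=junctions, tier=1,
                        metadata={"kind": "symbol_linker_attachment"})


def _complex_piece(
    symbol_name: str,
    symbols: SymbolLibrary,
    linkers: LinkerLibrary,
    pair_index: int,
) -> tuple[Piece, AssemblyTier]:
    """Build the tier-1 sub-assembly for one symbol/linker pairing and the
    tier-2 piece made from its product."""
    payload = symbols.payload(symbol_name)
    symbol_oligo = design_symbol_oligo(payload, L_sym=symbols.L_sym)
    left, right = linkers.left(pair_index), linkers.right(pair_index)
    sub = plan_first_tier(symbol_oligo, left, right, linkers.params,
                          symbol_name=symbol_name)
    product = Oligo(
        sub.product_seq,
        ends=S1_ENDS,
        label=f"complex:{symbol_name}{pair_index}",
        role=OligoRole.ASSEMBLY_PRODUCT,
    )
    piece = Piece(
        product,
        left_linker_index=left.index,
        right_linker_index=right.index,
        tier=2,
        symbol_name=symbol_name,
    )
    return piece, sub


def plan_data_gene(
    symbol_order: Sequence[str],
    mode: str,
    symbols: SymbolLibrary,
    linkers: LinkerLibrary,
    reference_order: Sequence[str] | None = None,
) -> AssemblyPlan:
    """Plan a complete data storage gene realising ``symbol_order``.

    ``mode='pair_linkers'``: linker pairs 1..n are paired with the requested
    symbols in order and joined consecutively (right i -> left i+1).
    ``mode='design_joins'``: the symbol/linker pairing is fixed by
    ``reference_order`` (pair i attaches to the i-th reference symbol, as
    when reusing already-built complexes) and the splint joins are computed
    to visit the pieces in the requested order; duplicate symbols are drawn
    from the reference first-come-first-served.
    """
    order = list(symbol_order)
    n = len(order)
    if n < 2:
        raise ValueError("a data gene needs at least two symbols")
    if n > len(linkers):
        raise ValueError(f"order needs {n} linker pairs, library has {len(linkers)}")
    for name in order:
        if name not in symbols:
            raise KeyError(f"unknown symbol {name!r}")

    if mode == "pair_linkers":
        assignment = list(zip(order, range(1, n + 1)))  # (symbol, pair index) in chain order
    elif mode == "design_joins":
        if reference_order is None:
            raise ValueError("design_joins mode requires the reference_order "
                             "that fixed the symbol-linker pairing")
        reference = list(reference_order)
        if sorted(reference) != sorted(order):
            raise ValueError("requested order must be a permutation of the "
                             "reference order's symbols")
        available: list[tuple[str, int]] = [
            (name, i) for i, name in enumerate(reference, start=1)
        ]
        assignment = []
        for name in order:
            for j, (ref_name, idx) in enumerate(available):
                if ref_name == name:
                    assignment.append((name, idx))
                    del available[j]
                    break
            else:  # pragma: no cover - guarded by the permutation check
                raise ValueError(f"no unused complex left for symbol {name!r}")
    else:
        raise ValueError(f"mode must be 'pair_linkers' or 'design_joins', got {mode!r}")

    used = [idx for _, idx in assignment]
    if len(set(used)) != len(used):
        raise ValueError("each linker pair may be used at most once per plan")

    pieces: list[Piece] = []
    sub_tiers: list[AssemblyTier] = []
    for name, pair_index in assignment:
        piece, sub = _complex_piece(name, symbols, linkers, pair_index)
        pieces.append(piece)
        sub_tiers.append(sub)

    junctions = []
    for i in range(n - 1):
        up, down = pieces[i], pieces[i + 1]
        join = JoinSpec(up.right_linker_index, down.left_linker_index)
        cs = design_catalytic_strand(
            up.oligo, down.oligo, linkers.params,
            label=f"join:right{join.upstream_right_linker_index}"
                  f"|left{join.downstream_left_linker_index}",
        )
        junctions.append(Junction(i, i + 1, cs, join=join))

    tier2 = AssemblyTier(pieces=pieces, junctions=junctions, tier=2,
                         metadata={"mode": mode})
    recovered = order_from_joins(pieces, tier2.joins)
    assert recovered == order, "planner self-check failed"
    return AssemblyPlan(first_tier=sub_tiers, later_tiers=[tier2],
                        symbol_order=order, metadata={"mode": mode})


def order_from_joins(pieces: Sequence[Piece], joins: Sequence[JoinSpec]) -> list[str]:
    """Recover the unique linear chain induced by a join set.

    Raises :class:`TopologyError` (naming the offending linker indices) if a
    linker index is reused, or the join graph has a cycle, branch, or is
    disconnected -- anything other than a single simple path over all pieces.
    """
    by_left: dict[int, int] = {}
    by_right: dict[int, int] = {}
    for i, p in enumerate(pieces):
        if p.left_linker_index is not None:
            if p.left_linker_index in by_left:
                raise TopologyError(f"left linker {p.left_linker_index} used twice")
            by_left[p.left_linker_index] = i
        if p.right_linker_index is not None:
            if p.right_linker_index in by_right:
                raise TopologyError(f"right linker {p.right_linker_index} used twice")
            by_right[p.right_linker_index] = i

    successor: dict[int, int] = {}
    has_incoming: set[int] = set()
    seen_r: set[int] = set()
    seen_l: set[int] = set()
    for j in joins:
        r, l = j.upstream_right_linker_index, j.downstream_left_linker_index
        if r in seen_r:
            raise TopologyError(f"right linker {r} appears in two joins")
        if l in seen_l:
            raise TopologyError(f"left linker {l} appears in two joins")
        seen_r.add(r)
        seen_l.add(l)
        if r not in by_right:
            raise TopologyError(f"join references absent right linker {r}")
        if l not in by_left:
            raise TopologyError(f"join references absent left linker {l}")
        up, down = by_right[r], by_left[l]
        if up in successor:
            raise TopologyError(f"branch at piece {up} (right linker {r})")
        successor[up] = down
        if down in has_incoming:
            raise TopologyError(f"branch into piece {down} (left linker {l})")
        has_incoming.add(down)

    heads = [i for i in range(len(pieces)) if i not in has_incoming]
    if len(pieces) > 1 and len(joins) != len(pieces) - 1:
        raise TopologyError(
            f"{len(pieces)} pieces need {len(pieces) - 1} joins, got {len(joins)}"
        )
    if len(heads) != 1:
        raise TopologyError(
            f"join graph has {len(heads)} chain heads (cycle or disconnected); "
            f"heads at pieces {heads}"
        )
    chain = [heads[0]]
    while chain[-1] in successor:
        nxt = successor[chain[-1]]
        if nxt in chain:
            raise TopologyError(f"cycle detected at piece {nxt}")
        chain.append(nxt)
    if len(chain) != len(pieces):
        raise TopologyError(
            f"join graph is disconnected: chain covers {len(chain)} of "
            f"{len(pieces)} pieces"
        )
    return [pieces[i].symbol_name for i in chain]


def brute_force_order(pieces: Sequence[Piece], joins: Sequence[JoinSpec]) -> list[str]:
    """Permutation-enumeration oracle for :func:`order_from_joins` (testing
    aid; feasible for <= ~7 pieces). Finds the ordering in which every
    adjacent pair is licensed by exactly one join."""
    want = {(j.upstream_right_linker_index, j.downstream_left_linker_index)
            for j in joins}
    hits = []
    for perm in permutations(range(len(pieces))):
        edges = {
            (pieces[a].right_linker_index, pieces[b].left_linker_index)
            for a, b in zip(perm, perm[1:])
        }
        if edges == want and len(edges) == len(pieces) - 1:
            hits.append([pieces[i].symbol_name for i in perm])
    if len(hits) != 1:
        raise TopologyError(f"{len(hits)} orderings satisfy the join set")
    return hits[0]
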