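"""Recover symbol order and bits from assembled sequences or noisy reads.

Decoding anchors on the linker-connecting regions, which are unique per
linker, then extracts the payload window sitting between the constant
symbol-connecting flanks of each complex:

    [LC_left_i][SC_left] G [payload] AGC [SC_right][LC_right_i] ...

Clean assemblies are decoded by exact anchor matching (both orientations;
the reverse complement is tried if the forward strand yields no anchors).
Noisy reads use bounded edit-distance approximate matching (edlib) with
leftmost-lowest-distance tie-breaking, per-read symbol calls, and a
position-wise majority vote across reads. Indels are handled only through
the edit-distance matcher; no base-level consensus is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import edlib

from .codec import SymbolLibrary, symbols_to_bits
from .library_design import LinkerLibrary, S1_SUFFIX, S2_PREFIX
from .sequence_core import clean_sequence, reverse_complement

__all__ = [
    "DecodeError",
    "AmbiguityError",
    "DecodeResult",
    "decode_assembly",
    "decode_noisy_reads",
]


class DecodeError(ValueError):
    """No anchors found / sequence cannot be decoded."""


class AmbiguityError(DecodeError):
    """Anchor placements or votes do not determine a unique answer."""


@dataclass
class DecodeResult:
    symbol_order: list[str]
    bits: str
    orientation: str  # "forward" | "reverse_complement"
    confidence: list[float] = field(default_factory=list)  # per symbol position
    anomalies: list[str] = field(default_factory=list)
    n_reads_used: int = 0


def _exact_anchor_hits(seq: str, linkers: LinkerLibrary) -> list[tuple[int, int]]:
    """All exact occurrences of left linker-connecting anchors: (pos, index).
    Raises on overlapping/ambiguous placements."""
    hits: list[tuple[int, int]] = []
    for pair in linkers.pairs:
        left = pair[0]
        anchor = left.linker_connecting_seq
        start = 0
        while True:
            pos = seq.find(anchor, start)
            if pos < 0:
                break
            hits.append((pos, left.index))
            start = pos + 1
    hits.sort()
    for (pa, ia), (pb, ib) in zip(hits, hits[1:]):
        if pb < pa + len(linkers.pairs[0][0].linker_connecting_seq):
            raise AmbiguityError(
                f"overlapping anchor placements: left linker {ia} at {pa} and "
                f"left linker {ib} at {pb}"
            )
    return hits


def _payload_at(seq: str, anchor_end: int, linkers: LinkerLibrary, L_sym: int) -> str | None:
    """Exact payload extraction after a left anchor ending at ``anchor_end``:
    expects SC_left, G, payload, AGC, SC_right in order; None on mismatch."""
    sc_left, sc_right = linkers.sc_left, linkers.sc_right
    i = anchor_end
    if seq[i : i + len(sc_left)] != sc_left:
        return None
    i += len(sc_left)
    if seq[i : i + 1] != S2_PREFIX:
        return None
    payload = seq[i + 1 : i + 1 + L_sym]
    j = i + 1 + L_sym
    if len(payload) != L_sym or seq[j : j + len(S1_SUFFIX)] != S1_SUFFIX:
        return None
    j += len(S1_SUFFIX)
    if seq[j : j + len(sc_right)] != sc_right:
        return None
    return payload


def decode_assembly(
    seq: str,
    symbols: SymbolLibrary,
    linkers: LinkerLibrary,
) -> DecodeResult:
    """Decode a clean assembled sequence by exact anchor matching.

    Tries the forward orientation first; if no anchors are found, the
    reverse complement. Raises :class:`DecodeError` when neither orientation
    contains any library anchor.
    """
    seq = clean_sequence(seq, allow_empty=False)
    for orientation, s in (("forward", seq), ("reverse_complement", reverse_complement(seq))):
        hits = _exact_anchor_hits(s, linkers)
        if not hits:
            continue
        anomalies: list[str] = []
        order: list[str] = []
        payloads: list[str] = []
        lc_len = len(linkers.pairs[0][0].linker_connecting_seq)
        for pos, index in hits:
            payload = _payload_at(s, pos + lc_len, linkers, symbols.L_sym)
            if payload is None:
                anomalies.append(f"left linker {index} anchor at {pos}: malformed complex")
                continue
            try:
                name = symbols.name_of(payload)
            except KeyError:
                anomalies.append(f"unknown payload {payload} after left linker {index}")
                continue
            order.append(name)
            payloads.append(payload)
        if not order:
            raise DecodeError("anchors found but no complex could be decoded")
        return DecodeResult(
            symbol_order=order,
            bits=symbols_to_bits(payloads, symbols),
            orientation=orientation,
            confidence=[1.0] * len(order),
            anomalies=anomalies,
        )
    raise DecodeError("no library anchors found in either orientation")


def _edlib_best_hit(query: str, target: str, k: int) -> tuple[int, int, int] | None:
    """Best infix match of query in target within edit distance k:
    (start, end, distance), leftmost among lowest-distance hits; None if
    nothing within k; AmbiguityError if two non-overlapping equally-good
    leftmost candidates tie exactly."""
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    locs = sorted((s if s is not None else 0, e) for s, e in res["locations"])
    start, end = locs[0]
    return (start, end + 1, res["editDistance"])


def _call_read(
    read: str,
    symbols: SymbolLibrary,
    linkers: LinkerLibrary,
    max_edit_fraction: float,
) -> tuple[list[str], str] | None:
    """Symbol calls for one read, trying both orientations; returns
    (calls, orientation) or None if the read is unusable. Ambiguous payload
    calls (edit-distance ties) are recorded as '?' and excluded from votes."""
    best: tuple[int, list[tuple[int, str]], str] | None = None
    sc_left, sc_right = linkers.sc_left, linkers.sc_right
    pad = 4  # indel slack around the payload window
    for orientation in ("forward", "reverse_complement"):
        s = read if orientation == "forward" else reverse_complement(read)
        found: list[tuple[int, str]] = []
        for pair in linkers.pairs:
            left = pair[0]
            anchor = left.linker_connecting_seq + sc_left
            k = ceil(max_edit_fraction * len(anchor))
            hit = _edlib_best_hit(anchor, s, k)
            if hit is None:
                continue
            start, end, _ = hit
            window = s[end : end + 1 + symbols.L_sym + len(S1_SUFFIX) + pad]
            call = _nearest_payload(window, symbols)
            found.append((start, call))
        if found and (best is None or len(found) > best[0]):
            found.sort()
            best = (len(found), found, orientation)
    if best is None:
        return None
    return [call for _, call in best[1]], best[2]


def _nearest_payload(window: str, symbols: SymbolLibrary) -> str:
    """Nearest library payload to the expected G+payload+AGC region by infix
    edit distance; '?' on a tie (ambiguous, excluded from the vote)."""
    if not window:
        return "?"
    scored: list[tuple[int, str]] = []
    for name, payload in symbols.entries.items():
        probe = S2_PREFIX + payload + S1_SUFFIX
        res = edlib.align(probe, window, mode="HW", task="distance")
        d = res["editDistance"]
        scored.append((d if d >= 0 else len(probe), name))
    scored.sort()
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return "?"
    return scored[0][1]


def decode_noisy_reads(
    reads: Sequence[str],
    symbols: SymbolLibrary,
    linkers: LinkerLibrary,
    max_edit_fraction: float = 0.15,
    min_reads: int = 3,
) -> DecodeResult:
    """Decode a gene from error-injected reads by per-read approximate
    anchor matching and position-wise majority vote.

    Anchors (left linker-connecting region + constant flank) are located
    per read within edit distance ``ceil(max_edit_fraction * anchor_len)``;
    each read contributes one ordered list of symbol calls; reads agreeing
    with the modal chain length vote per position. Confidence is the winning
    vote fraction. Deterministic given the inputs.
    """
    if not reads:
        raise ValueError("read set is empty")
    if not 0 <= max_edit_fraction < 0.5:
        raise ValueError("max_edit_fraction must lie in [0, 0.5)")

    calls_per_read: list[list[str]] = []
    orientations: list[str] = []
    for read in reads:
        read = clean_sequence(read, allow_empty=False)
        result = _call_read(read, symbols, linkers, max_edit_fraction)
        if result is not None:
            calls_per_read.append(result[0])
            orientations.append(result[1])
    if len(calls_per_read) < min_reads:
        raise DecodeError(
            f"only {len(calls_per_read)} usable reads (< min_reads={min_reads})"
        )

    lengths = [len(c) for c in calls_per_read]
    modal_len = max(set(lengths), key=lambda n: (lengths.count(n), n))
    voters = [c for c in calls_per_read if len(c) == modal_len]

    order: list[str] = []
    confidence: list[float] = []
    anomalies: list[str] = []
    for pos in range(modal_len):
        votes: dict[str, int] = {}
        for c in voters:
            if c[pos] != "?":
                votes[c[pos]] = votes.get(c[pos], 0) + 1
        total = sum(votes.values())
        if not votes:
            raise AmbiguityError(f"no unambiguous calls at position {pos}")
        winner = max(sorted(votes), key=votes.get)
        frac = votes[winner] / total
        if frac <= 0.5 and len(votes) > 1:
            raise AmbiguityError(
                f"no majority at position {pos}; votes: {dict(sorted(votes.items()))}"
            )
        order.append(winner)
        confidence.append(frac)

    fwd = orientations.count("forward")
    orientation = "forward" if fwd * 2 >= len(orientations) else "reverse_complement"
    payloads = [symbols.payload(name) for name in order]
    return DecodeResult(
        symbol_order=order,
        bits=symbols_to_bits(payloads, symbols),
        orientation=orientation,
        confidence=confidence,
        anomalies=anomalies,
        n_reads_used=len(voters),
    )
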