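"""Bits <-> symbol payloads.

A symbol is a short payload oligo of fixed length ``L_sym`` (default 8 nt)
carrying ``2 * L_sym`` bits (default 16) under a bijective 2-bit-per-base
map. The default map is lexicographic (A=00, C=01, G=10, T=11); any
bijection works, so it is a configurable field. Symbol names ("A", "B", ...)
are labels only -- identity is the payload sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence_core import ALPHABET, clean_sequence

__all__ = [
    "DEFAULT_BIT_MAP",
    "SymbolLibrary",
    "bits_to_symbols",
    "symbols_to_bits",
]

#: Lexicographic 2-bit word -> base assignment.
DEFAULT_BIT_MAP: dict[str, str] = {"00": "A", "01": "C", "10": "G", "11": "T"}


def _validate_bit_map(bit_map: dict[str, str]) -> None:
    words = sorted(bit_map)
    if words != ["00", "01", "10", "11"]:
        raise ValueError(f"bit_map keys must be the four 2-bit words, got {words}")
    if sorted(bit_map.values()) != sorted(ALPHABET):
        raise ValueError("bit_map must be a bijection onto {A, C, G, T}")


@dataclass
class SymbolLibrary:
    """Named symbol payloads plus the bit<->base map.

    ``entries`` is an ordered mapping of symbol name -> payload; all payloads
    share length ``L_sym`` and are pairwise distinct.
    """

    entries: dict[str, str] = field(default_factory=dict)
    bit_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BIT_MAP))
    L_sym: int = 8

    def __post_init__(self) -> None:
        _validate_bit_map(self.bit_map)
        if self.L_sym < 1:
            raise ValueError("L_sym must be positive")
        self.entries = {name: clean_sequence(p) for name, p in self.entries.items()}
        for name, payload in self.entries.items():
            if len(payload) != self.L_sym:
                raise ValueError(
                    f"payload for {name!r} has length {len(payload)}, expected {self.L_sym}"
                )
        payloads = list(self.entries.values())
        if len(set(payloads)) != len(payloads):
            raise ValueError("symbol payloads must be pairwise distinct")

    @property
    def bits_per_symbol(self) -> int:
        return 2 * self.L_sym

    def payload(self, name: str) -> str:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(f"unknown symbol {name!r}") from None

    def name_of(self, payload: str) -> str:
        payload = clean_sequence(payload)
        for name, p in self.entries.items():
            if p == payload:
                return name
        raise KeyError(f"no symbol with payload {payload}")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _check_bits(bits: str) -> None:
    bad = set(bits) - {"0", "1"}
    if bad:
        raise ValueError(f"bit string contains non-binary characters {sorted(bad)}")


def bits_to_symbols(bits: str, lib: SymbolLibrary | None = None) -> list[str]:
    """Encode a bit string as a list of symbol payloads.

    The bit string length must be a multiple of ``2 * L_sym``; padding is the
    caller's responsibility (no implicit padding, so the inverse is exact).
    """
    lib = lib if lib is not None else SymbolLibrary()
    _check_bits(bits)
    block = lib.bits_per_symbol
    if len(bits) % block != 0:
        raise ValueError(
            f"bit string length {len(bits)} is not a multiple of {block} "
            "(pad explicitly before encoding)"
        )
    payloads = []
    for i in range(0, len(bits), block):
        word = bits[i : i + block]
        payloads.append("".join(lib.bit_map[word[j : j + 2]] for j in range(0, block, 2)))
    return payloads


def symbols_to_bits(payloads: list[str], lib: SymbolLibrary | None = None) -> str:
    """Decode symbol payloads back to the bit string (exact inverse of
    :func:`bits_to_symbols`)."""
    lib = lib if lib is not None else SymbolLibrary()
    inverse = {base: word for word, base in lib.bit_map.items()}
    out = []
    for p in payloads:
        p = clean_sequence(p)
        if len(p) != lib.L_sym:
            raise ValueError(f"payload {p} has length {len(p)}, expected {lib.L_sym}")
        out.append("".join(inverse[b] for b in p))
    return "".join(out)
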