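"""File formats, configuration, and seeded fixture generation.

FASTA is the single oligo interchange format; structured metadata lives in
the headers as ``key=value`` pairs so libraries remain usable by standard
tools. Reads are accepted as FASTA or FASTQ (qualities ignored). Plans and
configs serialize as JSON, product mixtures as FASTA or TSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly_planner import AssemblyPlan, AssemblyTier, JoinSpec, Junction, Piece
from .codec import SymbolLibrary
from .library_design import (
    CatalyticStrand,
    LibraryDesignParams,
    Linker,
    LinkerLibrary,
)
from .ligation_simulator import ProductMixture
from .sequence_core import (
    AlphabetError,
    EndState,
    Oligo,
    OligoRole,
    TerminalChemistry,
    clean_sequence,
    reverse_complement,
)

__all__ = [
    "LibraryParseError",
    "RunConfig",
    "write_library_fasta",
    "read_library_fasta",
    "write_mixture_fasta",
    "write_mixture_tsv",
    "generate_fixture_reads",
    "read_reads",
    "write_reads_fastq",
    "plan_to_dict",
    "plan_from_dict",
]


class LibraryParseError(ValueError):
    """Malformed library FASTA; message carries the offending line number."""


# --------------------------------------------------------------------------
# library FASTA

def _header_kv(description: str) -> dict[str, str]:
    parts = description.split()[1:]  # drop the record id
    out = {}
    for p in parts:
        if "=" in p:
            k, v = p.split("=", 1)
            out[k] = v
    return out


def _interval(s: str) -> tuple[int, int]:
    a, b = s.split(":")
    return int(a), int(b)


def write_library_fasta(
    path: str | Path,
    linkers: LinkerLibrary | None = None,
    symbols: SymbolLibrary | None = None,
) -> None:
    """Serialize symbol payloads and/or linker pairs to one FASTA file with
    role metadata in the headers."""
    records = []
    if symbols is not None:
        for name, payload in symbols.entries.items():
            records.append(
                SeqRecord(Seq(payload), id=name,
                          description=f"{name} role=symbol L_sym={symbols.L_sym}")
            )
    if linkers is not None:
        for lk in linkers.all_linkers():
            rid = f"{lk.side}_linker_{lk.index}"
            lc = "{}:{}".format(*lk.linker_connecting_region)
            sc = "{}:{}".format(*lk.symbol_connecting_region)
            records.append(
                SeqRecord(
                    Seq(lk.seq), id=rid,
                    description=f"{rid} role={lk.side}_linker side={lk.side} "
                                f"index={lk.index} lc={lc} sc={sc}",
                )
            )
    SeqIO.write(records, str(path), "fasta")


def read_library_fasta(
    path: str | Path,
    params: LibraryDesignParams | None = None,
) -> tuple[SymbolLibrary | None, LinkerLibrary | None]:
    """Parse a library FASTA written by :func:`write_library_fasta`.

    Round-trips sequence, role, and region coordinates. Raises
    :class:`LibraryParseError` with the line number on malformed headers or
    alphabet violations.
    """
    header_lines: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                rid = line[1:].split()[0] if line[1:].split() else ""
                header_lines.setdefault(rid, lineno)

    symbol_entries: dict[str, str] = {}
    L_sym: int | None = None
    left: dict[int, Linker] = {}
    right: dict[int, Linker] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        lineno = header_lines.get(rec.id, 0)
        kv = _header_kv(rec.description)
        if "role" not in kv:
            raise LibraryParseError(f"line {lineno}: header missing role= field")
        try:
            seq = clean_sequence(str(rec.seq))
        except AlphabetError as e:
            raise LibraryParseError(f"line {lineno}: {e}") from e
        role = kv["role"]
        if role == "symbol":
            symbol_entries[rec.id] = seq
            L_sym = int(kv.get("L_sym", len(seq)))
        elif role in ("left_linker", "right_linker"):
            try:
                lk = Linker(
                    side=kv["side"], index=int(kv["index"]), seq=seq,
                    linker_connecting_region=_interval(kv["lc"]),
                    symbol_connecting_region=_interval(kv["sc"]),
                )
            except (KeyError, ValueError) as e:
                raise LibraryParseError(f"line {lineno}: bad linker header ({e})") from e
            (left if lk.side == "left" else right)[lk.index] = lk
        else:
            raise LibraryParseError(f"line {lineno}: unknown role {role!r}")

    symbols = (
        SymbolLibrary(entries=symbol_entries, L_sym=L_sym) if symbol_entries else None
    )
    linkers = None
    if left or right:
        if sorted(left) != sorted(right):
            raise LibraryParseError(
                f"unpaired linker indices: left {sorted(left)} vs right {sorted(right)}"
            )
        pairs = [(left[i], right[i]) for i in sorted(left)]
        p = params or LibraryDesignParams(
            n_linker_pairs=len(pairs),
            linker_connecting_len=len(pairs[0][0].linker_connecting_seq),
            symbol_connecting_len=len(pairs[0][0].symbol_connecting_seq),
        )
        linkers = LinkerLibrary(pairs=pairs, params=p)
    return symbols, linkers


# --------------------------------------------------------------------------
# product mixtures

def write_mixture_fasta(path: str | Path, mix: ProductMixture) -> None:
    records = [
        SeqRecord(
            Seq(p.seq),
            id=f"product_{p.span[0]}_{p.span[1]}",
            description=f"product_{p.span[0]}_{p.span[1]} span={p.span[0]}:{p.span[1]} "
                        f"count={p.count} abundance={p.abundance:.6g}",
        )
        for p in mix.products
    ]
    SeqIO.write(records, str(path), "fasta")


def write_mixture_tsv(path: str | Path, mix: ProductMixture) -> None:
    with open(path, "w") as fh:
        fh.write("span_start\tspan_end\tlength_nt\tcount\tabundance\n")
        for p in mix.products:
            fh.write(
                f"{p.span[0]}\t{p.span[1]}\t{len(p.seq)}\t{p.count}\t{p.abundance:.6g}\n"
            )


# --------------------------------------------------------------------------
# fixture reads

def generate_fixture_reads(
    product: str,
    n_reads: int,
    substitution_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Seeded synthetic reads of an assembled product: each read is the
    product (randomly forward or reverse-complemented) with i.i.d.
    substitutions and indels at the stated per-base rates. A stand-in for
    real nanopore reads; the error process is i.i.d., with none of the
    homopolymer or systematic bias structure of a real sequencer.
    """
    product = clean_sequence(product, allow_empty=False)
    for name, rate in (("substitution_rate", substitution_rate),
                       ("indel_rate", indel_rate)):
        if not 0 <= rate < 0.5:
            raise ValueError(f"{name} must lie in [0, 0.5)")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    reads = []
    for _ in range(n_reads):
        template = product if rng.random() < 0.5 else reverse_complement(product)
        out = []
        for b in template:
            if indel_rate and rng.random() < indel_rate / 2:  # insertion before b
                out.append(bases[rng.integers(4)])
            if indel_rate and rng.random() < indel_rate / 2:  # deletion of b
                continue
            if substitution_rate and rng.random() < substitution_rate:
                out.append(bases[(bases.index(b) + int(rng.integers(1, 4))) % 4])
            else:
                out.append(b)
        reads.append("".join(out))
    return reads


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension; qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [clean_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_reads_fastq(path: str | Path, reads: Sequence[str]) -> None:
    records = []
    for i, r in enumerate(reads):
        rec = SeqRecord(Seq(r), id=f"read_{i}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# --------------------------------------------------------------------------
# plan JSON

def _strand_to_dict(cs: CatalyticStrand) -> dict:
    return {
        "arm_s2": cs.arm_s2, "core": cs.core, "arm_s1": cs.arm_s1,
        "motif": cs.motif, "label": cs.label,
        "intended_upstream": cs.intended_upstream,
        "intended_downstream": cs.intended_downstream,
    }


def _oligo_to_dict(o: Oligo) -> dict:
    return {
        "seq": o.seq, "label": o.label, "role": o.role.value,
        "five_prime": o.ends.five_prime.value, "three_prime": o.ends.three_prime.value,
    }


def _oligo_from_dict(d: dict) -> Oligo:
    return Oligo(
        d["seq"],
        ends=TerminalChemistry(EndState(d["five_prime"]), EndState(d["three_prime"])),
        label=d["label"], role=OligoRole(d["role"]),
    )


def _tier_to_dict(tier: AssemblyTier) -> dict:
    return {
        "tier": tier.tier,
        "metadata": tier.metadata,
        "pieces": [
            {
                "oligo": _oligo_to_dict(p.oligo),
                "left_linker_index": p.left_linker_index,
                "right_linker_index": p.right_linker_index,
                "tier": p.tier,
                "symbol_name": p.symbol_name,
            }
            for p in tier.pieces
        ],
        "junctions": [
            {
                "upstream_piece": j.upstream_piece,
                "downstream_piece": j.downstream_piece,
                "catalytic_strand": _strand_to_dict(j.catalytic_strand),
                "join": None if j.join is None else {
                    "upstream_right_linker_index": j.join.upstream_right_linker_index,
                    "downstream_left_linker_index": j.join.downstream_left_linker_index,
                },
            }
            for j in tier.junctions
        ],
        "activated_pieces": tier.activated_pieces,
        "s2_piece": tier.s2_piece,
    }


def _tier_from_dict(d: dict) -> AssemblyTier:
    pieces = [
        Piece(
            oligo=_oligo_from_dict(p["oligo"]),
            left_linker_index=p["left_linker_index"],
            right_linker_index=p["right_linker_index"],
            tier=p["tier"], symbol_name=p["symbol_name"],
        )
        for p in d["pieces"]
    ]
    junctions = [
        Junction(
            upstream_piece=j["upstream_piece"],
            downstream_piece=j["downstream_piece"],
            catalytic_strand=CatalyticStrand(**j["catalytic_strand"]),
            join=None if j["join"] is None else JoinSpec(**j["join"]),
        )
        for j in d["junctions"]
    ]
    return AssemblyTier(pieces=pieces, junctions=junctions, tier=d["tier"],
                        metadata=d.get("metadata", {}))


def plan_to_dict(plan: AssemblyPlan) -> dict:
    return {
        "symbol_order": plan.symbol_order,
        "metadata": plan.metadata,
        "first_tier": [_tier_to_dict(t) for t in plan.first_tier],
        "later_tiers": [_tier_to_dict(t) for t in plan.later_tiers],
    }


def plan_from_dict(d: dict) -> AssemblyPlan:
    return AssemblyPlan(
        first_tier=[_tier_from_dict(t) for t in d["first_tier"]],
        later_tiers=[_tier_from_dict(t) for t in d["later_tiers"]],
        symbol_order=d["symbol_order"], metadata=d.get("metadata", {}),
    )


# --------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit: design parameters,
    reaction conditions, simulation settings, codec settings, paths."""

    design: dict = field(default_factory=dict)  # LibraryDesignParams fields
    conditions: dict = field(default_factory=dict)  # ReactionConditions fields
    simulation: dict = field(
        default_factory=lambda: {"mode": "deterministic", "n_molecules": 1, "seed": 0}
    )
    codec: dict = field(default_factory=lambda: {"L_sym": 8})
    paths: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(**{k: d.get(k, {}) for k in
                      ("design", "conditions", "simulation", "codec", "paths")})

    def design_params(self) -> LibraryDesignParams:
        return LibraryDesignParams(**self.design)
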