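# splintstore

In-silico toolkit for **linker-directed DNA data storage with DNAzyme
catalytic-splint ligation**: encode bits into short symbol oligos, design
the orthogonal linker and catalytic-strand libraries that direct assembly,
plan tiered ligations realising any symbol order, simulate the
activation/ligation chemistry at rule level, and decode assembled (or
error-injected) sequences back to bits.

It is written for people working on oligo-assembly approaches to DNA data
writing: instead of synthesising a storage strand base by base, prefabricated
8-nt **symbols** (16 bits each under a 2-bit-per-base map) are joined in a
chosen order by **linkers**, with a ligating DNAzyme (E47) acting as a
catalytic splint in place of a protein ligase. Assembly is geometric: m
k-piece ligation steps yield k^m symbols per strand, so three five-piece
steps store 125 symbols = 2000 bits.

## The model

Every ligation junction obeys the E47 grammar: the upstream (S1) substrate
ends 5'-...AGC-3' with a 3' phosphate that is activated (imidazole + EDC)
to a phosphorimidazolide, and the downstream (S2) substrate starts with G
on a 5' hydroxyl. The splint is `arm_S2 + core + arm_S1` — a 24-nt catalytic
core flanked by 13- and 10-nt binding arms complementary to the substrate
ends (47 nt total). The 4-nt catalytic motif is the reverse complement of
the junction bases, rc(AGC|G) = 5'-CGCT-3'.

Junction efficiency is modelled as a product of gates and factors:

```
eff = [Zn present] x [S1 activated, ends AGC] x [S2 5'-OH, starts G]
      x [both arms fully complementary]
      x activity(motif) x 1 / (1 + c_imidazole / K)
```

with `activity` = {CGCT: 1.00, CGCA: 0.16, CGCC: 0.50, all single-base
mutants of the first three positions: 0} and K = 20 mM by default.
Stochastic mode treats each junction of each molecule as an independent
Bernoulli trial with probability `eff * p_base`, so an n-piece chain goes
full-length with probability `(eff * p_base)^(n-1)`, and the two-component
regime (one substrate serving as both S1 and S2) produces concatemer sizes
that are geometric with mean `1/(1-q)`.

A symbol oligo is `G + payload + AGC`: the required motif bases sit outside
the 8-nt encoding region. Linkers carry a constant 13-nt symbol-connecting
region per side (any linker attaches to any symbol) and a unique 20-nt
linker-connecting region (only the intended neighbours join), screened for
pairwise Hamming distance >= 8 and cross-complementary runs <= 6.

## Worked example

`python examples/plan_and_simulate_gene.py` plans the order A,B,C,B,A by
symbol–linker pairing, simulates both ligation tiers, and decodes:

```
plan: 5 three-piece sub-assemblies, then one 5-piece tier with 4 splints
  join right linker 1 -> left linker 2
  join right linker 2 -> left linker 3
  join right linker 3 -> left linker 4
  join right linker 4 -> left linker 5

assembled gene: 390 nt (5 symbols x 12 nt + 10 linkers x 33 nt)
decoded order: ABCBA | bits recovered: 80
```

Each three-piece sub-assembly uses two splints; the five-piece tier uses
four. The 390-nt product stores 5 x 16 = 80 bits, and decoding anchors on
the unique linker-connecting regions to recover both the order and the bits.

Other examples: `design_library.py` (orthogonality screening),
`junction_chemistry.py` (the motif activity table and the zinc/activation/
imidazole gates), `noisy_read_decoding.py` (recovery from 100 reads at 1%
substitution via approximate anchor matching and majority vote),
`two_component_concatemers.py` (geometric multimer sizes),
`encode_decode_roundtrip.py` (bits in, bits out).

A thin CLI mirrors the library: `splintstore design | encode | plan |
simulate | decode | stats | demo`. `splintstore stats --k 5 --m 3` prints
`125 symbols / 2000 bits after 3 5-piece steps`; `splintstore demo --seed 42`
runs the full three-gene reproduction and reports per-gene pass/fail.

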