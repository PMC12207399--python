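# Methods

## Scope and modelling level

splintstore models linker-directed assembly of DNA data storage genes with
the E47 ligating DNAzyme as a *rule-level* system: sequences, terminal
chemistry states, and junction success probabilities. It deliberately does
not model kinetics (k_obs), pH or temperature effects, secondary structure,
melting thermodynamics, gel migration, or PCR amplification artifacts.
The unit of state is an oligo: a 5'→3' string over {A,C,G,T} plus the
chemical state of each terminus (5' hydroxyl/phosphate; 3' hydroxyl/
phosphate/phosphorimidazolide, the last reachable only through the
activation step).

## Junction grammar and sequence layouts

Every ligatable junction requires: upstream (S1) substrate ending
5'-...AGC-3' with an activated 3' phosphorimidazolide; downstream (S2)
substrate starting with G on a 5' hydroxyl; Zn²⁺ present; and a catalytic
splint whose arms are fully complementary to the two substrate ends. The
splint's 4-nt catalytic motif is the reverse complement of the four
junction bases: rc(AGC+G) = CGCT.

Layout choices the published scheme leaves open were fixed as follows:

* **Symbol oligo** = `G + payload + AGC` (12 nt with the default 8-nt
  payload). This is the minimal layout placing the required motif bases
  outside the encoding region while letting the symbol act as S2 on its
  left junction and S1 on its right junction.
* **Left linker** = `linker_connecting (20 nt) + symbol_connecting (13 nt)`;
  **right linker** is the mirror image. Whole linkers therefore also start
  with G and end with AGC, so tier-2 products again satisfy the grammar and
  tiers can recurse.
* The symbol-connecting region is constant *per side* (one sequence for all
  left linkers, another for all right linkers). A single sequence shared
  literally by both sides cannot simultaneously terminate a left linker
  (...AGC) and open a right linker (G...); per-side constancy is what the
  scheme functionally requires — any linker attaches to any symbol using
  the same two symbol-side splints.
* **Catalytic strand** = `arm_S2 (13 nt) + core (24 nt) + arm_S1 (10 nt)`,
  47 nt with defaults. Which arm carries 10 vs 13 nt is not documented for
  the original enzyme and is configurable; the default assigns the 13-nt
  arm to the downstream substrate. The true catalytic core sequence is not
  published in machine-readable form; the shipped core is an arbitrary
  24-mer with the motif at offset 10. Simulation results depend only on the
  motif, so this choice is inert by construction.
* Splint arms are clamped to the substrate length when the substrate is
  shorter than the configured arm (the 12-nt symbol oligo cannot host a
  13-nt arm). Clamping is opt-in (`LibraryDesignParams.clamp_arms`);
  planners enable it for symbol-adjacent junctions, and direct calls fail
  loudly by default.

## Library design

Linker libraries are produced by rejection sampling under a fixed seed
(`random.Random`), so design is bit-identical across runs. Constraints, all
configurable:

| parameter | default | rationale |
|---|---|---|
| linker_connecting length | 20 nt | unique join addresses; ≥ longest arm |
| symbol_connecting length | 13 nt | = longest arm, so an arm sits in one region |
| min pairwise Hamming (linker-connecting) | 8 | standard barcode-design margin |
| max cross-complementary run | 6 nt | below both arm lengths, so no spurious splinting |
| retry cap per sequence | 10,000 | fail loudly, never silently relax |

The cross-hybridization proxy is the longest contiguous substring of one
strand whose reverse complement occurs in the other (longest common
substring against the reverse complement, by dynamic programming). It is a
deliberate simplification: no nearest-neighbour thermodynamics, no
mismatch-tolerant duplexes. `orthogonality_report` re-screens any library
from scratch — pairwise runs over all strands (including self, which catches
hairpin-prone palindromes), Hamming distances over join addresses, and
splint-arm off-target runs — and is used in tests as an independent check
of the generator.

## Ligation simulation

Junction efficiency is a product of hard gates and two factors:
`activity(motif) × 1/(1 + c/K)`. The motif table is
{CGCT 1.00, CGCA 0.16, CGCC 0.50, all six single-base mutants of the first
three positions 0.0}; relative chromatographic peak areas are assumed to
translate linearly into success probability. CGCC experimentally also gave
unexpected side products; these are not modelled structurally (their nature
is unreported) — only the 50% main-product activity is kept, with a runtime
warning. The imidazole inhibition term `1/(1 + c/K)`, K = 20 mM, is an
invented monotone one-parameter model: quantitative dose-response data are
not available in machine-readable form, so only monotonicity should be
treated as empirically grounded. EDC carryover is tracked but inert, per
the observation that it does not inhibit ligation.

Deterministic mode concatenates piece sequences wherever junction
efficiency is positive and splits the chain at dead junctions. Stochastic
mode draws, per molecule, independent Bernoulli successes with probability
`efficiency × p_base` per junction (`numpy.random.default_rng(seed)`), and
reports every contiguous fragment species with counts, fragment-fraction
abundances, and per-molecule fractions; total nucleotides are conserved
exactly. There is no strand competition, diffusion, or time course: the
measured wet-lab yields (~40% three-piece, ~0.082% five-piece) are exposed
as `MEASURED_YIELD_PRESETS` for calibrating `p_base`, not as emergent
predictions. The two-component regime (substrate = its own S1 and S2) draws
chain sizes from Geometric(1−q), the exact distribution implied by
sequential independent extension.

## Planning

A tier with n pieces always has n−1 junctions, n−1 splints, one chain head,
and one 3'-terminal S2; all other pieces are marked for activation, and the
simulator enforces that chemistry rather than re-deriving roles. Two
mechanisms realise an order: `pair_linkers` assigns pairs 1..n to the
requested symbols in order with consecutive joins; `design_joins` keeps a
caller-supplied canonical pairing (the reference ordering is a required
argument, never inferred) and computes the joins, resolving duplicate
symbols first-come-first-served against the reference. `order_from_joins`
inverts a join set and raises a topology error (naming the offending
indices) on cycles, branches, reuse, or disconnection; a brute-force
permutation-enumeration oracle backs it in tests. Tiers beyond the second
follow the same recursion and are supported but should be regarded as an
extrapolation: the demonstrated chemistry covers tiers 1–2 only.

## Decoding

Clean assemblies: exact search for the unique left linker-connecting
anchors (forward first, reverse complement if nothing is found), then exact
extraction of the `G+payload+AGC` window between the constant
symbol-connecting flanks. Noisy reads: per read, each composite anchor
(linker-connecting + constant flank, 33 nt) is located by bounded
edit-distance infix alignment (edlib, threshold `ceil(fraction × anchor
length)`, default fraction 0.15), taking the leftmost lowest-distance hit;
the payload window is called by nearest edit distance over the library,
with distance ties recorded as ambiguous and excluded from voting. The
final order is a position-wise majority vote (strict majority required)
across reads agreeing with the modal chain length; confidence is the
winning vote fraction. There is no base-level consensus — indels are
absorbed only by the edit-distance matcher.

## Synthetic data

The published oligo sequences live in supplementary material not available
here, so `fixtures.make_demo_libraries(seed)` generates stand-in libraries
obeying every stated constraint: three random 8-nt payloads (pairwise
Hamming ≥ 3 so noisy payload calls stay separated) and five linker pairs.
The three demonstration gene orders (ABCBA, BCACB, CBCAB — the third
realised by join redesign over the second's pairing) are the published
orders and are fixed. The read generator applies i.i.d. substitutions and
indels with random orientation per read; it has none of a real nanopore
channel's homopolymer or context-dependent error structure, so decoder
results on it bound algorithmic, not platform, performance. Because the
libraries are stand-ins, sequence-level quantities that depend on the
original oligos (e.g. the 583-bp amplicon) are out of scope; structural
and statistical quantities (piece counts, motif table, growth arithmetic,
yield scaling) are not affected by the substitution.

## Problem sizes and numerics

Default statistical checks use 10⁴ molecules (stochastic yields, multimer
sizes; assertions at 3 binomial/geometric standard errors), 100 reads at 1%
substitution for noisy decoding, and 200 random order/message seeds for the
end-to-end identity property. Efficiency comparisons are exact floating
products of table values; no tolerance is needed below 3-SE statistical
bands. Degenerate inputs fail loudly: empty sequences, non-binary bits,
q = 1 (unbounded chains), empty read sets, and exhausted design spaces all
raise typed errors.
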