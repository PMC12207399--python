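"""The two-component regime: one substrate serving as both S1 and S2.

A single substrate whose splint clamps its own ends concatemerizes without
a designed length limit; chain sizes follow a geometric distribution with
per-junction success probability q.
"""

from splintstore import (
    Oligo,
    ReactionConditions,
    design_catalytic_strand,
    simulate_two_component,
)
from splintstore.sequence_core import S1_ENDS

substrate = Oligo("G" + "TCAGGATCCTGAACTGGATTCCAGGATCCTGAACTGGATT" + "AGC",
                  ends=S1_ENDS)  # 44 nt, starts G, ends AGC-phosphate
splint = design_catalytic_strand(substrate, substrate)

dist = simulate_two_component(substrate, splint,
                              ReactionConditions(p_base=0.8),
                              n_molecules=10_000, seed=1)
print(f"per-junction success q = {dist.q:.2f}")
print(f"mean chain size = {dist.mean_size:.2f} "
      f"(geometric expectation 1/(1-q) = {1/(1-dist.q):.2f})")
print(f"largest multimer = {dist.max_size} pieces")
counts = dist.size_counts()
print("size histogram (first 8):",
      {k: counts[k] for k in sorted(counts)[:8]})
# with q = 0.8 roughly a fifth of the chains reach eight pieces or more
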