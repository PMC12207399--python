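"""Probe the rule-level ligation chemistry of a single junction.

Shows the catalytic motif activity table (CGCT full, CGCA 16%, CGCC 50%,
single-base mutants of the other positions dead), the zinc and activation
gates, and imidazole carryover inhibition.
"""

import warnings

from splintstore import (
    Oligo,
    ReactionConditions,
    activate,
    design_catalytic_strand,
    junction_efficiency,
)
from splintstore.sequence_core import S1_ENDS

upstream = Oligo("G" + "ATCCTGAACTGGATTC" + "AGC", ends=S1_ENDS)
downstream = Oligo("G" + "TTGACCAGTATCGGAT" + "AGC", ends=S1_ENDS)
splint = design_catalytic_strand(upstream, downstream)
print(f"splint: {len(splint.arm_s2)}-nt arm + {len(splint.core)}-nt core + "
      f"{len(splint.arm_s1)}-nt arm = {len(splint.seq)} nt, motif {splint.motif}")

up = activate(upstream)  # 3' phosphate -> phosphorimidazolide

print("\nmotif activity (fraction of the unmutated motif):")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for motif in ["CGCT", "CGCA", "CGCC", "GGCT", "TGCT", "CCCT", "CACT",
                  "CGGT", "CGTT"]:
        eff = junction_efficiency(up, downstream, splint.with_motif(motif))
        print(f"  {motif}: {eff:.2f}")

print("\ngates:")
print("  no zinc      ->",
      junction_efficiency(up, downstream, splint,
                          ReactionConditions(zinc_present=False)))
print("  not activated->", junction_efficiency(upstream, downstream, splint))

print("\nimidazole carryover inhibition, 1/(1 + c/K) with K = 20 mM:")
for c in (0, 5, 20, 100):
    eff = junction_efficiency(up, downstream, splint,
                              ReactionConditions(imidazole_carryover_mM=c))
    print(f"  {c:>3} mM -> {eff:.3f}")
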