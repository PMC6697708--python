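"""Catalytic-dyad and conserved-Arg geometry of a dehydratase-like chain.

Builds a chain whose sequence carries the canonical motifs (the
His-anchoring HxxxGxxxxP and the C-terminal LxLxR boundary) with
side-chain stub atoms, then measures the diagnostic distances.
"""

from dhprof import (SyntheticStructureSpec, chain_sequence,
                    conserved_arg_distance, find_catalytic_dyad,
                    make_structure_pair, scan_motifs)

# a toy sequence: His motif near the N-terminus, Asp mid-chain, LxLxR at the end
sequence = ("HAADGAAAAP" + "A" * 30 + "D" + "A" * 30 + "LALAR")
spec = SyntheticStructureSpec(n_residues=len(sequence), sequence=sequence, seed=8)
structure, _, _ = make_structure_pair(spec)

seq_map = chain_sequence(structure, "A")
for match in scan_motifs(seq_map, ("HxxxGxxxxP", "LxLxR")):
    print(f"motif {match.pattern} at residue {match.start_residue[0]} "
          f"({match.matched})")

geometry = find_catalytic_dyad(structure, "A", max_dyad_distance=1e9)
geometry = conserved_arg_distance(structure, "A", geometry)

print(f"catalytic His {geometry.catalytic_his[0]}, "
      f"Asp {geometry.catalytic_asp[0]}, "
      f"dyad N...O distance {geometry.dyad_distance:.2f} A "
      f"(accepted: {geometry.dyad_found})")
print(f"conserved Arg {geometry.conserved_arg[0]}, "
      f"Arg-His Ca distance {geometry.arg_his_ca_distance:.1f} A")
# In real dehydratase domains the dyad N...O distance averages under
# 3.8 A and the Arg-His Ca span about 17.8 A — the scale that fits a
# phosphopantetheine-tethered substrate into the catalytic cavity.  On
# this random-walk toy chain the measured values are arbitrary; the
# example shows the workflow, not the biology.
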