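"""Iterative Cα superposition of two homologous domain structures.

Builds a synthetic domain pair with known noise and a handful of
deliberately displaced loop residues, then runs the sequence-guided
iterative superposition and prints the cycle trace.
"""

from dhprof import SyntheticStructureSpec, iterative_superpose, make_structure_pair

spec = SyntheticStructureSpec(
    n_residues=250,
    noise_sigma=0.4,                 # Å, expected per-atom deviation
    displaced=list(range(120, 133)), # a loop pushed 6 Å out of place
    seed=17,
)
domain_a, domain_b, truth = make_structure_pair(spec)

result = iterative_superpose(domain_a, "A", domain_b, "A",
                             cutoff=2.0, max_cycles=5)

print(f"final RMSD {result.rmsd:.2f} A over {result.n_pairs} residues")
for cycle, n_pairs, rmsd, n_rejected in result.cycles:
    print(f"  cycle {cycle}: {n_pairs} pairs, rmsd {rmsd:.2f} A, "
          f"{n_rejected} rejected")
print(f"rejected residues: {sorted(n for n, _ in result.rejected)}")
print(f"planted displaced: {sorted(truth.displaced)}")
# The final RMSD reflects only the rigid core: the displaced loop is
# rejected cycle by cycle, exactly like the 'RMSD x Å within N residues'
# figures quoted for homologous dehydratase domains.
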