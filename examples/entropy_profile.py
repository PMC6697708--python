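"""Occupancy-refined Shannon entropy of a family alignment.

Samples a 330-sequence alignment with two planted variable blocks among
conserved background, refines it to at least 10% column occupancy, and
prints the most and least conserved positions.
"""

import numpy as np

from dhprof import ColumnSpec, SyntheticMsaSpec, entropy_profile, make_msa

columns = []
for j in range(80):
    if 20 <= j < 30 or 55 <= j < 63:              # variable loops
        columns.append(ColumnSpec(kind="dirichlet", concentration=2.0))
    elif j % 7 == 0:                              # occasional insert state
        columns.append(ColumnSpec(kind="dirichlet", concentration=1.0,
                                  gap_probability=0.95))
    else:                                         # conserved scaffold
        columns.append(ColumnSpec(kind="conserved", letter="ACDEFGHIKL"[j % 10]))

msa, truth = make_msa(SyntheticMsaSpec(n_sequences=330, columns=columns, seed=5))
profile = entropy_profile(msa, min_occupancy=0.10)

print(f"{len(profile.column_indices)}/{msa.n_columns} columns survive the "
      f"10% occupancy refinement")
order = np.argsort(profile.entropy)
print("most conserved columns (H ~ 0 bits):",
      [profile.column_indices[i] for i in order[:5]])
print("most variable columns (H near log2(20) = 4.32 bits):",
      [profile.column_indices[i] for i in order[-5:]])
print(f"mean H {profile.entropy.mean():.2f} bits")
# Low H marks scaffold and catalytic positions; the high-H columns are
# the planted variable blocks — the signature used to flag
# substrate-binding loops in a real domain family.
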