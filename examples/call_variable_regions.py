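"""End-to-end variable-region calling on a coupled structure+MSA bundle.

Reproduces the hallmark two-loop pattern of dehydratase domains: one
poorly conserved loop with missing electron density and one poorly
conserved loop with elevated B-factors, both called as variable
substrate-binding regions with the evidence that supports them.
"""

from dhprof import (CoupledRegion, RegionCallParams, SyntheticStructureSpec,
                    make_domain_bundle, profile_domain)

spec = SyntheticStructureSpec(n_residues=290, seed=11)
coupling = [
    CoupledRegion(120, 130, high_h=True, unmodeled=True),   # missing density
    CoupledRegion(200, 212, high_h=True, high_b=True),      # high B-factors
]
bundle = make_domain_bundle(spec, coupling=coupling)

params = RegionCallParams(labels={(118, 132): "loop-1", (198, 214): "loop-2"})
profile = profile_domain(bundle.structure, "A", msa=bundle.msa,
                         reference_id=bundle.reference_id, params=params,
                         with_active_site=False)

for region in profile.regions:
    print(f"{region.label or '(unlabelled)'}: residues {region.start}-{region.end}, "
          f"evidence {sorted(region.evidence)}, "
          f"mean H {region.mean_h:.2f} bits"
          + (f", mean z {region.mean_z:.2f}" if region.mean_z is not None else ""))
# Both planted loops are recovered with their distinct evidence types —
# sequence variability coinciding with crystallographic disorder is the
# joint signal for substrate-binding-region candidacy.
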