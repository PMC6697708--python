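# dhprof

Sequence–structure profiling of polyketide synthase (PKS) **dehydratase
(DH) domains** — and, more generally, of any enzyme family where the
question is: *which parts of the fold are conserved scaffold, and which
are variable, flexible loops that select the substrate?*

DH domains of modular type I PKSs share a double-hotdog fold with an
invariant His/Asp catalytic dyad, yet act on chemically diverse
acyl-ACP intermediates. Comparative crystallography shows the fold's
divergence concentrates in a few loops (the α3–β11 and β7–α2 regions)
that are poorly conserved in sequence *and* disordered in crystal
structures — high B-factors or missing electron density — and that line
the acyl-intermediate-binding cavity. `dhprof` turns that style of
analysis into a reusable, tested pipeline for structural
bioinformaticians and PKS engineers.

## What it computes

- **Structure I/O** (`dhprof.structures`): PDB/mmCIF → uniform
  chain/residue/atom model with B-factors, occupancies (altlocs
  collapsed to highest occupancy), ligand store, and unmodeled residues
  from REMARK 465 / `_pdbx_unobs_or_zero_occ_residues` plus inferred
  numbering gaps.
- **Pairwise identity** (`dhprof.align`): Needleman–Wunsch global
  alignment (BLOSUM62, gap open 10 / extend 0.5) with explicit
  percent-identity conventions.
- **Iterative Cα superposition** (`dhprof.superpose`): Kabsch
  least-squares fit with per-cycle batch rejection of pairs deviating
  beyond a cutoff (default 2.0 Å, 5 cycles) — the protocol behind
  "RMSD *x* Å within *N* residues" comparisons.
- **Flexibility** (`dhprof.flexibility`): per-residue mean B over a
  selection, z-scored within the chain; flexible segments = high-z runs
  plus unmodeled gaps.
- **Conservation** (`dhprof.conservation`): occupancy refinement of an
  MSA (keep columns with ≥ 10% non-gap occupancy), per-column Shannon
  entropy H = −Σᵢ pᵢ log₂ pᵢ (bits, over the 20 standard residues, gaps
  excluded), and a column→residue map onto a reference chain.
- **Active-site geometry** (`dhprof.active_site`): scanning of the
  conserved DH motifs (HxxxGxxxxP, GYxYGPxF, LPFxW, HPLL, LxLxR),
  His/Asp dyad selection (min over Nδ1/Nε2 × Oδ1/Oδ2), conserved-Arg
  Cα–His Cα span, and in-ligand distances (e.g. PPant phosphate →
  substrate C-3).
- **Region calling** (`dhprof.regions`): a residue joins a variable
  substrate-binding region when its mapped column entropy reaches the
  75th percentile of the chain's entropy track **and** it is flexible
  (z ≥ 1) or unmodeled; flagged residues are merged (gap ≤ 1) and short
  segments (< 3) dropped, each region tagged with its evidence.
- **Synthetic data** (`dhprof.synthetic`): seeded generators for
  structure pairs with known transforms/noise/B-profiles/gaps, MSAs with
  per-column Dirichlet distributions and gap structure, and coupled
  bundles with planted variable regions — every fixture ships its own
  ground truth.

## Worked example

```sh
python examples/call_variable_regions.py
```

prints

```
loop-1: residues 120-130, evidence ['high_entropy', 'unmodeled'], mean H 4.25 bits
loop-2: residues 200-212, evidence ['high_bfactor', 'high_entropy'], mean H 4.24 bits, mean z 3.99
```

A 290-residue synthetic domain was built with two planted variable
loops: one left out of the model (missing density) and one with elevated
B-factors, both made poorly conserved in a coupled 330-sequence MSA.
The caller recovers both loops at their exact planted bounds, tagging
each with the evidence type that supports it — mean column entropy near
the 4.32-bit maximum (versus ≈ 0.9 bits background) and, for the
modeled loop, a mean B-factor z-score of ≈ 4. This is the joint
sequence-variability/structural-disorder signature used to nominate
substrate-binding loops in real DH families.

Other examples: `examples/superpose_domains.py` (outlier-rejecting
superposition), `examples/entropy_profile.py` (occupancy refinement and
entropy), `examples/active_site_geometry.py` (motifs and dyad
distances).

There is also a thin CLI mirroring the library:

```sh
dhprof synth bundle --seed 4 --out fixtures/
dhprof profile --structure fixtures/bundle.pdb:A \
    --msa fixtures/bundle_msa.fasta --ref REF --out profile.json
dhprof superpose A.pdb:A B.pdb:A --cutoff 2.0 --cycles 5
dhprof entropy msa.fasta --min-occupancy 0.10 --tsv entropy.tsv
```

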