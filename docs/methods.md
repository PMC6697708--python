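# Methods

## The analysis in one paragraph

Given (i) crystal structures of homologous enzyme domains and (ii) a
family multiple sequence alignment, the pipeline asks where sequence
variability and structural disorder coincide. Conservation is measured
as per-column Shannon entropy after occupancy refinement; disorder as
per-residue B-factor z-scores and unmodeled (missing-density) segments;
structural divergence as core RMSD from iterative outlier-rejecting Cα
superposition; and functional anchoring as conserved-motif positions
and catalytic His/Asp dyad geometry. Residues that are simultaneously
high-entropy and flexible/unmodeled are merged into "variable region"
calls — in PKS dehydratase domains these correspond to the α3–β11 and
β7–α2 loops lining the acyl-intermediate-binding cavity.

## Superposition

The rigid fit is the Kabsch algorithm: centroids subtracted, SVD of the
cross-covariance H = BᵀA, rotation R = V·diag(1,1,det(VUᵀ))·Uᵀ. The
determinant correction guarantees a proper rotation (no reflection);
near-collinear point sets (singular-value ratio < 1e-9) are returned
flagged `degenerate` rather than raised, because the optimal RMSD is
still well defined even though the rotation is not unique.

`iterative_superpose` pairs Cα atoms through the gapless columns of a
global sequence alignment of the two chains' *modeled* residues
(unmodeled residues can never pair), fits, then rejects **all** pairs
deviating more than `cutoff` (default 2.0 Å) in one batch and refits,
up to `max_cycles` (default 5) or until no pair is rejected. Batch
rejection rather than one-at-a-time keeps the procedure deterministic
and O(cycles) instead of O(outliers). At the cycle limit the final
rejection is *not* applied, so the reported RMSD always corresponds to
the reported pair set. The defaults mirror the common align-style
protocol implied by published "RMSD within N residues" figures; both
are exposed.

## Conservation

Entropy is H = −Σ pᵢ log₂ pᵢ in bits over the 20 standard amino acids.
Gaps and ambiguous letters (B, Z, X, U, O) are excluded from the
frequency counts but ambiguous letters still count toward column
occupancy: they are occupied positions without an unambiguous frequency
bin. Occupancy refinement keeps columns with non-gap fraction ≥
`min_occupancy` (default 0.10, inclusive — "at least 10%"). Base-e
output is available (`base=math.e`) for cross-checking toolchains that
report nats. No sequence weighting or background correction is applied;
the statistic is deliberately the plain column entropy.

`map_to_reference` ungaps the chosen reference row, globally aligns it
to the chain sequence, requires ≥ 0.9 identity (guarding against a
wrong chain), maps columns through aligned pairs, and trims mismatched
terminal pairs. One extension matters for the region caller: reference
positions whose chain residue is *unmodeled* are assigned residue
numbers by interpolation whenever the run of skipped reference
positions exactly matches the author-numbering gap between the mapped
flanks. Without this, missing-density loops could never receive an
entropy value, and the strongest-disorder evidence could never combine
with conservation evidence.

## Flexibility

Per-residue B is the mean over the atom selection (default Cα;
`backbone`/`all` available), z-scored within the chain — absolute B
scales are not comparable across crystal forms, so normalization is
never per structure. A constant-B chain yields all-zero z-scores with a
warning instead of dividing by zero. Flexible segments are maximal runs
of ≥ `min_length` (default 3) consecutive residues with z ≥
`z_threshold` (default 1.0); unmodeled gaps are separate annotations
regardless of length since missing density is itself the disorder
signal. The z/length defaults are this package's operationalization of
the qualitative "partially higher B-factors" criterion used in putty-
representation analyses; they are parameters, not claims.

## Region calling

A residue is flagged when (H ≥ the `h_percentile` cutoff of the mapped
entropy track, default 75th percentile) AND (z ≥ `z_threshold`, default
1.0, OR the residue is unmodeled). Unmodeled residues pass the
flexibility arm automatically — missing density is treated as the
strongest disorder evidence — and inherit the entropy of their mapped
column. Flagged residues merge across gaps ≤ `merge_gap` (default 1);
segments shorter than `min_length` (default 3) are dropped. Evidence
tags (`high_entropy`, `high_bfactor`, `unmodeled`) record which
criteria fired anywhere in the segment. Canonical loop names (α3–β11
and the like) are user configuration — a residue-range → label map —
because secondary-structure element numbering is family convention, not
something inferable from one chain. When secondary structure is
reported it comes from HELIX/SHEET records, with a coarse φ/ψ fallback
(helix φ∈[−100°,−30°], ψ∈[−80°,−5°], runs ≥ 4; strand φ∈[−180°,−40°],
ψ∈[90°,180°]∪[−180°,−170°], runs ≥ 3).

The percentile-based entropy cutoff makes the caller scale-free across
families with different overall diversity, at the cost that in a
mostly-conserved domain the 75th percentile sits inside the background
distribution and an occasional borderline background cluster can
co-fire with B-factor noise. At the stated effect sizes (planted
H ≥ 3.5 bits vs ≤ 1 bit background, planted z ≥ 2) residue-level
precision and recall exceed 0.95 over 100 random domains.

## Active-site geometry

The dyad His candidate is the first residue of the first HxxxGxxxxP
match (the motif anchors the catalytic His); without a motif hit every
His competes. The partner Asp minimizes the distance over the four
imidazole-N × carboxylate-O combinations (Nδ1/Nε2 × Oδ1/Oδ2). The
acceptance cutoff defaults to 4.0 Å — slightly looser than the ≈ 3.8 Å
typical of functional dyads, so marginal dyads are not silently missed;
the measured distance is always reported. The conserved Arg is the
arginine of the *last* LxLxR match (the motif marks the C-terminal
domain boundary, so the last occurrence is the β14-proximal one).
Ligand distances are plain Euclidean norms between named atoms of a
heteroatom residue.

## Synthetic data

Structures are idealized Cα traces: smoothed random walks with exact
3.8 Å virtual bonds, no clash checking — the pipeline consumes
coordinates and B-factors, not stereochemistry. B-factors are Gaussian
background (mean 20 Å², sd 4 Å², floor 2 Å²) plus planted elevations;
unmodeled ranges are written as REMARK 465 and omitted from ATOM
records. The pair generator applies an exact rotation+translation and
isotropic Gaussian noise whose **expected per-atom deviation norm** is
`noise_sigma` (per-component sd σ/√3) — so a σ = 0.3 Å spec yields a
post-fit core RMSD of ≈ 0.3 Å — and optionally displaces listed
residues by 6 Å in random directions. His/Asp/Arg residues receive
side-chain stub atoms (CB plus the dyad-relevant N/O atoms) at
randomized 1.5–4 Å offsets from Cα.

MSAs are sampled column-independently: conserved columns, fixed
distributions, or distributions drawn once per column from a symmetric
Dirichlet; gaps are inserted i.i.d. per column. Each column's expected
entropy is estimated by the generator itself from 10⁵ multinomial draws
(plug-in entropy) and stored as ground truth, so tests never recompute
truth through the code under test.

Coupled bundles tie the two: the MSA's reference row equals the
structure's full construct sequence (one column per residue), coupled
regions get near-uniform column distributions (symmetric Dirichlet,
concentration 20 → H ≈ 4.2 bits) plus elevated B (+35 Å², z ≥ 2) or
missing density; background columns keep the reference letter with 10%
substitution mass (H ≈ 0.6–0.9 bits). Default sizes emulate a
family-scale study: 290-residue domains, 330-sequence alignments.

What the generators do **not** emulate: phylogenetic correlation
between sequences (columns are i.i.d. across sequences),
position-dependent gap structure of real indel processes, realistic
protein geometry, crystallographic artifacts (TLS, anisotropy, lattice
contacts inflating B), or correlated noise between structures. Passing
tests therefore demonstrate correctness of the statistics and the
calling logic under controlled conditions, not that the default
thresholds are optimal for any particular real family.

## Numerical choices and degenerate inputs

- Alignment tie-breaks: the aligner's first reported optimal traceback,
  which is deterministic for fixed inputs; identity defaults to the
  gap-excluded (aligned-pairs) convention with `shorter_seq` and
  `alignment_length` available, since published identity figures rarely
  state theirs.
- Altloc collapse: highest occupancy, ties by altloc letter ('A'
  first). Residue numbering is author numbering + insertion code
  everywhere. Numbering-gap inference assumes monotone numbering and is
  disabled (with a warning) otherwise; insertion-coded residues never
  participate in inference.
- Entropy of an all-gap column is an error by construction; occupancy
  refinement removes such columns before entropy is computed.
- Reports fix floats at 4 decimals and sort JSON keys; identical inputs
  and configuration give byte-identical reports within and across
  processes. All randomness flows through numpy's seeded PCG64.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: 100 random instances (N ∈ [3, 200]) for the rigid-fit oracle
comparison, 20 seeds of 200-residue pairs for noise/outlier recovery,
100 domains at the 290-residue/330-sequence family scale for region
recovery, and 50 structures for dyad brute-force agreement — the full
analysis at these sizes completes in well under a minute.

## Known limitations

- Sequence-guided superposition only: no sequence-independent (DALI /
  TM-align class) or flexible alignment, so divergent pairs below ~30%
  identity may pair Cαs suboptimally.
- Isotropic B only; ANISOU/TLS are ignored. B-factors conflate model
  and crystal effects the package does not deconvolve.
- Entropy treats columns independently and unweighted; heavily sampled
  subfamilies will dominate p.
- Exact reproduction of published identity/RMSD figures for specific
  deposited structures depends on their (often unstated) domain
  boundaries, alignment conventions and rejection cutoffs; the package
  exposes all of these as parameters rather than hard-coding any one
  tool's behaviour.
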