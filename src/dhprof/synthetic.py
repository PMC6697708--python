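"""Deterministic synthetic fixtures for every input class of the pipeline.

Generators emulate the statistical features the pipeline consumes — a
Cα trace with planted B-factor elevations, missing-density gaps and a
known rigid transform; an MSA with controlled per-column residue
distributions and gap structure; a coupled structure+MSA bundle that
reproduces the hallmark of variable substrate-binding loops (columns
that are simultaneously high-entropy and flexible/unmodeled).  They make
no attempt at physical realism: traces are idealized 3.8 Å virtual-bond
walks without clash checking, because the pipeline reads coordinates and
B-factors, not stereochemistry.

Every generator takes a seed and uses numpy's PCG64 generator, so the
same spec yields byte-identical fixtures on every run and platform.
Ground truth (expected entropies, planted transforms, region bounds) is
computed and stored by the generator itself so tests never share code
with the implementation under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation import MSA
from .errors import SpecError
from .structures import ONE_TO_THREE, Atom, Residue, Structure

_BOND = 3.8  # Cα–Cα virtual bond length, Å

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# -- structures ------------------------------------------------------------

@dataclass
class SyntheticStructureSpec:
    n_residues: int = 290
    sequence: str | None = None                     # random when omitted
    unmodeled: list[tuple[int, int]] = field(default_factory=list)
    b_background_mean: float = 20.0                 # Å²
    b_background_sd: float = 4.0
    b_segments: list[tuple[int, int, float]] = field(default_factory=list)  # +elevation Å²
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_angle_deg: float = 30.0
    translation: tuple[float, float, float] = (5.0, -3.0, 8.0)
    noise_sigma: float = 0.0                        # expected per-atom deviation, Å
    displaced: list[int] = field(default_factory=list)
    displacement: float = 6.0                       # Å, magnitude of planted offsets
    sidechain_stubs: dict[int, str] = field(default_factory=dict)  # resnum -> 3-letter
    ss_elements: list[tuple[str, int, int]] = field(default_factory=list)  # ('H'|'E', a, b)
    chain_id: str = "A"
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 3:
            raise SpecError("n_residues must be at least 3")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be non-negative")
        spans = sorted(self.unmodeled)
        for (a, b), nxt in zip(spans, spans[1:] + [None]):
            if not (1 <= a <= b <= self.n_residues):
                raise SpecError(f"unmodeled range {(a, b)} outside [1, {self.n_residues}]")
            if nxt is not None and nxt[0] <= b:
                raise SpecError("unmodeled ranges overlap")
        for a, b, _ in self.b_segments:
            if not (1 <= a <= b <= self.n_residues):
                raise SpecError(f"B-factor range {(a, b)} outside [1, {self.n_residues}]")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise SpecError("sequence length must equal n_residues")


@dataclass
class StructurePairTruth:
    rotation: np.ndarray
    translation: np.ndarray
    expected_core_rmsd: float
    displaced: set[int]
    unmodeled: list[tuple[int, int]]
    b_segments: list[tuple[int, int, float]]
    sequence: str


def _rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.eye(3)
    return Rotation.from_rotvec(axis / n * math.radians(angle_deg)).as_matrix()


def _ca_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth self-avoiding-ish random walk with 3.8 Å virtual bonds."""
    coords = np.zeros((n, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n):
        direction = direction + 0.6 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + _BOND * direction
    return coords


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=n))


_STUB_ATOMS = {
    "HIS": [("CB", 1.5), ("ND1", 2.8), ("NE2", 3.4)],
    "ASP": [("CB", 1.5), ("OD1", 2.6), ("OD2", 2.9)],
    "ARG": [("CB", 1.5), ("NH1", 4.0)],
}


def _build_structure(spec: SyntheticStructureSpec, coords: np.ndarray,
                     b_factors: np.ndarray, sequence: str,
                     rng: np.random.Generator, structure_id: str) -> Structure:
    unmodeled_nums = set()
    for a, b in spec.unmodeled:
        unmodeled_nums.update(range(a, b + 1))
    residues: list[Residue] = []
    for i in range(spec.n_residues):
        num = i + 1
        name = ONE_TO_THREE[sequence[i]]
        if num in spec.sidechain_stubs:
            name = spec.sidechain_stubs[num].upper()
        if num in unmodeled_nums:
            residues.append(Residue(name=name, number=num, atoms=[], modeled=False))
            continue
        atoms = [Atom(name="CA", element="C", position=coords[i].copy(),
                      occupancy=1.0, b_factor=float(b_factors[i]))]
        for atom_name, radius in _STUB_ATOMS.get(name, []):
            offset = rng.normal(size=3)
            offset *= radius / np.linalg.norm(offset)
            atoms.append(Atom(name=atom_name,
                              element=atom_name[0] if atom_name[0] in "NOC" else "C",
                              position=coords[i] + offset,
                              occupancy=1.0, b_factor=float(b_factors[i])))
        residues.append(Residue(name=name, number=num, atoms=atoms))
    st = Structure(id=structure_id, chains=[(spec.chain_id, residues)],
                   source_format="PDB")
    for kind, a, b in spec.ss_elements:
        (st.helices if kind == "H" else st.sheets).append((spec.chain_id, a, b))
    return st


def make_structure_pair(spec: SyntheticStructureSpec
                        ) -> tuple[Structure, Structure, StructurePairTruth]:
    """An idealized Cα-trace structure and a noisy rigid-transformed copy.

    Structure A carries the planted B-factor profile, unmodeled gaps,
    secondary-structure records and optional His/Asp/Arg side-chain
    stubs.  Structure B is A under the spec's rotation+translation, with
    isotropic Gaussian coordinate noise whose expected per-atom deviation
    norm is ``noise_sigma``, and with the listed residues additionally
    displaced by ``displacement`` Å in a random direction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sequence = spec.sequence or _random_sequence(spec.n_residues, rng)
    coords = _ca_trace(spec.n_residues, rng)

    b = rng.normal(spec.b_background_mean, spec.b_background_sd, spec.n_residues)
    b = np.clip(b, 2.0, None)
    for a_, b_, elevation in spec.b_segments:
        b[a_ - 1:b_] += elevation

    structure_a = _build_structure(spec, coords, b, sequence, rng, "synthA")

    rotation = _rotation_matrix(spec.rotation_axis, spec.rotation_angle_deg)
    translation = np.asarray(spec.translation, dtype=float)
    coords_b = coords @ rotation.T + translation
    if spec.noise_sigma > 0:
        # per-component sd sigma/sqrt(3) -> E[|noise|^2] = sigma^2
        coords_b = coords_b + rng.normal(0.0, spec.noise_sigma / math.sqrt(3.0),
                                         coords_b.shape)
    for num in spec.displaced:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords_b[num - 1] += spec.displacement * direction

    spec_b = SyntheticStructureSpec(**{**spec.__dict__, "unmodeled": []})
    structure_b = _build_structure(spec_b, coords_b, b, sequence, rng, "synthB")

    truth = StructurePairTruth(rotation=rotation, translation=translation,
                               expected_core_rmsd=spec.noise_sigma,
                               displaced=set(spec.displaced),
                               unmodeled=list(spec.unmodeled),
                               b_segments=list(spec.b_segments),
                               sequence=sequence)
    return structure_a, structure_b, truth


# -- alignments ------------------------------------------------------------

@dataclass
class ColumnSpec:
    """One MSA column: a conserved letter or a Dirichlet-drawn distribution."""

    kind: str = "conserved"        # 'conserved' | 'dirichlet' | 'fixed'
    letter: str = "A"
    concentration: float = 1.0     # symmetric Dirichlet parameter
    probabilities: np.ndarray | None = None   # used when kind == 'fixed'
    gap_probability: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("conserved", "dirichlet", "fixed"):
            raise SpecError(f"unknown column kind {self.kind!r}")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise SpecError("gap_probability outside [0,1]")
        if self.kind == "dirichlet" and self.concentration <= 0:
            raise SpecError("Dirichlet concentration must be positive")
        if self.kind == "fixed":
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (20,) or p.min() < 0 or abs(p.sum() - 1) > 1e-9:
                raise SpecError("fixed column needs a 20-vector of probabilities summing to 1")


@dataclass
class SyntheticMsaSpec:
    n_sequences: int = 330          # matches a family-scale domain alignment
    columns: list[ColumnSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise SpecError("n_sequences must be positive")
        if not self.columns:
            raise SpecError("at least one column spec required")
        for c in self.columns:
            c.validate()


@dataclass
class MsaTruth:
    expected_occupancy: np.ndarray      # 1 - gap probability, per column
    expected_entropy: np.ndarray        # bits, by high-n simulation
    probabilities: np.ndarray           # n_columns × 20 generating distributions


_TRUTH_DRAWS = 100_000


def _simulated_entropy(p: np.ndarray, rng: np.random.Generator) -> float:
    counts = rng.multinomial(_TRUTH_DRAWS, p)
    q = counts[counts > 0] / _TRUTH_DRAWS
    return float(-(q * np.log2(q)).sum())


def make_msa(spec: SyntheticMsaSpec) -> tuple[MSA, MsaTruth]:
    """Sample an MSA column-independently and store per-column ground truth.

    Each column's expected entropy is estimated by the generator itself
    from 10⁵ draws of the column's generating distribution (plug-in
    entropy), independent of the conservation module.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_cols = len(spec.columns)
    letters = np.empty((spec.n_sequences, n_cols), dtype="U1")
    probs = np.zeros((n_cols, 20))
    expected_h = np.zeros(n_cols)
    aa = np.array(list(AA20))

    for j, cspec in enumerate(spec.columns):
        if cspec.kind == "conserved":
            p = np.zeros(20)
            p[AA20.index(cspec.letter.upper())] = 1.0
        elif cspec.kind == "fixed":
            p = np.asarray(cspec.probabilities, dtype=float)
        else:
            p = rng.dirichlet(np.full(20, cspec.concentration))
        probs[j] = p
        expected_h[j] = 0.0 if cspec.kind == "conserved" else _simulated_entropy(p, rng)
        draws = aa[rng.choice(20, size=spec.n_sequences, p=p)]
        if cspec.gap_probability > 0:
            gaps = rng.random(spec.n_sequences) < cspec.gap_probability
            draws = np.where(gaps, "-", draws)
        letters[:, j] = draws

    records = [(f"seq{i:04d}", "".join(letters[i])) for i in range(spec.n_sequences)]
    truth = MsaTruth(
        expected_occupancy=np.array([1.0 - c.gap_probability for c in spec.columns]),
        expected_entropy=expected_h, probabilities=probs)
    return MSA(records=records), truth


# -- coupled bundles -------------------------------------------------------

@dataclass
class CoupledRegion:
    start: int
    end: int
    high_h: bool = True
    high_b: bool = False
    unmodeled: bool = False

    @property
    def expected_evidence(self) -> frozenset[str]:
        tags = set()
        if self.high_h:
            tags.add("high_entropy")
        if self.high_b:
            tags.add("high_bfactor")
        if self.unmodeled:
            tags.add("unmodeled")
        return frozenset(tags)


@dataclass
class DomainBundle:
    structure: Structure
    msa: MSA
    reference_id: str
    truth_regions: list[CoupledRegion]
    msa_truth: MsaTruth
    structure_truth: StructurePairTruth


#: background substitution probability off the reference letter; keeps
#: background column entropy at roughly 0.6-0.9 bits
_BACKGROUND_MISMATCH = 0.10
_HIGH_B_ELEVATION = 35.0   # Å² above background, comfortably z >= 2


def make_domain_bundle(structure_spec: SyntheticStructureSpec,
                       msa_spec: SyntheticMsaSpec | None = None,
                       coupling: list[CoupledRegion] = (),
                       reference_id: str = "REF") -> DomainBundle:
    """A pipeline-ready structure+MSA pair with coupled variable regions.

    The MSA's reference row equals the structure's full chain sequence
    (one column per residue, no reference gaps).  Coupled regions are
    made simultaneously high-entropy in the MSA (near-uniform column
    distributions) and flexible in the structure (elevated B or missing
    density); background columns stay close to the reference letter.
    """
    import copy
    spec = copy.deepcopy(structure_spec)
    n = spec.n_residues
    for region in coupling:
        if not (1 <= region.start <= region.end <= n):
            raise SpecError(f"coupled region {(region.start, region.end)} outside domain")
        if region.unmodeled:
            spec.unmodeled.append((region.start, region.end))
        if region.high_b:
            spec.b_segments.append((region.start, region.end, _HIGH_B_ELEVATION))
    spec.unmodeled = sorted(set(spec.unmodeled))

    structure, _, structure_truth = make_structure_pair(spec)
    sequence = structure_truth.sequence

    high_h_cols = set()
    for region in coupling:
        if region.high_h:
            high_h_cols.update(range(region.start, region.end + 1))

    columns = []
    for num in range(1, n + 1):
        if num in high_h_cols:
            columns.append(ColumnSpec(kind="dirichlet", concentration=20.0))
        else:
            p = np.full(20, _BACKGROUND_MISMATCH / 19)
            p[AA20.index(sequence[num - 1])] = 1.0 - _BACKGROUND_MISMATCH
            columns.append(ColumnSpec(kind="fixed", probabilities=p))
    msa_spec = msa_spec or SyntheticMsaSpec()
    msa_spec = SyntheticMsaSpec(n_sequences=msa_spec.n_sequences, columns=columns,
                                seed=msa_spec.seed if msa_spec.seed else spec.seed + 1)
    msa, msa_truth = make_msa(msa_spec)

    # overwrite the first record with the exact reference sequence
    records = [(reference_id, sequence)] + msa.records[1:]
    msa = MSA(records=records)
    return DomainBundle(structure=structure, msa=msa, reference_id=reference_id,
                        truth_regions=list(coupling), msa_truth=msa_truth,
                        structure_truth=structure_truth)
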