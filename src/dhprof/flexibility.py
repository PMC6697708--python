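"""Per-residue B-factor flexibility profiling and flexible-segment calls.

Crystallographic B-factors (atomic displacement parameters, Å²) report
positional disorder; stretches of elevated B, like stretches that could
not be modeled at all, mark flexible loops.  Normalization is a plain
z-score per chain — different crystal forms have incomparable absolute
B scales, so comparisons are only meaningful within a chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, NotFoundError
from .structures import Structure, unmodeled_segments

BACKBONE_ATOMS = ("N", "CA", "C", "O")

EVIDENCE_HIGH_B = "high_bfactor"
EVIDENCE_UNMODELED = "unmodeled"


@dataclass
class ResidueFlex:
    number: int
    icode: str
    name: str
    mean_b: float | None     # Å²; None for unmodeled residues
    z: float | None
    modeled: bool


@dataclass
class FlexibilityProfile:
    chain_id: str
    residues: list[ResidueFlex]
    mean_b: float
    sd_b: float
    atom_selection: str = "CA"
    #: unmodeled stretches of the chain as (start, end, length)
    gaps: list[tuple[int, int, int]] = field(default_factory=list)

    def z_by_residue(self) -> dict[tuple[int, str], float]:
        return {(r.number, r.icode): r.z for r in self.residues if r.modeled}


@dataclass
class RegionAnnotation:
    """A contiguous flagged residue segment with its supporting evidence."""

    chain_id: str
    start: int
    end: int
    evidence: frozenset[str]
    label: str = ""
    mean_h: float | None = None
    mean_z: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def bfactor_profile(structure: Structure, chain_id: str,
                    atom_selection: str = "CA") -> FlexibilityProfile:
    """Mean B per residue over an atom selection, z-scored within the chain.

    ``atom_selection`` is ``CA``, ``backbone`` or ``all``.  Unmodeled
    residues appear in the profile with no B value.  A chain of constant
    B yields all-zero z-scores with a warning.
    """
    if atom_selection not in ("CA", "backbone", "all"):
        raise ArgumentError(f"atom_selection must be CA|backbone|all, got {atom_selection!r}")
    residues = structure.chain(chain_id)

    records: list[ResidueFlex] = []
    values: list[float] = []
    for res in residues:
        if not res.modeled:
            records.append(ResidueFlex(res.number, res.icode, res.name, None, None, False))
            continue
        if atom_selection == "CA":
            atoms = [a for a in res.atoms if a.name == "CA"]
        elif atom_selection == "backbone":
            atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
        else:
            atoms = res.atoms
        if not atoms:
            records.append(ResidueFlex(res.number, res.icode, res.name, None, None, False))
            continue
        mean_b = float(np.mean([a.b_factor for a in atoms]))
        records.append(ResidueFlex(res.number, res.icode, res.name, mean_b, None, True))
        values.append(mean_b)

    if len(values) < 2:
        raise NotFoundError(f"chain {chain_id!r}: fewer than 2 modeled residues "
                            f"with {atom_selection} atoms")
    mean = float(np.mean(values))
    sd = float(np.std(values))
    if sd == 0.0:
        warnings.warn(f"chain {chain_id}: constant B-factor ({mean} Å²); "
                      "all z-scores set to 0", stacklevel=2)
    for rec in records:
        if rec.mean_b is not None:
            rec.z = 0.0 if sd == 0.0 else (rec.mean_b - mean) / sd
    return FlexibilityProfile(chain_id=chain_id, residues=records,
                              mean_b=mean, sd_b=sd, atom_selection=atom_selection,
                              gaps=unmodeled_segments(structure, chain_id))


def flexible_segments(profile: FlexibilityProfile, z_threshold: float = 1.0,
                      min_length: int = 3) -> list[RegionAnnotation]:
    """Flexible regions: high-B runs plus the chain's unmodeled gaps.

    High-B regions are maximal runs of at least ``min_length`` consecutive
    modeled residues with z ≥ ``z_threshold``.  Unmodeled gaps are
    appended as separate annotations regardless of length (missing
    density is itself the disorder signal).
    """
    regions: list[RegionAnnotation] = []
    run: list[int] = []
    modeled = [r for r in profile.residues if r.modeled and not r.icode]
    for rec in modeled:
        if rec.z is not None and rec.z >= z_threshold and (not run or rec.number == run[-1] + 1):
            run.append(rec.number)
        else:
            if len(run) >= min_length:
                regions.append(RegionAnnotation(profile.chain_id, run[0], run[-1],
                                                frozenset({EVIDENCE_HIGH_B})))
            run = [rec.number] if rec.z is not None and rec.z >= z_threshold else []
    if len(run) >= min_length:
        regions.append(RegionAnnotation(profile.chain_id, run[0], run[-1],
                                        frozenset({EVIDENCE_HIGH_B})))
    for start, end, _ in profile.gaps:
        regions.append(RegionAnnotation(profile.chain_id, start, end,
                                        frozenset({EVIDENCE_UNMODELED})))
    regions.sort(key=lambda r: (r.start, r.end))
    return regions
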