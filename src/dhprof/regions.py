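"""Variable substrate-binding region calling.

A residue is called part of a variable region when it is simultaneously
poorly conserved (column entropy at or above a percentile cutoff of the
chain's mapped entropy track) and conformationally flexible (B-factor
z-score at or above a threshold, or the residue could not be modeled at
all — missing density is treated as the strongest disorder evidence, so
unmodeled residues pass the flexibility arm automatically and inherit
the entropy of their mapped alignment column).  Flagged residues are
merged into maximal segments allowing short interruptions, short
segments are dropped, and each called region carries the evidence tags
that contributed.

This operationalizes the observation that in dehydratase domains the
loops that diverge most in sequence across the family are the same loops
that are disordered in crystal structures, and that those loops line the
acyl-intermediate-binding cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .active_site import ActiveSiteGeometry
from .conservation import ColumnResidueMap, EntropyProfile
from .errors import ArgumentError
from .flexibility import (EVIDENCE_HIGH_B, EVIDENCE_UNMODELED,
                          FlexibilityProfile, RegionAnnotation)
from .structures import Structure

EVIDENCE_HIGH_H = "high_entropy"


@dataclass
class RegionCallParams:
    h_percentile: float = 75.0   # percentile of the mapped entropy track
    z_threshold: float = 1.0
    min_length: int = 3
    merge_gap: int = 1
    #: optional residue-range → canonical-name map, e.g. {(230, 245): "α3–β11"}
    labels: Mapping[tuple[int, int], str] = field(default_factory=dict)


@dataclass
class DomainProfile:
    """The full per-domain report produced by :func:`profile_domain`."""

    structure_id: str
    chain_id: str
    flexibility: FlexibilityProfile | None
    entropy: EntropyProfile | None
    column_map: ColumnResidueMap | None
    active_site: ActiveSiteGeometry | None
    regions: list[RegionAnnotation]
    params: RegionCallParams


def _label_for(start: int, end: int,
               labels: Mapping[tuple[int, int], str]) -> str:
    # a region takes a user label when it overlaps the labelled range
    for (ls, le), name in labels.items():
        if start <= le and end >= ls:
            return name
    return ""


def call_variable_regions(entropy_track: Mapping[tuple[int, str], float],
                          flex: FlexibilityProfile,
                          params: RegionCallParams | None = None,
                          ) -> list[RegionAnnotation]:
    """Call regions that are jointly high-entropy and flexible/unmodeled.

    ``entropy_track`` maps (residue number, insertion code) to column
    entropy in bits; it must share numbering with the flexibility
    profile.  Residues without an entropy value (unmapped columns) are
    never flagged.
    """
    params = params or RegionCallParams()
    if not entropy_track:
        return []
    profile_ids = {(r.number, r.icode) for r in flex.residues}
    if not (set(entropy_track) & profile_ids):
        raise ArgumentError("entropy track and flexibility profile share no "
                            "residue numbers; inputs indexed differently?")

    h_values = np.array(sorted(entropy_track.values()))
    h_cutoff = float(np.percentile(h_values, params.h_percentile))

    flagged: dict[int, set[str]] = {}
    z_map = flex.z_by_residue()
    unmodeled_nums = set()
    for start, end, _ in flex.gaps:
        unmodeled_nums.update(range(start, end + 1))

    for rid, h in entropy_track.items():
        num, icode = rid
        if icode or h < h_cutoff:
            continue
        evidence = {EVIDENCE_HIGH_H}
        z = z_map.get(rid)
        if num in unmodeled_nums:
            evidence.add(EVIDENCE_UNMODELED)
        if z is not None and z >= params.z_threshold:
            evidence.add(EVIDENCE_HIGH_B)
        if len(evidence) > 1:      # entropy arm plus at least one flexibility arm
            flagged[num] = evidence

    segments = _merge(sorted(flagged), params.merge_gap)
    regions: list[RegionAnnotation] = []
    for start, end in segments:
        if end - start + 1 < params.min_length:
            continue
        evidence: set[str] = set()
        hs, zs = [], []
        for num in range(start, end + 1):
            evidence |= flagged.get(num, set())
            h = entropy_track.get((num, ""))
            if h is not None:
                hs.append(h)
            z = z_map.get((num, ""))
            if z is not None:
                zs.append(z)
        regions.append(RegionAnnotation(
            chain_id=flex.chain_id, start=start, end=end,
            evidence=frozenset(evidence),
            label=_label_for(start, end, params.labels),
            mean_h=float(np.mean(hs)) if hs else None,
            mean_z=float(np.mean(zs)) if zs else None))
    regions.sort(key=lambda r: r.start)
    return regions


def _merge(numbers: list[int], merge_gap: int) -> list[tuple[int, int]]:
    segments: list[tuple[int, int]] = []
    start = prev = None
    for n in numbers:
        if start is None:
            start = prev = n
        elif n - prev <= merge_gap + 1:
            prev = n
        else:
            segments.append((start, prev))
            start = prev = n
    if start is not None:
        segments.append((start, prev))
    return segments


def profile_domain(structure: Structure, chain_id: str,
                   msa=None, reference_id: str | None = None,
                   params: RegionCallParams | None = None,
                   min_occupancy: float = 0.10,
                   z_threshold: float | None = None,
                   atom_selection: str = "CA",
                   with_active_site: bool = True,
                   ligand_spec: tuple[str, str, str] | None = None) -> DomainProfile:
    """Run the full profiling pipeline on one chain.

    Conservation is skipped when ``msa``/``reference_id`` are omitted, in
    which case regions come from flexibility evidence alone
    (high-B runs and unmodeled gaps, via ``flexible_segments``).
    """
    from . import active_site as asite
    from .conservation import entropy_profile, entropy_track, map_to_reference
    from .flexibility import bfactor_profile, flexible_segments

    params = params or RegionCallParams()
    if z_threshold is not None:
        params.z_threshold = z_threshold

    flex = bfactor_profile(structure, chain_id, atom_selection)

    ent = cmap = None
    if msa is not None and reference_id is not None:
        ent = entropy_profile(msa, min_occupancy)
        cmap = map_to_reference(msa, reference_id, structure, chain_id)
        track = entropy_track(ent, cmap)
        regions = call_variable_regions(track, flex, params)
    else:
        regions = flexible_segments(flex, params.z_threshold, params.min_length)
        regions = [RegionAnnotation(r.chain_id, r.start, r.end, r.evidence,
                                    _label_for(r.start, r.end, params.labels),
                                    r.mean_h, r.mean_z) for r in regions]

    geometry = None
    if with_active_site:
        try:
            geometry = asite.find_catalytic_dyad(structure, chain_id)
            geometry = asite.conserved_arg_distance(structure, chain_id, geometry)
            if ligand_spec is not None:
                geometry.ligand_reach = asite.ligand_reach(structure, ligand_spec)
        except Exception as exc:  # geometry is auxiliary; report, don't abort
            geometry = ActiveSiteGeometry(chain_id=chain_id,
                                          notes=[f"active-site stage skipped: {exc}"])

    return DomainProfile(structure_id=structure.id, chain_id=chain_id,
                         flexibility=flex, entropy=ent, column_map=cmap,
                         active_site=geometry, regions=regions, params=params)


# -- secondary structure ---------------------------------------------------

_PHI_HELIX = (-100.0, -30.0)
_PSI_HELIX = (-80.0, -5.0)
_PHI_STRAND = (-180.0, -40.0)


def secondary_structure(structure: Structure, chain_id: str) -> dict[int, str]:
    """Per-residue secondary structure: 'H' helix, 'E' strand, '-' coil.

    HELIX/SHEET records take precedence; chains without them fall back to
    a coarse backbone-dihedral rule (helix: φ∈[−100°,−30°], ψ∈[−80°,−5°],
    runs ≥ 4; strand: φ∈[−180°,−40°], ψ∈[90°,180°]∪[−180°,−170°],
    runs ≥ 3).
    """
    residues = [r for r in structure.chain(chain_id) if r.modeled]
    ss = {r.number: "-" for r in residues}
    annotated = False
    for cid, start, end in structure.helices:
        if cid == chain_id:
            annotated = True
            for n in range(start, end + 1):
                if n in ss:
                    ss[n] = "H"
    for cid, start, end in structure.sheets:
        if cid == chain_id:
            annotated = True
            for n in range(start, end + 1):
                if n in ss:
                    ss[n] = "E"
    if annotated:
        return ss

    # dihedral fallback
    import math
    raw: dict[int, str] = {}
    for prev, cur, nxt in zip(residues, residues[1:], residues[2:]):
        try:
            phi = _dihedral(prev.atom("C").position, cur.atom("N").position,
                            cur.atom("CA").position, cur.atom("C").position)
            psi = _dihedral(cur.atom("N").position, cur.atom("CA").position,
                            cur.atom("C").position, nxt.atom("N").position)
        except Exception:
            continue
        if _PHI_HELIX[0] <= phi <= _PHI_HELIX[1] and _PSI_HELIX[0] <= psi <= _PSI_HELIX[1]:
            raw[cur.number] = "H"
        elif _PHI_STRAND[0] <= phi <= _PHI_STRAND[1] and \
                (90.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0):
            raw[cur.number] = "E"
    # enforce minimum run lengths (helix 4, strand 3)
    for kind, min_run in (("H", 4), ("E", 3)):
        nums = sorted(n for n, s in raw.items() if s == kind)
        run: list[int] = []
        for n in nums + [None]:
            if run and (n is None or n != run[-1] + 1):
                if len(run) >= min_run:
                    for m in run:
                        ss[m] = kind
                run = []
            if n is not None:
                run.append(n)
    return ss


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))
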