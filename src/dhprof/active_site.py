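"""Conserved-motif scanning and dehydratase active-site geometry.

Type I PKS dehydratase domains carry an invariant His/Asp catalytic
dyad — the His sits at the start of the HxxxGxxxxP motif near β3, the
Asp within α3 — plus a conserved surface Arg (last residue of the
C-terminal LxLxR boundary motif on β14) implicated in docking the acyl
carrier protein's phosphopantetheine arm.  Three distances diagnose a
functional domain: the His(imidazole N)–Asp(carboxylate O) dyad gap, the
Arg Cα – His Cα span that accommodates the phosphopantetheine arm, and
the in-ligand reach from the PPant phosphate to the substrate C-3
position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, NotFoundError
from .structures import SequenceMap, Structure, chain_sequence

#: canonical conserved DH motifs (wildcard 'x' = any residue)
DH_MOTIFS = ("HxxxGxxxxP", "GYxYGPxF", "LPFxW", "HPLL", "LxLxR")

HIS_MOTIF_DEFAULT = "HxxxGxxxxP"
ARG_MOTIF = "LxLxR"

_HIS_N_ATOMS = ("ND1", "NE2")
_ASP_O_ATOMS = ("OD1", "OD2")


@dataclass
class MotifMatch:
    pattern: str
    start: int                      # 0-based index into the SequenceMap
    start_residue: tuple[int, str]  # author number + icode of first residue
    matched: str


@dataclass
class ActiveSiteGeometry:
    chain_id: str
    catalytic_his: tuple[int, str] | None = None
    catalytic_asp: tuple[int, str] | None = None
    dyad_distance: float | None = None       # Å, min over N×O atom pairs
    dyad_found: bool = False
    conserved_arg: tuple[int, str] | None = None
    arg_his_ca_distance: float | None = None  # Å
    ligand_reach: float | None = None         # Å
    notes: list[str] = field(default_factory=list)


def _compile(pattern: str) -> re.Pattern:
    bad = set(pattern) - set("ACDEFGHIKLMNPQRSTVWYx")
    if bad:
        raise ArgumentError(f"invalid motif character(s) {sorted(bad)} in {pattern!r}")
    return re.compile("".join("." if c == "x" else c for c in pattern))


def scan_motifs(seq: SequenceMap, patterns=DH_MOTIFS) -> list[MotifMatch]:
    """All exact wildcard matches of each motif, sorted by position."""
    matches: list[MotifMatch] = []
    for pattern in patterns:
        rx = _compile(pattern)
        pos = 0
        while True:
            m = rx.search(seq.one_letter, pos)
            if m is None:
                break
            _, num, icode = seq.index_to_residue[m.start()]
            matches.append(MotifMatch(pattern=pattern, start=m.start(),
                                      start_residue=(num, icode), matched=m.group()))
            pos = m.start() + 1   # overlapping matches allowed
    matches.sort(key=lambda m: (m.start, m.pattern))
    return matches


def _min_atom_distance(res_a, names_a, res_b, names_b) -> float | None:
    best = None
    for na in names_a:
        if not res_a.has_atom(na):
            continue
        pa = res_a.atom(na).position
        for nb in names_b:
            if not res_b.has_atom(nb):
                continue
            d = float(np.linalg.norm(pa - res_b.atom(nb).position))
            if best is None or d < best:
                best = d
    return best


def find_catalytic_dyad(structure: Structure, chain_id: str,
                        his_motif: str = HIS_MOTIF_DEFAULT,
                        max_dyad_distance: float = 4.0) -> ActiveSiteGeometry:
    """Locate the His/Asp catalytic dyad of a chain.

    The candidate His is the first residue of the first ``his_motif``
    match when the motif occurs; otherwise every His is considered.  The
    partner Asp is the one whose carboxylate O lies nearest any imidazole
    N of a candidate His; the pair is accepted when that distance is at
    most ``max_dyad_distance`` Å (the measured distance is always
    reported, accepted or not).
    """
    seq = chain_sequence(structure, chain_id)
    residues = {r.res_id: r for r in structure.chain(chain_id) if r.modeled}
    geometry = ActiveSiteGeometry(chain_id=chain_id)

    motif_hits = scan_motifs(seq, (his_motif,))
    if motif_hits:
        candidates = [motif_hits[0].start_residue]
    else:
        candidates = [(num, ic) for (_, num, ic), letter
                      in zip(seq.index_to_residue, seq.one_letter) if letter == "H"]
    if not candidates:
        raise NotFoundError(f"chain {chain_id!r} contains no histidine")

    asps = [r for r in residues.values() if r.name == "ASP"]
    best: tuple[float, tuple[int, str], tuple[int, str]] | None = None
    for his_id in candidates:
        his = residues.get(his_id)
        if his is None:
            continue
        for asp in asps:
            d = _min_atom_distance(his, _HIS_N_ATOMS, asp, _ASP_O_ATOMS)
            if d is not None and (best is None or d < best[0]):
                best = (d, his_id, asp.res_id)

    if best is None:
        geometry.catalytic_his = candidates[0]
        geometry.notes.append("no Asp with carboxylate oxygens found; dyad not measurable")
        return geometry
    d, his_id, asp_id = best
    geometry.catalytic_his = his_id
    geometry.catalytic_asp = asp_id
    geometry.dyad_distance = d
    geometry.dyad_found = d <= max_dyad_distance
    if not geometry.dyad_found:
        geometry.notes.append(
            f"nearest His-Asp N···O distance {d:.2f} Å exceeds cutoff {max_dyad_distance} Å")
    return geometry


def conserved_arg_distance(structure: Structure, chain_id: str,
                           geometry: ActiveSiteGeometry,
                           arg_motif: str = ARG_MOTIF) -> ActiveSiteGeometry:
    """Add the conserved-Arg Cα to catalytic-His Cα distance to a geometry.

    The conserved Arg is the arginine of the last ``arg_motif`` (LxLxR)
    match in the chain — the motif marks the C-terminal domain boundary
    on β14, so the last occurrence is the β14-proximal one.
    """
    if geometry.catalytic_his is None:
        raise ArgumentError("catalytic His must be located before the Arg measurement")
    seq = chain_sequence(structure, chain_id)
    residues = {r.res_id: r for r in structure.chain(chain_id) if r.modeled}

    hits = [m for m in scan_motifs(seq, (arg_motif,))]
    if not hits:
        warnings.warn(f"chain {chain_id}: no {arg_motif} motif; conserved Arg not assigned",
                      stacklevel=2)
        return geometry
    last = hits[-1]
    arg_index = last.start + len(last.pattern) - 1
    _, num, icode = seq.index_to_residue[arg_index]
    geometry.conserved_arg = (num, icode)

    his = residues.get(geometry.catalytic_his)
    arg = residues.get((num, icode))
    if his is None or arg is None or not his.has_atom("CA") or not arg.has_atom("CA"):
        geometry.notes.append("Cα missing on His or Arg; distance not measured")
        return geometry
    geometry.arg_his_ca_distance = float(
        np.linalg.norm(his.atom("CA").position - arg.atom("CA").position))
    return geometry


def ligand_reach(structure: Structure,
                 ligand_spec: tuple[str, str, str]) -> float:
    """Distance (Å) between two named atoms of a bound ligand.

    ``ligand_spec`` is (het code, atom A, atom B), e.g. the
    phosphopantetheine phosphate to the substrate C-3 carbon of a bound
    acyl thioester.
    """
    het_code, atom_a, atom_b = ligand_spec
    for _, res in structure.ligands:
        if res.name == het_code.upper():
            if not res.has_atom(atom_a):
                raise NotFoundError(f"ligand {het_code}: atom {atom_a!r} not present")
            if not res.has_atom(atom_b):
                raise NotFoundError(f"ligand {het_code}: atom {atom_b!r} not present")
            return float(np.linalg.norm(res.atom(atom_a).position -
                                        res.atom(atom_b).position))
    raise NotFoundError(f"ligand {het_code!r} not found in structure {structure.id!r}")
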