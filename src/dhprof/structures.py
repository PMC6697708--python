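"""Coordinate-file I/O and a uniform hierarchical structure model.

Reads PDB and mmCIF files (via gemmi) into a light chain/residue/atom
model that keeps exactly what downstream profiling needs: coordinates,
B-factors, occupancies, declared-missing (unmodeled) residues, ligand
heteroatoms, and HELIX/SHEET annotations.  Reports always use author
residue numbering with insertion codes, matching how crystallographic
papers cite residues (e.g. His 69, Asp 231 of a dehydratase dyad).

Alternate locations are collapsed to a single copy per atom: highest
occupancy wins, ties broken by altloc letter ('A' first) — the standard
crystallographic convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

from .errors import FormatError, NotFoundError, ParseError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: residue number + insertion code, the key used throughout the package
ResId = tuple[int, str]


@dataclass
class Atom:
    """A single (altloc-collapsed) atom."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise FormatError(f"atom {self.name}: position must be 3 finite numbers")
        if not 0.0 <= self.occupancy <= 1.0:
            raise FormatError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if self.b_factor < 0:
            raise FormatError(f"atom {self.name}: negative B-factor {self.b_factor}")


@dataclass
class Residue:
    """A residue; ``modeled=False`` marks missing-density records with no atoms."""

    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    modeled: bool = True

    @property
    def res_id(self) -> ResId:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise NotFoundError(f"atom {name!r} not found in {self.name} {self.number}{self.icode}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """Polymer chains plus a separate ligand store (waters and heteroatoms)."""

    id: str
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    ligands: list[tuple[str, Residue]] = field(default_factory=list)
    source_format: str = "PDB"
    helices: list[tuple[str, int, int]] = field(default_factory=list)  # chain, start, end
    sheets: list[tuple[str, int, int]] = field(default_factory=list)

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise NotFoundError(f"chain {chain_id!r} not in structure {self.id!r} "
                            f"(has {self.chain_ids()})")


@dataclass
class SequenceMap:
    """One-letter sequence of modeled residues with pointers back to the chain."""

    one_letter: str
    index_to_residue: list[tuple[str, int, str]]  # (chain_id, number, icode)

    def __len__(self) -> int:
        return len(self.one_letter)


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    # keep highest occupancy per atom name; ties broken by altloc letter
    by_name: dict[str, Atom] = {}
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
                prev.occupancy, _altloc_rank(prev.altloc)):
            by_name[atom.name] = atom
    return list(by_name.values())


def _altloc_rank(altloc: str) -> float:
    # 'A' preferred over 'B' etc.; blank sorts first overall but blank
    # altlocs never collide with lettered ones for the same atom name
    return -ord(altloc) if altloc else 0.0


def _parse_remark_465(path: Path) -> list[tuple[str, str, int, str]]:
    """Missing residues declared in PDB REMARK 465: (chain, resname, num, icode)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("REMARK 465"):
                continue
            body = line[10:].rstrip("\n")
            # data lines: "     ALA A   240" (optionally a model number first)
            fields = body.split()
            if len(fields) < 3:
                continue
            if len(fields) == 4 and fields[0].isdigit():
                fields = fields[1:]
            resname, chain, numfield = fields[0], fields[1], fields[2]
            if resname.upper() not in THREE_TO_ONE and resname.upper() not in ("MSE",) \
                    and not resname.isalpha():
                continue
            if len(chain) != 1:
                continue
            icode = ""
            if numfield and numfield[-1].isalpha():
                icode = numfield[-1]
                numfield = numfield[:-1]
            try:
                num = int(numfield)
            except ValueError:
                continue
            out.append((chain, resname.upper(), num, icode))
    return out


def _missing_from_mmcif(path: Path) -> list[tuple[str, str, int, str]]:
    """Missing residues from the _pdbx_unobs_or_zero_occ_residues category."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    table = block.find("_pdbx_unobs_or_zero_occ_residues.",
                       ["auth_asym_id", "auth_comp_id", "auth_seq_id"])
    out = []
    for row in table:
        chain, resname, num = row[0], row[1], row[2]
        icode = ""
        if num and num[-1].isalpha():
            icode, num = num[-1], num[:-1]
        try:
            out.append((chain, resname.upper(), int(num), icode))
        except ValueError:
            continue
    return out


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_water():
        return False
    if res.name.upper() in THREE_TO_ONE or res.name.upper() == "MSE":
        return True
    return info is not None and info.is_amino_acid()


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Polymer ATOM records populate the chains; waters and ligand HETATM
    records go to the ligand store; REMARK 465 (PDB) or
    ``_pdbx_unobs_or_zero_occ_residues`` (mmCIF) entries become unmodeled
    residues interleaved at their author-numbered positions.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown coordinate format {format!r} (expected PDB, mmCIF or auto)")

    try:
        coor_fmt = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
        st = gemmi.read_structure(str(path), format=coor_fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name} as {fmt.upper()}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path.name}: no models found")

    missing = _parse_remark_465(path) if fmt == "pdb" else _missing_from_mmcif(path)

    structure = Structure(id=st.name or path.stem,
                          source_format="PDB" if fmt == "pdb" else "mmCIF")
    model = st[0]
    seen_chain_ids: set[str] = set()
    for gchain in model:
        cid = gchain.name
        if cid in seen_chain_ids:
            raise FormatError(f"{path.name}: duplicate chain id {cid!r}")
        seen_chain_ids.add(cid)
        residues: list[Residue] = []
        for gres in gchain:
            atoms = [Atom(name=a.name, element=a.element.name,
                          position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                          occupancy=min(max(a.occ, 0.0), 1.0), b_factor=max(a.b_iso, 0.0),
                          altloc=a.altloc if a.altloc != "\x00" else "")
                     for a in gres]
            res = Residue(name=gres.name.upper(), number=gres.seqid.num,
                          icode=gres.seqid.icode.strip(), atoms=_collapse_altlocs(atoms))
            if _is_polymer_residue(gres):
                residues.append(res)
            else:
                structure.ligands.append((cid, res))
        if residues:
            structure.chains.append((cid, residues))

    # splice declared-missing residues into their chains
    for chain_id, resname, num, icode in missing:
        ghost = Residue(name=resname, number=num, icode=icode, atoms=[], modeled=False)
        placed = False
        for cid, residues in structure.chains:
            if cid == chain_id:
                if any(r.res_id == ghost.res_id for r in residues):
                    placed = True  # already modeled; declaration ignored
                    break
                residues.append(ghost)
                placed = True
                break
        if not placed:
            structure.chains.append((chain_id, [ghost]))

    for cid, residues in structure.chains:
        residues.sort(key=lambda r: (r.number, r.icode))

    for helix in st.helices:
        structure.helices.append((helix.start.chain_name,
                                  helix.start.res_id.seqid.num,
                                  helix.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            structure.sheets.append((strand.start.chain_name,
                                     strand.start.res_id.seqid.num,
                                     strand.end.res_id.seqid.num))
    return structure


def chain_sequence(structure: Structure, chain_id: str,
                   mse_as_met: bool = False) -> SequenceMap:
    """One-letter sequence of the modeled residues of a chain, in chain order.

    Nonstandard residues map to ``'X'``; selenomethionine maps to ``'M'``
    when ``mse_as_met`` is set.
    """
    residues = structure.chain(chain_id)
    letters: list[str] = []
    pointers: list[tuple[str, int, str]] = []
    for res in residues:
        if not res.modeled:
            continue
        if res.name in THREE_TO_ONE:
            letters.append(THREE_TO_ONE[res.name])
        elif res.name == "MSE" and mse_as_met:
            letters.append("M")
        else:
            letters.append("X")
        pointers.append((chain_id, res.number, res.icode))
    if not letters:
        raise NotFoundError(f"chain {chain_id!r} has no modeled residues")
    return SequenceMap(one_letter="".join(letters), index_to_residue=pointers)


def unmodeled_segments(structure: Structure, chain_id: str) -> list[tuple[int, int, int]]:
    """Contiguous unmodeled stretches of a chain as (start, end, length).

    The union of declared-missing residues and inferred author-numbering
    gaps between consecutive modeled residues.  Inference assumes monotone
    numbering; a non-monotone chain disables inference with a warning.
    Insertion-coded residues never contribute to inference.
    """
    residues = structure.chain(chain_id)
    missing_nums: set[int] = set()
    modeled_nums: list[int] = []
    for res in residues:
        if res.modeled:
            if not res.icode:
                modeled_nums.append(res.number)
        elif not res.icode:
            missing_nums.add(res.number)

    monotone = all(b > a for a, b in zip(modeled_nums, modeled_nums[1:]))
    if not monotone:
        warnings.warn(f"chain {chain_id}: non-monotone residue numbering; "
                      "gap inference disabled", stacklevel=2)
    else:
        for a, b in zip(modeled_nums, modeled_nums[1:]):
            missing_nums.update(range(a + 1, b))

    modeled_set = set(modeled_nums)
    missing_nums -= modeled_set
    return _runs(sorted(missing_nums))


def _runs(numbers: Iterable[int]) -> list[tuple[int, int, int]]:
    segments: list[tuple[int, int, int]] = []
    start = prev = None
    for n in numbers:
        if start is None:
            start = prev = n
        elif n == prev + 1:
            prev = n
        else:
            segments.append((start, prev, prev - start + 1))
            start = prev = n
    if start is not None:
        segments.append((start, prev, prev - start + 1))
    return segments


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a minimal PDB dialect: REMARK 465, HELIX, SHEET, ATOM/HETATM, END.

    Sufficient for fixtures and for handing transformed coordinates to a
    molecular viewer; not a general-purpose deposition writer.
    """
    lines: list[str] = []
    header = False
    for cid, residues in structure.chains:
        for res in residues:
            if res.modeled:
                continue
            if not header:
                lines.append("REMARK 465   M RES C SSSEQI")
                header = True
            lines.append(f"REMARK 465     {res.name:>3s} {cid}{res.number:>6d}{res.icode:1s}".rstrip())
    for i, (cid, start, end) in enumerate(structure.helices, 1):
        chain = {r.res_id: r for r in structure.chain(cid)}
        sname = chain.get((start, ""), Residue("ALA", start)).name
        ename = chain.get((end, ""), Residue("ALA", end)).name
        lines.append(f"HELIX  {i:>3d} {i:>3d} {sname:>3s} {cid} {start:>4d}  "
                     f"{ename:>3s} {cid} {end:>4d}  1{'':>30s}{end - start + 1:>6d}")
    for i, (cid, start, end) in enumerate(structure.sheets, 1):
        chain = {r.res_id: r for r in structure.chain(cid)}
        sname = chain.get((start, ""), Residue("ALA", start)).name
        ename = chain.get((end, ""), Residue("ALA", end)).name
        lines.append(f"SHEET  {i:>3d} S{i:>2d} 1 {sname:>3s} {cid}{start:>4d}  "
                     f"{ename:>3s} {cid}{end:>4d}  0")
    serial = 1
    for cid, residues in structure.chains:
        for res in residues:
            for atom in res.atoms:
                lines.append(_atom_line("ATOM", serial, atom, res, cid))
                serial += 1
    for cid, res in structure.ligands:
        for atom in res.atoms:
            lines.append(_atom_line("HETATM", serial, atom, res, cid))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _atom_line(record: str, serial: int, atom: Atom, res: Residue, cid: str) -> str:
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.position
    return (f"{record:<6s}{serial:>5d} {name:<4s}{atom.altloc or ' '}{res.name:>3s} "
            f"{cid}{res.number:>4d}{res.icode or ' '}   "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{atom.occupancy:>6.2f}{atom.b_factor:>6.2f}"
            f"{'':>10s}{atom.element:>2s}")
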