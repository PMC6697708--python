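"""Occupancy-refined per-column Shannon entropy over a protein MSA.

The conservation statistic is the column Shannon entropy

    H_j = − Σ_i p_ij · log2 p_ij                     [bits]

where p_ij are amino-acid frequencies at column j over the 20 standard
residues; gaps and ambiguous letters are excluded from the frequency
counts (ambiguous letters still count toward occupancy — they are
occupied positions with no unambiguous frequency bin).  Before entropy
is computed the alignment is refined so every retained column has at
least a minimum fraction of non-gap characters (default 10%, inclusive),
which removes insert states carried by a handful of sequences.

A column→residue map ties retained columns to author-numbered residues
of a reference structure so that entropy can be plotted along a chain
and combined with crystallographic flexibility evidence.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .align import AlignmentParams, global_align
from .errors import (ArgumentError, EmptyAlignmentError, FormatError,
                     NotFoundError, ReferenceMismatchError)
from .structures import SequenceMap, Structure, chain_sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MAX_ENTROPY_BITS = math.log2(20)


@dataclass
class MSA:
    """An ordered multiple sequence alignment; gap character normalized to '-'."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("empty alignment")
        norm = []
        length = None
        for rid, seq in self.records:
            seq = seq.upper().replace(".", "-")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise FormatError(f"ragged alignment: {rid!r} has length "
                                  f"{len(seq)}, expected {length}")
            norm.append((rid, seq))
        self.records = norm

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.records)

    def row(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise NotFoundError(f"sequence id {rid!r} not in alignment")


def read_msa(path: str | Path, fmt: str = "auto") -> MSA:
    """Read a gapped FASTA, Clustal or Stockholm alignment."""
    path = Path(path)
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = {"aln": "clustal", "clustal": "clustal", "sto": "stockholm",
               "stk": "stockholm", "stockholm": "stockholm"}.get(suffix.lstrip("."), "fasta")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot read {path.name} as {fmt}: {exc}") from exc
    return MSA(records=[(rec.id, str(rec.seq)) for rec in aln])


def column_occupancy(msa: MSA) -> np.ndarray:
    """Per-column fraction of non-gap characters."""
    arr = np.frombuffer("".join(seq for _, seq in msa.records).encode("ascii"),
                        dtype="S1").reshape(msa.n_sequences, msa.n_columns)
    return (arr != b"-").mean(axis=0)


def refine_msa(msa: MSA, min_occupancy: float = 0.10) -> tuple[MSA, list[int]]:
    """Drop columns whose occupancy falls below ``min_occupancy`` (inclusive keep).

    Returns the refined alignment and the original indices of retained columns.
    """
    if not 0.0 < min_occupancy <= 1.0:
        raise ArgumentError(f"min_occupancy must be in (0,1], got {min_occupancy}")
    occ = column_occupancy(msa)
    retained = [j for j in range(msa.n_columns) if occ[j] >= min_occupancy]
    if not retained:
        raise EmptyAlignmentError(
            f"no column reaches occupancy {min_occupancy}; alignment empty after refinement")
    refined = MSA(records=[(rid, "".join(seq[j] for j in retained))
                           for rid, seq in msa.records])
    return refined, retained


def shannon_entropy(column: str, base: float = 2.0) -> float:
    """Shannon entropy of one alignment column over the 20 standard residues.

    Gaps and nonstandard letters are excluded from the counts.  Base 2
    gives bits (default); base e gives nats.
    """
    counts = Counter(c for c in column.upper() if c in _AA_INDEX)
    total = sum(counts.values())
    if total == 0:
        raise ArgumentError("entropy undefined: column has no standard residues")
    p = np.array(list(counts.values()), dtype=float) / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


@dataclass
class EntropyProfile:
    """Per-column occupancy, entropy, and residue frequencies after refinement."""

    column_indices: list[int]          # original MSA column index
    occupancy: np.ndarray
    entropy: np.ndarray                # bits (or nats when base=e)
    frequencies: np.ndarray            # n_columns × 20, rows sum to 1
    min_occupancy: float
    base: float = 2.0

    def entropy_at(self, original_index: int) -> float:
        return float(self.entropy[self.column_indices.index(original_index)])


def entropy_profile(msa: MSA, min_occupancy: float = 0.10,
                    base: float = 2.0) -> EntropyProfile:
    """Occupancy refinement followed by per-column Shannon entropy."""
    occ_full = column_occupancy(msa)
    refined, retained = refine_msa(msa, min_occupancy)
    n = len(retained)
    entropy = np.zeros(n)
    freqs = np.zeros((n, 20))
    for k in range(n):
        column = refined.column(k)
        counts = np.zeros(20)
        for c in column:
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        if total > 0:
            p = counts / total
            freqs[k] = p
            nz = p[p > 0]
            entropy[k] = float(-(nz * (np.log(nz) / np.log(base))).sum())
    return EntropyProfile(column_indices=retained,
                          occupancy=occ_full[retained].copy(),
                          entropy=entropy, frequencies=freqs,
                          min_occupancy=min_occupancy, base=base)


@dataclass
class ColumnResidueMap:
    """Bijective pairing of MSA columns with reference-chain residue numbers."""

    pairs: list[tuple[int, tuple[int, str]]]   # (column index, (resnum, icode))
    reference_id: str
    chain_id: str = ""
    identity: float = 1.0

    def column_for_residue(self) -> dict[tuple[int, str], int]:
        return {rid: col for col, rid in self.pairs}

    def residue_for_column(self) -> dict[int, tuple[int, str]]:
        return dict(self.pairs)


def map_to_reference(msa: MSA, reference_id: str, structure: Structure,
                     chain_id: str, min_identity: float = 0.9,
                     align_params: AlignmentParams | None = None,
                     infer_unmodeled: bool = True) -> ColumnResidueMap:
    """Map MSA columns to author residue numbers of a reference chain.

    The reference row is ungapped and globally aligned to the chain's
    modeled sequence; columns where the reference row is non-gap are then
    carried through the alignment onto residue numbers.  Mismatched
    terminal pairs are trimmed so map ends are trustworthy.

    With ``infer_unmodeled`` (default), reference positions left unpaired
    because the chain residue is unmodeled are assigned their residue
    numbers by interpolation whenever the run of skipped reference
    positions exactly matches the author-numbering gap between the
    flanking mapped residues — so missing-density loops still receive a
    column (and hence an entropy value).
    """
    row = msa.row(reference_id)
    ungapped = row.replace("-", "")
    if not ungapped:
        raise ReferenceMismatchError(f"reference row {reference_id!r} is all gaps")
    chain_map = chain_sequence(structure, chain_id)
    alignment = global_align(ungapped, chain_map.one_letter, align_params)
    if alignment.identity < min_identity:
        raise ReferenceMismatchError(
            f"reference row {reference_id!r} matches chain {chain_id!r} at identity "
            f"{alignment.identity:.3f} < {min_identity}; wrong chain or sequence?")

    # residue position in ungapped reference row -> original MSA column
    ref_columns = [j for j, c in enumerate(row) if c != "-"]

    pairs: list[tuple[int, tuple[int, str]]] = []
    for ia, ib in alignment.pairs:
        _, num, icode = chain_map.index_to_residue[ib]
        pairs.append((ref_columns[ia], (num, icode)))
    # trim mismatched tails
    ref_letters = {ref_columns[ia]: ungapped[ia] for ia, _ in alignment.pairs}
    chain_letters = {ref_columns[ia]: chain_map.one_letter[ib]
                     for ia, ib in alignment.pairs}
    while pairs and ref_letters[pairs[0][0]] != chain_letters[pairs[0][0]]:
        pairs.pop(0)
    while pairs and ref_letters[pairs[-1][0]] != chain_letters[pairs[-1][0]]:
        pairs.pop()

    if infer_unmodeled and pairs:
        aligned_ref = {ia for ia, _ in alignment.pairs}
        col_to_refpos = {col: ia for ia, col in
                         ((i, ref_columns[i]) for i in range(len(ungapped)))}
        inferred: list[tuple[int, tuple[int, str]]] = []
        for (col_a, (num_a, ic_a)), (col_b, (num_b, ic_b)) in zip(pairs, pairs[1:]):
            if ic_a or ic_b:
                continue
            ia, ib_pos = col_to_refpos[col_a], col_to_refpos[col_b]
            skipped = [i for i in range(ia + 1, ib_pos) if i not in aligned_ref]
            gap = num_b - num_a - 1
            if gap > 0 and len(skipped) == ib_pos - ia - 1 == gap:
                for offset, i in enumerate(skipped, start=1):
                    inferred.append((ref_columns[i], (num_a + offset, "")))
        pairs = sorted(pairs + inferred)
    return ColumnResidueMap(pairs=pairs, reference_id=reference_id,
                            chain_id=chain_id, identity=alignment.identity)


def entropy_track(profile: EntropyProfile,
                  mapping: ColumnResidueMap) -> dict[tuple[int, str], float]:
    """Per-residue entropy values: the profile pushed through a column map."""
    by_column = {col: h for col, h in zip(profile.column_indices, profile.entropy)}
    track: dict[tuple[int, str], float] = {}
    for col, rid in mapping.pairs:
        if col in by_column:
            track[rid] = float(by_column[col])
    return track
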