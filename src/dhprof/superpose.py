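"""Rigid-body Cα superposition with iterative outlier rejection.

The core fit is the Kabsch algorithm: the closed-form least-squares
rotation between two paired point sets via singular value decomposition
of the cross-covariance matrix, with the reflection corrected so the
returned rotation is proper (det +1).

``iterative_superpose`` reproduces the protocol behind "RMSD x Å within
N residues" figures common in structural comparisons of homologous
domains: Cα pairs are taken from the gapless columns of a global
sequence alignment, fitted, and pairs deviating beyond a cutoff are
rejected in batches until convergence.  The final RMSD is therefore a
core RMSD over the retained pairs, and the cycle trace records how many
pairs each round discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentParams, global_align
from .errors import ArgumentError, DegenerateSuperpositionError
from .structures import SequenceMap, Structure, chain_sequence

#: singular-value ratio below which the point set is treated as collinear
_DEGENERACY_TOL = 1e-9


@dataclass
class SuperpositionResult:
    """Rigid transform mapping the mobile set onto the reference set."""

    rotation: np.ndarray          # 3x3, proper orthonormal
    translation: np.ndarray       # 3-vector, Å
    rmsd: float                   # Å over retained pairs
    n_pairs: int
    cycles: list[tuple[int, int, float, int]] = field(default_factory=list)
    degenerate: bool = False      # collinear/planar input: rotation not unique
    #: residue ids (number, icode) of the retained pairs, reference chain
    retained: list[tuple[int, str]] = field(default_factory=list)
    #: residue ids rejected across all cycles, reference chain
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an N×3 coordinate array."""
        return coords @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform mapping ``coords_b`` onto ``coords_a``.

    Both arrays are N×3 and paired row-for-row, N ≥ 3.  Collinear input
    yields a flagged (``degenerate=True``) but still least-squares-valid
    result rather than an exception.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ArgumentError(f"paired N×3 arrays required, got {a.shape} and {b.shape}")
    if a.shape[0] < 3:
        raise DegenerateSuperpositionError(
            f"at least 3 point pairs required, got {a.shape[0]}")

    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    aa = a - centroid_a
    bb = b - centroid_b

    h = bb.T @ aa                       # cross-covariance
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T        # maps centered b onto centered a
    translation = centroid_a - rotation @ centroid_b

    diff = bb @ rotation.T - aa
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    degenerate = bool(s[0] > 0 and s[1] / s[0] < _DEGENERACY_TOL)
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_pairs=a.shape[0],
                               cycles=[(1, a.shape[0], rmsd, 0)],
                               degenerate=degenerate)


def _paired_ca_coords(structure_a: Structure, chain_a: str,
                      structure_b: Structure, chain_b: str,
                      params: AlignmentParams | None):
    """Cα coordinate pairs from the gapless columns of a sequence alignment."""
    seq_a = chain_sequence(structure_a, chain_a)
    seq_b = chain_sequence(structure_b, chain_b)
    alignment = global_align(seq_a.one_letter, seq_b.one_letter, params)

    res_a = {r.res_id: r for r in structure_a.chain(chain_a) if r.modeled}
    res_b = {r.res_id: r for r in structure_b.chain(chain_b) if r.modeled}

    ids_a, pts_a, pts_b = [], [], []
    for ia, ib in alignment.pairs:
        _, num_a, ic_a = seq_a.index_to_residue[ia]
        _, num_b, ic_b = seq_b.index_to_residue[ib]
        ra, rb = res_a[(num_a, ic_a)], res_b[(num_b, ic_b)]
        if ra.has_atom("CA") and rb.has_atom("CA"):
            ids_a.append((num_a, ic_a))
            pts_a.append(ra.atom("CA").position)
            pts_b.append(rb.atom("CA").position)
    return ids_a, np.array(pts_a, dtype=float), np.array(pts_b, dtype=float)


def iterative_superpose(structure_a: Structure, chain_a: str,
                        structure_b: Structure, chain_b: str,
                        cutoff: float = 2.0, max_cycles: int = 5,
                        align_params: AlignmentParams | None = None,
                        ) -> SuperpositionResult:
    """Sequence-guided Cα superposition with per-cycle batch outlier rejection.

    Pairs come from gapless alignment columns of modeled residues only.
    After each Kabsch fit, every pair deviating more than ``cutoff`` Å is
    dropped and the fit repeated, until no pair is rejected or
    ``max_cycles`` is reached.
    """
    if cutoff <= 0:
        raise ArgumentError(f"cutoff must be positive, got {cutoff}")
    ids, pts_a, pts_b = _paired_ca_coords(structure_a, chain_a,
                                          structure_b, chain_b, align_params)
    if len(ids) < 3:
        raise DegenerateSuperpositionError(
            f"only {len(ids)} aligned Cα pairs between "
            f"{chain_a} and {chain_b}; need at least 3")

    keep = np.ones(len(ids), dtype=bool)
    cycles: list[tuple[int, int, float, int]] = []
    result: SuperpositionResult | None = None
    for cycle in range(1, max_cycles + 1):
        result = kabsch(pts_a[keep], pts_b[keep])
        deviations = np.linalg.norm(result.transform(pts_b) - pts_a, axis=1)
        outliers = keep & (deviations > cutoff)
        cycles.append((cycle, int(keep.sum()), result.rmsd, int(outliers.sum())))
        # at max_cycles the last rejection is not applied, so the reported
        # rmsd always corresponds to the retained pair set
        if not outliers.any() or cycle == max_cycles:
            break
        if (keep & ~outliers).sum() < 3:
            raise DegenerateSuperpositionError(
                f"outlier rejection at cutoff {cutoff} Å left fewer than 3 pairs")
        keep &= ~outliers

    assert result is not None
    result.cycles = cycles
    result.n_pairs = int(keep.sum())
    result.retained = [rid for rid, k in zip(ids, keep) if k]
    result.rejected = [rid for rid, k in zip(ids, keep) if not k]
    return result
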