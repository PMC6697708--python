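"""Independent reference implementations used only to check dhprof.

Each oracle deliberately uses a different algorithm (or a naive
brute-force formulation) than the library code it validates, so
agreement is evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices


def quaternion_superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Horn's quaternion method for least-squares rigid superposition.

    Returns (rotation, rmsd) mapping ``coords_b`` onto ``coords_a``.
    Entirely SVD-free: builds the 4x4 key matrix from the cross-covariance
    and takes the eigenvector of its largest eigenvalue.
    """
    a = coords_a - coords_a.mean(axis=0)
    b = coords_b - coords_b.mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    eigvals, eigvecs = np.linalg.eigh(key)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    rotation = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    diff = b @ rotation.T - a
    rmsd = math.sqrt((diff ** 2).sum() / a.shape[0])
    return rotation, rmsd


def gotoh_score(seq_a: str, seq_b: str, matrix_name: str = "BLOSUM62",
                gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Affine-gap global alignment score by explicit three-state DP.

    The opening of a gap costs ``gap_open`` for the first gapped position
    and ``gap_extend`` for each further position (matching Biopython's
    open/extend convention where the first gap position scores
    ``-gap_open``).
    """
    matrix = substitution_matrices.load(matrix_name)
    n, m = len(seq_a), len(seq_b)
    neg = -math.inf
    M = np.full((n + 1, m + 1), neg)   # match/mismatch state
    X = np.full((n + 1, m + 1), neg)   # gap in seq_b (up)
    Y = np.full((n + 1, m + 1), neg)   # gap in seq_a (left)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def column_entropy_bits(column: str) -> float:
    """Plain-arithmetic Shannon entropy over the 20 standard residues."""
    counts = Counter(c for c in column.upper() if c in "ACDEFGHIKLMNPQRSTVWY")
    total = sum(counts.values())
    h = 0.0
    for count in counts.values():
        p = count / total
        h -= p * math.log2(p)
    return h


def sliding_window_matches(sequence: str, pattern: str) -> list[int]:
    """Naive wildcard motif scan: all start indices where pattern fits."""
    hits = []
    k = len(pattern)
    for i in range(len(sequence) - k + 1):
        if all(pc == "x" or pc == sc
               for pc, sc in zip(pattern, sequence[i:i + k])):
            hits.append(i)
    return hits


def brute_force_dyad(structure, chain_id: str):
    """Minimum His(N)–Asp(O) distance over every His×Asp pair of a chain.

    Returns ((his_num, his_icode), (asp_num, asp_icode), distance) or None.
    """
    residues = [r for r in structure.chain(chain_id) if r.modeled]
    best = None
    for his in residues:
        if his.name != "HIS":
            continue
        for asp in residues:
            if asp.name != "ASP":
                continue
            for na in ("ND1", "NE2"):
                if not his.has_atom(na):
                    continue
                for no in ("OD1", "OD2"):
                    if not asp.has_atom(no):
                        continue
                    d = float(np.linalg.norm(his.atom(na).position -
                                             asp.atom(no).position))
                    if best is None or d < best[2]:
                        best = (his.res_id, asp.res_id, d)
    return best


def missing_numbers(full_range: range, modeled: set[int]) -> list[tuple[int, int, int]]:
    """Set-difference oracle for unmodeled segments over a numbering range."""
    missing = sorted(set(full_range) - modeled)
    segments = []
    start = prev = None
    for n in missing:
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
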