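"""Sequence alignment, alignment restriction, and rigid superposition.

Morphing needs its two endpoint conformations to (a) have the same number of
points and (b) sit in the same coordinate frame.  When the inputs differ in
length we align their sequences with Needleman-Wunsch (BLOSUM62, gap open
-10, gap extend -1 by default) and keep only the aligned positions; the end
structure is then rigidly superposed onto the start with the Kabsch
(SVD-based least-squares) algorithm.

Restriction can place residues next to each other that were not consecutive
in the original start structure.  Those positions are recorded in the
``broken_edge`` / ``broken_angle`` flags of :class:`AlignedPair`; the DP
scoring later treats the corresponding bond-length and bond-angle windows as
free (score 0), since no physical pseudo-bond exists there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_structures import CaTrace

__all__ = [
    "AlignedPair",
    "RigidTransform",
    "global_align",
    "alignment_score",
    "restrict_to_aligned",
    "kabsch_superpose",
    "rmsd",
    "preprocess_pair",
]

AlignmentColumns = list          # list[tuple[Optional[int], Optional[int]]]


@dataclass
class RigidTransform:
    """A proper rotation plus translation: x -> R x + t."""

    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be a proper rotation (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class AlignedPair:
    """Two equal-length traces plus chain-continuity flags.

    ``broken_edge[j]`` is True when aligned positions j and j+1 are not
    consecutive residues of the original start structure; ``broken_angle[j]``
    is True when either flanking edge is broken (always True at the termini,
    where no angle is defined).
    """

    start: CaTrace
    end: CaTrace
    broken_edge: np.ndarray
    broken_angle: np.ndarray

    def __post_init__(self) -> None:
        if len(self.start) != len(self.end):
            raise ValueError("start and end traces must have equal length")
        n = len(self.start)
        self.broken_edge = np.asarray(self.broken_edge, dtype=bool)
        self.broken_angle = np.asarray(self.broken_angle, dtype=bool)
        if self.broken_edge.shape != (n - 1,) or self.broken_angle.shape != (n,):
            raise ValueError("flag arrays must have lengths n-1 and n")
        if not (self.broken_angle[0] and self.broken_angle[-1]):
            raise ValueError("terminal broken_angle flags must be True")

    @property
    def n(self) -> int:
        return len(self.start)


def _make_aligner(matrix: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _check_sequences(seq_a: str, seq_b: str) -> None:
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")


def alignment_score(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                    open_gap: float = -10.0, extend_gap: float = -1.0) -> float:
    """Optimal global alignment score (symmetric in its arguments)."""
    _check_sequences(seq_a, seq_b)
    return float(_make_aligner(matrix, open_gap, extend_gap).score(seq_a, seq_b))


def global_align(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                 open_gap: float = -10.0, extend_gap: float = -1.0) -> AlignmentColumns:
    """Needleman-Wunsch global alignment as a list of index columns.

    Returns one ``(i, j)`` tuple per alignment column; ``i`` (or ``j``) is
    ``None`` where the column is a gap in that sequence.  The first optimal
    alignment reported by the aligner is used, which is deterministic.
    """
    _check_sequences(seq_a, seq_b)
    aln = _make_aligner(matrix, open_gap, extend_gap).align(seq_a, seq_b)[0]
    columns: AlignmentColumns = []
    blocks_a, blocks_b = aln.aligned
    pos_a = pos_b = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        for i in range(pos_a, sa):
            columns.append((i, None))
        for j in range(pos_b, sb):
            columns.append((None, j))
        for i, j in zip(range(sa, ea), range(sb, eb)):
            columns.append((i, j))
        pos_a, pos_b = ea, eb
    for i in range(pos_a, len(seq_a)):
        columns.append((i, None))
    for j in range(pos_b, len(seq_b)):
        columns.append((None, j))
    return columns


def _consecutive_in_start(trace: CaTrace, i: int, k: int) -> bool:
    """Are original start positions i and k (k = i+? ) physically consecutive?"""
    if k != i + 1:
        return False
    ch_i, num_i, ic_i = trace.residue_ids[i]
    ch_k, num_k, ic_k = trace.residue_ids[k]
    if ch_i != ch_k:
        return False
    # Consecutive numbering, or an insertion-code step at the same number.
    return num_k == num_i + 1 or (num_k == num_i and ic_k != ic_i)


def restrict_to_aligned(trace_a: CaTrace, trace_b: CaTrace,
                        alignment: AlignmentColumns) -> AlignedPair:
    """Keep only aligned (match) columns; record start-chain discontinuities."""
    matches = [(i, j) for i, j in alignment if i is not None and j is not None]
    if len(matches) < 2:
        raise ValueError(f"only {len(matches)} aligned columns; need at least 2")
    idx_a = [i for i, _ in matches]
    idx_b = [j for _, j in matches]
    if max(idx_a) >= len(trace_a) or max(idx_b) >= len(trace_b):
        raise IndexError("alignment indices exceed trace lengths")
    n = len(matches)
    broken_edge = np.array(
        [not _consecutive_in_start(trace_a, idx_a[j], idx_a[j + 1]) for j in range(n - 1)],
        dtype=bool,
    )
    broken_angle = np.ones(n, dtype=bool)
    if n > 2:
        broken_angle[1:-1] = broken_edge[:-1] | broken_edge[1:]
    return AlignedPair(trace_a.subset(idx_a), trace_b.subset(idx_b), broken_edge, broken_angle)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain point-wise RMSD in Angstrom (no superposition performed)."""
    a = np.asarray(getattr(a, "coords", a), dtype=float)
    b = np.asarray(getattr(b, "coords", b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    SVD formulation with reflection correction; returns the optimal
    :class:`RigidTransform` and the minimized RMSD.
    """
    mobile = np.asarray(getattr(mobile, "coords", mobile), dtype=float)
    target = np.asarray(getattr(target, "coords", target), dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points for a well-defined superposition")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, ct - rot @ cm)
    return transform, rmsd(transform.apply(mobile), target)


def preprocess_pair(trace_a: CaTrace, trace_b: CaTrace, *,
                    matrix: str = "BLOSUM62", open_gap: float = -10.0,
                    extend_gap: float = -1.0) -> tuple[AlignedPair, RigidTransform, float]:
    """Full preprocessing: align sequences, restrict, superpose end onto start.

    Returns the :class:`AlignedPair` (with the end trace already moved into
    the start frame), the transform that was applied, and the superposed RMSD.
    """
    alignment = global_align(trace_a.sequence, trace_b.sequence,
                             matrix=matrix, open_gap=open_gap, extend_gap=extend_gap)
    pair = restrict_to_aligned(trace_a, trace_b, alignment)
    transform, fit_rmsd = kabsch_superpose(pair.end.coords, pair.start.coords)
    pair = AlignedPair(pair.start, pair.end.with_coords(transform.apply(pair.end.coords)),
                       pair.broken_edge, pair.broken_angle)
    return pair, transform, fit_rmsd
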