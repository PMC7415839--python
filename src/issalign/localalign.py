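"""Smith-Waterman local alignment with affine gap penalties.

The dynamic-programming fill is JIT-compiled with numba; traceback runs in
Python over the filled matrices. Tie-breaking is fully deterministic:
diagonal is preferred over up (gap in the second sequence) over left (gap in
the first), and among equal-scoring end cells the lexicographically smallest
(row, column) is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InvariantError
from .seqcore import (
    GAP,
    PairwiseAlignment,
    Region,
    ScoringScheme,
    SequenceRecord,
    empty_alignment,
)

_NEG = -(2**28)

DEFAULT_SCHEME = ScoringScheme()


def encode_sequence(residues: str) -> np.ndarray:
    """Encode residues as ``ord(letter) - ord('A')`` for matrix lookup."""
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8).astype(
        np.int64
    ) - ord("A")


@njit(cache=True)
def _sw_fill(ea, eb, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n = ea.shape[0]
    m = eb.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in b, consumes a
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in a, consumes b
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i - 1, j] - gap_open
            ee = E[i - 1, j] - gap_extend
            if ee > e:
                e = ee
            E[i, j] = e
            f = H[i, j - 1] - gap_open
            ff = F[i, j - 1] - gap_extend
            if ff > f:
                f = ff
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[ea[i - 1], eb[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, bi, bj


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a pair, with its delimiting regions.

    Regions are ``None`` when the optimal score is 0 (empty alignment).
    """

    alignment: PairwiseAlignment
    score: int
    query_region: Region | None
    subject_region: Region | None


def smith_waterman(
    a: SequenceRecord,
    b: SequenceRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> AlignmentResult:
    """Optimal local alignment of ``a`` against ``b`` under affine gaps."""
    sub = scheme.encoded()
    ea = encode_sequence(a.residues)
    eb = encode_sequence(b.residues)
    H, E, F, bi, bj = _sw_fill(
        ea, eb, sub, np.int32(scheme.gap_open), np.int32(scheme.gap_extend)
    )
    score = int(H[bi, bj])
    if score <= 0:
        return AlignmentResult(empty_alignment(a.id, b.id), 0, None, None)

    go, ge = scheme.gap_open, scheme.gap_extend
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            h = int(H[i, j])
            if h == 0:
                break
            if (
                i > 0
                and j > 0
                and h == int(H[i - 1, j - 1]) + int(sub[ea[i - 1], eb[j - 1]])
            ):
                cols_a.append(a.residues[i - 1])
                cols_b.append(b.residues[j - 1])
                i -= 1
                j -= 1
            elif h == int(E[i, j]):
                state = "E"
            elif h == int(F[i, j]):
                state = "F"
            else:  # pragma: no cover - defensive
                raise InvariantError("inconsistent traceback state")
        elif state == "E":
            cols_a.append(a.residues[i - 1])
            cols_b.append(GAP)
            # prefer closing the gap (shortest gap run) when scores tie
            if int(E[i, j]) == int(H[i - 1, j]) - go:
                state = "H"
            i -= 1
        else:  # state == "F"
            cols_a.append(GAP)
            cols_b.append(b.residues[j - 1])
            if int(F[i, j]) == int(H[i, j - 1]) - go:
                state = "H"
            j -= 1

    row_a = "".join(reversed(cols_a))
    row_b = "".join(reversed(cols_b))
    aln = PairwiseAlignment(a.id, b.id, i, j, row_a, row_b, float(score))
    return AlignmentResult(
        alignment=aln,
        score=score,
        query_region=Region(a.id, i, bi),
        subject_region=Region(b.id, j, bj),
    )


def alignment_score(aln: PairwiseAlignment, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Substitution sum minus affine gap penalties over the given columns.

    A gap run of length L costs ``gap_open + gap_extend * (L - 1)``; runs in
    different rows are charged separately even when adjacent.
    """
    total = 0
    gap_row = 0  # 0 none, 1 gap in row_a, 2 gap in row_b
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca == GAP and cb == GAP:
            raise InvariantError("gap-gap column")
        if ca == GAP:
            total -= scheme.gap_extend if gap_row == 1 else scheme.gap_open
            gap_row = 1
        elif cb == GAP:
            total -= scheme.gap_extend if gap_row == 2 else scheme.gap_open
            gap_row = 2
        else:
            total += scheme.score(ca, cb)
            gap_row = 0
    return total
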