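"""Core domain types: sequences, regions, hits, paths, alignments, residue maps.

All coordinates are 0-based, half-open. External 1-based inclusive dialects
are converted at the I/O boundary only. The gap symbol in emitted alignments
is ``-``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import (
    ConfigurationError,
    CoordinateError,
    InvariantError,
)

GAP = "-"

#: the 20 standard amino acids
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues allowed in a SequenceRecord
ALPHABET = frozenset(AA20 + "X")


def normalize_residues(raw: str) -> str:
    """Uppercase ``raw`` and map residues outside the 20-letter alphabet to X.

    Non-alphabetic characters (including gaps) are rejected.
    """
    up = raw.upper()
    out = []
    for ch in up:
        if not ch.isalpha():
            raise InvariantError(f"non-sequence character {ch!r} in residues")
        out.append(ch if ch in ALPHABET else "X")
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InvariantError("SequenceRecord id must be nonempty")
        if not self.residues:
            raise InvariantError(f"SequenceRecord {self.id!r} has no residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise InvariantError(
                f"SequenceRecord {self.id!r} contains residues outside the "
                f"20-letter alphabet plus X: {sorted(bad)}; normalize first"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def subrecord(self, start: int, end: int) -> "SequenceRecord":
        """Extract ``[start, end)`` as a record keeping the same id."""
        if not (0 <= start < end <= self.length):
            raise CoordinateError(
                f"sub-region [{start}, {end}) invalid for {self.id!r} "
                f"of length {self.length}"
            )
        return SequenceRecord(self.id, self.residues[start:end], self.description)


@dataclass(frozen=True)
class Region:
    """Half-open interval ``[start, end)`` on a named sequence."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvariantError(
                f"Region [{self.start}, {self.end}) on {self.sequence_id!r} "
                "violates 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def check_within(self, seq_length: int) -> None:
        if self.end > seq_length:
            raise CoordinateError(
                f"Region [{self.start}, {self.end}) exceeds sequence "
                f"{self.sequence_id!r} of length {seq_length}"
            )


@functools.lru_cache(maxsize=None)
def _load_matrix(name: str, path: str | None) -> substitution_matrices.Array:
    if path is not None:
        mat = substitution_matrices.read(path)
    else:
        try:
            mat = substitution_matrices.load(name)
        except FileNotFoundError as exc:
            raise ConfigurationError(f"unknown substitution matrix {name!r}") from exc
    arr = np.asarray(mat)
    if arr.shape[0] != arr.shape[1] or not np.array_equal(arr, arr.T):
        raise ConfigurationError(f"substitution matrix {name!r} is not symmetric")
    return mat


@functools.lru_cache(maxsize=None)
def _encode_matrix(name: str, path: str | None) -> np.ndarray:
    """26x26 integer score array indexed by ``ord(letter) - ord('A')``.

    Letters absent from the matrix alphabet score as X.
    """
    mat = _load_matrix(name, path)
    alphabet = mat.alphabet
    if "X" not in alphabet:
        raise ConfigurationError(
            f"matrix {name!r} has no X column; cannot score unknown residues"
        )
    enc = np.zeros((26, 26), dtype=np.int32)
    for a in range(26):
        ca = chr(ord("A") + a)
        ca = ca if ca in alphabet else "X"
        for b in range(26):
            cb = chr(ord("A") + b)
            cb = cb if cb in alphabet else "X"
            enc[a, b] = int(mat[ca, cb])
    return enc


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + gap_extend * (L - 1)``: the open
    penalty is charged on the first gapped residue, extension thereafter.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    matrix_path: str | None = None

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigurationError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise ConfigurationError("gap_extend must not exceed gap_open")
        _load_matrix(self.matrix, self.matrix_path)  # fail fast on unknown name

    def encoded(self) -> np.ndarray:
        return _encode_matrix(self.matrix, self.matrix_path)

    def score(self, a: str, b: str) -> int:
        enc = self.encoded()
        return int(enc[ord(a) - ord("A"), ord(b) - ord("A")])


@dataclass(frozen=True)
class SearchHit:
    """One local match found by a search engine, in full-sequence coordinates."""

    query_id: str
    subject_id: str
    query_region: Region
    subject_region: Region
    evalue: float
    bitscore: float
    layer: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise InvariantError("evalue must be nonnegative")
        if self.layer < 0:
            raise InvariantError("layer must be nonnegative")


@dataclass(frozen=True)
class SearchPath:
    """A chain of hits from the original query through intermediates to a
    final-database subject. Scored by the sum of member E-values; the
    smallest sum marks the best path."""

    hits: tuple[SearchHit, ...]

    def __post_init__(self) -> None:
        hits = tuple(self.hits)
        object.__setattr__(self, "hits", hits)
        if not hits:
            raise InvariantError("SearchPath must contain at least one hit")
        if hits[0].layer != 0:
            raise InvariantError("SearchPath must start at layer 0")
        seen = {hits[0].query_id}
        for k, hit in enumerate(hits):
            if hit.layer != k:
                raise InvariantError("SearchPath layers must increase by 1 from 0")
            if k > 0 and hits[k - 1].subject_id != hit.query_id:
                raise InvariantError(
                    f"hit {k} query {hit.query_id!r} does not chain from "
                    f"previous subject {hits[k - 1].subject_id!r}"
                )
            if hit.subject_id in seen:
                raise InvariantError(
                    f"sequence {hit.subject_id!r} appears twice on the path"
                )
            seen.add(hit.subject_id)

    @property
    def path_score(self) -> float:
        return float(sum(h.evalue for h in self.hits))

    @property
    def query_id(self) -> str:
        return self.hits[0].query_id

    @property
    def subject_id(self) -> str:
        return self.hits[-1].subject_id

    @property
    def sequence_ids(self) -> tuple[str, ...]:
        return (self.query_id,) + tuple(h.subject_id for h in self.hits)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Columnar gapped alignment of two sequence sub-regions.

    ``start_a`` / ``start_b`` are the coordinates (in whatever frame the
    caller works in) of the first residue of each row; ungapping a row
    yields the contiguous sub-sequence starting there.
    """

    id_a: str
    id_b: str
    start_a: int
    start_b: int
    row_a: str
    row_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise InvariantError("alignment rows differ in length")
        for k, (ca, cb) in enumerate(zip(self.row_a, self.row_b)):
            if ca == GAP and cb == GAP:
                raise InvariantError(f"gap-gap column at index {k}")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0

    def ungapped_a(self) -> str:
        return self.row_a.replace(GAP, "")

    def ungapped_b(self) -> str:
        return self.row_b.replace(GAP, "")


def empty_alignment(id_a: str, id_b: str) -> PairwiseAlignment:
    return PairwiseAlignment(id_a, id_b, 0, 0, "", "", 0.0)


def matched_pairs(aln: PairwiseAlignment) -> list[tuple[int, int]]:
    """Coordinates of residue-over-residue columns, in the alignment's frame."""
    i, j = aln.start_a, aln.start_b
    out: list[tuple[int, int]] = []
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca != GAP and cb != GAP:
            out.append((i, j))
        if ca != GAP:
            i += 1
        if cb != GAP:
            j += 1
    return out


@dataclass(frozen=True)
class ResidueMap:
    """Monotone partial residue correspondence between two sequences.

    ``pairs`` is strictly increasing in both coordinates (full-sequence,
    0-based); it may be empty.
    """

    source_id: str
    target_id: str
    pairs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            if not (i1 < i2 and j1 < j2):
                raise InvariantError(
                    f"ResidueMap {self.source_id!r}->{self.target_id!r} is not "
                    f"strictly monotone at ({i1},{j1}) -> ({i2},{j2})"
                )
        neg = [(i, j) for i, j in pairs if i < 0 or j < 0]
        if neg:
            raise InvariantError(f"negative indices in ResidueMap: {neg[:3]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def inverted(self) -> "ResidueMap":
        return ResidueMap(
            self.target_id, self.source_id, tuple((j, i) for i, j in self.pairs)
        )


def identity_map(seq_id: str, length: int, target_id: str | None = None) -> ResidueMap:
    return ResidueMap(
        seq_id, target_id or seq_id, tuple((i, i) for i in range(length))
    )


def residue_map_from_alignment(
    aln: PairwiseAlignment,
    offset_a: int = 0,
    offset_b: int = 0,
    length_a: int | None = None,
    length_b: int | None = None,
) -> ResidueMap:
    """Lift an alignment's matched columns to full-sequence coordinates.

    ``offset_a`` / ``offset_b`` are added to the alignment's own coordinate
    frame; pass the full-sequence start position of each aligned
    sub-sequence when the rows were extracted sub-regions.
    """
    pairs = tuple(
        (offset_a + i, offset_b + j) for i, j in matched_pairs(aln)
    )
    if pairs:
        max_i = pairs[-1][0]
        max_j = max(j for _, j in pairs)
        if length_a is not None and max_i >= length_a:
            raise CoordinateError(
                f"offset {offset_a} pushes index {max_i} past length {length_a}"
            )
        if length_b is not None and max_j >= length_b:
            raise CoordinateError(
                f"offset {offset_b} pushes index {max_j} past length {length_b}"
            )
    return ResidueMap(aln.id_a, aln.id_b, pairs)
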