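"""Query-template alignment generation through intermediate sequences.

Per-layer Smith-Waterman alignments are lifted to full-sequence coordinates
and composed as residue maps; the composition defines the query-template
alignment, and the stacked multi-row alignment threads every path sequence
so that each per-edge pairwise alignment's residue positions are preserved
exactly. No dynamic-programming multiple-alignment step is involved.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Mapping

from .errors import CompositionError, InputError, InvariantError
from .iss_search import IssConfig, extend_region
from .localalign import alignment_score, smith_waterman
from .seqcore import (
    GAP,
    PairwiseAlignment,
    ResidueMap,
    ScoringScheme,
    SearchPath,
    SequenceRecord,
    empty_alignment,
    matched_pairs,
    residue_map_from_alignment,
)


def compose_maps(m1: ResidueMap, m2: ResidueMap) -> ResidueMap:
    """Relational composition: ``(i, k)`` whenever ``(i, j)`` in ``m1`` and
    ``(j, k)`` in ``m2``. Monotone by monotonicity of the inputs."""
    if m1.target_id != m2.source_id:
        raise CompositionError(
            f"cannot compose {m1.source_id!r}->{m1.target_id!r} with "
            f"{m2.source_id!r}->{m2.target_id!r}"
        )
    j_to_k = dict(m2.pairs)
    pairs = tuple((i, j_to_k[j]) for i, j in m1.pairs if j in j_to_k)
    return ResidueMap(m1.source_id, m2.target_id, pairs)


def aligned_region_length(aln: PairwiseAlignment) -> int:
    """Count of residue-over-residue (matched) columns."""
    return len(matched_pairs(aln))


def alignment_from_map(
    rmap: ResidueMap,
    seq_a: SequenceRecord,
    seq_b: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> PairwiseAlignment:
    """Emit a gapped alignment whose matched columns are exactly ``rmap``.

    Unmatched residues between consecutive anchors appear as
    residue-vs-gap columns, first-sequence insertions before
    second-sequence insertions; sequence outside the outermost anchors is
    trimmed (local semantics).
    """
    if not rmap.pairs:
        return empty_alignment(rmap.source_id, rmap.target_id)
    row_a: list[str] = []
    row_b: list[str] = []
    (i0, j0) = rmap.pairs[0]
    prev_i, prev_j = i0, j0
    row_a.append(seq_a.residues[i0])
    row_b.append(seq_b.residues[j0])
    for i, j in rmap.pairs[1:]:
        for x in range(prev_i + 1, i):
            row_a.append(seq_a.residues[x])
            row_b.append(GAP)
        for y in range(prev_j + 1, j):
            row_a.append(GAP)
            row_b.append(seq_b.residues[y])
        row_a.append(seq_a.residues[i])
        row_b.append(seq_b.residues[j])
        prev_i, prev_j = i, j
    aln = PairwiseAlignment(
        rmap.source_id, rmap.target_id, i0, j0, "".join(row_a), "".join(row_b)
    )
    if scheme is not None:
        aln = PairwiseAlignment(
            aln.id_a,
            aln.id_b,
            aln.start_a,
            aln.start_b,
            aln.row_a,
            aln.row_b,
            float(alignment_score(aln, scheme)),
        )
    return aln


@dataclass(frozen=True)
class MergedAlignment:
    """Stacked gapped rows for query, each intermediate, and template."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        lengths = {len(text) for _, text in self.rows}
        if len(lengths) > 1:
            raise InvariantError("merged alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, seq_id: str) -> str:
        for rid, text in self.rows:
            if rid == seq_id:
                return text
        raise KeyError(seq_id)

    def restricted_pairs(self, id_a: str, id_b: str) -> list[tuple[int, int]]:
        """Matched full-coordinate pairs between two rows, for checking that
        per-edge alignments survived the merge unchanged."""
        ra, rb = self.row(id_a), self.row(id_b)
        # recover each row's starting coordinate from the stored offsets
        starts = dict(getattr(self, "_starts", {}))
        i, j = starts.get(id_a, 0), starts.get(id_b, 0)
        out = []
        for ca, cb in zip(ra, rb):
            if ca != GAP and cb != GAP:
                out.append((i, j))
            if ca != GAP:
                i += 1
            if cb != GAP:
                j += 1
        return out


def _empty_merged(ids: list[str]) -> MergedAlignment:
    return MergedAlignment(tuple((rid, "") for rid in ids))


def build_merged(
    ids: list[str],
    sequences: Mapping[str, SequenceRecord],
    edge_maps: list[ResidueMap],
) -> MergedAlignment:
    """Stack the chain's sequences into one alignment that preserves every
    edge map exactly.

    Positions linked (transitively) by the edge maps form chain components;
    each component becomes one column. Components are emitted in the unique
    order consistent with every row (monotone edge maps make that order
    acyclic); unmatched residues between anchors are emitted as
    single-residue columns, lower rows first. Each row is trimmed to the
    span of its anchors.
    """
    m = len(ids)
    if m != len(edge_maps) + 1:
        raise CompositionError("need exactly one edge map per adjacent pair")
    if any(len(em) == 0 for em in edge_maps):
        return _empty_merged(ids)

    nxt = [dict(em.pairs) for em in edge_maps]
    prev_img = [set(d.values()) for d in nxt]  # image in row r+1

    # components: dict row -> position, covering a contiguous row range
    comps: list[dict[int, int]] = []
    for r in range(m - 1):
        for i in sorted(nxt[r]):
            if r > 0 and i in prev_img[r - 1]:
                continue  # chain continues from an earlier row
            comp = {r: i}
            rr, pp = r, i
            while rr < m - 1 and pp in nxt[rr]:
                pp = nxt[rr][pp]
                rr += 1
                comp[rr] = pp
            comps.append(comp)

    row_comps: list[list[int]] = [[] for _ in range(m)]
    for ci, comp in enumerate(comps):
        for r in comp:
            row_comps[r].append(ci)
    for r in range(m):
        row_comps[r].sort(key=lambda ci: comps[ci][r])
        if not row_comps[r]:  # pragma: no cover - excluded by empty-map guard
            return _empty_merged(ids)

    ptr = [0] * m  # next component index per row
    pos = [comps[row_comps[r][0]][r] for r in range(m)]  # next residue per row
    done = [False] * len(comps)
    remaining = len(comps)
    columns: list[dict[int, int]] = []
    while remaining:
        candidates = [
            ci
            for ci, comp in enumerate(comps)
            if not done[ci]
            and all(row_comps[r][ptr[r]] == ci for r in comp)
        ]
        if not candidates:  # pragma: no cover - impossible for monotone chains
            raise InvariantError("inconsistent component ordering")
        ci = min(
            candidates, key=lambda c: (min(comps[c]), comps[c][min(comps[c])])
        )
        comp = comps[ci]
        for r in sorted(comp):
            while pos[r] < comp[r]:
                columns.append({r: pos[r]})
                pos[r] += 1
        columns.append(dict(comp))
        for r in comp:
            pos[r] = comp[r] + 1
            ptr[r] += 1
        done[ci] = True
        remaining -= 1

    rows = []
    starts = {}
    for r, rid in enumerate(ids):
        res = sequences[rid].residues
        rows.append(
            (rid, "".join(res[col[r]] if r in col else GAP for col in columns))
        )
        starts[rid] = comps[row_comps[r][0]][r]
    merged = MergedAlignment(tuple(rows))
    object.__setattr__(merged, "_starts", starts)
    return merged


def chain_to_alignment(
    path: SearchPath,
    sequences: Mapping[str, SequenceRecord],
    cfg: IssConfig,
) -> tuple[PairwiseAlignment, MergedAlignment]:
    """Align the query to the path's template through its intermediates.

    For each edge, Smith-Waterman is run between the stored extended
    sub-sequences (the same regions the search used), lifted to full
    coordinates, and composed left to right. Returns the split-out
    query-template alignment plus the full merged stack; both are empty
    when the composed map is empty (callers fall back to the direct
    alignment).
    """
    ids = list(path.sequence_ids)
    missing = [i for i in ids if i not in sequences]
    if missing:
        raise InputError(f"unresolvable sequence ids on path: {missing}")
    n_edges = len(path.hits)
    if len(cfg.extension_lengths) < n_edges:
        raise CompositionError(
            f"config supplies {len(cfg.extension_lengths)} extension lengths "
            f"for a path with {n_edges} edges"
        )

    edge_maps: list[ResidueMap] = []
    prev_rec = sequences[path.query_id]
    prev_off = 0
    for k, hit in enumerate(path.hits):
        subject = sequences[hit.subject_id]
        reg = extend_region(hit.subject_region, cfg.extension_lengths[k], subject.length)
        sub_rec = subject.subrecord(reg.start, reg.end)
        res = smith_waterman(prev_rec, sub_rec, cfg.scheme)
        edge_maps.append(
            residue_map_from_alignment(
                res.alignment,
                offset_a=prev_off,
                offset_b=reg.start,
                length_a=sequences[res.alignment.id_a].length,
                length_b=subject.length,
            )
        )
        prev_rec = sub_rec
        prev_off = reg.start

    composed = functools.reduce(compose_maps, edge_maps)
    query_rec = sequences[path.query_id]
    template_rec = sequences[path.subject_id]
    pairwise = alignment_from_map(composed, query_rec, template_rec, cfg.scheme)
    merged = build_merged(ids, sequences, edge_maps)
    return pairwise, merged


def select_alignment(
    via_intermediates: PairwiseAlignment, direct: PairwiseAlignment
) -> tuple[PairwiseAlignment, str]:
    """Keep whichever alignment covers the longer aligned region.

    Ties go to the intermediate-derived alignment. Returns the winner plus
    a provenance flag, ``"intermediate"`` or ``"direct"``.
    """
    if {via_intermediates.id_a, via_intermediates.id_b} != {direct.id_a, direct.id_b}:
        raise InputError("alignments concern different sequence pairs")
    if aligned_region_length(via_intermediates) >= aligned_region_length(direct):
        return via_intermediates, "intermediate"
    return direct, "direct"
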