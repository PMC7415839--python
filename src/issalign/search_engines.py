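"""Pluggable homology-search backends.

Any engine fulfilling :class:`SearchEngine` can drive the layered search: it
takes a (sub-)query with its full-sequence offset, a database, an E-value
cutoff and a hit cap, and returns hits in full-sequence coordinates sorted
by ascending E-value. Two backends ship here: a self-contained
Smith-Waterman scan and an adapter for BLAST-style tabular reports produced
by external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Protocol

from .errors import ConfigurationError, InvariantError, ParseError
from .localalign import smith_waterman
from .seqcore import Region, ScoringScheme, SearchHit, SequenceRecord

# Gumbel parameters for gapped BLOSUM62 with open 11 / extend 1.
LAMBDA = 0.267
K = 0.041


@dataclass
class SequenceDatabase:
    """A collection of sequences, optionally carrying SCOP-style sccs codes."""

    name: str
    records: dict[str, SequenceRecord] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, rec in self.records.items():
            if rid != rec.id:
                raise InvariantError(f"record keyed {rid!r} has id {rec.id!r}")
        extra = set(self.classification) - set(self.records)
        if extra:
            raise InvariantError(
                f"classification for unknown ids: {sorted(extra)[:3]}"
            )

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Iterable[SequenceRecord],
        classification: dict[str, str] | None = None,
    ) -> "SequenceDatabase":
        index: dict[str, SequenceRecord] = {}
        for rec in records:
            if rec.id in index:
                raise InvariantError(f"duplicate sequence id {rec.id!r}")
            index[rec.id] = rec
        return cls(name, index, dict(classification or {}))

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records


def evalue_from_score(score: float, m: int, n: int) -> float:
    """Karlin-Altschul style significance: ``K * m * n * exp(-lambda * S)``."""
    return K * m * n * math.exp(-LAMBDA * score)


def bitscore_from_score(score: float) -> float:
    return (LAMBDA * score - math.log(K)) / math.log(2)


class SearchEngine(Protocol):
    """Behavioral contract every search backend must satisfy."""

    def search(
        self,
        query: SequenceRecord,
        db: SequenceDatabase,
        *,
        evalue_cutoff: float,
        max_hits: int,
        layer: int = 0,
        query_offset: int = 0,
    ) -> list[SearchHit]:
        """Hits sorted by ascending evalue, all <= cutoff, count <= max_hits,
        with regions in full-sequence coordinates."""
        ...


def scan_search(
    query: SequenceRecord,
    db: SequenceDatabase,
    scheme: ScoringScheme,
    evalue_cutoff: float,
    max_hits: int,
    *,
    layer: int = 0,
    query_offset: int = 0,
) -> list[SearchHit]:
    """Exhaustive Smith-Waterman scan of ``query`` against every db record.

    ``query`` may be an extracted sub-region; ``query_offset`` lifts hit
    query-regions back to full-sequence coordinates. Self-hits (same id)
    are excluded.
    """
    if evalue_cutoff <= 0:
        raise ConfigurationError("evalue cutoff must be positive")
    if max_hits <= 0:
        raise ConfigurationError("max_hits must be positive")
    hits: list[SearchHit] = []
    for sid in sorted(db.records):
        if sid == query.id:
            continue
        subject = db.records[sid]
        res = smith_waterman(query, subject, scheme)
        if res.score <= 0:
            continue
        ev = evalue_from_score(res.score, query.length, subject.length)
        if ev > evalue_cutoff:
            continue
        assert res.query_region is not None and res.subject_region is not None
        hits.append(
            SearchHit(
                query_id=query.id,
                subject_id=sid,
                query_region=Region(
                    query.id,
                    query_offset + res.query_region.start,
                    query_offset + res.query_region.end,
                ),
                subject_region=res.subject_region,
                evalue=ev,
                bitscore=bitscore_from_score(res.score),
                layer=layer,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits[:max_hits]


@dataclass(frozen=True)
class ScanEngine:
    """Built-in backend: Smith-Waterman scan with Karlin-Altschul E-values."""

    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def search(
        self,
        query: SequenceRecord,
        db: SequenceDatabase,
        *,
        evalue_cutoff: float,
        max_hits: int,
        layer: int = 0,
        query_offset: int = 0,
    ) -> list[SearchHit]:
        return scan_search(
            query,
            db,
            self.scheme,
            evalue_cutoff,
            max_hits,
            layer=layer,
            query_offset=query_offset,
        )


_N_COLUMNS = 8


def parse_tabular_hits(text: str, layer: int = 0) -> list[SearchHit]:
    """Parse 8-column tabular search output into hits.

    Expected columns: qseqid sseqid evalue bitscore qstart qend sstart send,
    with 1-based inclusive coordinates. Multiple rows for one
    (query, subject) pair collapse to the row with the smallest evalue;
    output preserves first-appearance order.
    """
    best: dict[tuple[str, str], SearchHit] = {}
    order: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != _N_COLUMNS:
            raise ParseError(
                f"line {lineno}: expected {_N_COLUMNS} columns, got {len(fields)}"
            )
        qid, sid = fields[0], fields[1]
        try:
            evalue = float(fields[2])
            bitscore = float(fields[3])
            qstart, qend, sstart, send = (int(x) for x in fields[4:8])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
        if qstart < 1 or sstart < 1 or qstart > qend or sstart > send:
            raise ParseError(
                f"line {lineno}: invalid 1-based inclusive coordinates "
                f"{qstart}-{qend} / {sstart}-{send}"
            )
        if evalue < 0:
            raise ParseError(f"line {lineno}: negative evalue")
        hit = SearchHit(
            query_id=qid,
            subject_id=sid,
            query_region=Region(qid, qstart - 1, qend),
            subject_region=Region(sid, sstart - 1, send),
            evalue=evalue,
            bitscore=bitscore,
            layer=layer,
        )
        key = (qid, sid)
        if key not in best:
            best[key] = hit
            order.append(key)
        elif hit.evalue < best[key].evalue:
            best[key] = hit
    return [best[k] for k in order]


@dataclass
class TabularEngine:
    """Adapter serving pre-parsed external-tool hits through the contract.

    Coordinates in the parsed file are already full-sequence, so the
    ``query_offset`` argument is ignored.
    """

    hits: list[SearchHit]

    @classmethod
    def from_text(cls, text: str) -> "TabularEngine":
        return cls(parse_tabular_hits(text))

    def search(
        self,
        query: SequenceRecord,
        db: SequenceDatabase,
        *,
        evalue_cutoff: float,
        max_hits: int,
        layer: int = 0,
        query_offset: int = 0,
    ) -> list[SearchHit]:
        if evalue_cutoff <= 0:
            raise ConfigurationError("evalue cutoff must be positive")
        if max_hits <= 0:
            raise ConfigurationError("max_hits must be positive")
        found = [
            SearchHit(
                query_id=h.query_id,
                subject_id=h.subject_id,
                query_region=h.query_region,
                subject_region=h.subject_region,
                evalue=h.evalue,
                bitscore=h.bitscore,
                layer=layer,
            )
            for h in self.hits
            if h.query_id == query.id
            and h.subject_id != query.id
            and h.subject_id in db
            and h.evalue <= evalue_cutoff
        ]
        found.sort(key=lambda h: (h.evalue, h.subject_id))
        return found[:max_hits]
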