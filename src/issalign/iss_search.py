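"""Layered intermediate sequence search.

Hits from one round become (extended sub-region) queries for the next; the
last round always targets the final database. Complete chains are ranked by
the sum of E-values along the path, smallest first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError, InputError, InvariantError
from .search_engines import SearchEngine, SequenceDatabase
from .seqcore import Region, ScoringScheme, SearchHit, SearchPath, SequenceRecord


def extend_region(r: Region, ext: int, seq_length: int) -> Region:
    """Widen ``r`` by ``ext`` on both sides, clamped to ``[0, seq_length)``."""
    if ext < 0:
        raise ConfigurationError("extension length must be nonnegative")
    return Region(r.sequence_id, max(0, r.start - ext), min(seq_length, r.end + ext))


@dataclass(frozen=True)
class IssConfig:
    """Search hyperparameters, one entry per search layer.

    Arrays have ``n_intermediate_layers + 1`` entries; the last entry
    belongs to the final-database search. Defaults: extension length 5 per
    intermediate layer and 20 for the final layer; E-value cutoff 1e-3 for
    intermediate layers and 10 for the final.
    """

    n_intermediate_layers: int = 2
    extension_lengths: tuple[int, ...] | None = None
    evalue_cutoffs: tuple[float, ...] | None = None
    max_hits_per_layer: tuple[int, ...] | None = None
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    #: when False, whole intermediate sequences are re-queried instead of
    #: extended hit sub-regions (for ablation only; True is the method).
    use_subregions: bool = True

    def __post_init__(self) -> None:
        n = self.n_intermediate_layers
        if n < 0:
            raise ConfigurationError("n_intermediate_layers must be >= 0")
        ext = self.extension_lengths
        if ext is None:
            ext = (5,) * n + (20,)
        ext = tuple(int(x) for x in ext)
        cut = self.evalue_cutoffs
        if cut is None:
            cut = (1e-3,) * n + (10.0,)
        cut = tuple(float(x) for x in cut)
        cap = self.max_hits_per_layer
        if cap is None:
            cap = (100,) * (n + 1)
        cap = tuple(int(x) for x in cap)
        for name, arr in (
            ("extension_lengths", ext),
            ("evalue_cutoffs", cut),
            ("max_hits_per_layer", cap),
        ):
            if len(arr) != n + 1:
                raise ConfigurationError(
                    f"{name} must have {n + 1} entries (one per search layer), "
                    f"got {len(arr)}"
                )
        if any(c <= 0 for c in cut):
            raise ConfigurationError("evalue cutoffs must be positive")
        if any(e < 0 for e in ext):
            raise ConfigurationError("extension lengths must be nonnegative")
        if any(m <= 0 for m in cap):
            raise ConfigurationError("max hits must be positive")
        object.__setattr__(self, "extension_lengths", ext)
        object.__setattr__(self, "evalue_cutoffs", cut)
        object.__setattr__(self, "max_hits_per_layer", cap)


def _next_query(
    hit: SearchHit, subject: SequenceRecord, ext: int, use_subregions: bool
) -> tuple[SequenceRecord, int]:
    """The record (and its full-sequence offset) used to query the next layer."""
    if not use_subregions:
        return subject, 0
    reg = extend_region(hit.subject_region, ext, subject.length)
    return subject.subrecord(reg.start, reg.end), reg.start


def iss_search(
    query: SequenceRecord,
    intermediate_dbs: list[SequenceDatabase],
    final_db: SequenceDatabase,
    engine: SearchEngine,
    cfg: IssConfig,
) -> list[SearchPath]:
    """Run the layered search and return every cycle-free complete path.

    Direct (0-intermediate) hits against the final database are always
    merged into the result, so the layered search never loses what a plain
    search finds.
    """
    if not query.residues:
        raise InputError("empty query")
    n = cfg.n_intermediate_layers
    if len(intermediate_dbs) != n:
        raise ConfigurationError(
            f"expected {n} intermediate databases, got {len(intermediate_dbs)}"
        )

    # frontier items: (hits so far, query record for next search, offset)
    frontier: list[tuple[tuple[SearchHit, ...], SequenceRecord, int]] = [
        ((), query, 0)
    ]
    for layer in range(n):
        nxt: list[tuple[tuple[SearchHit, ...], SequenceRecord, int]] = []
        for hits_so_far, rec, off in frontier:
            used = {query.id} | {h.subject_id for h in hits_so_far}
            try:
                found = engine.search(
                    rec,
                    intermediate_dbs[layer],
                    evalue_cutoff=cfg.evalue_cutoffs[layer],
                    max_hits=cfg.max_hits_per_layer[layer],
                    layer=layer,
                    query_offset=off,
                )
            except Exception as exc:
                raise InputError(f"search failed at layer {layer}: {exc}") from exc
            for hit in found:
                if hit.subject_id in used:
                    continue
                subject = intermediate_dbs[layer].records[hit.subject_id]
                sub, sub_off = _next_query(
                    hit, subject, cfg.extension_lengths[layer], cfg.use_subregions
                )
                nxt.append((hits_so_far + (hit,), sub, sub_off))
        frontier = nxt

    paths: list[SearchPath] = []
    for hits_so_far, rec, off in frontier:
        used = {query.id} | {h.subject_id for h in hits_so_far}
        try:
            found = engine.search(
                rec,
                final_db,
                evalue_cutoff=cfg.evalue_cutoffs[n],
                max_hits=cfg.max_hits_per_layer[n],
                layer=n,
                query_offset=off,
            )
        except Exception as exc:
            raise InputError(f"search failed at final layer {n}: {exc}") from exc
        for hit in found:
            if hit.subject_id in used:
                continue
            paths.append(SearchPath(hits_so_far + (hit,)))

    if n > 0:
        direct = engine.search(
            query,
            final_db,
            evalue_cutoff=cfg.evalue_cutoffs[n],
            max_hits=cfg.max_hits_per_layer[n],
            layer=0,
            query_offset=0,
        )
        for hit in direct:
            paths.append(SearchPath((replace(hit, layer=0),)))
    return paths


@dataclass(frozen=True)
class RankedHit:
    """One final subject with its best (smallest E-value sum) path."""

    subject_id: str
    best_path: SearchPath
    score: float
    rank: int


def rank_hits(paths: list[SearchPath]) -> list[RankedHit]:
    """Group paths by final subject, keep the minimum-score path per subject,
    and rank subjects by ascending score.

    Ties break on shorter path first, then lexicographic subject id.
    """
    best: dict[str, SearchPath] = {}
    for path in paths:
        sid = path.subject_id
        cur = best.get(sid)
        if cur is None or (path.path_score, len(path.hits)) < (
            cur.path_score,
            len(cur.hits),
        ):
            best[sid] = path
    ordered = sorted(
        best.items(), key=lambda kv: (kv[1].path_score, len(kv[1].hits), kv[0])
    )
    return [
        RankedHit(subject_id=sid, best_path=path, score=path.path_score, rank=k)
        for k, (sid, path) in enumerate(ordered, start=1)
    ]
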