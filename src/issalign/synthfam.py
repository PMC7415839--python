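"""Synthetic remote-homolog families with exact ground-truth correspondences.

Chains Q -> I1 -> ... -> Ik -> T are generated by repeated substitution and
indel rounds; every edit is tracked, so the true residue map of any ordered
pair along the chain is known exactly and composes consistently. These
families stand in for large intermediate/structural databases in tests and
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, MetricError
from .search_engines import SequenceDatabase
from .seqcore import AA20, ResidueMap, ScoringScheme, SequenceRecord

#: indels keep this many residues clear of each end
_EDGE_MARGIN = 3
#: geometric indel-length parameter (mean length 2)
_INDEL_P = 0.5


def _mutation_table(scheme: ScoringScheme) -> np.ndarray:
    """Row-stochastic 20x20 replacement probabilities, P(b|a) for b != a,
    proportional to exp(score(a,b) / 2). Keeps mutated sequences detectable
    by score-based search at realistic identities."""
    n = len(AA20)
    tab = np.zeros((n, n))
    for ai, a in enumerate(AA20):
        for bi, b in enumerate(AA20):
            if ai == bi:
                continue
            tab[ai, bi] = np.exp(scheme.score(a, b) / 2.0)
        tab[ai] /= tab[ai].sum()
    return tab


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))


def _evolve_step(
    residues: str,
    branch_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
    mut_table: np.ndarray,
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """One parent -> child round; returns the child and its true map
    (parent index, child index) pairs."""
    aa_index = {a: i for i, a in enumerate(AA20)}
    L = len(residues)
    n_sub = int(round((1.0 - branch_identity) * L))
    if n_sub > L:
        raise GenerationError("identity target unreachable")
    sub_pos = set(rng.choice(L, size=n_sub, replace=False).tolist())
    child = list(residues)
    for p in sub_pos:
        ai = aa_index.get(child[p], rng.integers(0, len(AA20)))
        child[p] = AA20[rng.choice(len(AA20), p=mut_table[ai])]

    parent_of = list(range(L))  # child position -> parent position, -1 inserted
    n_indels = int(rng.poisson(indel_rate * L))
    for _ in range(n_indels):
        cur = len(child)
        if cur <= 2 * _EDGE_MARGIN + 4:
            break
        length = int(rng.geometric(_INDEL_P))
        pos = int(rng.integers(_EDGE_MARGIN, cur - _EDGE_MARGIN))
        if rng.random() < 0.5:  # deletion
            length = min(length, cur - _EDGE_MARGIN - pos)
            if length <= 0:
                continue
            del child[pos : pos + length]
            del parent_of[pos : pos + length]
        else:  # insertion
            ins = [AA20[i] for i in rng.integers(0, len(AA20), size=length)]
            child[pos:pos] = ins
            parent_of[pos:pos] = [-1] * length
    pairs = tuple((p, c) for c, p in enumerate(parent_of) if p >= 0)
    return "".join(child), pairs


@dataclass(frozen=True)
class SyntheticFamily:
    """A generated chain with exact truth maps for every ordered pair."""

    chain: tuple[SequenceRecord, ...]
    true_maps: dict[tuple[str, str], ResidueMap]
    branch_identity: float
    indel_rate: float
    seed: int
    decoys: tuple[SequenceRecord, ...] = field(default_factory=tuple)

    @property
    def query(self) -> SequenceRecord:
        return self.chain[0]

    @property
    def template(self) -> SequenceRecord:
        return self.chain[-1]

    @property
    def intermediates(self) -> tuple[SequenceRecord, ...]:
        return self.chain[1:-1]

    def true_map(self, source_id: str, target_id: str) -> ResidueMap:
        key = (source_id, target_id)
        if key in self.true_maps:
            return self.true_maps[key]
        rev = (target_id, source_id)
        if rev in self.true_maps:
            return self.true_maps[rev].inverted()
        raise KeyError(key)

    def sequences(self) -> dict[str, SequenceRecord]:
        out = {rec.id: rec for rec in self.chain}
        out.update({rec.id: rec for rec in self.decoys})
        return out


def pair_identity(rmap: ResidueMap, seq_a: SequenceRecord, seq_b: SequenceRecord) -> float:
    """Fraction of mapped pairs with identical residues; 0 for empty maps."""
    if not rmap.pairs:
        return 0.0
    same = sum(1 for i, j in rmap.pairs if seq_a.residues[i] == seq_b.residues[j])
    return same / len(rmap.pairs)


def generate_family(
    seed: int,
    ancestor_length: int = 150,
    n_intermediates: int = 2,
    branch_identity: float = 0.55,
    indel_rate: float = 0.02,
    n_decoys: int = 0,
    decoy_length: int | None = None,
    scheme: ScoringScheme | None = None,
    name_prefix: str = "",
) -> SyntheticFamily:
    """Generate a chain Q, I1..Ik, T plus optional unrelated decoys.

    Identical seeds give byte-identical families. With ``indel_rate=0``
    every true map is a full identity map on indices.
    """
    if ancestor_length < 30:
        raise GenerationError("ancestor_length must be >= 30")
    if not (0.0 < branch_identity < 1.0):
        raise GenerationError("branch_identity must lie strictly in (0, 1)")
    if indel_rate < 0:
        raise GenerationError("indel_rate must be nonnegative")
    if n_intermediates < 0:
        raise GenerationError("n_intermediates must be nonnegative")
    scheme = scheme or ScoringScheme()
    mut_table = _mutation_table(scheme)
    rng = np.random.default_rng(seed)

    names = (
        [f"{name_prefix}Q"]
        + [f"{name_prefix}I{k}" for k in range(1, n_intermediates + 1)]
        + [f"{name_prefix}T"]
    )
    residues = random_sequence(rng, ancestor_length)
    chain = [SequenceRecord(names[0], residues, "synthetic ancestor")]
    step_maps: list[ResidueMap] = []
    for k in range(1, len(names)):
        residues, pairs = _evolve_step(
            residues, branch_identity, indel_rate, rng, mut_table
        )
        chain.append(SequenceRecord(names[k], residues, "synthetic homolog"))
        step_maps.append(ResidueMap(names[k - 1], names[k], pairs))

    # truth for every ordered (earlier, later) pair, by composition
    from .align_merge import compose_maps  # local import avoids a cycle

    true_maps: dict[tuple[str, str], ResidueMap] = {}
    for a in range(len(names)):
        acc: ResidueMap | None = None
        for b in range(a + 1, len(names)):
            acc = step_maps[b - 1] if acc is None else compose_maps(acc, step_maps[b - 1])
            true_maps[(names[a], names[b])] = acc

    decoys = tuple(
        SequenceRecord(
            f"{name_prefix}D{d}",
            random_sequence(rng, decoy_length or ancestor_length),
            "unrelated decoy",
        )
        for d in range(1, n_decoys + 1)
    )
    return SyntheticFamily(
        chain=tuple(chain),
        true_maps=true_maps,
        branch_identity=branch_identity,
        indel_rate=indel_rate,
        seed=seed,
        decoys=decoys,
    )


@dataclass(frozen=True)
class MultiDomainDecoy:
    """A homologous domain fused to an unrelated one, boundary recorded."""

    record: SequenceRecord
    boundary: int
    homolog_source_id: str
    true_map: ResidueMap  # homolog source -> decoy positions


def make_multidomain_decoy(
    family: SyntheticFamily,
    unrelated_length: int,
    seed: int,
    decoy_id: str | None = None,
) -> MultiDomainDecoy:
    """Concatenate a copy of the family's first intermediate (the template
    when the chain has none) with an unrelated random domain."""
    rng = np.random.default_rng(seed)
    source = family.intermediates[0] if family.intermediates else family.template
    homolog = source.residues
    unrelated = random_sequence(rng, unrelated_length)
    rec = SequenceRecord(
        decoy_id or f"{source.id}_decoy{seed}",
        homolog + unrelated,
        "multi-domain decoy",
    )
    tmap = ResidueMap(
        source.id, rec.id, tuple((i, i) for i in range(len(homolog)))
    )
    return MultiDomainDecoy(
        record=rec, boundary=len(homolog), homolog_source_id=source.id, true_map=tmap
    )


def true_pair_accuracy(
    predicted: ResidueMap, truth: ResidueMap
) -> tuple[float, float]:
    """Precision and recall of predicted residue pairs against the truth."""
    if not truth.pairs:
        raise MetricError("recall undefined: truth map is empty")
    pred = set(predicted.pairs)
    true = set(truth.pairs)
    inter = len(pred & true)
    precision = inter / len(pred) if pred else 0.0
    recall = inter / len(true)
    return precision, recall


@dataclass(frozen=True)
class Benchmark:
    """A desk-scale detection benchmark with superfamily truth labels."""

    queries: tuple[SequenceRecord, ...]
    query_classification: dict[str, str]
    intermediate_dbs: tuple[SequenceDatabase, ...]
    final_db: SequenceDatabase


def generate_benchmark(
    seed: int,
    n_queries: int = 20,
    ancestor_length: int = 120,
    branch_identity: float = 0.55,
    indel_rate: float = 0.02,
    n_random_decoys: int = 30,
    scheme: ScoringScheme | None = None,
) -> Benchmark:
    """Build a 2-intermediate-layer benchmark: one superfamily per query.

    Layer databases hold the first and second intermediates of every
    family; the final database holds each family's template plus a sibling
    leaf (same superfamily) and unrelated random decoys (each its own
    superfamily).
    """
    scheme = scheme or ScoringScheme()
    mut_table = _mutation_table(scheme)
    queries: list[SequenceRecord] = []
    qcls: dict[str, str] = {}
    db1: list[SequenceRecord] = []
    db2: list[SequenceRecord] = []
    final: list[SequenceRecord] = []
    final_cls: dict[str, str] = {}
    for f in range(n_queries):
        fam = generate_family(
            seed=int(np.random.default_rng([seed, f]).integers(0, 2**31)),
            ancestor_length=ancestor_length,
            n_intermediates=2,
            branch_identity=branch_identity,
            indel_rate=indel_rate,
            scheme=scheme,
            name_prefix=f"f{f}_",
        )
        sccs = f"s.{f + 1}.1.1"
        queries.append(fam.query)
        qcls[fam.query.id] = sccs
        db1.append(fam.intermediates[0])
        db2.append(fam.intermediates[1])
        final.append(fam.template)
        final_cls[fam.template.id] = sccs
        # a sibling leaf: one more evolution round off the second intermediate
        rng = np.random.default_rng([seed, f, 17])
        sib_res, _ = _evolve_step(
            fam.intermediates[1].residues, branch_identity, indel_rate, rng, mut_table
        )
        sib = SequenceRecord(f"f{f}_T2", sib_res, "sibling leaf")
        final.append(sib)
        final_cls[sib.id] = sccs
    rng = np.random.default_rng([seed, 999])
    for d in range(n_random_decoys):
        rec = SequenceRecord(
            f"decoy{d}", random_sequence(rng, ancestor_length), "random decoy"
        )
        final.append(rec)
        final_cls[rec.id] = f"d.{900 + d}.1.1"
    return Benchmark(
        queries=tuple(queries),
        query_classification=qcls,
        intermediate_dbs=(
            SequenceDatabase.from_records("layer1", db1),
            SequenceDatabase.from_records("layer2", db2),
        ),
        final_db=SequenceDatabase.from_records("final", final, final_cls),
    )
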