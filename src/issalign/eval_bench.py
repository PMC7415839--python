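"""Homology-detection evaluation: superfamily truth labels and AUC_n.

A detection counts as a true positive when the subject shares the query's
SCOP superfamily (the first three dot-fields of the sccs code). AUC_n
considers the ranking only up to the n-th false positive and is normalized
by n and by the number of true homologs in the database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ClassificationError, MetricError
from .search_engines import SequenceDatabase
from .seqcore import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_N_VALUES = (10, 50, 100, 250, 500)


def superfamily_label(query_sccs: str, subject_sccs: str) -> bool:
    """True iff the two sccs codes agree on class.fold.superfamily."""
    qf = query_sccs.split(".")
    sf = subject_sccs.split(".")
    if len(qf) < 3 or len(sf) < 3:
        raise ClassificationError(
            f"sccs codes need >= 3 dot-fields: {query_sccs!r} vs {subject_sccs!r}"
        )
    return qf[:3] == sf[:3]


@dataclass(frozen=True)
class LabeledRanking:
    """A confidence-ordered hit list with truth flags.

    ``n_true_total`` counts every homolog of the query in the searched
    database, retrieved or not.
    """

    entries: tuple[tuple[str, bool], ...]
    n_true_total: int

    def __post_init__(self) -> None:
        flagged = sum(1 for _, flag in self.entries if flag)
        if self.n_true_total < flagged:
            raise MetricError(
                f"n_true_total={self.n_true_total} below flagged count {flagged}"
            )


def auc_n(ranking: LabeledRanking, n: int) -> float:
    """Truncated ROC area: ``sum(t_i for i in 1..n) / (n * T)`` where ``t_i``
    is the number of true positives ranked above the i-th false positive.

    When the list contains fewer than n false positives, the missing ones
    count as ranked after everything retrieved.
    """
    if n < 1:
        raise MetricError("n must be >= 1")
    T = ranking.n_true_total
    if T < 1:
        raise MetricError("AUC_n undefined: query has no true homolog")
    tp = 0
    t_sum = 0
    n_fp = 0
    for _, flag in ranking.entries:
        if flag:
            tp += 1
        else:
            n_fp += 1
            t_sum += tp
            if n_fp == n:
                break
    if n_fp < n:
        total_tp = sum(1 for _, flag in ranking.entries if flag)
        t_sum += (n - n_fp) * total_tp
    return t_sum / (n * T)


def label_ranking(
    query_id: str,
    query_sccs: str,
    ranked_ids: Sequence[str],
    db: SequenceDatabase,
) -> LabeledRanking:
    """Flag a ranked id list against superfamily truth; self-hits dropped."""
    entries = []
    for sid in ranked_ids:
        if sid == query_id:
            continue
        entries.append((sid, superfamily_label(query_sccs, db.classification[sid])))
    n_true = sum(
        1
        for sid, sccs in db.classification.items()
        if sid != query_id and superfamily_label(query_sccs, sccs)
    )
    return LabeledRanking(tuple(entries), n_true)


def evaluate_queries(
    queries: Iterable[SequenceRecord],
    db: SequenceDatabase,
    search_fn: Callable[[SequenceRecord], Sequence[str]],
    n_values: Sequence[int] = DEFAULT_N_VALUES,
    query_classification: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One AUC_n per (query, n) as a tidy table.

    ``search_fn`` maps a query record to its ranked subject ids (best
    first). Query sccs codes come from ``query_classification`` when given,
    else from the database's classification. Queries without any
    same-superfamily database entry are skipped with a warning.
    """
    qcls = query_classification if query_classification is not None else db.classification
    rows = []
    for query in queries:
        if query.id not in qcls:
            raise ClassificationError(f"no sccs code for query {query.id!r}")
        ranking = label_ranking(query.id, qcls[query.id], search_fn(query), db)
        if ranking.n_true_total == 0:
            logger.warning(
                "query %s has no same-superfamily entry in %s; skipped",
                query.id,
                db.name,
            )
            continue
        for n in n_values:
            rows.append(
                {
                    "query_id": query.id,
                    "n": int(n),
                    "auc_n": auc_n(ranking, int(n)),
                    "n_true": ranking.n_true_total,
                }
            )
    return pd.DataFrame(rows, columns=["query_id", "n", "auc_n", "n_true"])


def summarize_auc(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and median AUC_n across queries, per n."""
    if table.empty:
        return pd.DataFrame(columns=["n", "mean_auc", "median_auc", "n_queries"])
    out = (
        table.groupby("n")["auc_n"]
        .agg(mean_auc="mean", median_auc="median", n_queries="count")
        .reset_index()
    )
    return out
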