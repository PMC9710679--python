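"""Collocation detection and synteny-weighted cluster scoring.

This is the core of the method. Each scaffold's subjects (genes with hits,
sorted by position) are swept left to right; a group extends while the
intergenic distance to the next subject — ``max(0, next.start - prev.end)``,
clamped at zero for overlapping genes — stays within the gap threshold
(default 20 kbp). A finalized group is emitted as a cluster only if it
satisfies the user thresholds: minimum distinct queries hit (``unique``),
minimum total hits (``min_hits``), and, if given, all required query ids.

Each cluster receives a similarity score

    S = h + i * s

where ``h`` is the number of distinct query sequences with hits in the
cluster, ``s`` is the number of contiguous subject-gene pairs with conserved
synteny (pairs whose best-hit queries are adjacent in the query order), and
``i`` weights synteny (default 0.5). Clusters are ranked by descending S,
breaking ties by descending h then ascending uid.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Mapping, Sequence

from .datamodel import (
    Cluster,
    DetectParams,
    Query,
    Scaffold,
    ScoreBreakdown,
    Session,
    SessionValidationError,
    Subject,
    DEFAULT_SYNTENY_WEIGHT,
)

logger = logging.getLogger("clusterseek")


def intergenic_distance(prev: Subject, nxt: Subject) -> int:
    """End-to-start distance between consecutive genes, clamped at 0."""
    return max(0, nxt.start - prev.end)


def _passes_thresholds(group: Sequence[Subject], params: DetectParams) -> bool:
    query_ids = {h.query_id for s in group for h in s.hits}
    if len(query_ids) < params.unique:
        return False
    total_hits = sum(len(s.hits) for s in group)
    if total_hits < params.min_hits:
        return False
    return params.require <= query_ids


def score_cluster(
    subjects: Sequence[Subject],
    query_index: Mapping[str, int],
    weight_i: float = DEFAULT_SYNTENY_WEIGHT,
) -> ScoreBreakdown:
    """Score a cluster with S = h + i*s.

    ``h`` counts distinct queries with >= 1 hit over all cluster subjects.
    Each subject is labelled with the query index of its single best hit
    (highest bitscore; ties broken by lowest e-value, then lowest query
    index); ``s`` counts adjacent subject pairs, in genomic order, whose
    labels differ by exactly 1 (direction-agnostic).
    """
    query_ids = {h.query_id for s in subjects for h in s.hits}
    h = len(query_ids)
    labels = [query_index.get(s.best_hit(query_index).query_id, -1) for s in subjects]
    s = sum(1 for a, b in zip(labels, labels[1:]) if abs(a - b) == 1)
    return ScoreBreakdown(h=h, s=s, i=weight_i)


def detect_clusters(
    scaffold: Scaffold,
    params: DetectParams,
    queries: Sequence[Query],
    *,
    weight_i: float = DEFAULT_SYNTENY_WEIGHT,
) -> list[Cluster]:
    """Sweep one scaffold and emit scored clusters sorted by start.

    The scaffold's subjects must already be sorted by (start, end, id); an
    unsorted scaffold is an internal-invariant error, never silently
    re-sorted.
    """
    keys = [(s.start, s.end, s.id) for s in scaffold.subjects]
    if any(a >= b for a, b in zip(keys, keys[1:])):
        raise SessionValidationError(
            f"scaffold {scaffold.accession}: subjects not sorted; refusing to detect")
    query_index = {q.id: q.index for q in queries}
    clusters: list[Cluster] = []
    group: list[Subject] = []

    def _finalize() -> None:
        if group and _passes_thresholds(group, params):
            clusters.append(Cluster(
                scaffold_accession=scaffold.accession,
                subject_ids=[s.id for s in group],
                start=min(s.start for s in group),
                end=max(s.end for s in group),
                score=score_cluster(group, query_index, weight_i),
            ))

    for subject in scaffold.subjects:
        if not group or intergenic_distance(group[-1], subject) <= params.gap:
            group.append(subject)
        else:
            _finalize()
            group = [subject]
    _finalize()
    clusters.sort(key=lambda c: c.start)
    return clusters


def detect_all(
    session: Session,
    params: DetectParams | None = None,
    *,
    weight_i: float = DEFAULT_SYNTENY_WEIGHT,
) -> list[Cluster]:
    """Detect clusters on every scaffold of a session (uids unassigned)."""
    params = params or session.detect
    clusters: list[Cluster] = []
    for _, scaffold in session.iter_scaffolds():
        clusters.extend(detect_clusters(scaffold, params, session.queries,
                                        weight_i=weight_i))
    return clusters


def assign_ids_and_rank(session: Session) -> Session:
    """Assign sequential uids and store clusters in deterministic order.

    Uids start at 1 and follow (organism name, strain, scaffold accession,
    cluster start) order — the order summaries group by. Rank order (used by
    score-sorted output) is descending S, ties by descending h, then
    ascending uid; see :func:`ranked_clusters`.
    """
    org_of = {sc.accession: (org.name, org.strain)
              for org, sc in session.iter_scaffolds()}
    session.clusters.sort(key=lambda c: (*org_of.get(c.scaffold_accession, ("", "")),
                                         c.scaffold_accession, c.start, c.end))
    for uid, cluster in enumerate(session.clusters, start=1):
        cluster.uid = uid
    return session


def ranked_clusters(session: Session) -> list[Cluster]:
    """Clusters in rank order: most similar (highest S) first."""
    return sorted(session.clusters, key=lambda c: (-c.score.S, -c.score.h, c.uid))


def redetect(
    session: Session,
    params: DetectParams | None = None,
    *,
    weight_i: float = DEFAULT_SYNTENY_WEIGHT,
) -> Session:
    """Re-run detection on a (loaded) session, replacing stored clusters.

    Uids are reassigned from 1; uids from a previous detection are not
    preserved.
    """
    if params is not None:
        session.detect = params
    session.clusters = detect_all(session, session.detect, weight_i=weight_i)
    return assign_ids_and_rank(session)
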