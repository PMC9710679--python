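"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from clusterseek.datamodel import (
    Cluster,
    DetectParams,
    FilterParams,
    Hit,
    Organism,
    Query,
    Scaffold,
    ScoreBreakdown,
    Session,
    Subject,
)
from clusterseek.fixtures import example_spec, generate_genomes, generate_hit_table


# ---------------------------------------------------------------------------
# Small constructors
# ---------------------------------------------------------------------------

def make_hit(query_id: str, subject_id: str, *, identity=75.0, coverage=90.0,
             evalue=1e-30, bitscore=200.0) -> Hit:
    return Hit(query_id, subject_id, identity, coverage, evalue, bitscore)


def make_subject(sid: str, start: int, end: int, query_ids, **hit_kwargs) -> Subject:
    """Subject hit by the given queries; first query id is the best hit."""
    hits = []
    for k, qid in enumerate(query_ids):
        hits.append(make_hit(qid, sid, bitscore=300.0 - 10 * k, **hit_kwargs))
    return Subject(sid, start, end, "+", hits)


def make_queries(n: int) -> list[Query]:
    return [Query(id=f"q{i}", index=i, length=150) for i in range(n)]


def random_scaffold(rng: np.random.Generator, n_queries: int = 5,
                    max_subjects: int = 15) -> Scaffold:
    """Random scaffold with strictly sorted subjects and random hit patterns."""
    n = int(rng.integers(1, max_subjects + 1))
    starts = np.sort(rng.choice(np.arange(0, 200_000, 10), size=n, replace=False))
    subjects = []
    for k, start in enumerate(starts):
        length = int(rng.integers(200, 3000))
        hit_queries = rng.choice(n_queries, size=int(rng.integers(1, 4)), replace=False)
        hits = [Hit(f"q{int(q)}", f"s{k}", float(rng.uniform(30, 100)),
                    float(rng.uniform(50, 100)), float(10.0 ** -rng.uniform(5, 50)),
                    float(rng.uniform(50, 500))) for q in hit_queries]
        subjects.append(Subject(f"s{k}", int(start), int(start) + length, "+", hits))
    scaffold = Scaffold("RAND001", subjects)
    scaffold.sort_subjects()
    return scaffold


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_maximal_runs(subjects, gap: int):
    """Brute-force maximal runs under the gap predicate.

    Independent formulation: mark every adjacent pair as linked iff the
    clamped end-to-start distance is within the gap, then read off maximal
    linked stretches by scanning the boolean vector.
    """
    if not subjects:
        return []
    linked = [max(0, b.start - a.end) <= gap for a, b in zip(subjects, subjects[1:])]
    runs, current = [], [0]
    for idx, is_linked in enumerate(linked):
        if is_linked:
            current.append(idx + 1)
        else:
            runs.append(current)
            current = [idx + 1]
    runs.append(current)
    return [[subjects[i] for i in run] for run in runs]


def oracle_detect(subjects, params: DetectParams):
    """Reference cluster detection: maximal runs filtered by thresholds."""
    emitted = []
    for run in oracle_maximal_runs(subjects, params.gap):
        queries_hit = set()
        total = 0
        for subject in run:
            for hit in subject.hits:
                queries_hit.add(hit.query_id)
                total += 1
        if (len(queries_hit) >= params.unique and total >= params.min_hits
                and set(params.require) <= queries_hit):
            emitted.append(run)
    return emitted


def oracle_adjacent_pairs(labels) -> int:
    """Brute-force count of adjacent positions whose labels differ by one."""
    count = 0
    for k in range(len(labels) - 1):
        if labels[k] - labels[k + 1] in (1, -1):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Reusable fixture data
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Two-organism synthetic fixture set with decoys, seed 7."""
    spec = example_spec(7, n_queries=4, n_organisms=2, n_decoys=6)
    return generate_genomes(spec, tmp_path_factory.mktemp("genomes"))


@pytest.fixture(scope="session")
def fixture_tables(fixture_set):
    hit_text, ipg_text = generate_hit_table(fixture_set, seed=7)
    return hit_text, ipg_text


@pytest.fixture()
def small_session() -> Session:
    """Hand-built session: 2 organisms, 3 clusters, 4 queries."""
    queries = make_queries(4)
    sc1 = Scaffold("SC1", [
        make_subject("p1", 1000, 2000, ["q0"]),
        make_subject("p2", 2500, 3500, ["q1"]),
        make_subject("p3", 4000, 5000, ["q2", "q3"]),
    ])
    sc2 = Scaffold("SC2", [
        make_subject("p4", 100, 900, ["q2"]),
        make_subject("p5", 1200, 2100, ["q0", "q1"]),
    ])
    sc3 = Scaffold("SC3", [
        make_subject("p6", 50, 700, ["q0"]),
        make_subject("p7", 60000, 61000, ["q1"]),
    ])
    orgs = [
        Organism("Examplia prima", "X1", [sc1, sc2]),
        Organism("Examplia secunda", "", [sc3]),
    ]
    clusters = [
        Cluster("SC1", ["p1", "p2", "p3"], 1000, 5000, ScoreBreakdown(4, 2, 0.5), uid=1),
        Cluster("SC2", ["p4", "p5"], 100, 2100, ScoreBreakdown(3, 1, 0.5), uid=2),
        Cluster("SC3", ["p6"], 50, 700, ScoreBreakdown(1, 0, 0.5), uid=3),
    ]
    session = Session(queries=queries, organisms=orgs, clusters=clusters,
                      detect=DetectParams(gap=20000, unique=1, min_hits=1))
    session.validate()
    return session
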