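"""Collocation sweep, synteny-weighted scoring, uid assignment and ranking."""

import itertools

import numpy as np
import pytest

from clusterseek.datamodel import (
    Cluster,
    DetectParams,
    Hit,
    Organism,
    Scaffold,
    ScoreBreakdown,
    Session,
    SessionValidationError,
    Subject,
)
from clusterseek.detect import (
    assign_ids_and_rank,
    detect_clusters,
    intergenic_distance,
    ranked_clusters,
    redetect,
    score_cluster,
)

from conftest import (
    make_queries,
    make_subject,
    oracle_adjacent_pairs,
    oracle_detect,
    random_scaffold,
)


QUERIES = make_queries(5)
LOOSE = DetectParams(gap=20000, unique=1, min_hits=1)


def _scaffold(*spans, qid="q0"):
    subjects = [make_subject(f"s{k}", a, b, [qid]) for k, (a, b) in enumerate(spans)]
    return Scaffold("SC", subjects)


class TestSweep:
    def test_gap_splits_into_two_clusters(self):
        scaffold = _scaffold((1000, 2000), (15000, 16000), (50000, 51000))
        clusters = detect_clusters(scaffold, LOOSE, QUERIES)
        assert [c.subject_ids for c in clusters] == [["s0", "s1"], ["s2"]]
        assert (clusters[0].start, clusters[0].end) == (1000, 16000)

    def test_larger_gap_merges_all(self):
        scaffold = _scaffold((1000, 2000), (15000, 16000), (50000, 51000))
        params = DetectParams(gap=40000, unique=1, min_hits=1)
        clusters = detect_clusters(scaffold, params, QUERIES)
        assert [c.subject_ids for c in clusters] == [["s0", "s1", "s2"]]

    def test_overlapping_genes_clamp_to_zero(self):
        prev = make_subject("a", 100, 900, ["q0"])
        nxt = make_subject("b", 500, 1200, ["q0"])
        assert intergenic_distance(prev, nxt) == 0
        scaffold = Scaffold("SC", [prev, nxt])
        clusters = detect_clusters(scaffold, DetectParams(gap=0, unique=1, min_hits=1), QUERIES)
        assert [c.subject_ids for c in clusters] == [["a", "b"]]

    def test_unsorted_scaffold_refused(self):
        scaffold = Scaffold("SC", [make_subject("b", 500, 600, ["q0"]),
                                   make_subject("a", 100, 200, ["q0"])])
        with pytest.raises(SessionValidationError, match="not sorted"):
            detect_clusters(scaffold, LOOSE, QUERIES)

    def test_unique_and_min_hits_independent(self):
        # 2 subjects, 3 hits over 2 distinct queries
        s0 = Subject("s0", 0, 500, "+", [Hit("q0", "s0", 75, 90, 1e-20, 200),
                                         Hit("q1", "s0", 75, 90, 1e-20, 150)])
        s1 = Subject("s1", 1000, 1500, "+", [Hit("q0", "s1", 75, 90, 1e-20, 180)])
        scaffold = Scaffold("SC", [s0, s1])
        assert detect_clusters(scaffold, DetectParams(20000, unique=2, min_hits=3), QUERIES)
        assert not detect_clusters(scaffold, DetectParams(20000, unique=3, min_hits=1), QUERIES)
        assert not detect_clusters(scaffold, DetectParams(20000, unique=1, min_hits=4), QUERIES)

    def test_require_is_conjunctive(self):
        scaffold = _scaffold((0, 500), (1000, 1500))
        hit_all = DetectParams(20000, 1, 1, frozenset({"q0"}))
        hit_missing = DetectParams(20000, 1, 1, frozenset({"q0", "q4"}))
        assert detect_clusters(scaffold, hit_all, QUERIES)
        assert not detect_clusters(scaffold, hit_missing, QUERIES)

    def test_matches_bruteforce_oracle_on_random_scaffolds(self):
        rng = np.random.default_rng(101)
        for _ in range(300):
            scaffold = random_scaffold(rng)
            params = DetectParams(
                gap=int(rng.integers(0, 40000)),
                unique=int(rng.integers(1, 4)),
                min_hits=int(rng.integers(1, 5)),
                require=frozenset(f"q{i}" for i in
                                  rng.choice(5, size=int(rng.integers(0, 2)), replace=False)),
            )
            got = detect_clusters(scaffold, params, QUERIES)
            expected = oracle_detect(scaffold.subjects, params)
            assert [c.subject_ids for c in got] == [[s.id for s in run] for run in expected]
            for cluster, run in zip(got, expected):
                assert cluster.start == min(s.start for s in run)
                assert cluster.end == max(s.end for s in run)

    def test_merge_only_behaviour_as_gap_grows(self):
        rng = np.random.default_rng(202)
        params0 = DetectParams(gap=0, unique=1, min_hits=1)
        for _ in range(30):
            scaffold = random_scaffold(rng)
            prev_count, prev_span = None, None
            for gap in (0, 2000, 10000, 50000, 250000):
                clusters = detect_clusters(
                    scaffold, DetectParams(gap=gap, unique=1, min_hits=1), QUERIES)
                count = len(clusters)
                span = max((c.span for c in clusters), default=0)
                if prev_count is not None:
                    assert count <= prev_count
                    assert span >= prev_span
                prev_count, prev_span = count, span


class TestScore:
    def test_perfect_synteny(self):
        subjects = [make_subject(f"s{k}", k * 1000, k * 1000 + 500, [f"q{k}"])
                    for k in range(4)]
        score = score_cluster(subjects, {f"q{i}": i for i in range(5)}, 0.5)
        assert (score.h, score.s, score.S) == (4, 3, 5.5)

    def test_shuffled_labels_lose_synteny(self):
        order = [2, 0, 3, 1]
        subjects = [make_subject(f"s{k}", k * 1000, k * 1000 + 500, [f"q{q}"])
                    for k, q in enumerate(order)]
        score = score_cluster(subjects, {f"q{i}": i for i in range(5)}, 0.5)
        assert (score.h, score.s, score.S) == (4, 0, 4.0)

    def test_zero_weight_reduces_to_h(self):
        subjects = [make_subject(f"s{k}", k * 1000, k * 1000 + 500, [f"q{k}"])
                    for k in range(3)]
        score = score_cluster(subjects, {f"q{i}": i for i in range(5)}, 0.0)
        assert score.S == score.h == 3

    def test_best_hit_labelling_uses_bitscore_then_evalue(self):
        # q3 has the higher bitscore -> label comes from q3, not q0
        subject = Subject("s0", 0, 500, "+", [
            Hit("q0", "s0", 75, 90, 1e-10, 100.0),
            Hit("q3", "s0", 75, 90, 1e-10, 300.0),
        ])
        nxt = make_subject("s1", 1000, 1500, ["q2"])
        score = score_cluster([subject, nxt], {f"q{i}": i for i in range(5)}, 0.5)
        assert score.s == 1  # labels 3,2 adjacent

    def test_exhaustive_arrangements_match_bruteforce_counter(self):
        """S = h + i*s over every label arrangement of up to 5 subjects."""
        qindex = {f"q{i}": i for i in range(4)}
        for n in range(1, 5):
            for labels in itertools.product(range(4), repeat=n):
                subjects = [make_subject(f"s{k}", k * 1000, k * 1000 + 400, [f"q{q}"])
                            for k, q in enumerate(labels)]
                score = score_cluster(subjects, qindex, 0.5)
                assert score.s == oracle_adjacent_pairs(labels)
                assert score.h == len(set(labels))
                assert score.S == score.h + 0.5 * score.s
                assert score_cluster(subjects, qindex, 0.0).S == score.h

    def test_adjacent_extension_increments_s(self):
        base = [make_subject(f"s{k}", k * 1000, k * 1000 + 400, [f"q{k}"]) for k in range(3)]
        qindex = {f"q{i}": i for i in range(5)}
        extended = base + [make_subject("s3", 3000, 3400, ["q3"])]
        assert score_cluster(extended, qindex).s == score_cluster(base, qindex).s + 1


class TestIdsAndRank:
    def _session(self, scores):
        queries = make_queries(5)
        scaffolds, clusters = [], []
        for k, (h, s) in enumerate(scores):
            subject = make_subject(f"p{k}", 100, 600, [f"q{i}" for i in range(h)])
            scaffolds.append(Scaffold(f"SC{k}", [subject]))
            clusters.append(Cluster(f"SC{k}", [f"p{k}"], 100, 600, ScoreBreakdown(h, s, 0.5)))
        session = Session(queries=queries,
                          organisms=[Organism("Org", "", scaffolds)],
                          clusters=clusters)
        return session

    def test_rank_breaks_score_tie_by_h(self):
        # S = 5.5 (h=4,s=3), 4.0 (h=4,s=0), 5.5 (h=5,s=1)
        session = assign_ids_and_rank(self._session([(4, 3), (4, 0), (5, 1)]))
        ranked = ranked_clusters(session)
        assert [(c.score.S, c.score.h) for c in ranked] == [(5.5, 5), (5.5, 4), (4.0, 4)]

    def test_single_cluster_gets_uid_1(self):
        session = assign_ids_and_rank(self._session([(2, 1)]))
        assert [c.uid for c in session.clusters] == [1]
        assert ranked_clusters(session)[0].uid == 1

    def test_uids_sequential_in_organism_scaffold_start_order(self, small_session):
        session = assign_ids_and_rank(small_session)
        assert [c.uid for c in session.clusters] == [1, 2, 3]
        accs = [c.scaffold_accession for c in session.clusters]
        assert accs == ["SC1", "SC2", "SC3"]

    def test_redetect_reassigns_uids_from_1(self, small_session):
        session = redetect(small_session, DetectParams(gap=20000, unique=1, min_hits=1))
        assert [c.uid for c in session.clusters] == list(range(1, len(session.clusters) + 1))
        # with the huge gap on SC3 the two distant subjects split into 2 clusters
        sc3 = [c for c in session.clusters if c.scaffold_accession == "SC3"]
        assert len(sc3) == 2
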