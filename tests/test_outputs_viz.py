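"""Summaries, binary table, extraction and heatmap payload."""

import json

import numpy as np
import pytest
from Bio import SeqIO
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from clusterseek.datamodel import (
    Cluster,
    DetectParams,
    Organism,
    ParameterError,
    Scaffold,
    ScoreBreakdown,
    Session,
)
from clusterseek.outputs_viz import (
    SUMMARY_COLUMNS,
    binary_table,
    extract_clusters,
    extract_sequences,
    plot_payload,
    write_gne_html,
    write_plot_html,
    write_summary,
)
from clusterseek.pipeline import search_tabular

from conftest import make_queries, make_subject


class TestSummary:
    def test_empty_session_has_sentinel(self):
        text = write_summary(Session(queries=make_queries(1)))
        assert "No clusters found." in text

    def test_score_sort_puts_max_first(self, small_session):
        text = write_summary(small_session, format="tsv", sort="score")
        first = text.splitlines()[1].split("\t")
        assert float(first[SUMMARY_COLUMNS.index("S")]) == max(
            c.score.S for c in small_session.clusters)

    def test_tsv_constant_field_count_and_lossless_cluster_fields(self, small_session):
        text = write_summary(small_session, format="tsv")
        lines = text.strip().split("\n")
        widths = {len(line.split("\t")) for line in lines}
        assert widths == {len(SUMMARY_COLUMNS)}
        # re-parse: per-cluster fields round-trip
        by_uid = {}
        for line in lines[1:]:
            row = dict(zip(SUMMARY_COLUMNS, line.split("\t")))
            by_uid.setdefault(int(row["uid"]), row)
        for cluster in small_session.clusters:
            row = by_uid[cluster.uid]
            assert int(row["start"]) == cluster.start + 1
            assert int(row["end"]) == cluster.end
            assert float(row["S"]) == cluster.score.S
            assert int(row["h"]) == cluster.score.h
            assert int(row["s"]) == cluster.score.s
            assert row["scaffold"] == cluster.scaffold_accession

    def test_human_format_lists_each_cluster(self, small_session):
        text = write_summary(small_session)
        for cluster in small_session.clusters:
            assert f"[Cluster {cluster.uid}]" in text


class TestBinaryTable:
    def test_count_cells(self, small_session):
        table = binary_table(small_session)
        row = table[table.uid == 1].iloc[0]
        assert [row["q0"], row["q1"], row["q2"], row["q3"]] == [1, 1, 1, 1]
        row3 = table[table.uid == 3].iloc[0]
        assert [row3["q0"], row3["q1"], row3["q2"], row3["q3"]] == [1, 0, 0, 0]

    def test_row_sums_equal_cluster_hit_totals(self, small_session):
        table = binary_table(small_session)
        qcols = [q.id for q in small_session.queries]
        for cluster in small_session.clusters:
            total = sum(len(s.hits) for s in small_session.cluster_subjects(cluster))
            assert table[table.uid == cluster.uid][qcols].to_numpy().sum() == total

    def test_identity_cell_takes_best(self):
        queries = make_queries(1)
        subject = make_subject("p1", 0, 500, ["q0"])
        subject.hits[0].identity = 60.0
        import copy
        second = copy.deepcopy(subject.hits[0])
        second.identity = 80.0
        second.bitscore = 100.0
        subject.hits.append(second)
        session = Session(
            queries=queries,
            organisms=[Organism("O", "", [Scaffold("S1", [subject])])],
            clusters=[Cluster("S1", ["p1"], 0, 500, ScoreBreakdown(1, 0), uid=1)])
        table = binary_table(session, cell="identity")
        assert table.iloc[0]["q0"] == 80.0


class TestExtractSequences:
    def test_query_filter(self, small_session):
        text = extract_sequences(small_session, queries=["q1"], delimited=True)
        ids = [line.split("\t")[0] for line in text.strip().split("\n")[1:]]
        assert ids == ["p2", "p5"]

    def test_no_filters_each_subject_once(self, small_session):
        text = extract_sequences(small_session, delimited=True)
        ids = [line.split("\t")[0] for line in text.strip().split("\n")[1:]]
        assert sorted(ids) == ["p1", "p2", "p3", "p4", "p5", "p6"]
        assert len(ids) == len(set(ids))

    def test_organism_regex(self, small_session):
        text = extract_sequences(small_session, organisms="secunda", delimited=True)
        ids = [line.split("\t")[0] for line in text.strip().split("\n")[1:]]
        assert ids == ["p6"]

    def test_invalid_regex_is_parameter_error(self, small_session):
        with pytest.raises(ParameterError):
            extract_sequences(small_session, organisms="[unclosed")

    def test_fasta_mode_with_sequences(self, small_session):
        text = extract_sequences(small_session, queries=["q2"],
                                 sequences={"p3": "MAAA", "p4": "MCCC"})
        assert ">p3 " in text and "MAAA" in text and "MCCC" in text


class TestExtractClusters:
    @pytest.fixture()
    def searched(self, fixture_set, fixture_tables):
        hit_text, ipg_text = fixture_tables
        return search_tabular(fixture_set.profile, hit_text, ipg_text)

    def test_min_score_filter(self, searched, fixture_set, tmp_path):
        high = max(c.score.S for c in searched.clusters)
        written, skipped = extract_clusters(
            searched, [str(p) for p in fixture_set.genbank_paths], tmp_path,
            min_score=high + 0.1)
        assert written == [] and skipped == 0
        written, _ = extract_clusters(
            searched, [str(p) for p in fixture_set.genbank_paths], tmp_path,
            min_score=high)
        assert len(written) >= 1

    def test_uid_filter_and_cds_content(self, searched, fixture_set, tmp_path):
        written, skipped = extract_clusters(
            searched, [str(p) for p in fixture_set.genbank_paths], tmp_path, uids=[2])
        assert len(written) == 1 and skipped == 0
        record = next(SeqIO.parse(str(written[0]), "genbank"))
        cluster = next(c for c in searched.clusters if c.uid == 2)
        n_cds = sum(1 for f in record.features if f.type == "CDS")
        assert n_cds >= len(cluster.subject_ids)
        assert len(record.seq) == cluster.span

    def test_unobtainable_sequence_skipped_with_count(self, searched, tmp_path):
        written, skipped = extract_clusters(searched, {}, tmp_path)
        assert written == [] and skipped == len(searched.clusters)

    def test_bigscape_region_feature(self, searched, fixture_set, tmp_path):
        written, _ = extract_clusters(
            searched, [str(p) for p in fixture_set.genbank_paths], tmp_path / "b",
            uids=[1], bigscape=True)
        record = next(SeqIO.parse(str(written[0]), "genbank"))
        regions = [f for f in record.features if f.type == "region"]
        assert regions and regions[0].qualifiers["product"] == ["other"]


class TestPlotPayload:
    def test_leaf_order_matches_reference_linkage(self, small_session):
        payload = plot_payload(small_session)
        matrix = np.array(payload["identity"])
        expected = sch.leaves_list(sch.linkage(matrix, method="average",
                                               metric="euclidean")).tolist()
        assert payload["leaf_order"] == expected

    def test_identical_rows_are_adjacent_leaves(self):
        queries = make_queries(2)
        scaffolds, clusters = [], []
        patterns = [["q0"], ["q0", "q1"], ["q0"]]  # clusters 1 and 3 identical
        for k, qs in enumerate(patterns):
            subject = make_subject(f"p{k}", 100, 600, qs)
            scaffolds.append(Scaffold(f"S{k}", [subject]))
            clusters.append(Cluster(f"S{k}", [f"p{k}"], 100, 600,
                                    ScoreBreakdown(len(qs), 0), uid=k + 1))
        session = Session(queries=queries,
                          organisms=[Organism("O", "", scaffolds)], clusters=clusters)
        order = plot_payload(session)["leaf_order"]
        assert abs(order.index(0) - order.index(2)) == 1

    def test_single_cluster_payload(self, small_session):
        small_session.clusters = small_session.clusters[:1]
        payload = plot_payload(small_session)
        assert payload["leaf_order"] == [0] and payload["linkage"] is None

    def test_no_clusters_is_error(self):
        with pytest.raises(ParameterError):
            plot_payload(Session(queries=make_queries(1)))

    def test_multi_hit_annotation_and_tooltips(self, small_session):
        payload = plot_payload(small_session)
        row = payload["tooltips"][0][0]
        assert row["hits"][0]["subject"] == "p1"
        assert "viewer_url" in row["hits"][0]

    def test_html_report_is_standalone(self, small_session, tmp_path):
        path = write_plot_html(small_session, tmp_path / "plot.html")
        text = path.read_text()
        assert text.startswith("<!DOCTYPE html>")
        assert "row_labels" in text  # embedded payload
        start = text.index("const payload = ") + len("const payload = ")
        end = text.index(";\n", start)
        payload = json.loads(text[start:end])
        assert payload["uids"] == [c.uid for c in small_session.clusters]


def test_gne_html_report(tmp_path, small_session):
    from clusterseek.gne import compute_gne

    rows = compute_gne(small_session, max_gap=30000, samples=4)
    path = write_gne_html(rows, tmp_path / "gne.html")
    text = path.read_text()
    assert "total_clusters" in text and text.startswith("<!DOCTYPE html>")
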