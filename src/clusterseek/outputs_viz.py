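"""Summaries, the binary table, sequence/cluster extraction and HTML reports.

All genomic coordinates in user-facing output are 1-based inclusive; the
session's internal convention is 0-based half-open.
"""

from __future__ import annotations

import io
import json
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from Bio import SeqIO
from Bio.SeqFeature import FeatureLocation, SeqFeature

from .datamodel import Cluster, GneRow, ParameterError, Session
from .detect import ranked_clusters

logger = logging.getLogger("clusterseek")

SUMMARY_COLUMNS = (
    "uid", "organism", "strain", "scaffold", "start", "end", "S", "h", "s",
    "query", "subject", "identity", "coverage", "evalue", "bitscore",
)


def _ordered_clusters(session: Session, sort: str) -> list[Cluster]:
    if sort == "score":
        return ranked_clusters(session)
    if sort == "organism":
        return list(session.clusters)
    raise ParameterError(f"sort must be organism|score, got {sort!r}")


def write_summary(session: Session, format: str = "human", sort: str = "organism") -> str:
    """Render the per-cluster summary.

    ``human`` groups clusters into readable blocks; ``tsv``/``csv`` emit one
    row per hit with the cluster fields repeated, so the field count is
    constant across rows. ``sort="organism"`` keeps uid (organism/scaffold)
    order; ``sort="score"`` prints rank order, most similar clusters first.
    """
    clusters = _ordered_clusters(session, sort)
    if format in ("tsv", "csv"):
        delim = "\t" if format == "tsv" else ","
        out = io.StringIO()
        out.write(delim.join(SUMMARY_COLUMNS) + "\n")
        for cluster in clusters:
            organism = session.organism_of_scaffold(cluster.scaffold_accession)
            base = [str(cluster.uid), organism.name, organism.strain,
                    cluster.scaffold_accession, str(cluster.start + 1), str(cluster.end),
                    f"{cluster.score.S:g}", str(cluster.score.h), str(cluster.score.s)]
            for subject in session.cluster_subjects(cluster):
                for hit in subject.hits:
                    row = base + [hit.query_id, subject.id, f"{hit.identity:g}",
                                  f"{hit.coverage:g}", f"{hit.evalue:g}", f"{hit.bitscore:g}"]
                    out.write(delim.join(row) + "\n")
        return out.getvalue()
    if format != "human":
        raise ParameterError(f"format must be human|tsv|csv, got {format!r}")

    out = io.StringIO()
    out.write("Cluster search summary\n======================\n")
    if not clusters:
        out.write("No clusters found.\n")
        return out.getvalue()
    for cluster in clusters:
        organism = session.organism_of_scaffold(cluster.scaffold_accession)
        out.write(f"\n[Cluster {cluster.uid}] {organism.full_name} "
                  f"{cluster.scaffold_accession}:{cluster.start + 1}-{cluster.end} "
                  f"S={cluster.score.S:g} (h={cluster.score.h}, s={cluster.score.s})\n")
        out.write(f"  {'Query':<16}{'Subject':<20}{'Identity':>9}{'Coverage':>9}"
                  f"{'E-value':>12}{'Bitscore':>10}\n")
        for subject in session.cluster_subjects(cluster):
            for hit in subject.hits:
                out.write(f"  {hit.query_id:<16}{subject.id:<20}{hit.identity:>9.1f}"
                          f"{hit.coverage:>9.1f}{hit.evalue:>12.3g}{hit.bitscore:>10.1f}\n")
    return out.getvalue()


def binary_table(session: Session, cell: str = "count") -> pd.DataFrame:
    """Presence/absence table: one row per cluster, one column per query.

    ``count`` cells hold the number of hits in the cluster for that query;
    ``identity`` cells the best percent identity (0 when absent). Leading
    columns key each cluster by uid, organism, scaffold, coordinates and
    score.
    """
    if cell not in ("count", "identity"):
        raise ParameterError(f"cell must be count|identity, got {cell!r}")
    query_ids = [q.id for q in session.queries]
    rows = []
    for cluster in session.clusters:
        organism = session.organism_of_scaffold(cluster.scaffold_accession)
        values = {qid: 0 if cell == "count" else 0.0 for qid in query_ids}
        for subject in session.cluster_subjects(cluster):
            for hit in subject.hits:
                if hit.query_id not in values:
                    continue
                if cell == "count":
                    values[hit.query_id] += 1
                else:
                    values[hit.query_id] = max(values[hit.query_id], hit.identity)
        rows.append({"uid": cluster.uid, "organism": organism.full_name,
                     "scaffold": cluster.scaffold_accession,
                     "start": cluster.start + 1, "end": cluster.end,
                     "score": cluster.score.S, **values})
    return pd.DataFrame(rows, columns=["uid", "organism", "scaffold", "start",
                                       "end", "score", *query_ids])


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _compile(pattern: str | None):
    if pattern is None:
        return None
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise ParameterError(f"invalid regular expression {pattern!r}: {exc}") from None


def extract_sequences(
    session: Session,
    *,
    queries: Sequence[str] | None = None,
    organisms: str | None = None,
    scaffolds: Sequence[str] | None = None,
    delimited: bool = False,
    sequences: Mapping[str, str] | None = None,
) -> str:
    """Extract clustered subject sequences matching the filters.

    Filters: ``queries`` keeps subjects hit by at least one listed query;
    ``organisms`` is a regular expression on the organism name; ``scaffolds``
    is a list of scaffold accessions. Each matching subject appears once
    (de-duplicated by id). Output is FASTA — with organism/scaffold/
    coordinate annotations on the header, and sequences from ``sequences``
    when provided — or, with ``delimited=True``, a TSV of the same records.
    """
    org_re = _compile(organisms)
    wanted_queries = set(queries) if queries else None
    wanted_scaffolds = set(scaffolds) if scaffolds else None
    seen: set[str] = set()
    records: list[tuple[str, str, str, int, int]] = []
    for cluster in session.clusters:
        organism = session.organism_of_scaffold(cluster.scaffold_accession)
        if org_re and not org_re.search(organism.full_name):
            continue
        if wanted_scaffolds and cluster.scaffold_accession not in wanted_scaffolds:
            continue
        for subject in session.cluster_subjects(cluster):
            if subject.id in seen:
                continue
            if wanted_queries and not ({h.query_id for h in subject.hits} & wanted_queries):
                continue
            seen.add(subject.id)
            records.append((subject.id, organism.full_name, cluster.scaffold_accession,
                            subject.start + 1, subject.end))
    if delimited:
        lines = ["\t".join(("subject", "organism", "scaffold", "start", "end"))]
        lines += ["\t".join(map(str, r)) for r in records]
        return "\n".join(lines) + "\n"
    out = io.StringIO()
    for sid, org, scaf, start, end in records:
        out.write(f">{sid} organism={org} scaffold={scaf} location={start}-{end}\n")
        if sequences and sid in sequences:
            out.write(sequences[sid] + "\n")
        else:
            out.write("\n")
    return out.getvalue()


def _cluster_filter(
    session: Session,
    uids: Sequence[int] | None,
    organisms: str | None,
    scaffolds: Sequence[str] | None,
    min_score: float | None,
) -> list[Cluster]:
    org_re = _compile(organisms)
    out = []
    for cluster in session.clusters:
        if uids and cluster.uid not in set(uids):
            continue
        organism = session.organism_of_scaffold(cluster.scaffold_accession)
        if org_re and not org_re.search(organism.full_name):
            continue
        if scaffolds and cluster.scaffold_accession not in set(scaffolds):
            continue
        if min_score is not None and cluster.score.S < min_score:
            continue
        out.append(cluster)
    return out


def extract_clusters(
    session: Session,
    genome_records: Mapping[str, "SeqIO.SeqRecord"] | Sequence[str | Path],
    out_dir: str | Path,
    *,
    uids: Sequence[int] | None = None,
    organisms: str | None = None,
    scaffolds: Sequence[str] | None = None,
    min_score: float | None = None,
    bigscape: bool = False,
    flank: int = 0,
) -> tuple[list[Path], int]:
    """Write one GenBank file per matching cluster.

    ``genome_records`` is either a mapping of scaffold accession to Biopython
    SeqRecord or a list of GenBank file paths to read them from. Each output
    spans the cluster plus ``flank`` bp either side and keeps the CDS
    features of every gene wholly inside that span — intermediate non-hit
    genes included. ``bigscape=True`` adds a region feature with a product
    qualifier for interoperability with BiG-SCAPE. Clusters whose scaffold
    sequence is unobtainable are skipped with a warning; the skipped count is
    returned alongside the written paths.
    """
    if not isinstance(genome_records, Mapping):
        loaded = {}
        for path in genome_records:
            for record in SeqIO.parse(str(path), "genbank"):
                loaded[record.id] = record
        genome_records = loaded
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    skipped = 0
    for cluster in _cluster_filter(session, uids, organisms, scaffolds, min_score):
        record = genome_records.get(cluster.scaffold_accession)
        if record is None:
            logger.warning("cluster %s: scaffold %s sequence unobtainable; skipped",
                           cluster.uid, cluster.scaffold_accession)
            skipped += 1
            continue
        lo = max(0, cluster.start - flank)
        hi = min(len(record.seq), cluster.end + flank)
        sub = record[lo:hi]
        sub.id = f"{cluster.scaffold_accession}_cluster{cluster.uid}"
        sub.name = sub.id[:16]
        sub.description = (f"cluster {cluster.uid} "
                           f"{cluster.scaffold_accession}:{lo + 1}-{hi} S={cluster.score.S:g}")
        sub.annotations["molecule_type"] = record.annotations.get("molecule_type", "DNA")
        sub.annotations["organism"] = record.annotations.get("organism", "")
        if bigscape:
            region = SeqFeature(FeatureLocation(0, hi - lo), type="region",
                                qualifiers={"product": ["other"]})
            sub.features.insert(0, region)
        path = out_dir / f"cluster{cluster.uid}.gbk"
        SeqIO.write(sub, str(path), "genbank")
        written.append(path)
    return written, skipped


# ---------------------------------------------------------------------------
# Heatmap report
# ---------------------------------------------------------------------------

def plot_payload(session: Session, *, method: str = "average", metric: str = "euclidean") -> dict:
    """Assemble the data behind the cluster heatmap report.

    The matrix holds the best hit identity per (cluster, query); rows are
    ordered by the leaf order of agglomerative clustering (average linkage,
    Euclidean distance by default) of the identity vectors. Cell annotations
    show the hit count when a query has multiple hits in a cluster; per-cell
    tooltips carry subject details and a genome-viewer URL template.
    """
    if not session.clusters:
        raise ParameterError("plot requires at least one cluster")
    identity = binary_table(session, cell="identity")
    counts = binary_table(session, cell="count")
    query_ids = [q.id for q in session.queries]
    matrix = identity[query_ids].to_numpy(dtype=float)
    if len(session.clusters) > 1:
        linkage = sch.linkage(matrix, method=method, metric=metric)
        leaf_order = sch.leaves_list(linkage).tolist()
        linkage_out = linkage.tolist()
    else:
        leaf_order, linkage_out = [0], None

    tooltips: list[list[dict]] = []
    for cluster in session.clusters:
        row = []
        for qid in query_ids:
            cells = []
            for subject in session.cluster_subjects(cluster):
                for hit in subject.hits:
                    if hit.query_id != qid:
                        continue
                    cells.append({
                        "subject": subject.id,
                        "identity": hit.identity,
                        "coverage": hit.coverage,
                        "evalue": hit.evalue,
                        "bitscore": hit.bitscore,
                        "start": subject.start + 1,
                        "end": subject.end,
                        "viewer_url": (
                            "https://www.ncbi.nlm.nih.gov/nuccore/"
                            f"{cluster.scaffold_accession}?report=graph"
                            f"&from={subject.start + 1}&to={subject.end}"),
                    })
            row.append({"hits": cells})
        tooltips.append(row)

    row_labels = []
    for cluster in session.clusters:
        organism = session.organism_of_scaffold(cluster.scaffold_accession)
        row_labels.append(f"{organism.full_name} {cluster.scaffold_accession} "
                          f"[{cluster.uid}]")
    return {
        "queries": query_ids,
        "row_labels": row_labels,
        "uids": [c.uid for c in session.clusters],
        "identity": matrix.tolist(),
        "counts": counts[query_ids].to_numpy(dtype=float).astype(int).tolist(),
        "leaf_order": leaf_order,
        "linkage": linkage_out,
        "tooltips": tooltips,
    }


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Cluster heatmap</title>
<style>
body {{ font-family: sans-serif; }}
table {{ border-collapse: collapse; }}
td.cell {{ width: 2em; height: 2em; text-align: center; border: 1px solid #ddd;
          font-size: 0.8em; }}
td.label {{ padding: 0 0.5em; font-size: 0.8em; white-space: nowrap; }}
th {{ font-size: 0.8em; writing-mode: vertical-rl; padding: 0.3em; }}
</style></head>
<body>
<h1>Cluster heatmap</h1>
<p>Rows are detected clusters in dendrogram leaf order; columns are query
sequences. Cells are shaded by best hit identity (white 0% to blue 100%);
a number marks queries with multiple hits in the cluster. Hover a cell for
hit details.</p>
<div id="heatmap"></div>
<script>
const payload = {payload};
const el = document.getElementById("heatmap");
let html = "<table><tr><td></td>" +
  payload.queries.map(q => "<th>" + q + "</th>").join("") + "</tr>";
for (const r of payload.leaf_order) {{
  html += "<tr><td class='label'>" + payload.row_labels[r] + "</td>";
  payload.identity[r].forEach((v, c) => {{
    const count = payload.counts[r][c];
    const text = count > 1 ? String(count) : "";
    const tips = payload.tooltips[r][c].hits.map(h =>
      h.subject + " " + h.identity.toFixed(1) + "% e=" + h.evalue).join("; ");
    html += "<td class='cell' title='" + tips +
      "' style='background: rgba(33,102,172," + (v / 100) + ")'>" + text + "</td>";
  }});
  html += "</tr>";
}}
html += "</table>";
el.innerHTML = html;
</script>
</body></html>
"""


def write_plot_html(session: Session, path: str | Path, **kwargs) -> Path:
    """Serialize the heatmap report to a standalone HTML file with embedded data."""
    payload = plot_payload(session, **kwargs)
    text = _HTML_TEMPLATE.format(payload=json.dumps(payload))
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return path


_GNE_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Genomic neighbourhood estimation</title></head>
<body>
<h1>Genomic neighbourhood estimation</h1>
<p>Total predicted clusters and mean/median cluster size (bp) at each
intergenic distance threshold.</p>
<svg id="chart" width="720" height="420" style="border:1px solid #ccc"></svg>
<script>
const rows = {rows};
const svg = document.getElementById("chart");
const W = 720, H = 420, pad = 50;
const maxGap = Math.max(...rows.map(r => r.gap), 1);
const maxSize = Math.max(...rows.map(r => r.mean_size), 1);
const maxTotal = Math.max(...rows.map(r => r.total_clusters), 1);
function line(vals, vmax, colour) {{
  const pts = rows.map((r, k) => [
    pad + (W - 2 * pad) * r.gap / maxGap,
    H - pad - (H - 2 * pad) * vals[k] / vmax]);
  const p = document.createElementNS("http://www.w3.org/2000/svg", "polyline");
  p.setAttribute("points", pts.map(q => q.join(",")).join(" "));
  p.setAttribute("fill", "none"); p.setAttribute("stroke", colour);
  const title = document.createElementNS("http://www.w3.org/2000/svg", "title");
  title.textContent = rows.map((r, k) => "gap=" + r.gap + ": " + vals[k]).join("\\n");
  p.appendChild(title);
  svg.appendChild(p);
}}
line(rows.map(r => r.mean_size), maxSize, "#2166ac");
line(rows.map(r => r.median_size), maxSize, "#67a9cf");
line(rows.map(r => r.total_clusters), maxTotal, "#b2182b");
</script>
</body></html>
"""


def write_gne_html(rows: Sequence[GneRow], path: str | Path) -> Path:
    """Serialize gne rows to a standalone HTML line-chart report."""
    data = [{"gap": r.gap, "total_clusters": r.total_clusters,
             "mean_size": r.mean_size, "median_size": r.median_size} for r in rows]
    path = Path(path)
    path.write_text(_GNE_TEMPLATE.format(rows=json.dumps(data)), encoding="utf-8")
    return path
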