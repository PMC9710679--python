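"""Obtain raw homology hits from a pluggable backend and quality-filter them.

Backends share one contract: each returns plain :class:`Hit` records (and,
for the remote backend, the subject accessions needed to resolve genomic
context). The tabular path — a 12-column BLAST/DIAMOND ``outfmt 6`` table —
is the common denominator: local alignment output is parsed through it, and
canned tables stand in for live remote searches in tests.

Filtering applies the three user thresholds (minimum identity, minimum
coverage, maximum e-value), all inclusive.
"""

from __future__ import annotations

import abc
import io
import logging
import shutil
import subprocess
import tempfile
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .datamodel import (
    DialectError,
    FilterParams,
    Hit,
    InputError,
    RemoteError,
    ResumableSearchError,
)
from .query_io import QueryProfile

logger = logging.getLogger("clusterseek")

#: Column order of the standard 12-column tabular alignment output
#: (BLAST/DIAMOND ``outfmt 6``).
HIT_TABLE_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Profile (HMM) hits have no percent identity; they carry sentinel values
#: that always pass identity/coverage filters, so only the e-value threshold
#: applies to them.
PROFILE_SENTINEL = 100.0


@dataclass(frozen=True)
class BackendContract:
    name: str
    resume_by_rid: bool = False
    profiles: bool = False


BACKENDS = {
    "remote": BackendContract("remote", resume_by_rid=True),
    "local": BackendContract("local"),
    "hmm": BackendContract("hmm", profiles=True),
    "combi": BackendContract("combi", profiles=True),
    "tabular": BackendContract("tabular"),
}


# ---------------------------------------------------------------------------
# Tabular ingestion
# ---------------------------------------------------------------------------

def ingest_hit_table(
    stream: str | Path | io.TextIOBase | Iterable[str],
    query_lengths: Mapping[str, int],
    *,
    dialect: Sequence[str] = HIT_TABLE_COLUMNS,
) -> list[Hit]:
    """Parse a 12-column tab-separated hit table into Hit records.

    Coverage is computed from the query alignment span:
    ``100 * (qend - qstart + 1) / query_length``. Multiple HSPs for the same
    query-subject pair are collapsed to the single best by bitscore (ties:
    lowest e-value), since cluster detection operates per query-subject
    relationship.
    """
    if tuple(dialect) != HIT_TABLE_COLUMNS:
        raise DialectError(f"unsupported hit-table dialect; expected columns {HIT_TABLE_COLUMNS}")
    if isinstance(stream, Path) or (
            isinstance(stream, str) and "\n" not in stream and Path(stream).is_file()):
        lines: Iterable[str] = Path(stream).read_text().splitlines()
    elif isinstance(stream, str):
        lines = stream.splitlines()
    elif isinstance(stream, io.TextIOBase):
        lines = stream.read().splitlines()
    else:
        lines = list(stream)

    best: dict[tuple[str, str], Hit] = {}
    order: list[tuple[str, str]] = []
    unknown: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise DialectError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}")
        qseqid, sseqid = fields[0], fields[1]
        if qseqid not in query_lengths:
            unknown.add(qseqid)
            continue
        try:
            pident = float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            evalue, bitscore = float(fields[10]), float(fields[11])
        except ValueError as exc:
            raise DialectError(f"line {lineno}: malformed numeric field ({exc})") from None
        coverage = min(100.0, 100.0 * (qend - qstart + 1) / query_lengths[qseqid])
        hit = Hit(qseqid, sseqid, pident, coverage, evalue, bitscore)
        key = (qseqid, sseqid)
        prev = best.get(key)
        if prev is None:
            best[key] = hit
            order.append(key)
        elif (hit.bitscore, -hit.evalue) > (prev.bitscore, -prev.evalue):
            best[key] = hit
    if unknown:
        raise InputError(
            f"hit table references queries not in the profile: {sorted(unknown)}")
    return [best[key] for key in order]


def filter_hits(hits: Iterable[Hit], params: FilterParams) -> list[Hit]:
    """Retain hits meeting all quality thresholds (inclusive); order preserved."""
    return [
        h for h in hits
        if h.identity >= params.min_identity
        and h.coverage >= params.min_coverage
        and h.evalue <= params.max_evalue
    ]


# ---------------------------------------------------------------------------
# Local alignment backend
# ---------------------------------------------------------------------------

def run_local_search(
    profile: QueryProfile,
    db_path: str | Path,
    *,
    executable: str = "blastp",
    evalue_ceiling: float = 10.0,
    threads: int = 1,
    extra_args: Sequence[str] = (),
) -> list[Hit]:
    """Search query proteins against a local formatted protein database.

    Runs a local protein aligner (``blastp`` by default) requesting the
    standard 12-column tabular output, then parses it with
    :func:`ingest_hit_table`.
    """
    if not profile.queries or not profile.sequences:
        raise InputError("no query sequences to search")
    db = Path(db_path)
    if not db.with_suffix(db.suffix + ".pin").exists() and not db.exists():
        raise InputError(f"alignment database not found: {db}")
    if shutil.which(executable) is None:
        raise RemoteError(
            f"alignment executable {executable!r} not found on PATH; install it or "
            f"supply hits as a tabular file instead")
    with tempfile.NamedTemporaryFile("w", suffix=".faa", delete=False) as tmp:
        tmp.write(profile.to_fasta())
        query_path = tmp.name
    cmd = [executable, "-query", query_path, "-db", str(db), "-outfmt", "6",
           "-evalue", str(evalue_ceiling), "-num_threads", str(threads), *extra_args]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    Path(query_path).unlink(missing_ok=True)
    if proc.returncode != 0:
        raise RemoteError(f"{executable} failed (exit {proc.returncode}): {proc.stderr.strip()}")
    return ingest_hit_table(proc.stdout, profile.query_lengths)


def make_alignment_db(fasta_path: str | Path, *, executable: str = "makeblastdb") -> Path:
    """Format a protein FASTA for the local aligner; returns the db path."""
    fasta = Path(fasta_path)
    if shutil.which(executable) is None:
        raise RemoteError(f"database formatter {executable!r} not found on PATH")
    proc = subprocess.run(
        [executable, "-in", str(fasta), "-dbtype", "prot"], capture_output=True, text=True)
    if proc.returncode != 0:
        raise RemoteError(f"{executable} failed: {proc.stderr.strip()}")
    return fasta


# ---------------------------------------------------------------------------
# Profile HMM backend
# ---------------------------------------------------------------------------

def run_hmm_search(
    profile_accessions: Sequence[str],
    fasta_db_path: str | Path,
    hmm_file: str | Path,
) -> list[Hit]:
    """Search profile HMMs against a local protein FASTA database.

    The requested profiles are extracted by accession (or name) from
    ``hmm_file`` and searched against the database sequences; one Hit is
    emitted per profile-sequence match, carrying the match e-value and
    bitscore. Identity and coverage are set to sentinel 100 because percent
    identity is undefined for profile matches; only the e-value threshold
    filters profile hits. Profile hits can be mixed with protein-query hits
    for hybrid searches.
    """
    import pyhmmer

    if not profile_accessions:
        raise InputError("no profile accessions given")
    def _text(value) -> str | None:
        if value is None:
            return None
        return value.decode() if isinstance(value, bytes) else str(value)

    wanted = list(dict.fromkeys(profile_accessions))
    found: dict[str, object] = {}
    with pyhmmer.plan7.HMMFile(str(hmm_file)) as handle:
        for hmm in handle:
            acc = _text(hmm.accession)
            name = _text(hmm.name)
            base_acc = acc.split(".")[0] if acc else None
            for key in wanted:
                if key in (acc, name, base_acc) and key not in found:
                    found[key] = hmm
    missing = [k for k in wanted if k not in found]
    if missing:
        raise InputError(f"profiles not found in {hmm_file}: {missing}")

    with pyhmmer.easel.SequenceFile(str(fasta_db_path), digital=True) as seqs:
        targets = seqs.read_block()
    hits_out: list[Hit] = []
    for key in wanted:
        for tophits in pyhmmer.hmmsearch([found[key]], targets):
            for match in tophits:
                mname = match.name
                hits_out.append(Hit(
                    query_id=key,
                    subject_id=mname.decode() if isinstance(mname, bytes) else str(mname),
                    identity=PROFILE_SENTINEL,
                    coverage=PROFILE_SENTINEL,
                    evalue=match.evalue,
                    bitscore=match.score,
                ))
    hits_out.sort(key=lambda h: (h.query_id, -h.bitscore, h.evalue))
    return hits_out


# ---------------------------------------------------------------------------
# Remote adapter contract
# ---------------------------------------------------------------------------

class RemoteAdapter(abc.ABC):
    """Interface to a remote search service.

    A search is submitted once and assigned a request identifier (RID); the
    service is then polled until the search reaches a terminal state, at
    which point results are retrieved as a standard 12-column hit table plus
    the subject accessions needed for genomic-context resolution. A search
    can be resumed later from its RID without re-submitting.
    """

    @abc.abstractmethod
    def submit(self, profile: QueryProfile, entrez_query: str | None = None) -> str:
        """Submit a search, optionally pre-filtered by an Entrez query; returns the RID."""

    @abc.abstractmethod
    def status(self, rid: str) -> str:
        """Return 'WAITING', 'READY', 'FAILED' or 'UNKNOWN' for a RID."""

    @abc.abstractmethod
    def retrieve(self, rid: str) -> str:
        """Return the 12-column tabular hit text for a READY RID."""


class CannedRemoteAdapter(RemoteAdapter):
    """Offline adapter serving a pre-computed hit table under a fixed RID."""

    def __init__(self, hit_table_text: str, rid: str = "CANNED01"):
        self.hit_table_text = hit_table_text
        self.rid = rid
        self.submissions: list[tuple[int, str | None]] = []

    def submit(self, profile: QueryProfile, entrez_query: str | None = None) -> str:
        self.submissions.append((len(profile.queries), entrez_query))
        return self.rid

    def status(self, rid: str) -> str:
        return "READY" if rid == self.rid else "UNKNOWN"

    def retrieve(self, rid: str) -> str:
        if rid != self.rid:
            raise ResumableSearchError(f"unknown RID {rid!r}")
        return self.hit_table_text


def remote_search(
    adapter: RemoteAdapter,
    profile: QueryProfile,
    *,
    entrez_query: str | None = None,
    rid: str | None = None,
    poll_interval: float = 0.0,
    max_polls: int = 100,
) -> tuple[list[Hit], list[str], str]:
    """Run (or resume) a remote search through ``adapter``.

    When ``rid`` is given the search is resumed: no submission happens and
    results are retrieved directly once the RID reports READY. Returns the
    parsed hits, the distinct subject accessions (in first-seen order) and
    the RID used.
    """
    if rid is None:
        rid = adapter.submit(profile, entrez_query)
    for _ in range(max_polls):
        state = adapter.status(rid)
        if state == "READY":
            break
        if state == "UNKNOWN":
            raise ResumableSearchError(
                f"RID {rid!r} is unknown or expired; re-run the search without --rid")
        if state == "FAILED":
            raise RemoteError(f"remote search {rid!r} failed")
        if poll_interval:
            time.sleep(poll_interval)
    else:
        raise RemoteError(f"remote search {rid!r} did not finish after {max_polls} polls")
    hits = ingest_hit_table(adapter.retrieve(rid), profile.query_lengths)
    accessions = list(dict.fromkeys(h.subject_id for h in hits))
    return hits, accessions, rid
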