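"""Core domain types and the serializable search session.

Every other stage of the pipeline reads and writes these types. A search
session captures the complete state of one search — the ordered queries, the
filtering and detection parameters, the organism → scaffold → subject → hit
hierarchy and the detected clusters — and round-trips losslessly through a
canonical JSON representation, so detection can be re-run with new parameters
without repeating the homology search.

Coordinate convention: all coordinates are 0-based half-open internally.
External formats (GenBank, IPG tables, summary output) are 1-based inclusive
and are converted at the I/O boundary.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("clusterseek")

SESSION_VERSION = "1.0"

# Published defaults: the intergenic-distance threshold (a cluster is
# finalized when no new hit lies within this many bp of the previous hit) and
# the weight of synteny in the cluster similarity score S = h + i*s.
DEFAULT_GAP = 20000
DEFAULT_SYNTENY_WEIGHT = 0.5

DEFAULT_UNIQUE = 3
DEFAULT_MIN_HITS = 3
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 50.0
DEFAULT_MAX_EVALUE = 0.01


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ClusterSeekError(Exception):
    """Base class for all package errors."""


class InputError(ClusterSeekError):
    """Empty or otherwise unusable user input."""


class DialectError(ClusterSeekError):
    """A tabular input does not conform to the expected column layout."""


class SessionValidationError(ClusterSeekError):
    """A session (or one of its components) violates a structural invariant."""


class SessionParseError(ClusterSeekError):
    """A session file could not be parsed; names the offending field."""


class SessionVersionError(ClusterSeekError):
    """A session file declares a version newer than this package supports."""


class StoreError(ClusterSeekError):
    """The genome coordinate store is absent or corrupt."""


class ParameterError(ClusterSeekError):
    """An operation was called with out-of-range parameters."""


class ResumableSearchError(ClusterSeekError):
    """A remote request identifier could not be resumed."""


class RemoteError(ClusterSeekError):
    """A remote backend call failed (retryable)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Query:
    """One input query: a protein sequence or a domain profile.

    ``index`` is the 0-based position in the query order; synteny scoring and
    the binary table both rely on this ordering.
    """

    id: str
    index: int
    length: int | None = None
    kind: str = "protein"

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "profile"):
            raise SessionValidationError(f"query kind must be protein|profile, got {self.kind!r}")
        if self.index < 0:
            raise SessionValidationError(f"query index must be >= 0, got {self.index}")
        if self.length is not None and self.length <= 0:
            raise SessionValidationError(f"query length must be positive, got {self.length}")


@dataclass
class Hit:
    """One query → subject homology match."""

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        self.identity = float(self.identity)
        self.coverage = float(self.coverage)
        self.evalue = float(self.evalue)
        self.bitscore = float(self.bitscore)
        if not 0.0 <= self.identity <= 100.0:
            raise SessionValidationError(f"identity out of [0,100]: {self.identity}")
        if not 0.0 <= self.coverage <= 100.0:
            raise SessionValidationError(f"coverage out of [0,100]: {self.coverage}")
        if self.evalue < 0:
            raise SessionValidationError(f"evalue must be >= 0: {self.evalue}")


@dataclass
class Subject:
    """A protein-coding gene in a searched genome with >= 1 query hit.

    ``start``/``end`` are 0-based half-open genomic coordinates. Hits are kept
    sorted by descending bitscore (ties: ascending e-value, then query index).
    """

    id: str
    start: int
    end: int
    strand: str
    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SessionValidationError(
                f"subject {self.id}: start must be < end ({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise SessionValidationError(f"subject {self.id}: strand must be + or -")
        for hit in self.hits:
            if hit.subject_id != self.id:
                raise SessionValidationError(
                    f"subject {self.id}: hit subject_id {hit.subject_id!r} does not match")

    def sort_hits(self, query_index: Mapping[str, int]) -> None:
        self.hits.sort(key=lambda h: (-h.bitscore, h.evalue, query_index.get(h.query_id, 1 << 30)))

    def best_hit(self, query_index: Mapping[str, int]) -> Hit:
        return min(self.hits,
                   key=lambda h: (-h.bitscore, h.evalue, query_index.get(h.query_id, 1 << 30)))


@dataclass
class Scaffold:
    """A genomic scaffold holding subjects sorted by position."""

    accession: str
    subjects: list[Subject] = field(default_factory=list)

    def sort_subjects(self) -> None:
        self.subjects.sort(key=lambda s: (s.start, s.end, s.id))

    def validate(self) -> None:
        keys = [(s.start, s.end, s.id) for s in self.subjects]
        if any(a >= b for a, b in zip(keys, keys[1:])):
            raise SessionValidationError(
                f"scaffold {self.accession}: subjects not strictly sorted by (start, end, id)")


@dataclass
class Organism:
    name: str
    strain: str = ""
    scaffolds: list[Scaffold] = field(default_factory=list)

    @property
    def full_name(self) -> str:
        return f"{self.name} {self.strain}".strip()

    def validate(self) -> None:
        accs = [s.accession for s in self.scaffolds]
        if len(accs) != len(set(accs)):
            raise SessionValidationError(
                f"organism {self.full_name}: duplicate scaffold accessions")
        for scaffold in self.scaffolds:
            scaffold.validate()


@dataclass
class ScoreBreakdown:
    """Cluster similarity S = h + i*s.

    h: distinct queries with at least one hit in the cluster.
    s: adjacent subject-gene pairs whose best-hit queries are adjacent in the
       query order (conserved synteny).
    i: synteny weighting factor.
    """

    h: int
    s: int
    i: float = DEFAULT_SYNTENY_WEIGHT

    @property
    def S(self) -> float:
        return self.h + self.i * self.s

    def __post_init__(self) -> None:
        if self.h < 1:
            raise SessionValidationError(f"score h must be >= 1, got {self.h}")
        if self.s < 0:
            raise SessionValidationError(f"score s must be >= 0, got {self.s}")


@dataclass
class Cluster:
    """A scored contiguous run of subjects on one scaffold.

    ``uid`` is assigned once per session (sequential, starting at 1) after
    all scaffolds have been swept; it is None for freshly detected clusters.
    """

    scaffold_accession: str
    subject_ids: list[str]
    start: int
    end: int
    score: ScoreBreakdown
    uid: int | None = None

    def __post_init__(self) -> None:
        if not self.subject_ids:
            raise SessionValidationError("cluster must contain at least one subject")
        if self.start > self.end:
            raise SessionValidationError("cluster start must be <= end")
        if self.uid is not None and self.uid < 1:
            raise SessionValidationError(f"cluster uid must be positive, got {self.uid}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class FilterParams:
    """Hit quality thresholds: all three are inclusive (>=, >=, <=)."""

    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    max_evalue: float = DEFAULT_MAX_EVALUE

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 100:
            raise ParameterError(f"min_identity out of [0,100]: {self.min_identity}")
        if not 0 <= self.min_coverage <= 100:
            raise ParameterError(f"min_coverage out of [0,100]: {self.min_coverage}")
        if self.max_evalue <= 0:
            raise ParameterError(f"max_evalue must be > 0: {self.max_evalue}")


@dataclass
class DetectParams:
    """Cluster detection thresholds.

    gap:      maximum intergenic distance (bp) between consecutive subjects.
    unique:   minimum number of distinct queries hit within a cluster.
    min_hits: minimum total number of hits within a cluster (independent of
              ``unique``; neither bounds the other).
    require:  query ids that must all be hit within a cluster (conjunctive).
    """

    gap: int = DEFAULT_GAP
    unique: int = DEFAULT_UNIQUE
    min_hits: int = DEFAULT_MIN_HITS
    require: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.require = frozenset(self.require)
        if self.gap < 0:
            raise ParameterError(f"gap must be >= 0: {self.gap}")
        if self.unique < 1:
            raise ParameterError(f"unique must be >= 1: {self.unique}")
        if self.min_hits < 1:
            raise ParameterError(f"min_hits must be >= 1: {self.min_hits}")


@dataclass
class GneRow:
    """Cluster count and size statistics at one gap value."""

    gap: int
    total_clusters: int
    mean_size: float
    median_size: float


MODES = ("remote", "local", "hmm", "combi", "tabular")


@dataclass
class Session:
    """Complete serializable state of one search."""

    queries: list[Query] = field(default_factory=list)
    filter: FilterParams = field(default_factory=FilterParams)
    detect: DetectParams = field(default_factory=DetectParams)
    organisms: list[Organism] = field(default_factory=list)
    clusters: list[Cluster] = field(default_factory=list)
    mode: str = "tabular"
    rid: str | None = None
    version: str = SESSION_VERSION
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SessionValidationError(f"unknown mode {self.mode!r}")

    # -- helpers ----------------------------------------------------------

    @property
    def query_index(self) -> dict[str, int]:
        return {q.id: q.index for q in self.queries}

    def iter_scaffolds(self) -> Iterator[tuple[Organism, Scaffold]]:
        for organism in self.organisms:
            for scaffold in organism.scaffolds:
                yield organism, scaffold

    def subject_map(self) -> dict[tuple[str, str], Subject]:
        """Map (scaffold accession, subject id) -> Subject."""
        out: dict[tuple[str, str], Subject] = {}
        for _, scaffold in self.iter_scaffolds():
            for subject in scaffold.subjects:
                out.setdefault((scaffold.accession, subject.id), subject)
        return out

    def cluster_subjects(self, cluster: Cluster) -> list[Subject]:
        smap = self.subject_map()
        return [smap[(cluster.scaffold_accession, sid)] for sid in cluster.subject_ids]

    def organism_of_scaffold(self, accession: str) -> Organism:
        for organism, scaffold in self.iter_scaffolds():
            if scaffold.accession == accession:
                return organism
        raise SessionValidationError(f"scaffold {accession!r} not in session")

    def validate(self) -> None:
        ids = [q.id for q in self.queries]
        if len(ids) != len(set(ids)):
            raise SessionValidationError("duplicate query ids")
        if [q.index for q in self.queries] != list(range(len(self.queries))):
            raise SessionValidationError("query indices must form 0..n-1 in order")
        for organism in self.organisms:
            organism.validate()
        uids = [c.uid for c in self.clusters if c.uid is not None]
        if len(uids) != len(set(uids)):
            raise SessionValidationError("duplicate cluster uid")
        smap = self.subject_map()
        for cluster in self.clusters:
            for sid in cluster.subject_ids:
                if (cluster.scaffold_accession, sid) not in smap:
                    raise SessionValidationError(
                        f"cluster {cluster.uid}: subject {sid!r} not resolvable on "
                        f"scaffold {cluster.scaffold_accession!r}")


# ---------------------------------------------------------------------------
# Serialization: canonical JSON, byte-stable across save/load/save
# ---------------------------------------------------------------------------

_KNOWN_KEYS = ("version", "mode", "queries", "filter", "detect", "organisms", "clusters", "rid")


def _num(x: float) -> float | int:
    """Canonical number formatting: integral floats emit as ints."""
    f = float(x)
    if f.is_integer() and abs(f) < 1e15:
        return int(f)
    return f


def _hit_obj(h: Hit) -> dict:
    return {
        "query_id": h.query_id,
        "subject_id": h.subject_id,
        "identity": _num(h.identity),
        "coverage": _num(h.coverage),
        "evalue": _num(h.evalue),
        "bitscore": _num(h.bitscore),
    }


def session_to_obj(session: Session) -> dict:
    obj: dict = {
        "version": session.version,
        "mode": session.mode,
        "queries": [
            {"id": q.id, "index": q.index, "length": q.length, "kind": q.kind}
            for q in session.queries
        ],
        "filter": {
            "min_identity": _num(session.filter.min_identity),
            "min_coverage": _num(session.filter.min_coverage),
            "max_evalue": _num(session.filter.max_evalue),
        },
        "detect": {
            "gap": session.detect.gap,
            "unique": session.detect.unique,
            "min_hits": session.detect.min_hits,
            "require": sorted(session.detect.require),
        },
        "organisms": [
            {
                "name": org.name,
                "strain": org.strain,
                "scaffolds": [
                    {
                        "accession": sc.accession,
                        "subjects": [
                            {
                                "id": su.id,
                                "start": su.start,
                                "end": su.end,
                                "strand": su.strand,
                                "hits": [_hit_obj(h) for h in su.hits],
                            }
                            for su in sc.subjects
                        ],
                    }
                    for sc in org.scaffolds
                ],
            }
            for org in session.organisms
        ],
        "clusters": [
            {
                "uid": c.uid,
                "scaffold_accession": c.scaffold_accession,
                "subject_ids": list(c.subject_ids),
                "start": c.start,
                "end": c.end,
                "score": {
                    "h": c.score.h,
                    "s": c.score.s,
                    "i": _num(c.score.i),
                    "S": _num(c.score.S),
                },
            }
            for c in session.clusters
        ],
        "rid": session.rid,
    }
    for key in sorted(session.extra):
        if key not in _KNOWN_KEYS:
            obj[key] = session.extra[key]
    return obj


def save_session(session: Session, path: str | Path | io.TextIOBase) -> None:
    """Write the canonical JSON form of ``session``.

    Keys appear in a fixed order and numbers in a fixed format, so that
    save(load(save(x))) is byte-identical to save(x).
    """
    session.validate()
    text = json.dumps(session_to_obj(session), indent=2, ensure_ascii=False) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def _req(obj: dict, key: str, ctx: str):
    if key not in obj:
        raise SessionParseError(f"missing field {ctx}.{key}")
    return obj[key]


def session_from_obj(obj: dict) -> Session:
    if not isinstance(obj, dict):
        raise SessionParseError("session payload is not a JSON object")
    version = str(_req(obj, "version", "session"))
    try:
        major = int(re.match(r"(\d+)", version).group(1))
    except (AttributeError, ValueError):
        raise SessionParseError(f"unparseable version string {version!r}") from None
    if major > int(SESSION_VERSION.split(".")[0]):
        raise SessionVersionError(
            f"session version {version} is newer than supported {SESSION_VERSION}")
    try:
        queries = [
            Query(id=q["id"], index=q["index"], length=q.get("length"), kind=q.get("kind", "protein"))
            for q in _req(obj, "queries", "session")
        ]
        fobj = _req(obj, "filter", "session")
        filt = FilterParams(fobj["min_identity"], fobj["min_coverage"], fobj["max_evalue"])
        dobj = _req(obj, "detect", "session")
        det = DetectParams(dobj["gap"], dobj["unique"], dobj["min_hits"],
                           frozenset(dobj.get("require", ())))
        organisms = []
        for o in _req(obj, "organisms", "session"):
            scaffolds = []
            for sc in o["scaffolds"]:
                subjects = []
                for su in sc["subjects"]:
                    hits = [Hit(h["query_id"], h["subject_id"], h["identity"],
                                h["coverage"], h["evalue"], h["bitscore"])
                            for h in su["hits"]]
                    subjects.append(Subject(su["id"], su["start"], su["end"], su["strand"], hits))
                scaffolds.append(Scaffold(sc["accession"], subjects))
            organisms.append(Organism(o["name"], o.get("strain", ""), scaffolds))
        clusters = []
        for c in _req(obj, "clusters", "session"):
            sobj = c["score"]
            clusters.append(Cluster(
                scaffold_accession=c["scaffold_accession"],
                subject_ids=list(c["subject_ids"]),
                start=c["start"], end=c["end"],
                score=ScoreBreakdown(sobj["h"], sobj["s"], sobj["i"]),
                uid=c["uid"],
            ))
    except KeyError as exc:
        raise SessionParseError(f"missing field {exc.args[0]!r} in session payload") from None
    extra = {k: v for k, v in obj.items() if k not in _KNOWN_KEYS}
    session = Session(queries=queries, filter=filt, detect=det, organisms=organisms,
                      clusters=clusters, mode=obj.get("mode", "tabular"),
                      rid=obj.get("rid"), version=version, extra=extra)
    session.validate()
    return session


def load_session(path: str | Path | io.TextIOBase) -> Session:
    """Load a session file, re-validating all structural invariants."""
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionParseError(f"malformed session file: {exc}") from None
    return session_from_obj(obj)
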