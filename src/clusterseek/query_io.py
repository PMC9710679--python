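"""Parse query inputs into an ordered query profile.

Queries can come from a protein FASTA file, from annotated GenBank/EMBL
records (one query per CDS feature, in genomic order), or from a plain list
of sequence identifiers whose sequences are fetched later by a remote
adapter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from .datamodel import InputError, Query

logger = logging.getLogger("clusterseek")

_AA_EXTRA = set("Xx*")


@dataclass
class QueryProfile:
    """Ordered queries plus their amino-acid sequences.

    ``sequences`` has no entry for profile (HMM) queries, which have no
    single sequence.
    """

    queries: list[Query] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def query_index(self) -> dict[str, int]:
        return {q.id: q.index for q in self.queries}

    @property
    def query_lengths(self) -> dict[str, int]:
        return {q.id: q.length for q in self.queries if q.length is not None}

    def add(self, qid: str, sequence: str | None, kind: str = "protein") -> Query:
        query = Query(id=qid, index=len(self.queries), kind=kind,
                      length=len(sequence) if sequence else None)
        self.queries.append(query)
        if sequence:
            self.sequences[qid] = sequence
        return query

    def to_fasta(self) -> str:
        return "".join(f">{q.id}\n{self.sequences[q.id]}\n"
                       for q in self.queries if q.id in self.sequences)


def sniff_format(path: str | Path) -> str:
    """Guess the file format from its first non-blank line."""
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("LOCUS"):
                return "genbank"
            if line.startswith("ID "):
                return "embl"
            break
    raise InputError(f"could not determine query file format of {path}")


def _clean_protein(seq: str, label: str) -> str:
    seq = seq.strip().replace("*", "")
    bad = {c for c in seq.upper() if c not in "ACDEFGHIKLMNPQRSTVWYXBZJUO"}
    if bad:
        raise InputError(f"query {label!r}: non amino-acid characters {sorted(bad)}")
    return seq


def _cds_label(feature, counter: int) -> str:
    for key in ("protein_id", "locus_tag", "gene"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return f"query_{counter}"


def _cds_translation(feature, record) -> str | None:
    if "translation" in feature.qualifiers:
        return feature.qualifiers["translation"][0]
    try:
        if feature.location is None:
            return None
        nt = feature.extract(record.seq)
        if len(nt) % 3 != 0:
            return None
        return str(Seq(nt).translate(table=1)).rstrip("*")
    except Exception:
        return None


def parse_query_file(path: str | Path, format: str = "auto") -> QueryProfile:
    """Read query proteins from a FASTA, GenBank or EMBL file.

    FASTA: one query per record, in file order. GenBank/EMBL: one query per
    CDS feature, ordered by (record appearance, feature start, feature end,
    locus_tag); the translation qualifier is used when present, otherwise the
    CDS is conceptually translated with the standard genetic code. CDS
    features that cannot be translated are skipped with a warning.
    """
    path = Path(path)
    if format == "auto":
        format = sniff_format(path)
    profile = QueryProfile()
    if format == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            profile.add(record.id, _clean_protein(str(record.seq), record.id))
    elif format in ("genbank", "embl"):
        counter = 0
        for record in SeqIO.parse(str(path), format):
            feats = [f for f in record.features if f.type == "CDS"]
            feats.sort(key=lambda f: (int(f.location.start), int(f.location.end),
                                      f.qualifiers.get("locus_tag", [""])[0]))
            for feature in feats:
                counter += 1
                translation = _cds_translation(feature, record)
                if not translation:
                    logger.warning("skipping CDS %s in %s: no translation and "
                                   "coordinates not translatable",
                                   _cds_label(feature, counter), record.id)
                    continue
                label = _cds_label(feature, counter)
                profile.add(label, _clean_protein(translation, label))
    else:
        raise InputError(f"unknown query format {format!r}")
    if not profile.queries:
        raise InputError(f"no query sequences found in {path}")
    return profile


def parse_query_identifiers(source: str | Path | Iterable[str]) -> list[str]:
    """Parse whitespace/newline-delimited sequence identifiers.

    Accepts a path, a string, or an iterable of lines. Returns an
    order-preserving, de-duplicated list; sequence retrieval for these
    identifiers is delegated to the remote adapter.
    """
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = "\n".join(source)
    seen: dict[str, None] = {}
    for token in text.split():
        seen.setdefault(token)
    if not seen:
        raise InputError("no query identifiers found")
    return list(seen)
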