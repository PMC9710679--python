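"""Genomic-context resolution.

Filtered hits name subject proteins but carry no coordinates. This stage
attaches each hit protein to every genomic placement on record — from an
Identical Protein Groups (IPG) table in remote mode, or from the local
coordinate store in local mode — and assembles the organism → scaffold →
subject hierarchy that cluster detection sweeps. Every placement is kept: a
protein placed on N scaffolds yields N subjects, each carrying the full hit
set, so no potential cluster is missed through annotation error or
fragmented assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .datamodel import DialectError, Hit, Organism, Scaffold, Subject
from .genomedb import GeneRecord

logger = logging.getLogger("clusterseek")

#: Expected header of the NCBI IPG tab-separated dialect.
IPG_COLUMNS = (
    "Id", "Source", "Nucleotide Accession", "Start", "Stop", "Strand",
    "Protein", "Protein Name", "Organism", "Strain",
)


@dataclass(frozen=True)
class IpgRow:
    """One genomic placement of a protein, normalized to 0-based half-open."""

    ipg_id: str
    source: str
    nucleotide_accession: str
    start: int   # 0-based inclusive
    stop: int    # exclusive
    strand: str
    protein_accession: str
    protein_name: str
    organism: str
    strain: str


def parse_ipg_table(text: str) -> list[IpgRow]:
    """Parse an NCBI-dialect IPG table (tab-separated, with header).

    Every data row is kept — one row per placement of a protein. Coordinates
    arrive 1-based inclusive; rows whose start exceeds stop (a minus-strand
    dialect) are normalized so start < stop with strand set to "-".
    """
    lines = [line for line in text.splitlines() if line.strip()]
    if not lines:
        return []
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header[:len(IPG_COLUMNS)] != IPG_COLUMNS:
        raise DialectError(
            f"unexpected IPG header {header}; expected columns {IPG_COLUMNS}")
    rows: list[IpgRow] = []
    for line in lines[1:]:
        fields = line.rstrip("\n").split("\t")
        fields += [""] * (len(IPG_COLUMNS) - len(fields))
        ipg_id, source, acc, start_s, stop_s, strand, prot, name, org, strain = \
            fields[:len(IPG_COLUMNS)]
        start1, stop1 = int(start_s), int(stop_s)
        if start1 > stop1:
            start1, stop1 = stop1, start1
            strand = "-"
        if strand not in ("+", "-"):
            strand = "+"
        if not acc:
            raise DialectError(f"IPG row for protein {prot!r} lacks a nucleotide accession")
        rows.append(IpgRow(ipg_id, source, acc, start1 - 1, stop1, strand,
                           prot, name, org, strain))
    return rows


@dataclass(frozen=True)
class Placement:
    """Backend-neutral view of one genomic placement of a protein."""

    protein_key: str
    organism: str
    strain: str
    scaffold: str
    start: int
    end: int
    strand: str


def as_placements(
    placements: Iterable[Union[IpgRow, GeneRecord, Placement]],
) -> list[Placement]:
    out = []
    for p in placements:
        if isinstance(p, Placement):
            out.append(p)
        elif isinstance(p, IpgRow):
            out.append(Placement(p.protein_accession, p.organism, p.strain,
                                 p.nucleotide_accession, p.start, p.stop, p.strand))
        elif isinstance(p, GeneRecord):
            # local-mode join key is the integer db_index, not the protein_id
            out.append(Placement(str(p.db_index), p.organism, p.strain,
                                 p.scaffold, p.start, p.end, p.strand))
        else:
            raise TypeError(f"unsupported placement type {type(p).__name__}")
    return out


def build_hierarchy(
    hits: Sequence[Hit],
    placements: Iterable[Union[IpgRow, GeneRecord, Placement]],
    query_index: Mapping[str, int] | None = None,
) -> tuple[list[Organism], list[str]]:
    """Group hits into the organism → scaffold → subject hierarchy.

    Returns ``(organisms, unplaced)`` where ``unplaced`` lists the subject
    protein ids that received hits but have no known genomic placement (they
    are reported, never silently dropped). Subjects within a scaffold are
    sorted by (start, end, id); hits within a subject by descending bitscore
    (ties: ascending e-value, then query index). Organisms are identified by
    the (name, strain) pair and ordered by it.
    """
    query_index = dict(query_index or {})
    hits_by_protein: dict[str, list[Hit]] = {}
    for hit in hits:
        hits_by_protein.setdefault(hit.subject_id, []).append(hit)

    placed = as_placements(placements)
    by_protein: dict[str, list[Placement]] = {}
    for p in placed:
        by_protein.setdefault(p.protein_key, []).append(p)

    organisms: dict[tuple[str, str], Organism] = {}
    scaffolds: dict[tuple[str, str, str], Scaffold] = {}
    unplaced: list[str] = []
    for protein, protein_hits in hits_by_protein.items():
        protein_placements = by_protein.get(protein)
        if not protein_placements:
            unplaced.append(protein)
            continue
        for p in protein_placements:
            okey = (p.organism, p.strain)
            organism = organisms.get(okey)
            if organism is None:
                organism = organisms[okey] = Organism(p.organism, p.strain)
            skey = (p.organism, p.strain, p.scaffold)
            scaffold = scaffolds.get(skey)
            if scaffold is None:
                scaffold = scaffolds[skey] = Scaffold(p.scaffold)
                organism.scaffolds.append(scaffold)
            subject = Subject(protein, p.start, p.end, p.strand,
                              [Hit(**vars(h)) for h in protein_hits])
            subject.sort_hits(query_index)
            scaffold.subjects.append(subject)

    for organism in organisms.values():
        organism.scaffolds.sort(key=lambda s: s.accession)
        for scaffold in organism.scaffolds:
            scaffold.sort_subjects()
    out = [organisms[k] for k in sorted(organisms)]
    if unplaced:
        logger.warning("%d hit protein(s) had no genomic placement: %s",
                       len(unplaced), ", ".join(sorted(unplaced)[:10]))
    return out, sorted(unplaced)
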