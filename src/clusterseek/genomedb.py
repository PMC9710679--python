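"""Local genome databases for offline searches.

``make_db`` builds, in one pass over a collection of genome files, the two
stores a local search needs: a protein FASTA (to be formatted for the
aligner) whose headers are unique integer database indices, and an embedded
SQLite store mapping each index to the gene's organism, scaffold and
coordinates. At search time, hit subject ids (database indices) are resolved
back to genomic coordinates with a single query against the store.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .datamodel import InputError, StoreError

logger = logging.getLogger("clusterseek")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS genes (
    db_index INTEGER PRIMARY KEY,
    protein_id TEXT NOT NULL,
    organism TEXT NOT NULL,
    strain TEXT NOT NULL,
    scaffold TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    translation TEXT NOT NULL
);
"""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene in the local store (0-based half-open coords)."""

    db_index: int
    protein_id: str
    organism: str
    strain: str
    scaffold: str
    start: int
    end: int
    strand: str
    translation: str


def _genbank_genes(path: Path) -> Iterable[tuple[str, str, str, int, int, str, str]]:
    """Yield (protein_id, organism, strain, start, end, strand, translation) per
    CDS, tagged with scaffold accession: yields (scaffold, *gene)."""
    for record in SeqIO.parse(str(path), "genbank"):
        organism = record.annotations.get("organism", "") or path.stem
        strain = ""
        for feature in record.features:
            if feature.type == "source" and "strain" in feature.qualifiers:
                strain = feature.qualifiers["strain"][0]
                break
        feats = [f for f in record.features if f.type == "CDS"]
        feats.sort(key=lambda f: (int(f.location.start), int(f.location.end)))
        counter = 0
        for feature in feats:
            counter += 1
            translation = None
            if "translation" in feature.qualifiers:
                translation = feature.qualifiers["translation"][0]
            else:
                try:
                    nt = feature.extract(record.seq)
                    if len(nt) % 3 == 0:
                        translation = str(Seq(nt).translate(table=1)).rstrip("*")
                except Exception:
                    translation = None
            if not translation:
                logger.warning("skipping CDS without translation in %s:%s", path.name, record.id)
                continue
            protein_id = (feature.qualifiers.get("protein_id")
                          or feature.qualifiers.get("locus_tag")
                          or feature.qualifiers.get("gene")
                          or [f"{record.id}_{counter}"])[0]
            strand = "-" if feature.location.strand == -1 else "+"
            yield (record.id, protein_id, organism, strain,
                   int(feature.location.start), int(feature.location.end),
                   strand, translation.replace("*", ""))


def _find_fasta_partner(gff_path: Path) -> Path:
    for ext in (".fasta", ".fa", ".fna"):
        candidate = gff_path.with_suffix(ext)
        if candidate.exists():
            return candidate
    raise InputError(f"GFF3 file {gff_path} has no FASTA partner "
                     f"({gff_path.stem}.fasta/.fa/.fna)")


def _gff3_genes(gff_path: Path) -> Iterable[tuple[str, str, str, str, int, int, str, str]]:
    """Parse a GFF3 + FASTA pair; CDS parts are merged per parent feature into
    one gene span and translated from the paired FASTA (standard code)."""
    import gffutils

    fasta_path = _find_fasta_partner(gff_path)
    seqs = {rec.id: rec.seq for rec in SeqIO.parse(str(fasta_path), "fasta")}
    try:
        db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:
        raise InputError(f"unparseable GFF3 file {gff_path}: {exc}") from None
    organism = gff_path.stem
    groups: dict[str, list] = {}
    for cds in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = list(db.parents(cds, level=1))
        key = parents[0].id if parents else (cds.id or f"{cds.seqid}:{cds.start}")
        groups.setdefault(key, []).append(cds)
    entries = []
    for key, parts in groups.items():
        parts.sort(key=lambda f: f.start)
        seqid = parts[0].seqid
        start = min(p.start for p in parts) - 1  # GFF3 is 1-based inclusive
        end = max(p.end for p in parts)
        strand = parts[0].strand if parts[0].strand in "+-" else "+"
        if seqid not in seqs:
            raise InputError(f"{gff_path}: scaffold {seqid!r} missing from {fasta_path}")
        chunks = [str(seqs[seqid][p.start - 1:p.end]) for p in parts]
        nt = Seq("".join(chunks))
        if strand == "-":
            nt = nt.reverse_complement()
        if len(nt) % 3 != 0:
            logger.warning("skipping %s in %s: CDS length not a multiple of 3", key, gff_path.name)
            continue
        translation = str(nt.translate(table=1)).rstrip("*").replace("*", "")
        if not translation:
            continue
        entries.append((seqid, key, organism, "", start, end, strand, translation))
    entries.sort(key=lambda e: (e[0], e[4], e[5]))
    yield from entries


def _parse_genome(path: Path) -> list[tuple[str, str, str, str, int, int, str, str]]:
    if path.suffix.lower() in (".gff", ".gff3"):
        return list(_gff3_genes(path))
    return list(_genbank_genes(path))


def make_db(
    genome_paths: Sequence[str | Path],
    out_prefix: str | Path,
    *,
    batch_size: int = 10,
) -> tuple[Path, Path]:
    """Build the coordinate store and protein FASTA from genome files.

    Each path is a GenBank flat file or a GFF3 file with a FASTA partner
    sharing its basename. Genomes are parsed independently and flushed to the
    store every ``batch_size`` genomes; the output is identical for any batch
    size. Returns ``(store_path, fasta_path)``.
    """
    if not genome_paths:
        raise InputError("no genome files given")
    if batch_size < 1:
        raise InputError("batch_size must be >= 1")
    out_prefix = Path(out_prefix)
    store_path = out_prefix.with_suffix(".sqlite3")
    fasta_path = out_prefix.with_suffix(".faa")
    store_path.unlink(missing_ok=True)

    conn = sqlite3.connect(store_path)
    conn.executescript(_SCHEMA)
    db_index = 0
    batch: list[tuple] = []
    with open(fasta_path, "w") as fasta:
        for n, raw_path in enumerate(genome_paths, start=1):
            path = Path(raw_path)
            if not path.exists():
                conn.close()
                raise InputError(f"genome file not found: {path}")
            try:
                genes = _parse_genome(path)
            except InputError:
                conn.close()
                raise
            except Exception as exc:
                conn.close()
                raise InputError(f"unparseable genome file {path}: {exc}") from None
            for scaffold, protein_id, organism, strain, start, end, strand, translation in genes:
                db_index += 1
                batch.append((db_index, protein_id, organism, strain, scaffold,
                              start, end, strand, translation))
                fasta.write(f">{db_index}\n{translation}\n")
            if n % batch_size == 0:
                conn.executemany("INSERT INTO genes VALUES (?,?,?,?,?,?,?,?,?)", batch)
                conn.commit()
                batch.clear()
        if batch:
            conn.executemany("INSERT INTO genes VALUES (?,?,?,?,?,?,?,?,?)", batch)
            conn.commit()
    conn.close()
    logger.info("built genome db %s: %d genes from %d files", out_prefix, db_index,
                len(genome_paths))
    return store_path, fasta_path


def lookup_genes(
    store_path: str | Path,
    db_indices: Sequence[int | str],
) -> tuple[list[GeneRecord], list[int]]:
    """Resolve database indices to gene records in a single store round-trip.

    Returns ``(records, missing_indices)``; missing indices are reported,
    never fatal.
    """
    store_path = Path(store_path)
    if not store_path.exists():
        raise StoreError(f"coordinate store not found: {store_path}")
    indices = [int(i) for i in db_indices]
    if not indices:
        return [], []
    try:
        conn = sqlite3.connect(store_path)
        placeholders = ",".join("?" * len(indices))
        rows = conn.execute(
            f"SELECT db_index, protein_id, organism, strain, scaffold, start, end, "
            f"strand, translation FROM genes WHERE db_index IN ({placeholders}) "
            f"ORDER BY db_index", indices).fetchall()
        conn.close()
    except sqlite3.DatabaseError as exc:
        raise StoreError(f"corrupt coordinate store {store_path}: {exc}") from None
    records = [GeneRecord(*row) for row in rows]
    found = {r.db_index for r in records}
    missing = [i for i in indices if i not in found]
    return records, missing


def all_genes(store_path: str | Path) -> list[GeneRecord]:
    """Return every gene record in the store (ordered by db_index)."""
    store_path = Path(store_path)
    if not store_path.exists():
        raise StoreError(f"coordinate store not found: {store_path}")
    conn = sqlite3.connect(store_path)
    rows = conn.execute(
        "SELECT db_index, protein_id, organism, strain, scaffold, start, end, "
        "strand, translation FROM genes ORDER BY db_index").fetchall()
    conn.close()
    return [GeneRecord(*row) for row in rows]
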