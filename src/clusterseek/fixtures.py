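"""Deterministic synthetic data: toy genomes with planted homolog clusters.

Every pipeline stage is testable offline against these fixtures: the
generator plants runs of query homologues (with controlled intergenic gaps)
on synthetic scaffolds, pads them with decoy genes spaced widely enough to
never join a planted cluster, and emits the matching GenBank files, a
12-column hit table, an IPG placement table, and a truth table recording
every planted locus span. All randomness flows through one explicitly
seeded generator, so outputs are byte-stable.

The fixtures exercise plumbing and detection arithmetic, not biology: decoy
sequences are uniform-random proteins with no evolutionary structure, and
planted "homologues" are exact copies of the query proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .context import IPG_COLUMNS
from .datamodel import ParameterError
from .query_io import QueryProfile

logger = logging.getLogger("clusterseek")

_AA = "ACDEFGHIKLMNPQRSTVWY"
# one unambiguous codon per amino acid, for back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

#: Decoy genes are spaced at least this far apart (and from planted loci) so
#: that, at the default 20 kbp gap threshold, spurious decoy hits can only
#: ever form singleton groups — they can never bridge or join a planted
#: cluster.
DEFAULT_DECOY_SPACING = (25000, 40000)
DEFAULT_QUERY_LENGTH = 150


@dataclass(frozen=True)
class PlantedLocus:
    """One planted homolog run: gene order as query indices, gaps in bp."""

    organism: str
    scaffold: str
    start: int
    gene_order: tuple[int, ...]
    gaps: tuple[int, ...]
    strain: str = ""

    def __post_init__(self) -> None:
        if len(self.gaps) != max(len(self.gene_order) - 1, 0):
            raise ParameterError(
                f"locus on {self.scaffold}: need {len(self.gene_order) - 1} gaps, "
                f"got {len(self.gaps)}")
        if any(g < 0 for g in self.gaps):
            raise ParameterError("intergenic gaps must be >= 0")


@dataclass(frozen=True)
class PlantSpec:
    """Specification of a synthetic fixture set."""

    n_queries: int
    planted_loci: tuple[PlantedLocus, ...]
    n_decoys: int = 0
    seed: int = 0
    query_length: int = DEFAULT_QUERY_LENGTH
    decoy_spacing: tuple[int, int] = DEFAULT_DECOY_SPACING

    def __post_init__(self) -> None:
        for locus in self.planted_loci:
            bad = [i for i in locus.gene_order if not 0 <= i < self.n_queries]
            if bad:
                raise ParameterError(f"locus gene_order indices out of range: {bad}")


@dataclass(frozen=True)
class TruthGene:
    protein_id: str
    query_index: int | None   # None for decoys
    organism: str
    strain: str
    scaffold: str
    start: int
    end: int
    strand: str
    translation: str


@dataclass(frozen=True)
class TruthCluster:
    organism: str
    strain: str
    scaffold: str
    start: int
    end: int
    gene_ids: tuple[str, ...]


@dataclass
class FixtureSet:
    spec: PlantSpec
    profile: QueryProfile
    genbank_paths: list[Path]
    genes: list[TruthGene]
    truth_clusters: list[TruthCluster]

    @property
    def planted_genes(self) -> list[TruthGene]:
        return [g for g in self.genes if g.query_index is not None]

    @property
    def decoy_genes(self) -> list[TruthGene]:
        return [g for g in self.genes if g.query_index is None]

    def truth_table(self) -> str:
        lines = ["\t".join(("organism", "strain", "scaffold", "start", "end", "genes"))]
        for tc in self.truth_clusters:
            lines.append("\t".join((tc.organism, tc.strain, tc.scaffold,
                                    str(tc.start), str(tc.end), ",".join(tc.gene_ids))))
        return "\n".join(lines) + "\n"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(_AA[i] for i in rng.integers(0, len(_AA), length - 1))


def _back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def generate_queries(n: int, seed: int, length: int = DEFAULT_QUERY_LENGTH) -> QueryProfile:
    """Generate ``n`` random query proteins q0..q{n-1}."""
    rng = np.random.default_rng([0, seed])
    profile = QueryProfile()
    for i in range(n):
        profile.add(f"q{i}", _random_protein(rng, length))
    return profile


def generate_genomes(spec: PlantSpec, out_dir: str | Path) -> FixtureSet:
    """Lay out the planted loci and decoys, and write one GenBank per organism.

    Planted genes are exact copies of the query proteins (back-translated
    into the scaffold sequence), placed at the specified starts with the
    specified intergenic gaps. Decoys are random proteins distributed
    round-robin over the scaffolds after the planted content, spaced by
    ``spec.decoy_spacing``. Overlapping layouts raise a spec error. Running
    the generator twice with the same spec yields byte-identical files.
    """
    # distinct stream from the query generator, so decoy proteins can never
    # replay the query draws
    rng = np.random.default_rng([1, spec.seed])
    profile = generate_queries(spec.n_queries, spec.seed, spec.query_length)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes: list[TruthGene] = []
    truth_clusters: list[TruthCluster] = []
    scaffold_keys: list[tuple[str, str, str]] = []   # (organism, strain, scaffold)
    gene_counter = 0

    for locus in spec.planted_loci:
        key = (locus.organism, locus.strain, locus.scaffold)
        if key not in scaffold_keys:
            scaffold_keys.append(key)
        pos = locus.start
        members: list[str] = []
        locus_start = pos
        for k, qidx in enumerate(locus.gene_order):
            gene_counter += 1
            protein = profile.sequences[f"q{qidx}"]
            span = 3 * len(protein) + 3
            pid = f"g{gene_counter:04d}"
            genes.append(TruthGene(pid, qidx, locus.organism, locus.strain,
                                   locus.scaffold, pos, pos + span, "+", protein))
            members.append(pid)
            end = pos + span
            if k < len(locus.gaps):
                pos = end + locus.gaps[k]
        truth_clusters.append(TruthCluster(locus.organism, locus.strain, locus.scaffold,
                                           locus_start, genes[-1].end, tuple(members)))

    # decoys: round-robin over scaffolds, placed after all planted content
    if spec.n_decoys and not scaffold_keys:
        raise ParameterError("cannot place decoys: no scaffolds defined by planted_loci")
    next_pos: dict[tuple[str, str, str], int] = {}
    for key in scaffold_keys:
        last_end = max((g.end for g in genes
                        if (g.organism, g.strain, g.scaffold) == key), default=0)
        next_pos[key] = last_end
    for d in range(spec.n_decoys):
        key = scaffold_keys[d % len(scaffold_keys)]
        gene_counter += 1
        protein = _random_protein(rng, spec.query_length)
        spacing = int(rng.integers(spec.decoy_spacing[0], spec.decoy_spacing[1] + 1))
        start = next_pos[key] + spacing
        span = 3 * len(protein) + 3
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        genes.append(TruthGene(f"g{gene_counter:04d}", None, key[0], key[1], key[2],
                               start, start + span, strand, protein))
        next_pos[key] = start + span

    # overlap check per scaffold
    by_scaffold: dict[tuple[str, str, str], list[TruthGene]] = {}
    for g in genes:
        by_scaffold.setdefault((g.organism, g.strain, g.scaffold), []).append(g)
    for key, members in by_scaffold.items():
        members.sort(key=lambda g: g.start)
        for a, b in zip(members, members[1:]):
            if b.start < a.end:
                raise ParameterError(
                    f"overlapping gene layout on scaffold {key[2]}: "
                    f"{a.protein_id} [{a.start},{a.end}) vs {b.protein_id} [{b.start},{b.end})")

    # emit one GenBank per organism
    paths: list[Path] = []
    organisms = list(dict.fromkeys((g.organism, g.strain) for g in genes))
    for org_name, strain in organisms:
        records = []
        for key in scaffold_keys:
            if (key[0], key[1]) != (org_name, strain):
                continue
            members = sorted(by_scaffold[key], key=lambda g: g.start)
            length = members[-1].end + 500
            seq_arr = rng.integers(0, 4, length)
            seq = list("ACGT"[i] for i in seq_arr)
            for g in members:
                nt = _back_translate(g.translation)
                if g.strand == "-":
                    nt = str(Seq(nt).reverse_complement())
                seq[g.start:g.end] = nt
            record = SeqRecord(Seq("".join(seq)), id=key[2], name=key[2][:16],
                               description=f"synthetic scaffold of {org_name}".strip())
            record.annotations["molecule_type"] = "DNA"
            record.annotations["organism"] = org_name
            record.annotations["date"] = "01-JAN-2000"
            source = SeqFeature(FeatureLocation(0, length), type="source",
                                qualifiers={"organism": [org_name]})
            if strain:
                source.qualifiers["strain"] = [strain]
            record.features.append(source)
            for g in members:
                strand = 1 if g.strand == "+" else -1
                feature = SeqFeature(
                    FeatureLocation(g.start, g.end, strand=strand), type="CDS",
                    qualifiers={"protein_id": [g.protein_id],
                                "translation": [g.translation]})
                record.features.append(feature)
            records.append(record)
        fname = (f"{org_name}_{strain}".strip("_").replace(" ", "_") or "organism") + ".gbk"
        path = out_dir / fname
        SeqIO.write(records, str(path), "genbank")
        paths.append(path)
    return FixtureSet(spec, profile, paths, genes, truth_clusters)


def generate_hit_table(
    fixture: FixtureSet,
    *,
    identity_range: tuple[float, float] = (60.0, 95.0),
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, str]:
    """Emit a 12-column hit table and matching IPG table for a fixture set.

    One hit per planted gene, from its source query, with identity drawn
    uniformly from ``identity_range``, full query coverage and a strong
    e-value. Each decoy gene receives, with probability ``spurious_rate``, a
    weak spurious hit from a random query (moderate identity/coverage, but
    good enough to survive default filtering, so noise robustness is
    exercised downstream rather than masked by the filter). The IPG table
    lists one placement row per hit gene, with 1-based inclusive coordinates
    in the NCBI dialect.
    """
    rng = np.random.default_rng([2, seed])
    qlen = {q.id: q.length for q in fixture.profile.queries}
    hit_lines: list[str] = []
    ipg_lines = ["\t".join(IPG_COLUMNS)]
    ipg_id = 0

    def _ipg_row(gene: TruthGene) -> None:
        nonlocal ipg_id
        ipg_id += 1
        ipg_lines.append("\t".join((
            str(ipg_id), "INSDC", gene.scaffold, str(gene.start + 1), str(gene.end),
            gene.strand, gene.protein_id, "hypothetical protein",
            gene.organism, gene.strain)))

    for gene in fixture.planted_genes:
        qid = f"q{gene.query_index}"
        length = qlen[qid]
        identity = float(rng.uniform(*identity_range))
        evalue = 10.0 ** -float(rng.uniform(40, 120))
        bitscore = round(2.0 * length * identity / 100.0, 1)
        hit_lines.append("\t".join((
            qid, gene.protein_id, f"{identity:.1f}", str(length), "0", "0",
            "1", str(length), "1", str(length), f"{evalue:.2e}", f"{bitscore:.1f}")))
        _ipg_row(gene)

    for gene in fixture.decoy_genes:
        if rng.random() >= spurious_rate:
            continue
        qid = f"q{int(rng.integers(0, fixture.spec.n_queries))}"
        length = qlen[qid]
        qend = int(length * 0.7)
        hit_lines.append("\t".join((
            qid, gene.protein_id, f"{float(rng.uniform(35, 50)):.1f}", str(qend), "30", "2",
            "1", str(qend), "5", str(qend + 4), "1.0e-06", "62.0")))
        _ipg_row(gene)

    return "\n".join(hit_lines) + ("\n" if hit_lines else ""), "\n".join(ipg_lines) + "\n"


def example_spec(
    seed: int = 0,
    *,
    n_queries: int = 4,
    n_organisms: int = 2,
    n_decoys: int = 6,
    internal_gap_range: tuple[int, int] = (100, 5000),
) -> PlantSpec:
    """A ready-made spec: one planted locus per organism, tight internal gaps.

    Internal gaps stay well below the default 20 kbp threshold and decoys are
    spaced above it, so default-parameter detection recovers each planted
    locus exactly.
    """
    rng = np.random.default_rng(seed)
    loci = []
    for n in range(n_organisms):
        order = tuple(rng.permutation(n_queries).tolist())
        gaps = tuple(int(g) for g in
                     rng.integers(internal_gap_range[0], internal_gap_range[1] + 1,
                                  n_queries - 1))
        loci.append(PlantedLocus(
            organism=f"Synthetica exemplaris {chr(65 + n)}",
            scaffold=f"SYN{n + 1:03d}",
            start=int(rng.integers(1000, 5000)),
            gene_order=order,
            gaps=gaps,
        ))
    return PlantSpec(n_queries=n_queries, planted_loci=tuple(loci),
                     n_decoys=n_decoys, seed=seed)
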