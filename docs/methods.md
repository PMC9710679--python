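# Methods

## The model

clusterseek searches for *gene clusters*: sets of genes that are
functionally associated and physically collocated in a genomic
neighbourhood. The object of inference is not a single alignment but a
locus — a maximal run of homology hits on one scaffold whose pairwise
spacing stays below a threshold.

The pipeline is a chain of well-separated stages, each of which reads and
writes the same session data model:

1. **Query ingestion** (`query_io`) — an ordered profile of query proteins
   (or domain profiles). Order matters: it defines the reference gene order
   against which synteny is scored, and the column order of all tabular
   output.
2. **Hit acquisition and filtering** (`search_filter`) — any backend that
   yields (query, subject, identity, coverage, e-value, bitscore) records.
   Filtering keeps a hit iff identity ≥ `min_identity` **and** coverage ≥
   `min_coverage` **and** e-value ≤ `max_evalue`; all three comparisons are
   inclusive, a choice made once for reproducibility and documented in the
   CLI help. Coverage is the query alignment span,
   `100·(qend−qstart+1)/query_length`, when the backend does not report it
   directly. Multiple HSPs for one query–subject pair collapse to the single
   best by bitscore, because detection operates per query–subject
   relationship. Profile-HMM hits have no percent identity, so they carry
   sentinel identity/coverage of 100 and are filtered on e-value only.
3. **Context resolution** (`context`, `genomedb`) — hits name proteins;
   placements give them coordinates. Remote-style searches use an Identical
   Protein Groups (IPG) table, local searches the SQLite coordinate store
   built by `makedb`. Every placement is kept: a protein found on N
   scaffolds yields N subjects, each carrying the complete hit set. This
   deliberately over-counts rather than risk missing a cluster split by
   annotation error or assembly fragmentation; hit proteins with no known
   placement are reported in an "unplaced" list, never silently dropped.
4. **Detection** (`detect`) — a single left-to-right sweep per scaffold.
   The intergenic distance between consecutive subjects is
   `max(0, next.start − prev.end)`: gene-boundary distance, clamped at zero
   for overlapping genes, so overlaps always group. A group extends while
   this distance stays ≤ `gap` and is emitted iff (a) it hits ≥ `unique`
   distinct queries, (b) it contains ≥ `min_hits` hits in total, and (c) it
   hits every query named in `require` (conjunctive). `unique` and
   `min_hits` are independent thresholds; neither bounds the other.
5. **Scoring** — `S = h + i·s`. `h` counts distinct queries hit anywhere in
   the cluster. Each subject is labelled with the query *index* of its best
   hit (bitscore descending, ties by e-value ascending then query index);
   `s` counts adjacent subject pairs, in genomic order, whose labels differ
   by exactly one. Adjacency is direction-agnostic (|Δindex| = 1 counts
   whether the local order runs q0→q1 or q1→q0): conserved neighbourhood,
   inverted or not, is still synteny. Subjects are never multi-labelled;
   one gene contributes one label. Strand is ignored throughout grouping
   and scoring.
6. **IDs and ranking** — uids are assigned sequentially (from 1) in
   (organism, strain, scaffold, cluster start) order, the order summaries
   group by; rank order is descending `S`, ties broken by descending `h`,
   then ascending uid. Re-detection on a loaded session reassigns uids from
   1; stale ids are never preserved.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `gap` | 20000 | bp | max intergenic distance inside a cluster |
| `i` (synteny weight) | 0.5 | — | weight of `s` in `S = h + i·s` |
| `unique` | 3 | queries | min distinct queries hit |
| `min_hits` | 3 | hits | min total hits |
| `require` | ∅ | — | query ids that must all be hit |
| `min_identity` | 30 | % | hit filter (inclusive) |
| `min_coverage` | 50 | % | hit filter (inclusive) |
| `max_evalue` | 0.01 | — | hit filter (inclusive) |

The 20 kbp gap and the 0.5 synteny weight are the published defaults of
this method family. The remaining defaults mirror the conventional settings
of comparable homology-search tools; all are configurable per search and
stored in the session, so a saved session always re-detects under its own
parameters.

The 20 kbp default suits tightly packed (bacterial/fungal) clusters but is
arbitrary for loosely organised genomes. The `gne` sweep exists precisely
to interrogate it: `total_clusters` is non-increasing and mean/median
cluster size non-decreasing in `gap` (with `unique=1, min_hits=1`, raising
the gap can only merge groups), so the curves resemble logarithmic growth
and plateaus mark threshold ranges where the answer is stable. The gap grid
is linear from 0 to `max_gap` by default; the log grid replaces its first
point with 0 so the degenerate no-gap case is always sampled. Reading off a
"correct" neighbourhood size from the curve remains the scientist's call —
the package computes the curve, not the cut-off.

## Session format and numerics

Sessions are canonical JSON: fixed key order, integral floats emitted as
integers, sorted `require` lists, trailing unknown keys preserved in sorted
order. This makes save∘load∘save byte-identical, which the tests assert —
the cheapest possible guarantee that repeated re-detection cycles cannot
drift. All coordinates are 0-based half-open internally; GenBank, GFF3, IPG
and all user-facing output are 1-based inclusive and converted exactly once
at the I/O boundary. Cluster start/end are the min subject start / max
subject end; cluster size is `end − start` in bp.

Tie-breaks are total orders everywhere randomness could creep in: subjects
sort by (start, end, id); hits within a subject by (−bitscore, e-value,
query index); organisms by (name, strain). An unsorted scaffold reaching
the detector raises an internal-invariant error rather than being silently
re-sorted.

The local genome database is one SQLite file plus one protein FASTA whose
headers are the store's integer indices — the join key for local searches,
immune to duplicate user protein ids. `make_db` flushes every `batch_size`
genomes; output is identical for any batch size, and permuting input file
order changes only index assignment, never coordinates. GFF3 CDS parts are
merged per parent feature into one gene span (min start, max end) and
translated from the paired FASTA with the standard genetic code;
untranslatable CDS features are skipped with a warning.

## Backends

The contribution of the package is everything downstream of hit
acquisition, so alignment itself is delegated: the local backend shells out
to NCBI `blastp` (any aligner emitting the standard 12-column table can be
substituted via `executable=`), the profile backend runs HMMER through
pyhmmer with profiles extracted by accession from a local HMM flat file,
and the remote backend is an adapter interface (submit / status / retrieve,
resumable by request identifier) with a canned offline implementation used
in tests. Hybrid searches simply mix protein and profile hits; when both
hit the same subject, both hits are kept.

## What the synthetic fixtures do and do not show

`fixtures.generate_genomes` plants exact copies of the query proteins at
specified positions with specified intergenic gaps, pads scaffolds with
uniform-random decoy proteins spaced > 20 kbp apart, and back-translates
everything into the scaffold sequence so coordinate-based translation round
trips. `generate_hit_table` emits the matching hit and IPG tables, with
identities drawn from a configurable range and optional spurious decoy hits
that are deliberately strong enough to *survive* the default hit filter —
noise robustness is exercised in the detector (where spurious singletons
fail the `unique`/`min_hits` thresholds), not masked upstream. All
generation is a pure function of (spec, seed).

These fixtures validate plumbing and detection arithmetic: grouping,
thresholds, scoring, serialization, coordinate handling. They do not test
homology inference itself — decoys carry no evolutionary structure, planted
genes are identical to their queries, and no fixture exhibits paralogy,
pseudogenes, split genes or mis-annotation. Passing tests therefore show
that the method computes what it defines, not that the defaults are right
for any particular clade.

## Verification study sizes

The acceptance script and test suite run, in a few seconds on one core:
1000 random scaffolds of ≤ 15 subjects against a brute-force collocation
oracle; all 5408 label arrangements of ≤ 6 subjects against a brute-force
adjacent-pair counter; 15 planted loci across 5 replicate fixture sets for
exact-boundary recovery; a 25-point gap sweep checked row-by-row against
direct detection. These sizes give exhaustive coverage of the small cases
and dense randomized coverage of the rest while keeping the whole study
instant to re-run.

## Known limitations

- Clusters never span scaffolds; a locus split across contigs appears as
  (at most) one cluster per contig. The gap sweep helps diagnose, not
  stitch.
- RefSeq/INSDC duplicate placements are kept as distinct scaffolds; the
  over-count is visible in the summary rather than resolved.
- The remote adapter is a contract plus an offline implementation; live
  submission/polling against a public API is intentionally out of scope.
- The HTML reports are static documents with embedded data; they favour
  portability over the richer interactivity of a D3-style viewer.
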