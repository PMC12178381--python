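# Methods

## Coordinate model

All region mathematics is performed on a single internal convention:
1-based, closed intervals, grouped per chromosome. An `IntervalSet` is the
canonical form of a set of genomic bases: within a chromosome its
intervals are sorted, non-overlapping and non-adjacent, and two intervals
that touch (`end + 1 == next.start`) are merged because they cover
contiguous bases. Consequently two `IntervalSet`s are equal iff they cover
the same bases, every operation (union, intersection, subtraction, length,
overlap and containment queries) has base-set semantics, and the whole
algebra can be checked exactly against brute-force arithmetic on sets of
integer positions — which the test suite does on thousands of random
instances.

Conversions happen only at I/O boundaries: BED records (0-based,
half-open) become `(start+1, end)` on read and the inverse on write; GTF
and GFF3 are used as-is; UCSC refSeq-table `exonStarts`/`cdsStart` columns
are 0-based and shifted on read. Chromosome names are normalized to a
configurable style (default: `chr`-prefixed), so a panel BED written as
`1` and an annotation written as `chr1` reconcile automatically.

Strand is deliberately not modeled: every metric here is per-base and
strand-agnostic. Exon ordinals number exons in genomic order within each
transcript, regardless of strand.

## Coverage metrics

The coverage denominator for a gene is its **exon union**: the set-union
of all exon intervals of all its transcripts. This includes non-coding
genes and non-coding transcripts, which matters in practice (well-covered
non-coding genes exist in real panels). The alternative reading —
protein-coding bases only — is available as `cds_only`, which uses the
union of per-transcript exon∩CDS intersections and excludes genes with no
coding transcript (their count is logged).

Coverage fractions are stored as exact integer ratios
(`fractions.Fraction`) and rendered at fixed precision only in reports, so
equality assertions in tests are exact rather than approximate.

A gene is a **target gene** when at least one exon-union base lies in the
target set. The mask plays no role in membership: a fully masked target
gene is reported as targeted-but-undetectable (effective coverage 0),
which is the honest description of such designs, rather than silently
dropping the gene or silently keeping it looking covered.

## Variant classification

Two overlap rules are implemented because curated mutations are spans,
not points:

- `contained` (default): a mutation is targeted only when its full
  reference span lies inside the target set. Rationale: an indel that is
  only partially captured cannot be reliably called.
- `any`: one overlapping base suffices.

Masking is always any-overlap: a single masked base suppresses a call
absolutely. `detectable = targeted AND NOT masked`.

ClinVar rows are retained when the clinical-significance string,
lowercased, contains `pathogenic` but neither `conflicting` nor `benign`,
on the requested assembly only, deduplicated on (VariationID, Assembly).
The rule admits "Pathogenic", "Likely pathogenic",
"Pathogenic/Likely pathogenic" and also "Pathogenic, low penetrance";
it conservatively drops compound labels that mention "Benign". The
predicate is an injectable parameter (`significance_filter`) for users who
want a different policy. CMC rows are retained for significance tiers
1–3; rows with zero tested samples or unparseable genome positions are
dropped and itemized in a skip report, and every reader satisfies
retained + dropped + skipped = input rows.

Variant-to-gene attribution in per-gene counters uses the database's own
gene symbol (symbol join). Variants whose symbol is absent from the
annotation are still classified — classification is purely
coordinate-driven — and flagged `symbol_unmatched`.

## Noncovered mutation rate

For CMC mutations, the positive-sample proportion f = mutated/tested
estimates the probability that a tested tumor sample carries the
mutation. Summing f over all mutations a panel misses gives the expected
number of missed tier 1–3 mutations per sequenced sample. The sum is
computed with `math.fsum`, so it is exactly rounded and independent of
summation order — this is what lets the engine match the generator's
independently computed rates bit-for-bit. Four settings are always
reported: {target genes only, all genes} × {with, without masking}. The
reciprocal rendering ("1 in N samples") uses `round(1/r)`.

## Archives and workspaces

A panel analysis is persisted as a zip container of versioned payloads
(JSON metadata plus TSV tables for gene stats, exon rows and classified
variants) and a manifest with per-payload SHA-256 checksums. Loading
verifies checksums and the format version and refuses partial loads.
Payload bytes are a pure function of the analysis content (fixed entry
order, fixed zip timestamps); only the manifest's `created` field carries
wall-clock time, and comparisons exclude it. Integer-only storage of
counts (fractions are recomputed properties) makes the round trip
lossless and exactly equality-comparable.

A workspace is simply a directory of archives. Analyses made against
different annotation/database snapshots may be compared — deliberately,
since auditing drift across database versions is a real use case — but
every such workspace emits a provenance warning.

Fold changes in gene-metric comparisons are computed on mask-adjusted
values; when one side is zero the row carries a sentinel category
(`only_in_<panel>`) instead of a number, and numeric fold filters apply
only to finite ratios.

In the advertised-list audit the three gene lists (advertised-not-
detected, detected-not-advertised, fully-masked targets) are kept
disjoint: a fully masked gene that was not advertised is reported once,
under detected-not-advertised.

## Synthetic study design

The generator fabricates the smallest study that exercises every code
path: 2 chromosomes × 100 kb, 30 genes with 1–10 exons and 1–3
transcripts each (subset transcripts get extended exons so the exon union
is strictly larger than any single transcript), one non-coding gene, one
pair of genes with interleaved coordinates; two panels — ALPHA (17 target
genes at coverage fractions 0.1–1.0, with a mask that fully masks one
advertised gene and partially masks two others) and BETA (12 target
genes, no mask file); 100 ClinVar rows of which 37 survive the
pathogenicity/assembly filter, and 200 CMC rows of which 120 are tier
1–3 with valid coordinates and sample counts. Variant planting includes
multi-base spans straddling target-region edges (where the containment
and any-overlap rules disagree), masked-position variants, and one
annotation-unknown gene symbol. These sizes keep full per-base oracle
computation under a few seconds while covering every edge case the
readers and the engine branch on; they are not calibrated to any real
panel.

The ground-truth manifest is computed inside the generator by per-base
arithmetic over plain Python sets of `(chrom, position)` pairs — it never
calls the interval algebra or the engine. Panel BED files are written
with realistic mess (shuffled records, duplicates, adjacent fragments,
comment/track lines, bare chromosome names in the variant tables,
trailing commas in UCSC exon lists) that must not change any result.

What passing the synthetic suite does **not** show: fidelity on real
database dumps (whose headers and significance vocabularies drift over
time), biologically realistic mutation spectra or hotspot clustering,
genome-scale performance, and correctness of any specific vendor panel's
published numbers — those require the vendors' BED/mask files and dated
database snapshots, which cannot be redistributed.

## Numerical and degenerate-input choices

- Fractions are exact integer ratios; floats appear only in reports,
  rates (fsum) and comparison tables.
- An empty mask is a valid panel state (all masked counters zero); an
  empty target set is rejected at panel construction.
- A panel sharing no chromosome with the annotation is an error unless
  forced, since it almost always indicates a naming-style mismatch that
  normalization could not fix.
- Genes with exons on several chromosomes are split into per-chromosome
  entries suffixed with the chromosome name (with a warning).
- Zero-variant inputs are legal everywhere and produce zero rates;
  ClinVar records reaching the rate computation (no sample frequency) are
  a hard error, not a silent zero.
- Fold-change with two zero values is categorized `both_zero` and never
  filtered as finite.

## Known limitations

- No fusion or copy-number target assessment; small-variant regions only.
- No sequencing-depth or wet-lab uniformity modeling — "covered" means
  designed-to-be-covered.
- Database files are read from local paths only; fetching current
  ClinVar/RefSeq/CMC dumps is left to the user (their download pages
  require registration or produce multi-GB files).
- Per-gene variant counters join by database gene symbol by default
  (`variant_gene_join="coordinate"` attributes by exon-union overlap
  instead); the symbol join assumes the database symbol is current.
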