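# panelaudit

Audit and compare the DNA target regions of multigene NGS panels.

Commercial sequencing panels ship their target regions as BED files, often
together with a *mask* file of positions where variant calls are filtered
out because of known high error rates. Neither file, on its own, tells a
molecular pathologist what actually matters: which genes the panel really
covers (as opposed to the genes the brochure advertises), how much of each
gene's exon sequence is captured, which known pathogenic and oncogenic
mutations can — and cannot — be reported, and how often a sequenced sample
is expected to harbor an oncogenic mutation the panel will miss.
`panelaudit` answers these questions by intersecting panel target and mask
regions with a gene annotation (GTF, GFF3, or a UCSC refSeq-style table), a
ClinVar `variant_summary`-dialect table of pathogenic/likely-pathogenic
variants, and a COSMIC Cancer Mutation Census (CMC) table of tier 1–3
oncogenic mutations.

## The quantities it computes

All computation is exact set arithmetic over genomic base positions,
internally in 1-based closed coordinates (BED's 0-based half-open records
are converted at the I/O boundary). For a panel with target regions *T*
and mask *M*, and a gene *g* with exon union *E(g)* (the union of the exon
intervals of all annotated transcripts):

- **target genes** — all *g* with |E(g) ∩ T| ≥ 1. The mask is ignored
  here, so a gene whose entire targeted region is masked is still reported
  as a target gene — just one that can never yield a reportable call.
- **coverage** = |E(g) ∩ T| / |E(g)|, and
  **effective coverage** = |E(g) ∩ T \ M| / |E(g)| — the fraction where
  variants are actually reportable. A `--cds-only` switch replaces E(g)
  with the coding (CDS) union.
- **variant classification** — a database mutation with reference span
  *s* is *targeted* when s ⊆ T (default; `--variant-overlap any` relaxes
  this to s ∩ T ≠ ∅), *masked* when s ∩ M ≠ ∅, and *detectable* when
  targeted and not masked.
- **noncovered mutation rate** — Σ f(v) over CMC tier 1–3 mutations *v*
  the panel misses, where f(v) is the positive-sample proportion
  (mutated / tested samples). This is the expected number of missed
  oncogenic mutations per sequenced sample; its reciprocal is rendered as
  "1 in N samples". Computed for target genes only vs. all genes, with
  and without masking.

Analyses are persisted as checksummed zip archives; a directory of
archives is a *workspace* over which panels can be compared gene-by-gene
and exon-by-exon, searched for genes of interest, and audited against an
advertised gene list.

## Worked example

The package ships a deterministic generator that fabricates a complete
miniature study — a two-chromosome annotation with 30 genes, two panels
(ALPHA, with a mask; BETA, without), and ClinVar/CMC tables — together
with a ground-truth manifest:

```sh
panelaudit fixtures --seed 1 --out fixtures
panelaudit analyze fixtures/ALPHA.target.bed --name ALPHA \
    --annotation fixtures/genome.gtf --clinvar fixtures/clinvar.tsv \
    --cmc fixtures/cmc.tsv --mask fixtures/ALPHA.mask.bed --out ws
panelaudit analyze fixtures/BETA.target.bed --name BETA \
    --annotation fixtures/genome.gtf --clinvar fixtures/clinvar.tsv \
    --cmc fixtures/cmc.tsv --out ws
panelaudit audit ws/ALPHA.pau.zip fixtures/advertised.ALPHA.txt --out ws
```

The audit prints:

```
panel ALPHA: 5 advertised symbols
  advertised but not detected: GENE09, GENE11
  detected but not advertised: GENE01, GENE02, GENE04, GENE06, GENE08, ...
  targeted but fully masked: GENE05
  not found in annotation: (none)
```

Two of the five advertised genes are not touched by the panel design at
all, fourteen targeted genes are absent from the advertised list, and
GENE05 — fully covered on paper — has every targeted base masked, so it
will never produce a variant call. `panelaudit rates ws` then reports the
per-sample missed-mutation burden:

```
panel ALPHA:
  target_genes_masked      0.588225	1 in 2
  target_genes_unmasked    0.555619	1 in 2
  ...
panel BETA:
  target_genes_masked      0.275597	1 in 4
```

i.e. under this synthetic mutation spectrum, one ALPHA-sequenced sample in
two carries a tier 1–3 mutation in a target gene that the panel cannot
report (BETA: one in four). `panelaudit compare ws --panels ALPHA BETA
--metric exon_base --min-fold 1.5` writes the per-gene comparison table
and a scatter/column figure with masked portions shaded; `panelaudit
search ws --genes GENE02,GENE05,GENE30` prints an all-genes-targeted
verdict per panel.

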