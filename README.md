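# spliceret

Intron-retention quantification from split-read RNA-seq alignments, with
maternal / early-zygotic gene stratification.

Given a gene annotation (GTF), a genome (FASTA), aligned paired-end reads
(SAM/BAM with `N`-gapped split alignments) and a per-gene stage-expression
table, the pipeline:

1. **annotation** — extracts unique exon–intron boundaries, removes
   boundaries whose intron overlaps any annotated exon ("safe" filter),
   and applies a minimum intron/flank length filter for coverage analyses.
   Also computes a 1000-segment exon-presence gene-structure profile and
   splice-site base-count matrices (with per-position information content).
2. **expression** — classifies genes as `early_zygotic` (2–4 hr expression
   > 10 units and ≥ 5× the 0–2 hr value), `maternal` (not zygotic, 0–2 hr
   > 50 units), `excluded_high` (> 1000 units at either stage) or
   `unclassified`.
3. **retention** — classifies each fragment at each 5′ splice site as
   spliced / unspliced / mis-spliced (≥ 10 nt overlap on each side of the
   junction; ≥ 10 informative fragments per boundary) and reports
   per-boundary retention % = unspliced / (unspliced + spliced),
   stratified by gene class and intron-size bin (<100, 100–500, >500 nt).
4. **coverage** — normalized per-base read-coverage profiles in a 100 bp
   window centred on each 5′ splice site (≥ 50 window reads).
5. **amplicon** — in-silico RT-PCR product sizes for exon–exon vs
   intron–exon primer pairs on spliced vs intron-retained templates.
6. **simulate** — seeded synthetic worlds (genome, GTF, expression table,
   SAM alignments) with known per-boundary retention truth, used by the
   test suite and the acceptance script.

## CLI

```sh
spliceret simulate --out world --seed 1           # synthetic world + truth
spliceret boundaries --gtf world/annotation.gtf --out boundaries.tsv
spliceret classify-genes --expression world/expression.tsv --out classes.tsv
spliceret retention --gtf world/annotation.gtf --sam world/alignments.sam \
    --classes classes.tsv --out retention.tsv
spliceret coverage --gtf world/annotation.gtf --sam world/alignments.sam \
    --out coverage.tsv --summary coverage_summary.tsv
spliceret structure --gtf world/annotation.gtf --out structure.tsv
spliceret motif --gtf world/annotation.gtf --genome world/genome.fa \
    --out-donor donor.tsv --out-acceptor acceptor.tsv
spliceret amplicon --config amplicon.json --out amplicon.tsv
spliceret report --gtf world/annotation.gtf --sam world/alignments.sam \
    --genome world/genome.fa --expression world/expression.tsv --out report/
```

`report` runs every stage and writes all tables plus `manifest.json`
(parameters + input SHA-256 checksums). Intermediate artifacts are plain
headered TSVs; chained subcommands produce byte-identical tables to a
single `report` run.

## Conventions

Coordinates are 0-based half-open internally; GTF is read as 1-based
inclusive. A boundary's `donor_pos` is the first intronic base in
transcript sense and `acceptor_pos` the first exonic base after the
intron. Threshold inclusivity: length filters keep ≥ 50 nt; intron-size
bin edges 100 and 500 belong to the middle bin; expression thresholds are
strict (`>`), the 5× fold rule inclusive (`≥`).
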