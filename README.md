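# pseudoscan

Reference-based pseudogene detection and analysis for bacterial and
archaeal genomes.

Prokaryotic genomes are usually dense with intact genes, but after
ecological shifts or population bottlenecks — intracellular symbionts and
pathogens are the classic cases — broken gene remnants accumulate
quickly. Finding these pseudogenes matters for estimating a genome's
functional potential and for avoiding artifacts in phylogenomics, yet
general-purpose annotation pipelines are not designed for it. pseudoscan
condemns genes on explicit, tunable evidence:

* **Truncated / run-on ORFs** — a gene's protein length is compared with
  the mean length of its top database homologs; it is flagged when the
  ratio drops strictly below `length_ratio_min` (default 0.75) or rises
  strictly above `length_ratio_max` (default 1.25). Genes recruiting
  fewer than `min_hits_for_eval` homologs are left unevaluated rather
  than guessed at.
* **Fragmented genes** — adjacent ORFs that recruit the same database
  homologs (min-normalized subject-set overlap ≥ 0.5) are chained as
  fragments of one ancestral gene.
* **Intergenic remnants** — regions between annotated genes are searched
  against the protein database in all six reading frames, recovering
  degraded pseudogenes that gene callers no longer see.
* **Mutation-level evidence** (with a close reference genome) — each
  reference CDS is located on the query genome, realigned, and typed for
  inactivating lesions: frameshifting indels and the fraction of the
  protein they knock out of frame, nonsense substitutions (including
  stops that only exist in the shifted reading frame), and loss of start
  or stop codons.
* **Relaxed selection** — pairwise dN/dS by Nei–Gojobori (1986) counting:
  per-codon synonymous site fractions S and N with pathway-averaged
  difference counts Sd and Nd, Jukes–Cantor corrected,
  ω = dN/dS = JC(Nd/N) / JC(Sd/S). Interpretation is gated to
  0.01 < dS < 3 (defaults); outside that window ω never flags a gene.

A decay simulator (`break`) mutates a chosen fraction of genes
(`round(0.05 × level × n_genes)` at decay level 1–10) with one of five
inactivating mutations each and emits an invertible ground-truth report,
so the whole detector can be benchmarked end to end. A synthetic-fixture
generator builds protein families, genomes, diverged references with
controlled dS and ω, and planted intergenic remnants — no downloads
needed anywhere in the test suite.

## Worked example

```bash
pseudoscan fixtures --seed 4 --outdir fx
# fixture with 180 proteins / 200 genes -> fx

pseudoscan break --genome fx/genome.fna --gff fx/genome.gff \
    --level 3 --seed 11 --outdir broken
# 30 genes mutated at decay level 3 -> broken

pseudoscan annotate --genome broken/broken.fna --gff broken/broken.gff \
    --db fx/protein_db.faa --reference fx/reference_cds.fna --outdir ann
# 30 pseudogene calls, 170 intact, 0 unevaluated -> ann
```

Decay level 3 mutates `0.05 × 3 × 200 = 30` genes; the run recovers all
30 as pseudogene calls and leaves the other 170 intact. The calls land in
`ann/pseudogenes.gff` with the condemning evidence in the attributes:

```
##gff-version 3
contig_1  pseudoscan  pseudogene  5970   6482   .  -  .  ID=pseudo_00001;members=gene_0011;reasons=start_lost
contig_1  pseudoscan  pseudogene  13754  13996  .  +  .  ID=pseudo_00002;members=gene_0024;reasons=short
contig_1  pseudoscan  pseudogene  14145  14563  .  +  .  ID=pseudo_00003;members=gene_0025;reasons=frameshift,nonsense
```

`gene_0011` lost its start codon (the break report records
`start:ATG>CTG`), `gene_0024` lost an internal block and now sits below
75% of its homologs' mean length, and `gene_0025` carries a
frameshifting indel plus the premature stop it induced. A per-call
evidence table (`evidence.tsv`), pseudogene and intact-protein FASTA
files, a full parameter record (`parameters.json`) and a search cache
accompany the GFF. `pseudoscan reannotate --cache ann/cache ...`
re-derives calls under new thresholds without repeating any searches,
and `pseudoscan visualize` sweeps the length and similarity cutoffs over
the cache and renders the call-count surface.

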