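# Methods

## Model and procedure

pseudoscan treats pseudogene detection as an evidence-accumulation
problem against two references: a protein database standing in for the
clade's functional gene repertoire, and (optionally) the CDS set of a
single closely related genome. Every coding region in the annotated
query genome is scored independently against both, and any piece of
evidence — a length anomaly, a fragment chain, an intergenic remnant, an
inactivating lesion, or relaxed selection — suffices to create a call.
Calls overlapping by at least one nucleotide on the same strand are
consolidated, with reasons unioned.

All internal coordinates are 0-based half-open on the forward strand;
GenBank and GFF3 locations (1-based inclusive) are converted only at the
I/O boundary. Compound (`join`) GenBank locations are collapsed to their
enclosing span and flagged: the calling logic operates on genomic spans,
not exon structure. Locus tags must be unique per feature kind (GenBank
legitimately repeats a tag across a gene/CDS pair). Ambiguity characters
other than N are rejected at parse time so translation is deterministic.

### Length classification

For each gene, the query protein length is divided by the mean subject
length of its top database hits (default: best 15 by bitscore, E ≤ 1e-4).
A gene is *truncated* when the ratio is strictly below
`length_ratio_min` and *run-on* when strictly above `length_ratio_max`.
Strictness matters at the boundary: a gene at exactly 75% of the homolog
mean is not flagged. An optional stricter rule additionally requires the
length to fall more than `sd_k` population standard deviations below the
homolog mean. Genes with fewer than `min_hits_for_eval = 3` passing hits
are reported *unevaluated* rather than classified — absence of homologs
is not evidence of pseudogenization.

### Fragment chaining

Genes are ordered by coordinate; consecutive hit-bearing genes on the
same contig (strand-agnostic, since frameshifted fragments can flip
annotated strands) are linked when the overlap of their top-hit
subject-id sets, normalized by the smaller set, reaches
`shared_hit_fraction = 0.5`. Min-normalization tolerates fragments that
recruit fewer hits than their intact siblings. Links are closed
transitively; each chain of two or more genes becomes one call spanning
first start to last end. The chains provably equal the connected
components of the pairwise link graph (tested against a union–find
oracle).

### Intergenic recovery

The complement of the union of all gene/CDS spans is translated in six
frames and searched against the database (E ≤ 1e-5, regions shorter than
90 nt skipped). A region with any passing hit becomes an
*intergenic_remnant* call clipped to the union of HSP spans, with strand
from the majority frame sign. Remnant calls merge with gene calls only
by overlap; adjacency-based merging with a neighboring truncated gene is
a possible extension deliberately not implemented.

### Reference-guided analysis

Each reference CDS is located on the query genome by seeded six-frame
protein alignment. Candidate loci are clusters of same-contig,
same-strand HSPs within 100 nt of each other — chaining matters because a
mid-gene frameshift splits one gene's homology across two reading
frames. The winning locus is the candidate with the best
*nucleotide-level* alignment score of the reference CDS against the
candidate region (free end gaps): at the close evolutionary distances
where this analysis is meaningful, the orthologous locus is
near-identical in nucleotide space while paralogs that look alike in
protein space are not, so nucleotide rescoring resolves gene families
correctly. Ties break to the leftmost genomic start. The locus is
extended by 60 nt flanks and realigned globally (match 2, mismatch −3,
gap open 5, extend 2, region end gaps free).

Mutation typing reads the nucleotide alignment:

* **Indels** are maximal internal gap runs; frameshifting iff length mod
  3 ≠ 0. Terminal overhangs are never indels.
* **Stops** follow the ribosome: the query is read in contiguous
  triplets from the position aligned to the reference start, so the
  frame downstream of an indel is the shifted one. The first stop
  triplet is classified by position — `nonsense` inside the gene,
  nothing when it is the reference's own terminal stop read in frame —
  and reaching or passing the terminal stop without terminating is
  `stop_lost`. This is what catches late frameshifts whose only
  consequence is reading through the (now out-of-frame) original stop.
* **Start loss**: the query triplet at the reference start is outside
  the bacterial start set {ATG, GTG, TTG}.

**Frameshift impact** is the fraction of reference codons whose query
frame — the cumulative indel offset at the codon's first base — is not a
multiple of 3. In-frame indels contribute nothing; a +1 insertion after
codon 90 of a 100-codon gene scores 0.10; compensating +1/−1 indels
impact exactly the codons between them. The `frameshift` verdict fires
above `frameshift_impact_max = 0.10`. The definition is a declared
reconstruction validated against a direct re-translation oracle.

**dN/dS** uses Nei–Gojobori (1986) counting over the comparable codon
pairs of the alignment: gapless, N-free, sense in both rows, and
in-frame (cumulative offset ≡ 0 mod 3) — out-of-frame codons would
inflate dN spuriously. Sites: each codon position contributes the
fraction of its three single-nucleotide changes that are synonymous
(changes to stops count as nonsynonymous), so S + N = 3 per codon and
site totals are averaged over the two sequences. Differences: Sd and Nd
are averaged over every ordering of the differing positions (Sd + Nd
equals the number of differing positions for every pair). Proportions
pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (saturation). ω = dN/dS is
defined only when dS > 0. The `high_dnds` verdict requires ω >
`dnds_max = 0.30` *and* dS inside the gate (0.01, 3); a gated result can
never flag, whatever ω is. A pal2nal-style codon threading operation
(protein alignment → codon alignment) is provided for frameshift-free
pairs and external use; inside the per-gene chain the codon pairs are
read directly off the nucleotide alignment, which is equivalent for
clean pairs and well-defined for frameshifted ones.

### Decay simulation

`break` selects `round(0.05 × level × n_genes)` genes (minimum 1)
uniformly without replacement at decay level 1–10 and applies exactly
one mutation per gene, drawn uniformly from: nonsense substitution (a
sense codon in the middle 80% becomes a random stop), 1–2 nt insertion,
1–2 nt deletion, start-codon loss (first base mutated so the codon
leaves {ATG, GTG, TTG}), or truncation (an internal block of 30–60% of
the gene, a multiple of 3 so the truncation signal is isolated from
frameshift signals; genes under 12 codons fall back to nonsense,
recorded). The mutation-count rule and the five kinds are this package's
own parameterization, config-overridable, and made fully explicit by the
report format. One mutation per gene keeps truth attribution
unambiguous. Downstream coordinates shift consistently, untouched genes
stay byte-identical, and the report detail field suffices to invert
every mutation — reversibility is tested by restoring the original
genome exactly.

### Search engine

The engine contract is a callable from (query proteins, database) to raw
hits; anything satisfying it can drive the pipeline, and a thin adapter
runs external tabular-output search tools. The built-in engine pairs an
exact shared-5-mer prescreen (≥ 3 shared 5-mers, or ≥ 1 for very short
queries) with full Smith–Waterman alignment (BLOSUM62, gap open 11,
extend 1 — a gap of length k costs 11 + k). The prescreen only selects
candidate pairs; every reported alignment is an exact dynamic program,
so results are deterministic and reproducible. Bit scores use the
published gapped BLOSUM62 Karlin–Altschul constants (λ = 0.267,
K = 0.041); E = m·n·2^(−bits) with n the total database length. Equal
bitscores order by ascending subject id. Heuristic indexing for
large-database throughput is a non-goal.

### Caching and sweeps

`annotate` writes all search results (gene hits, intergenic hits,
per-reference-gene metrics) plus the genome checksum to a cache;
`reannotate` re-derives calls from the cache through the *same* assembly
code path, so unchanged thresholds reproduce the original result
byte-for-byte, and a cache from a different genome is refused as stale.
Because searches are never repeated, only thresholds at or tighter than
the cached search cutoffs are meaningful. The sweep evaluates the
consolidated call count over a grid of `length_ratio_min` × hit
percent-identity floor (the similarity axis can be switched to E-value
exponent in config) and renders a static 3D surface and per-contig call
map; interactive output is deliberately out of scope.

## Synthetic data: what it does and does not emulate

The fixture generator builds protein families (a seed protein plus two
homologs with an exact substitution count placing identity in
[0.82, 0.94], lengths preserved), genomes whose genes are random
synonymous back-translations of family seeds (ATG-started,
TAA-terminated, random strands, seeded random intergenic spacers), and
divergence with controlled dS and ω (per-position substitution
probabilities obtained by inverting the Jukes–Cantor correction;
synonymous and nonsynonymous neighbor sets resampled per codon; stops
never introduced). The standard benchmarking fixture has 200 genes from
60 families on one contig (~110 kb) and builds in well under a second.

Two deliberate design choices: homologs preserve length so intact genes
sit at a length ratio of exactly 1 (making the truncation signal clean),
and same-family gene copies are never placed adjacently — adjacency plus
shared homologs *is* the fragment signal, which must not occur in an
undecayed genome.

What this synthetic world lacks, and what passing tests therefore do not
demonstrate about real data: genes here have genuine full-length
database homologs of identical length, whereas real homolog length
distributions are broad and real databases contain domain-sharing
non-orthologs; intergenic DNA is uniform random, free of repeats,
IS elements and compositional bias; divergence has no indels and no
rate heterogeneity; and the reference genome is at a controlled,
uniform distance. Recovery rates on the fixture are upper bounds on
real-genome performance, which is why every threshold is exposed and a
sweep tool ships with the package.

## Numerical choices and degenerate inputs

Alignments take the first optimal traceback of a deterministic aligner;
repeated runs are byte-identical. Population (not sample) standard
deviation is used for homolog lengths. Empty hit sets propagate as
explicit no-evidence markers (`n_used = 0`), never as zeros. Codon pairs
containing gaps, N, or stops are excluded from dN/dS counting; zero
comparable pairs marks the result undefined (gated) rather than raising
out of the per-gene chain. Partial CDS (length not a multiple of 3) are
translated in frame 0 and marked; internal stops translate to `*` and
mark the feature instead of raising. Fragment chains use each gene's
top-15 deduplicated subject ids. Consolidation merges by ≥ 1 nt
same-strand overlap; a fragment chain's strand is the majority strand of
its members (ties +).

## Known limitations

Single best locus per reference CDS: paralog fan-out is not modeled.
dN/dS is pairwise NG86 only — no maximum-likelihood codon models, no
transition/transversion or codon-frequency corrections, and ω should be
read comparatively within a genome, not as an absolute rate. Sleuth
verdicts alone can condemn a gene (any single flag creates a call);
users wanting annotate-plus-sleuth consensus must tighten thresholds.
De novo ORF calling, pangenome-aware detection, and IS-element
special-casing are out of scope.
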