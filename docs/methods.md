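# Methods

`txforge` re-implements, as a tested library, the computational core of a
reference-annotation improvement and stage-comparison analysis for a
two-condition insect ovarian RNA-seq design: previtellogenic ovaries (PVS)
versus mature unfertilized eggs (Egg), two biological replicates each.
Because the egg is transcriptionally quiescent, transcripts detected there
are maternally deposited; "up-regulated" throughout means higher in Egg.

## Transfrag classification and annotation improvement

Assembled transcript fragments (transfrags) are compared to the reference
annotation by their intron chains — the ordered list of splice-junction
coordinate pairs. Codes follow the cuffcompare convention restricted to the
three classes the analysis consumes:

- `=` : identical intron chain to a reference transcript on the same strand
  (single-exon transfrags match single-exon reference transcripts they
  overlap). Terminal-exon growth does not break the match; it is how UTR
  extensions are detected.
- `j` : multi-exon, same strand, shares at least one junction with a
  reference transcript but not the whole chain — a candidate novel isoform.
- `u` : no exonic overlap with any reference transcript on either strand —
  a candidate novel (intergenic) gene.
- `other` : every remaining overlap pattern; excluded downstream.

Junction equality is exact coordinate equality; no fuzz window (synthetic
transfrags are exact; splice-site wobble handling is out of scope).

Novel isoforms must pass three filters: >= 20 supporting read pairs,
abundance >= 40% of the gene's major isoform (evaluated in the candidate's
condition of maximal abundance; ties for the major isoform break by
transcript id), and CPM > 1 in at least one condition. Supported `u`
transfrags are clustered by transitive same-strand exonic overlap into
`XLOC_`-style loci, one novel gene per locus. Single-exon `u` transfrags
are eligible (the multi-exon requirement applies to novel isoforms only).

Gene-boundary extensions are measured strand-aware on the genomic termini
of the per-gene span (union over isoforms): the 5' extension of a minus-
strand gene is growth of its right genomic terminus. The per-isoform
spliced-distance variant is not implemented.

## ORF completeness and CDS improvement

ORFs of at least 100 codons (stop excluded) are reported per frame as
maximal calls: *complete* (ATG..stop), *5'-partial* (sequence start to a
stop with no in-frame ATG before it), *3'-partial* (ATG with no downstream
stop), *internal* (frame open across the whole sequence). Oriented
transcripts are scanned forward-only; orientation-unknown contigs
six-frame. ATG is the only start codon; the standard genetic code is used;
length is the sole coding criterion (no homology evidence). A contig's
completeness label is the most complete type found, with the 5'- over
3'-partial tie broken toward 5'-partial — a declared convention, not a
biological claim.

For the CDS-improvement report the *best* ORF of a gene's transcripts is
the longest (ties to the more complete, then leftmost): the dominant
reading frame of a transcript is its longest open stretch, and a
completeness-first rule would let short spurious out-of-frame ORFs mask a
long truncated CDS. Categories: `gained_start` (reference best ORF lacked
an in-frame ATG, improved has one), `gained_stop` (likewise for the stop),
`new_complete` (reference had no reportable ORF, improved best is
complete), `unchanged`. A gene can gain both a start and a stop.

## De novo rescue

Unmapped reads are trimmed of terminal poly-A (3') and poly-T (both ends)
runs longer than 4 nt, then kept if longer than 25 nt with GC above 20%
(both strict). Contigs pass a fixed cascade: per-stage TPM >= 10 →
within-stage deduplication → quality-gate hook (pass-through unless an
external score table is supplied) → coding classification → cross-stage
deduplication → estimated reads >= 20. Deduplication is greedy
longest-first clustering at 95% nucleotide identity, identity defined as
matching positions over the shorter sequence length (computed as an infix
edit-distance alignment, both orientations); the representative is the
longest member and cluster abundance is the member sum. Repeat novelty is
a seeded (11-mer) ungapped local alignment against the consensus library:
*known* needs identity >= 0.8 and contig coverage >= 0.5, a hit below
either threshold is *novel*, no >= 30-nt matching segment is *no_hit*.
Thresholds are configurable; the gapped mode is intentionally absent
(synthetic truths require no gaps).

## Repeat-class quantification

Repeat copies of the same contig, class and strand that strictly overlap
are merged transitively (adjacency does not merge; distinct classes never
merge), and merged regions longer than 0.5 kb are quantified. Each genomic
placement of a read pair contributes weight 1/n_hits to every feature it
overlaps (>= 1 shared base, unstranded). Ambiguity is a pair-level
decision: if the placements of a pair collectively touch more than one
element class (gene vs any repeat class), the whole pair is ambiguous.
Weight is conserved exactly per sample: assigned + ambiguous + unassigned
equals the pair count, and this identity is asserted on every simulated
landscape.

## Counting, normalization and differential expression

Gene-level counting follows paired-fragment rules: pairs must have both
ends aligned on one contig and strand; `unique_only` (default) keeps
single-placement pairs; a pair overlapping several genes is assigned to
the gene with the largest overlapped base count, exact ties counted once
per tied gene (a strict-largest mode exists). CPM uses the per-sample
assigned totals as denominator (configurable); TPM divides by feature
length before scaling. Genes need CPM > 1 in at least 2 of the 4 samples
to be tested.

Between-sample scaling is TMM: reference = sample whose upper quartile of
CPM is closest to the mean; per-gene log2 ratios (M) trimmed 30%, mean
log2 abundances (A) trimmed 5%, both by average rank with inclusive
bounds; precision weights are the inverse binomial variance approximation;
factors rescaled to geometric mean one. The implementation reproduces
edgeR's `calcNormFactors(method="TMM")` to ~1e-9 (cross-checked in the
test suite via Rscript).

The DE engine is a self-contained negative-binomial Wald test with
variance mu + alpha mu^2. Per-gene dispersion is estimated by method of
moments on size-normalized counts (the shot-noise term uses the per-group
mean of 1/size); the default then pools these into one **common**
dispersion (their mean, floored at 1e-8) shared by all genes. With two
replicates per group a per-gene moment estimate is so noisy that the Wald
test's empirical type-I error is ~0.20 at alpha 0.05; pooling restores
calibration (~0.05, verified on 2,000 simulated null genes) while keeping
power ~1 at the planted log2FC = 3 / mean 500 / alpha 0.05 condition.
`dispersion="per_gene"` exposes the unpooled estimator. Coefficients come
from IRLS on the log link with offsets log(library size x TMM factor,
geometric-mean-one); p-values are two-sided normal on beta/se, adjusted by
Benjamini-Hochberg. A gene is called at padj <= 0.01 with linear fold
change (Egg/PVS) >= 2.5 or <= 1/2.5 — "fold-change 2.5" is read as linear
(the conventional unqualified meaning); a log2 reading is available via
`fc_scale="log2"`. Top-k tables rank DEGs of one direction by mean CPM in
that direction's condition after removing a caller-supplied exclusion set
(e.g. ribosomal-protein genes). Enrichment is a hypergeometric upper-tail
test over a caller-supplied term map against a background gene universe,
BH-controlled at FDR 0.05, with enrichment ratio
(overlap/|selected|)/(term size/|background|).

## The synthetic experiment

The generator defines the study conditions every test recovers against.
Defaults: 4 contigs x 400 kb at GC 0.5; 200 genes, each a 2-5-exon
transcript with a 200-400 nt 5'UTR, a 150-300-codon CDS and a 300-600 nt
3'UTR, placed non-overlapping with intergenic gaps; 40% of eligible genes
get a skipped-exon second isoform. Planted CDS codons avoid ATG and stop
trinucleotides, and a final scrub rewrites any residual ATG (G→C — no stop
codon contains C, so the edit can neither create a stop nor a new ATG), so
the planted ORF is the unique ATG-initiated ORF and truncation damage maps
one-to-one onto ORF completeness. The degraded "reference" drops 10% of
genes and 30% of secondary isoforms, and truncates terminal exons with
probability 0.3 per end; 40% of truncations cut 10-90 bp into the CDS
(removing the start or stop codon), the rest stay inside the UTR.
Truncations are confined to terminal exons so spliced and genomic
truncation distances coincide and extension recovery is exact.

Counts are NB(mean, alpha = 0.05) with per-gene lognormal means (median
500); 10% of genes carry a planted |log2FC| = 2 effect, sign random, "up"
meaning higher in Egg. Transfrags reproduce exact truth exon structures
with support = 0.5 x total counts (the capture rate) and per-condition
abundances; 5% sub-threshold single-exon noise transfrags are planted
intergenically. The repeat landscape plants five classes (Tc1-mariner the
most abundant, as in the real mobilome; Helitron, R1, Satellite, Unknown)
with within-class overlapping copy pairs to exercise merging, and
unique/multi-mapped read pairs per copy. The unmapped pool holds reads
from dropped-gene transcripts plus poly-A/T-tailed and low-GC junk, with
id prefixes that partition the pool exactly. Every stage derives its own
child seed from the config seed (CRC32 of the stage name), so outputs are
byte-identical across runs and independent of call order.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: sequencing error, positional coverage bias,
fragment-length distributions, assembler fragmentation or chimeras,
splice-site wobble, overlapping genes, and a realistic intergenic
fraction. The last point matters for the ambiguity statistic: the toy
genome is ~50% genic, so uniformly placed repeat copies often overlap
genes and ~30-40% of repeat pairs are ambiguous, whereas a sparse real
genome shows single-digit percentages. The headline counts of the original
study (thousands of novel genes and extended UTRs) require the original
libraries and assembly and are not reproduced at this scale; what is
reproduced is the machinery, exercised against a planted truth it must
recover exactly.

## Numerical choices and problem sizes

Degenerate inputs: empty annotations, all-zero genes and empty count
tables return empty results rather than erroring; a sample with zero
library size or a group with fewer than two replicates errors. IRLS runs
at most 50 iterations to 1e-10 with mean clipping at exp(±30); the BH
step matches `statsmodels.multipletests(method="fdr_bh")` to 1e-12
(asserted). Ties: major-isoform and cluster-representative ties break
lexicographically; largest-overlap ties count for all tied genes.

The default validation sizes — 200-gene recovery runs, 2,000 null and 500
planted-effect genes for calibration, 500-gene TMM matrices, 200-contig
clustering — were chosen so the full suite and the acceptance script each
complete in well under a minute on one CPU while keeping every binomial
check's sampling error far from its acceptance band.
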