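# Methods

This note documents the models, defaults and numerical choices behind
`apafrac`, and what the synthetic test bed does and does not establish.

## Coordinates and gene models

All coordinates are 0-based half-open on the forward genome strand
(BED-native); GTF/GFF3 input is converted on read. This removes off-by-one
ambiguity between the supported formats. Genes with multiple transcripts are
collapsed to a union-of-exons model because every statistic here is
per-gene, not per-transcript; the 3'-most exon is the strand-aware most
distal exon of the union, and the CDS end used for the 3'UTR boundary is the
most distal CDS boundary over all transcripts. A position inside the 3'-most
exon but upstream of the CDS end is classified as exonic-upstream, so the
four region classes (UTR3, UPSTREAM_EXON, INTRON, INTERGENIC) partition
every position. For noncoding or partially annotated genes (no CDS) the
whole 3'-most exon counts as 3'UTR, matching common 3'-end-seq practice.
Sites are assigned only to same-strand genes; when same-strand genes
overlap, the lexicographically smallest gene id wins, which keeps output
deterministic (the event is logged).

## CPA-site calling and PAS annotation

3'-end read positions are clustered per (chromosome, strand) by single
linkage: consecutive positions at most `window` apart merge. The default
window is 24 nt, the established convention for 3'READS-type data; it is
exposed as `--cluster-window`. On a sorted axis single linkage reduces to
cutting at gaps larger than the window, and because every cluster
representative lies inside its cluster's span, representatives of distinct
clusters are always more than one window apart — re-clustering the output is
a no-op (tested). The representative position is the count-weighted mode,
with ties broken toward the most distal position in transcription direction.

The PAS scan covers offsets −40..−1 upstream of the cleavage position on the
sense strand (hexamer start offsets −40..−6 so the hexamer lies wholly
inside; the inclusion of position 0 is a configurable boundary). Precedence
is AATAAA > ATTAAA > ten single-nucleotide AATAAA variants (AGTAAA, ACTAAA,
TATAAA, CATAAA, GATAAA, AATATA, AATACA, AATAGA, AATGAA, AATAAG, reported as
one "variant" class); among equal-precedence matches the one closest to the
cleavage site wins. The vocabulary is a configurable argument. Internal
priming filtering is not performed — 3'READS-type chemistry largely avoids
it — but `cluster_ends` accepts a pre-filtered position table, which is the
supported hook.

PAS frequency tables come in two modes: site frequency (every site weight 1)
and read-weighted (each site weighted by its read count in a chosen
reference sample). On data where highly expressed sites preferentially carry
AATAAA, the read-weighted canonical share is necessarily at least the
site-frequency share; the simulator plants exactly this structure and the
property is asserted end to end.

## Differential representation (UTR-APA, CR-APA)

For UTR-APA each gene is reduced to its two most abundant 3'UTR sites
(ranked by counts summed over the two compared samples; ties prefer the more
proximal site, for determinism). The change measure is the difference in
proximal-isoform fraction computed on these two isoforms only,
Δ = p̂_B − p̂_A, in fraction units. The primary decision rule is a two-sided
Fisher exact test at P ≤ 0.01 combined with |Δ| > 0.05 (five percentage
points); Benjamini–Hochberg q-values over all tested genes are emitted
alongside so either rule can be applied downstream. Genes with zero counts
in either sample are reported UNCHANGED with a `low_coverage` flag rather
than dropped silently. CR-APA pools all intronic/upstream-exonic site reads
against all 3'UTR reads of the same gene and applies identical machinery;
SHORTER_IN_B then means the truncated (upstream) isoform is overrepresented
in sample B.

The Fisher p is computed by direct hypergeometric enumeration: with margins
fixed, p sums the probabilities of all tables at most as probable as the one
observed, with a 1e-12 *relative* tie tolerance so that mathematically equal
probabilities computed with different round-off still count as ties; if
every table in the support qualifies, p is exactly 1. A zero row or column
margin yields p = 1 by convention. For tables with total ≤ 30 distinct
hypergeometric probabilities differ by at least 1/C(30,15) ≈ 6.5e-9, far
above the tolerance, so the tolerance can only capture true ties there; the
implementation is verified exhaustively against rational-arithmetic
enumeration and cross-checked against an independent library implementation.

## Depth-controlled robustness test

The published description of the depth-controlled significance analysis
this mirrors does not include its internals, so the procedure here is an
explicitly labelled surrogate with every knob exposed. Each of
`n_subsample` (default 20) replicates subsamples every library without
replacement (multivariate hypergeometric over its gene×site count vector) to
the shallowest library's depth, equalising sequencing depth. The per-gene
statistic is the difference of B/A log2-ratios between proximal and distal
counts pooled within fraction, with a 0.5 pseudocount; its mean and SD over
the replicates are reported. Significance per replicate comes from permuting
fraction labels over the gene's individual depth-matched reads with margins
fixed — the exact law of that permutation null is the hypergeometric
distribution of the pooled 2×2 table, so the per-replicate p is the
two-sided Fisher p. (A coarser alternative, pooling label permutations
across genes, has p-value resolution ~1/n_genes with one library per
fraction and therefore cannot reject after BH correction at all; the
read-level permutation has full resolution and identical logic.) Replicate
p-values are combined by their median and BH-controlled at FDR 10% by
default; the call direction is the sign of the mean statistic. Libraries
shallower than 100 reads abort with an explicit error.

## Coverage-based APA (PDUI)

Per-base depth across an annotated 3'UTR, oriented 5'→3' of the mRNA and
scaled to reads per million, is modelled jointly across samples as
`d(i) ≈ w_long + w_short·1[i < b]` with one shared breakpoint *b* and
per-sample non-negative weights. For a fixed breakpoint the least-squares
weights are closed-form segment means (w_long = suffix mean,
w_short = prefix − suffix mean; if that is negative the constraint binds and
the flat single-isoform model is used for that sample). The breakpoint
minimises total SSE over a candidate grid from 50 nt after the UTR start to
50 nt before its end, step 1 nt (configurable for speed); ties take the most
proximal candidate. Cumulative-sum algebra makes the scan O(L) per sample.
PDUI = w_long/(w_long+w_short); a fit with no detectable short isoform in
any sample (w_short ≈ 0) is flagged degenerate with PDUI 1. Defaults —
minimum mean raw coverage 30×, UTR length ≥ 150 nt, |ΔPDUI| ≥ 0.2,
BH-FDR ≤ 0.05 — are this package's stated defaults and all configurable.
The 30× skip filter is a production guard, separate from the model; recovery
experiments at lower depth pass an explicit `min_coverage`.

Significance uses read-equivalent counts: fitted weights rescaled to the
library's raw depth times the covered segment length divided by the read
length (default 50 nt), rounded, in a Fisher test with BH correction.
Inferred proximal sites are validated by distance to the nearest confirmed
CPA site on the same chromosome and strand; the default tolerance 250 bp is
inclusive at the boundary. Validation is applied per comparison.

## QC, similarity and overlap

Marker fold enrichment is (nuclear + 0.5)/(cytoplasmic + 0.5); the
pseudocount keeps folds finite without distorting large counts. Defaults:
MALAT1 ≥ 20-fold, XIST ≥ 200-fold, both configurable; all markers must pass.
Sample similarity is Spearman correlation of log2(x+1) site abundances
(sites zero everywhere dropped) with average-linkage clustering on 1−ρ and a
deterministic newick export. Cross-sample overlap counts an event as shared
in *k* sets when the same gene carries the same direction in exactly *k*
sets; genes with conflicting directions are counted once at their largest
consistent *k* and flagged, with ties between directions broken by a fixed
direction order — the conflict rule is this package's own choice, stated
rather than hidden. Replicate concordance reports both natural denominators
(union of events; smaller set) because an "overlap percentage" can mean
either.

## Synthetic data: what it emulates, and what it does not

The generator plants the structure the analysis assumes: ~70% of genes with
two 3'UTR sites, 10% of those carrying a nuclear→cytoplasmic shift in
proximal fraction of magnitude Uniform(0.08, 0.40) with directions 3:1
shorter-in-cytoplasm, per-gene library depths negative-binomial (mean 300,
dispersion 0.2 — overdispersed rather than Poisson, to stress the Fisher
calibration honestly), effect sizes as additive shifts in proximal fraction
clipped to [0.02, 0.98], 20% of genes with an additional intronic site,
read positions jittered ±10 nt to exercise clustering, PAS hexamers written
into the sequence at planted offsets in −30..−17 (windows are synthesised
free of competing vocabulary hexamers so the planted call is unambiguous),
marker genes at 50× (MALAT1-like) and 400× (XIST-like) nuclear enrichment,
and two-isoform step coverage with Poisson noise at 50× for the coverage
route. All sampling flows from explicit seeds; outputs are byte-stable.

What it does not emulate: mappability and alignment artefacts, internal
priming, overlapping genes and antisense transcription, intron-retention
coverage, positional biases within libraries, or biological covariance
between genes. Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under the assumed generative
structure, not performance on the full messiness of real sequencing data.

Simulation sizes used in the test suite and acceptance script (2,000 genes
for calibration, 300 per power grid point, 90 for PDUI recovery, 60 for the
determinism run) were chosen to give stable rates at desk scale.

## Known limitations

- The two-isoform coverage model cannot represent ≥3 coexpressed isoforms;
  the breakpoint then lands between the true sites and PDUI is a composite.
- Breakpoint localisation degrades as PDUI → 1 (the short-isoform signal
  vanishes); the degenerate flag marks the limit case only.
- The depth-controlled test's read-level permutation null is exact but,
  with a single library per fraction, cannot model biological replicate
  variance — with replicates it equalises depth but still pools within
  fraction.
- Gene assignment takes no account of expression when resolving overlapping
  same-strand genes; the deterministic lexicographic rule can misassign
  sites in dense loci.
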