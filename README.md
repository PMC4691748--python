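# apafrac

Analysis of **alternative cleavage and polyadenylation (APA) between
subcellular RNA fractions**. Most human genes carry more than one
cleavage/polyadenylation (CPA) site, so a gene's transcripts differ in 3'UTR
length (UTR-APA) or even coding content (CR-APA, when the proximal site sits
in an upstream intron or exon). Comparing nuclear against cytoplasmic RNA
pools asks a sharp biological question: are particular APA isoforms
preferentially exported, retained, or degraded? `apafrac` is for
transcriptomics researchers who have 3'-end sequencing (3'READS-like) counts
and/or fractionated RNA-seq coverage and want that comparison done with
explicit statistics and QC.

## What it computes

**3'-end route.** Cleavage positions are clustered into CPA sites by single
linkage (default 24 nt window), assigned to union-of-exons gene models and a
region class (3'UTR / upstream exon / intron), and annotated with the
polyadenylation signal (PAS) hexamer found in the 40 nt upstream of the
cleavage site (AATAAA > ATTAAA > single-nucleotide variants). For each gene
the two most abundant 3'UTR isoforms give a 2×2 count table between two
samples; with proximal fraction

p̂ᵢ = proximal / (proximal + distal) in sample *i*, Δ = p̂_B − p̂_A,

a gene is called **SHORTER_IN_B** (or LONGER_IN_B) when the two-sided Fisher
exact *P* ≤ 0.01 **and** |Δ| > 0.05, with Benjamini–Hochberg q-values
reported alongside. CR-APA uses the same machinery on pooled upstream-region
versus 3'UTR reads. A depth-controlled robustness test subsamples every
library to the shallowest depth (×20, seeded), scores each gene by the
difference of B/A log2-ratios between proximal and distal sites, and
controls BH-FDR at 10%.

**Coverage route.** RNA-seq depth across an annotated 3'UTR is fit jointly
over samples as a two-isoform mixture — a long isoform covering the whole
UTR and a short isoform ending at a shared breakpoint — by least squares on
a 1-nt candidate grid. PDUI (percentage distal usage index) per sample is
w_long/(w_long+w_short); genes with |ΔPDUI| ≥ 0.2 at BH-FDR ≤ 0.05 are
called, and each inferred proximal site is validated against a confirmed CPA
site annotation within 250 bp.

**QC and overlap.** Fractionations must show ≥20-fold nuclear enrichment of
MALAT1 and ≥200-fold of XIST (pseudocount 0.5); samples are compared by
Spearman correlation with an average-linkage dendrogram; event lists from
several cell lines or replicates are intersected into shared-in-*k*-sets
counts and direction-consistent replicate concordance.

A seeded synthetic-data generator (`apafrac.synthetic_data`) produces every
input the pipeline consumes — genome FASTA with planted PAS hexamers, GTF,
per-sample BED6 3'-end counts, bedGraph coverage — together with a
machine-readable truth ledger, and is itself a tested, first-class module.

## Worked example

```python
from apafrac import SimConfig, run_pipeline
from apafrac.apa_test import summarize_calls

results = run_pipeline(SimConfig(n_genes=200), seed=17, out_dir="apa_demo")

print("fraction QC:", {g: round(f, 1) for g, f in results["qc"].fold_enrichment.items()},
      "->", "PASS" if results["qc"].passed else "FAIL")
pas = results["pas_tables"]
print("canonical PAS (site-weighted):   %.3f" % (pas["site_frequency"]["AATAAA"]
                                                 + pas["site_frequency"]["ATTAAA"]))
print("canonical PAS (read-weighted):   %.3f" % (pas["read_weighted"]["AATAAA"]
                                                 + pas["read_weighted"]["ATTAAA"]))
print("UTR-APA cytoplasm vs nucleus:", summarize_calls(results["utr_cyt"]))
print("coverage dPDUI calls:", summarize_calls(results["pdui"]),
      "| validated:", int(results["pdui"].validated.sum()), "/", len(results["pdui"]))
```

prints

```
fraction QC: {'MALAT1': 49.8, 'XIST': 400.0} -> PASS
canonical PAS (site-weighted):   0.773
canonical PAS (read-weighted):   0.868
UTR-APA cytoplasm vs nucleus: {'n_tested': 139, 'n_shorter_in_b': 11, 'n_longer_in_b': 3}
coverage dPDUI calls: {'n_tested': 118, 'n_shorter_in_b': 3, 'n_longer_in_b': 1} | validated: 118 / 118
```

Reading this: both nuclear markers clear their enrichment thresholds, so the
simulated fractionation passes QC. Weighting PAS hexamers by read counts
raises the canonical AATAAA+ATTAAA share from 0.77 to 0.87 — highly
expressed sites carry the canonical signal. Of 139 genes with two expressed
3'UTR isoforms, 14 change significantly between fractions, biased toward
shorter-in-cytoplasm, matching the planted 10% affected / 3:1 direction
structure; the coverage route's inferred proximal sites all validate against
the 3'-end-derived site annotation. All result tables are also written under
`apa_demo/`.

The same stages are available from a shell:

```bash
apafrac simulate --seed 17 --out sim/
apafrac sites --ends nuclear=sim/ends_nuclear.bed --ends cytoplasmic=sim/ends_cytoplasmic.bed \
        --gtf sim/annotation.gtf --fasta sim/genome.fa --out sites.tsv
apafrac test --sites sites.tsv --mode utr --a nuclear --b cytoplasmic --out utr.tsv
```

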