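"""Differential representation of APA isoforms between two samples.

The core statistic of the pipeline. For each gene the two most abundant
3'UTR isoforms (UTR-APA) — or the pooled upstream-region reads versus the
pooled 3'-most-exon reads (CR-APA) — form a 2x2 count table between two
samples (e.g. nuclear vs cytoplasmic, or knockdown vs control). A two-sided
Fisher exact test plus an absolute change threshold on the proximal-isoform
fraction classifies each gene as SHORTER_IN_B, LONGER_IN_B or UNCHANGED.
Benjamini-Hochberg q-values are reported alongside the raw-P rule.

A depth-controlled robustness procedure (SAAP-style) is also provided: all
libraries are repeatedly subsampled to the shallowest library's depth, a
proximal-vs-distal log-ratio difference statistic is computed per gene, its
significance is assessed against a fraction-label permutation null pooled
across genes, and the per-replicate p-values are combined by their median
before FDR control. The internals of the original depth-controlled test are
not published with this pipeline's source material; this reconstruction is
this package's own surrogate, with every knob exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome_model import RegionClass
from .site_quant import CpaSite

logger = logging.getLogger("apafrac")

SHORTER_IN_B = "SHORTER_IN_B"
LONGER_IN_B = "LONGER_IN_B"
UNCHANGED = "UNCHANGED"

UPSTREAM_REGIONS = (RegionClass.INTRON, RegionClass.UPSTREAM_EXON)


@dataclass(frozen=True)
class IsoformPair:
    """The two most abundant 3'UTR isoforms of one gene, with counts in two samples."""

    gene_id: str
    proximal_site_id: str
    distal_site_id: str
    counts_a: tuple[int, int]  # (proximal, distal) in sample A
    counts_b: tuple[int, int]


def _is_proximal(pos1: int, pos2: int, strand: str) -> bool:
    """True if pos1 is upstream of pos2 in transcription direction."""
    return pos1 < pos2 if strand == "+" else pos1 > pos2


def top_two_utr_isoforms(gene_sites: Sequence[CpaSite],
                         ranking_samples: Sequence[str],
                         sample_a: str, sample_b: str) -> Optional[IsoformPair]:
    """Select a gene's two most abundant 3'UTR sites as its isoform pair.

    Ranking is by summed counts over ``ranking_samples``; ties are broken in
    favour of the more proximal site. Returns ``None`` (gene excluded) when
    fewer than two 3'UTR sites have nonzero ranking counts.
    """
    utr = [s for s in gene_sites if s.region == RegionClass.UTR3
           and s.total(ranking_samples) > 0]
    if len(utr) < 2:
        if gene_sites:
            logger.debug("gene %s: <2 expressed UTR3 sites, excluded",
                         gene_sites[0].gene_id)
        return None
    strand = utr[0].strand
    # sort: count desc, then proximal first (transcription-direction order)
    tx_order = (lambda s: s.pos) if strand == "+" else (lambda s: -s.pos)
    utr.sort(key=lambda s: (-s.total(ranking_samples), tx_order(s)))
    s1, s2 = utr[0], utr[1]
    if not _is_proximal(s1.pos, s2.pos, strand):
        s1, s2 = s2, s1
    return IsoformPair(
        gene_id=s1.gene_id or "",
        proximal_site_id=s1.site_id, distal_site_id=s2.site_id,
        counts_a=(s1.counts.get(sample_a, 0), s2.counts.get(sample_a, 0)),
        counts_b=(s1.counts.get(sample_b, 0), s2.counts.get(sample_b, 0)))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    p is the sum of hypergeometric probabilities (margins fixed) of all
    tables at most as probable as the observed one, with a 1e-12 relative
    tie tolerance (so exact ties computed with round-off still count as
    ties). A zero row or column margin gives p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - kmin]
    include = pmf <= p_obs * (1.0 + 1e-12)
    if include.all():
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def bh_fdr(p_values: Sequence[float], q: float = 0.10
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q_values, rejection mask at level q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def _classify(delta: float, p: float, alpha: float, min_change: float) -> str:
    if p <= alpha and delta > min_change:
        return SHORTER_IN_B
    if p <= alpha and delta < -min_change:
        return LONGER_IN_B
    return UNCHANGED


def test_utr_apa(pairs: Iterable[IsoformPair], alpha: float = 0.01,
                 min_change: float = 0.05) -> pd.DataFrame:
    """Fisher-exact differential representation of UTR-APA isoform pairs.

    For each gene the proximal-isoform fraction is computed in both samples
    from the two-isoform-restricted counts; the change is the difference of
    fractions (B - A, in fraction units, so 0.05 = 5 percentage points).
    A gene is called when p <= alpha and |change| > min_change; the sign of
    the change gives the direction (proximal up in B = SHORTER_IN_B).
    BH q-values over all tested genes are reported alongside.
    """
    rows = []
    for pair in pairs:
        pa, da = pair.counts_a
        pb, db = pair.counts_b
        tot_a, tot_b = pa + da, pb + db
        if tot_a == 0 or tot_b == 0:
            rows.append(dict(gene_id=pair.gene_id, mode="UTR_APA",
                             frac_proximal_a=np.nan, frac_proximal_b=np.nan,
                             delta=0.0, p_value=1.0, call=UNCHANGED,
                             low_coverage=True))
            continue
        fa, fb = pa / tot_a, pb / tot_b
        p = fisher_exact_2x2([[pa, da], [pb, db]])
        delta = fb - fa
        rows.append(dict(gene_id=pair.gene_id, mode="UTR_APA",
                         frac_proximal_a=fa, frac_proximal_b=fb, delta=delta,
                         p_value=p, call=_classify(delta, p, alpha, min_change),
                         low_coverage=False))
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_q"], _ = bh_fdr(df["p_value"].to_numpy())
    else:
        df["fdr_q"] = []
    return df


def test_cr_apa(gene_sites: dict[str, Sequence[CpaSite]], sample_a: str,
                sample_b: str, alpha: float = 0.01,
                min_change: float = 0.05) -> pd.DataFrame:
    """Coding-region APA test: upstream-region reads vs 3'UTR reads per gene.

    For each gene with at least one intronic/upstream-exonic site and at
    least one 3'UTR site, reads are pooled into (upstream, 3'UTR) counts per
    sample and tested with the same Fisher + change-threshold machinery.
    SHORTER_IN_B means the upstream (truncated) isoform is overrepresented
    in sample B.
    """
    rows = []
    for gene_id in sorted(gene_sites):
        sites = gene_sites[gene_id]
        up = [s for s in sites if s.region in UPSTREAM_REGIONS]
        utr = [s for s in sites if s.region == RegionClass.UTR3]
        if not up or not utr:
            continue
        ua = sum(s.counts.get(sample_a, 0) for s in up)
        ub = sum(s.counts.get(sample_b, 0) for s in up)
        ta = sum(s.counts.get(sample_a, 0) for s in utr)
        tb = sum(s.counts.get(sample_b, 0) for s in utr)
        tot_a, tot_b = ua + ta, ub + tb
        if tot_a == 0 or tot_b == 0:
            rows.append(dict(gene_id=gene_id, mode="CR_APA",
                             frac_proximal_a=np.nan, frac_proximal_b=np.nan,
                             delta=0.0, p_value=1.0, call=UNCHANGED,
                             low_coverage=True))
            continue
        fa, fb = ua / tot_a, ub / tot_b
        p = fisher_exact_2x2([[ua, ta], [ub, tb]])
        delta = fb - fa
        rows.append(dict(gene_id=gene_id, mode="CR_APA",
                         frac_proximal_a=fa, frac_proximal_b=fb, delta=delta,
                         p_value=p, call=_classify(delta, p, alpha, min_change),
                         low_coverage=False))
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_q"], _ = bh_fdr(df["p_value"].to_numpy())
    else:
        df["fdr_q"] = []
    return df


# ---------------------------------------------------------------------------
# depth-controlled robustness test (SAAP-style surrogate)
# ---------------------------------------------------------------------------

def _subsample_library(rng: np.random.Generator, counts: np.ndarray,
                       depth: int) -> np.ndarray:
    """Draw `depth` reads without replacement from a library's count vector."""
    total = int(counts.sum())
    if depth >= total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def saap_test(counts: pd.DataFrame, n_subsample: int = 20, fdr: float = 0.10,
              seed: int = 0, min_depth: int = 100, pseudocount: float = 0.5,
              fraction_a: Optional[str] = None,
              fraction_b: Optional[str] = None) -> pd.DataFrame:
    """Depth-controlled significance analysis of APA isoform-ratio changes.

    Parameters
    ----------
    counts:
        Long table with columns ``gene_id, library, fraction, proximal,
        distal``; ``fraction`` takes exactly two values (A = e.g. nuclear,
        B = e.g. cytoplasmic, in sorted order), ``library`` identifies a
        replicate sequencing library.
    n_subsample:
        Number of depth-matched subsample replicates (default 20).
    fdr:
        BH false-discovery-rate level for the final rejection (default 10%).

    For each subsample replicate every library is subsampled without
    replacement to the minimum library depth. The per-gene statistic is the
    difference of B/A log2-ratios between proximal and distal site counts
    (pooled over replicate libraries, with a pseudocount). Significance per
    replicate comes from permuting fraction labels over the gene's
    individual depth-matched reads with margins fixed — whose exact law is
    the hypergeometric two-sided (Fisher) p of the pooled 2x2 table. The
    per-gene p-values are combined over subsample replicates by their
    median and BH-controlled at ``fdr``.

    Returns a per-gene table with ``stat_mean, stat_sd, p_value, q_value,
    call`` (SHORTER_IN_B = proximal enriched in fraction B).
    """
    required = {"gene_id", "library", "fraction", "proximal", "distal"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    fractions = sorted(counts["fraction"].unique())
    if len(fractions) != 2:
        raise ValueError("exactly two fraction labels required")
    frac_a = fractions[0] if fraction_a is None else fraction_a
    frac_b = fractions[1] if fraction_b is None else fraction_b
    if {frac_a, frac_b} != set(fractions):
        raise ValueError("fraction_a/fraction_b do not match the table labels")
    genes = sorted(counts["gene_id"].unique())
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    libraries = (counts[["library", "fraction"]].drop_duplicates()
                 .sort_values("library").reset_index(drop=True))
    lib_vectors = []  # per library: length 2*n_genes (proximal block, distal block)
    for lib in libraries["library"]:
        sub = counts[counts["library"] == lib]
        vec = np.zeros(2 * n_genes, dtype=np.int64)
        idx = sub["gene_id"].map(gene_idx).to_numpy()
        vec[idx] = sub["proximal"].to_numpy(dtype=np.int64)
        vec[n_genes + idx] = sub["distal"].to_numpy(dtype=np.int64)
        lib_vectors.append(vec)
    depths = np.array([v.sum() for v in lib_vectors])
    target = int(depths.min())
    if target < min_depth:
        raise ValueError(
            f"shallowest library has {target} reads (< {min_depth}); "
            "too few to depth-match by subsampling")

    labels = libraries["fraction"].to_numpy()
    is_b_obs = labels == frac_b

    rng = np.random.default_rng(seed)

    stats = np.empty((n_genes, n_subsample))
    pvals = np.empty((n_genes, n_subsample))
    for t in range(n_subsample):
        mat = np.stack([_subsample_library(rng, v, target) for v in lib_vectors])
        pooled_b = mat[is_b_obs].sum(axis=0)
        pooled_a = mat[~is_b_obs].sum(axis=0)
        pb, db = pooled_b[:n_genes], pooled_b[n_genes:]
        pa, da = pooled_a[:n_genes], pooled_a[n_genes:]
        e = pseudocount
        stats[:, t] = (np.log2((pb + e) / (pa + e))
                       - np.log2((db + e) / (da + e)))
        pvals[:, t] = [fisher_exact_2x2([[int(pa[g]), int(da[g])],
                                         [int(pb[g]), int(db[g])]])
                       for g in range(n_genes)]

    p_med = np.median(pvals, axis=1)
    qvals, reject = bh_fdr(p_med, q=fdr)
    stat_mean = stats.mean(axis=1)
    calls = np.where(~reject, UNCHANGED,
                     np.where(stat_mean > 0, SHORTER_IN_B, LONGER_IN_B))
    return pd.DataFrame({
        "gene_id": genes,
        "stat_mean": stat_mean,
        "stat_sd": stats.std(axis=1, ddof=1) if n_subsample > 1 else 0.0,
        "n_replicates": n_subsample,
        "p_value": p_med,
        "q_value": qvals,
        "call": calls,
    })


def summarize_calls(results: pd.DataFrame) -> dict[str, int]:
    """Bar-plot quantities: number tested / shorter-in-B / longer-in-B."""
    return {
        "n_tested": int(len(results)),
        "n_shorter_in_b": int((results["call"] == SHORTER_IN_B).sum()),
        "n_longer_in_b": int((results["call"] == LONGER_IN_B).sum()),
    }
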