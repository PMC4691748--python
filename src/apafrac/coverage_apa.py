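"""Coverage-based APA inference over annotated 3'UTRs (DaPars-style).

RNA-seq coverage across an annotated 3'UTR is modelled as a mixture of two
isoforms sharing a de-novo proximal CPA site: a long isoform covering the
whole UTR with abundance w_long, and a short isoform covering the UTR up to
a breakpoint with abundance w_short. The breakpoint is selected on a
candidate grid to minimise total squared error jointly across samples, with
per-sample non-negative weights solved in closed form at each candidate.
PDUI (percentage of distal polyA site usage index) per sample is
w_long / (w_long + w_short); dPDUI between two samples drives the call.

Inferred proximal sites are validated against an external CPA-site
annotation: a prediction is kept as a "true" event when it lies within a
tolerance (default 250 bp, inclusive) of a confirmed site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .apa_test import (LONGER_IN_B, SHORTER_IN_B, UNCHANGED, bh_fdr,
                       fisher_exact_2x2)

logger = logging.getLogger("apafrac")

MIN_COVERAGE = 30.0     # minimum mean raw depth per sample
MIN_UTR_LENGTH = 150    # nt
GRID_MARGIN = 50        # breakpoint grid excludes this many nt at both ends
DEFAULT_READ_LENGTH = 50


@dataclass
class CoverageTrack:
    """Per-base depth over one annotated 3'UTR, oriented 5'->3' of the mRNA.

    ``depth[0]`` is the first UTR base in transcription direction (the
    genomic left end on '+', the right end on '-'). ``library_size`` is the
    library's total mapped reads, used for reads-per-million normalisation.
    """

    gene_id: str
    chrom: str
    start: int   # genomic UTR interval, 0-based half-open
    end: int
    strand: str
    sample_id: str
    depth: np.ndarray = field(default_factory=lambda: np.array([]))
    library_size: int = 1_000_000

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("negative depth")
        if len(self.depth) != self.end - self.start:
            raise ValueError("depth vector length must equal UTR length")

    @property
    def rpm(self) -> np.ndarray:
        return self.depth * (1e6 / self.library_size)


@dataclass
class TwoIsoformFit:
    """Joint two-isoform fit of one UTR: breakpoint plus per-sample weights."""

    gene_id: str
    breakpoint_offset: int            # nt from UTR 5' start (short isoform length)
    proximal_pos: int                 # genomic coordinate of the breakpoint
    chrom: str
    strand: str
    utr_length: int
    w_long: dict[str, float]          # RPM-scale abundances per sample
    w_short: dict[str, float]
    pdui: dict[str, float]
    degenerate: bool                  # no detectable short isoform
    library_sizes: dict[str, int]


def fit_two_isoform_model(tracks: Sequence[CoverageTrack],
                          min_coverage: float = MIN_COVERAGE,
                          min_length: int = MIN_UTR_LENGTH,
                          grid_margin: int = GRID_MARGIN,
                          grid_step: int = 1) -> Optional[TwoIsoformFit]:
    """Fit the joint two-isoform coverage model for one UTR across samples.

    Returns ``None`` (gene skipped, logged) when the UTR is too short or any
    sample's mean raw coverage is below ``min_coverage``. Depths are
    normalised to reads per million before the joint fit, so the breakpoint
    is shared while weights are per sample.
    """
    if not tracks:
        raise ValueError("no coverage tracks given")
    gene_id = tracks[0].gene_id
    L = len(tracks[0].depth)
    if any(len(t.depth) != L for t in tracks):
        raise ValueError(f"gene {gene_id}: samples disagree on UTR length")
    if L < min_length:
        logger.info("gene %s: UTR %d nt < %d, skipped", gene_id, L, min_length)
        return None
    for t in tracks:
        if t.depth.mean() < min_coverage:
            logger.info("gene %s: sample %s mean coverage %.1f < %.0fx, skipped",
                        gene_id, t.sample_id, t.depth.mean(), min_coverage)
            return None

    d = np.stack([t.rpm for t in tracks])          # samples x L
    csum = np.concatenate([np.zeros((len(tracks), 1)), np.cumsum(d, axis=1)], axis=1)
    csq = np.concatenate([np.zeros((len(tracks), 1)),
                          np.cumsum(d * d, axis=1)], axis=1)
    total, total_sq = csum[:, -1], csq[:, -1]

    bps = np.arange(grid_margin, L - grid_margin + 1, grid_step)
    if len(bps) == 0:
        bps = np.array([L // 2])
    # closed-form segment fit per candidate: prefix mean m1, suffix mean m2;
    # unconstrained LS gives w_long=m2, w_short=m1-m2; if m1<m2 the
    # non-negativity constraint binds and the flat model (overall mean) wins.
    n1 = bps[None, :].astype(float)
    n2 = (L - bps)[None, :].astype(float)
    s1 = csum[:, bps]
    m1 = s1 / n1
    m2 = (total[:, None] - s1) / n2
    sse_two = total_sq[:, None] - n1 * m1**2 - n2 * m2**2
    grand = total / L
    sse_flat = total_sq - L * grand**2
    sse = np.where(m1 >= m2, sse_two, sse_flat[:, None]).sum(axis=0)
    best = int(np.argmin(sse))          # ties -> most proximal candidate
    b = int(bps[best])

    w_long, w_short, pdui = {}, {}, {}
    degenerate = True
    for i, t in enumerate(tracks):
        wl = float(m2[i, best])
        ws = float(max(m1[i, best] - m2[i, best], 0.0))
        if m1[i, best] < m2[i, best]:
            wl, ws = float(grand[i]), 0.0
        w_long[t.sample_id], w_short[t.sample_id] = wl, ws
        denom = wl + ws
        pdui[t.sample_id] = 1.0 if denom <= 0 else wl / denom
        if ws > 1e-9 * max(wl, 1e-12):
            degenerate = False
    t0 = tracks[0]
    proximal_pos = t0.start + b if t0.strand == "+" else t0.end - b
    return TwoIsoformFit(gene_id=gene_id, breakpoint_offset=b,
                         proximal_pos=proximal_pos, chrom=t0.chrom,
                         strand=t0.strand, utr_length=L,
                         w_long=w_long, w_short=w_short, pdui=pdui,
                         degenerate=degenerate,
                         library_sizes={t.sample_id: t.library_size for t in tracks})


def _read_equivalents(fit: TwoIsoformFit, sample: str,
                      read_length: int) -> tuple[int, int]:
    """Approximate (long, short) isoform read counts behind the fit.

    Fitted RPM weights are rescaled to the library's raw depth; a segment of
    constant depth w over length L corresponds to about w*L/read_length reads.
    """
    scale = fit.library_sizes[sample] / 1e6
    long_reads = fit.w_long[sample] * scale * fit.utr_length / read_length
    short_reads = fit.w_short[sample] * scale * fit.breakpoint_offset / read_length
    return int(round(long_reads)), int(round(short_reads))


def delta_pdui_test(fits: Sequence[TwoIsoformFit], sample_a: str, sample_b: str,
                    min_abs_delta: float = 0.2, fdr: float = 0.05,
                    read_length: int = DEFAULT_READ_LENGTH) -> pd.DataFrame:
    """dPDUI calls between two samples from fitted two-isoform models.

    dPDUI = PDUI(B) - PDUI(A). Significance is a Fisher exact test on the
    long/short read-equivalent counts, BH-controlled at ``fdr``; a gene is
    called only when additionally |dPDUI| >= ``min_abs_delta``. Falling
    distal usage in B (dPDUI <= -min_abs_delta) is SHORTER_IN_B.
    """
    rows = []
    for fit in fits:
        pa, pb = fit.pdui[sample_a], fit.pdui[sample_b]
        la, sa = _read_equivalents(fit, sample_a, read_length)
        lb, sb = _read_equivalents(fit, sample_b, read_length)
        p = fisher_exact_2x2([[la, sa], [lb, sb]])
        rows.append(dict(gene_id=fit.gene_id, proximal_pos=fit.proximal_pos,
                         chrom=fit.chrom, strand=fit.strand,
                         pdui_a=pa, pdui_b=pb, delta_pdui=pb - pa,
                         p_value=p, degenerate=fit.degenerate))
    df = pd.DataFrame(rows)
    if not len(df):
        return df.assign(fdr_q=[], call=[])
    df["fdr_q"], reject = bh_fdr(df["p_value"].to_numpy(), q=fdr)
    call = np.full(len(df), UNCHANGED, dtype=object)
    call[reject & (df["delta_pdui"] <= -min_abs_delta)] = SHORTER_IN_B
    call[reject & (df["delta_pdui"] >= min_abs_delta)] = LONGER_IN_B
    df["call"] = call
    return df


def validate_site(proximal_pos: int, chrom: str, strand: str,
                  annotated_sites: pd.DataFrame,
                  tol: int = 250) -> tuple[bool, float]:
    """Distance of a predicted proximal site to the nearest confirmed site.

    ``annotated_sites`` is a BED6-like frame (chrom, start, end, name, score,
    strand); matching is restricted to same chromosome and strand. Returns
    ``(validated, distance)`` with the tolerance boundary inclusive.
    """
    if annotated_sites is None or len(annotated_sites) == 0:
        logger.warning("empty CPA-site annotation: nothing validates")
        return False, float("inf")
    sel = annotated_sites[(annotated_sites["chrom"] == chrom)
                          & (annotated_sites["strand"] == strand)]
    if len(sel) == 0:
        return False, float("inf")
    dist = float(np.min(np.abs(sel["start"].to_numpy() - proximal_pos)))
    return dist <= tol, dist


def annotate_validation(results: pd.DataFrame, annotated_sites: pd.DataFrame,
                        tol: int = 250) -> pd.DataFrame:
    """Add ``validated``/``nearest_annotated_distance`` columns to dPDUI results."""
    flags, dists = [], []
    for _, row in results.iterrows():
        ok, dist = validate_site(int(row.proximal_pos), row.chrom, row.strand,
                                 annotated_sites, tol=tol)
        flags.append(ok)
        dists.append(dist)
    out = results.copy()
    out["validated"] = flags
    out["nearest_annotated_distance"] = dists
    return out


def read_bedgraph(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, comment="t",
                       names=["chrom", "start", "end", "depth"])


def coverage_for_utr(bedgraph: pd.DataFrame, gene_id: str, chrom: str,
                     start: int, end: int, strand: str, sample_id: str,
                     library_size: int = 1_000_000) -> CoverageTrack:
    """Project a bedGraph onto one UTR interval as a 5'->3' depth vector."""
    depth = np.zeros(end - start)
    sel = bedgraph[(bedgraph["chrom"] == chrom) & (bedgraph["end"] > start)
                   & (bedgraph["start"] < end)]
    for _, row in sel.iterrows():
        lo, hi = max(int(row.start), start), min(int(row.end), end)
        depth[lo - start:hi - start] = float(row.depth)
    if strand == "-":
        depth = depth[::-1]
    return CoverageTrack(gene_id=gene_id, chrom=chrom, start=start, end=end,
                         strand=strand, sample_id=sample_id, depth=depth,
                         library_size=library_size)


def read_known_sites_bed(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name", "score", "strand"])
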