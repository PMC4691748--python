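"""CPA-site calling, quantification and PAS-hexamer annotation.

3'-end read positions (one cleavage coordinate per read, with a count) are
clustered per (chromosome, strand) by single linkage — consecutive positions
no more than a window apart merge — into cleavage/polyadenylation (CPA)
sites. Each site carries per-sample read counts, a gene/region assignment
and a polyadenylation-signal (PAS) call from scanning the 40 nt immediately
upstream of the cleavage position on the sense strand.

Internal-priming filtering is intentionally not performed here (3'READS-type
chemistry largely avoids it); callers may pass a pre-filtered position table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .genome_model import GeneModel, RegionClass, classify_position, extract_window

logger = logging.getLogger("apafrac")

#: canonical hexamer, its 1-nt A->T variant, and the ten other single-
#: nucleotide AATAAA variants reported as one "variant" display class.
CANONICAL_PAS = "AATAAA"
ATTAAA = "ATTAAA"
VARIANT_PAS: tuple[str, ...] = (
    "AGTAAA", "ACTAAA", "TATAAA", "CATAAA", "GATAAA",
    "AATATA", "AATACA", "AATAGA", "AATGAA", "AATAAG",
)
PAS_NONE = "NONE"

#: search window for the PAS, as offsets of the hexamer start relative to
#: the cleavage position (transcription direction, cleavage = offset 0).
PAS_WINDOW = (-40, -1)


@dataclass(frozen=True)
class PasCall:
    """A PAS hexamer call: which hexamer, starting at which upstream offset."""

    hexamer: str = PAS_NONE
    offset: Optional[int] = None  # hexamer start, nt upstream of cleavage

    def __post_init__(self):
        if (self.hexamer == PAS_NONE) != (self.offset is None):
            raise ValueError("hexamer NONE iff offset absent")

    @property
    def category(self) -> str:
        if self.hexamer == CANONICAL_PAS:
            return "AATAAA"
        if self.hexamer == ATTAAA:
            return "ATTAAA"
        if self.hexamer == PAS_NONE:
            return "NONE"
        return "variant"


@dataclass
class CpaSite:
    """One cleavage/polyadenylation site with per-sample read counts."""

    site_id: str
    chrom: str
    pos: int  # representative cleavage coordinate: count-weighted mode
    strand: str
    counts: dict[str, int] = field(default_factory=dict)
    gene_id: Optional[str] = None
    region: RegionClass = RegionClass.INTERGENIC
    pas: PasCall = field(default_factory=PasCall)

    def total(self, samples: Optional[Iterable[str]] = None) -> int:
        keys = self.counts.keys() if samples is None else samples
        return int(sum(self.counts.get(k, 0) for k in keys))


def cluster_ends(end_positions: pd.DataFrame, window: int = 24) -> list[CpaSite]:
    """Cluster 3'-end read positions into CPA sites by single linkage.

    Parameters
    ----------
    end_positions:
        DataFrame with columns ``chrom, pos, strand, count`` and optionally
        ``sample`` (missing -> all reads belong to sample ``"sample"``).
    window:
        Maximum gap (nt) between consecutive positions merged into one site.

    The representative position of a site is the count-weighted mode of its
    member positions (summed over samples); ties go to the most distal
    position in transcription direction.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    df = end_positions.copy()
    if "sample" not in df.columns:
        df["sample"] = "sample"
    if (df["count"] < 0).any():
        raise ValueError("negative read counts")
    df = df[df["count"] > 0]
    sites: list[CpaSite] = []
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=True):
        agg = sub.groupby("pos")["count"].sum().sort_index()
        positions = agg.index.to_numpy()
        totals = agg.to_numpy()
        if len(positions) == 0:
            continue
        # single linkage on a sorted axis = cut where the gap exceeds window
        cluster_of = np.concatenate(
            [[0], np.cumsum(np.diff(positions) > window)])
        reps = {}
        for cid in range(cluster_of[-1] + 1):
            members = cluster_of == cid
            p, t = positions[members], totals[members]
            best = t == t.max()
            reps[cid] = int(p[best].max() if strand == "+" else p[best].min())
        pos_to_cluster = dict(zip(positions.tolist(), cluster_of.tolist()))
        grouped = (sub.assign(_cid=sub.pos.map(pos_to_cluster))
                   .groupby(["_cid", "sample"])["count"].sum())
        counts_by_cluster: dict[int, dict[str, int]] = {}
        for (cid, sample), c in grouped.items():
            counts_by_cluster.setdefault(int(cid), {})[str(sample)] = int(c)
        for cid in sorted(reps):
            rep = reps[cid]
            sites.append(CpaSite(site_id=f"{chrom}:{rep}:{strand}", chrom=str(chrom),
                                 pos=rep, strand=str(strand),
                                 counts=counts_by_cluster.get(cid, {})))
    return sites


def sites_to_frame(sites: Iterable[CpaSite]) -> pd.DataFrame:
    """Tidy site table: one row per site, one count column per sample."""
    rows = []
    samples: set[str] = set()
    for s in sites:
        samples.update(s.counts)
    sample_cols = sorted(samples)
    for s in sites:
        row = {
            "site_id": s.site_id, "chrom": s.chrom, "pos": s.pos,
            "strand": s.strand, "gene_id": s.gene_id or "",
            "region": s.region.value, "pas": s.pas.hexamer,
            "pas_offset": "" if s.pas.offset is None else s.pas.offset,
        }
        for c in sample_cols:
            row[f"count_{c}"] = s.counts.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def assign_sites(sites: list[CpaSite], gene_models: list[GeneModel]) -> list[CpaSite]:
    """Assign each site to a same-strand gene and classify its region.

    Sites are assigned only to genes on the same strand whose span contains
    the site. Ties between overlapping same-strand genes are broken by the
    lexicographically smallest gene_id (logged). Intergenic sites are kept
    with ``gene_id=None``.
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in gene_models:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    for glist in by_key.values():
        glist.sort(key=lambda g: g.start)
    for site in sites:
        candidates = []
        for g in by_key.get((site.chrom, site.strand), []):
            if g.start <= site.pos < g.end:
                candidates.append(g)
        if not candidates:
            site.gene_id = None
            site.region = RegionClass.INTERGENIC
            continue
        if len(candidates) > 1:
            logger.info("site %s overlaps %d genes; assigned to smallest gene_id",
                        site.site_id, len(candidates))
        gene = min(candidates, key=lambda g: g.gene_id)
        site.gene_id = gene.gene_id
        site.region = classify_position(gene, site.pos, site.strand)
    return sites


def call_pas(site: CpaSite, fasta: Union[str, Path, Fasta],
             vocabulary: Optional[dict[str, int]] = None,
             window: tuple[int, int] = PAS_WINDOW) -> PasCall:
    """Scan the sense-strand upstream window of a site for a PAS hexamer.

    Precedence: AATAAA > ATTAAA > single-nucleotide variants; among matches
    of equal precedence the one closest to the cleavage site wins. Returns
    ``PasCall(NONE)`` when nothing in the vocabulary occurs or the available
    window is shorter than 6 nt.
    """
    if vocabulary is None:
        vocabulary = {CANONICAL_PAS: 0, ATTAAA: 1}
        vocabulary.update({v: 2 for v in VARIANT_PAS})
    lo, hi = window
    upstream = -lo
    # window covers offsets lo..hi; sequence index 0 corresponds to offset lo
    seq = extract_window(fasta, site.chrom, site.pos, site.strand,
                         upstream=upstream, downstream=hi + 1)
    if len(seq) < 6:
        return PasCall()
    # truncation at a contig start shifts index->offset mapping
    first_offset = hi + 1 - len(seq)
    best: Optional[tuple[int, int, str]] = None  # (precedence, -offset, hexamer)
    for i in range(len(seq) - 5):
        hexamer = seq[i:i + 6]
        if hexamer not in vocabulary:
            continue
        offset = first_offset + i
        if offset < lo or offset + 5 > hi:
            continue
        key = (vocabulary[hexamer], -offset, hexamer)
        if best is None or key < best:
            best = key
    if best is None:
        return PasCall()
    return PasCall(hexamer=best[2], offset=-best[1])


def annotate_pas(sites: list[CpaSite], fasta: Union[str, Path, Fasta],
                 vocabulary: Optional[dict[str, int]] = None) -> list[CpaSite]:
    if not isinstance(fasta, Fasta):
        fasta = Fasta(str(fasta))
    for s in sites:
        s.pas = call_pas(s, fasta, vocabulary=vocabulary)
    return sites


def pas_frequencies(sites: list[CpaSite], mode: str = "site_frequency",
                    reference_sample: str = "all") -> dict[str, float]:
    """PAS category frequencies across sites.

    ``site_frequency`` weights every site equally regardless of read number;
    ``read_weighted`` weights each site by its read count in
    ``reference_sample`` (``"all"`` = summed over samples), so highly
    expressed sites dominate.
    """
    if mode not in ("site_frequency", "read_weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    if (mode == "read_weighted" and reference_sample != "all"
            and not any(reference_sample in s.counts for s in sites)):
        raise KeyError(f"unknown sample {reference_sample!r}")
    categories = ["AATAAA", "ATTAAA", "variant", "NONE"]
    weights = dict.fromkeys(categories, 0.0)
    for s in sites:
        if mode == "site_frequency":
            w = 1.0
        elif reference_sample == "all":
            w = float(s.total())
        else:
            w = float(s.counts.get(reference_sample, 0))
        weights[s.pas.category] += w
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no weight to normalize (no sites or all-zero counts)")
    return {k: v / total for k, v in weights.items()}


def read_bed6_ends(paths: dict[str, Union[str, Path]]) -> pd.DataFrame:
    """Read per-sample BED6 files of cleavage positions (score = read count).

    Returns the ``chrom,pos,strand,count,sample`` table ``cluster_ends``
    consumes. The BED interval's 5' coordinate on the forward strand is used
    as the cleavage position (intervals are expected to be 1 nt wide).
    """
    frames = []
    for sample, path in sorted(paths.items()):
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "name", "score", "strand"])
        frames.append(pd.DataFrame({
            "chrom": bed.chrom, "pos": bed.start.astype(int),
            "strand": bed.strand, "count": bed.score.astype(int),
            "sample": sample,
        }))
    return pd.concat(frames, ignore_index=True)
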