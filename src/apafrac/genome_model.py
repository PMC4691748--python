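"""Gene-model and sequence handling shared by all pipeline stages.

Coordinates are 0-based half-open on the forward genome strand throughout
(BED-native; GTF/GFF3 are converted on read). Multi-transcript genes are
collapsed to a union-of-exons model, because the downstream isoform-ratio
analysis works per gene, not per transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import pyranges as pr
from pyfaidx import Fasta

logger = logging.getLogger("apafrac")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RegionClass(str, Enum):
    """Region of a gene a position falls in, relative to the 3'-most exon.

    Exactly one class applies per (position, gene) pair: the 3'UTR of the
    3'-most exon, any other exonic position (including the coding part of
    the 3'-most exon), intronic, or outside the gene span.
    """

    UTR3 = "UTR3"
    UPSTREAM_EXON = "UPSTREAM_EXON"
    INTRON = "INTRON"
    INTERGENIC = "INTERGENIC"


@dataclass
class GeneModel:
    """Union-of-exons model of one gene, strand-aware.

    ``exons`` are sorted, non-overlapping half-open intervals on the forward
    strand. ``cds_end`` is the strand-aware end of translation: on ``+`` the
    exclusive end coordinate of the distal-most CDS, on ``-`` the inclusive
    start coordinate of it (i.e. positions downstream in transcription
    direction are 3'UTR). ``None`` means noncoding/unknown, in which case the
    whole 3'-most exon counts as 3'UTR.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        if not exons:
            raise ValueError(f"gene {self.gene_id} has zero exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def three_prime_most_exon(self) -> tuple[int, int]:
        """Strand-aware last exon (leftmost in genome coordinates on '-')."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def annotated_utr3(self) -> tuple[int, int]:
        """3'UTR interval within the 3'-most exon (whole exon if no CDS)."""
        s, e = self.three_prime_most_exon
        if self.cds_end is None:
            return (s, e)
        if self.strand == "+":
            return (min(max(self.cds_end, s), e), e)
        return (s, max(min(self.cds_end, e), s))


def _prevalidate_tab9(path: Union[str, Path]) -> None:
    """Cheap structural check so parse failures report a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}: malformed record at line {lineno}: "
                                 f"expected >=8 tab-separated fields, got {len(fields)}")
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed coordinates at line {lineno}") from exc


def _models_from_feature_frame(df: pd.DataFrame, gene_key: str) -> list[GeneModel]:
    models: list[GeneModel] = []
    exon_df = df[df.Feature == "exon"]
    cds_df = df[df.Feature == "CDS"]
    for gene_id, sub in exon_df.groupby(gene_key, sort=True):
        chrom = str(sub.Chromosome.iloc[0])
        strand = str(sub.Strand.iloc[0])
        ivs = _union_intervals(list(zip(sub.Start.astype(int), sub.End.astype(int))))
        if not ivs:
            logger.warning("gene %s has zero exons; skipped", gene_id)
            continue
        cds_sub = cds_df[cds_df[gene_key] == gene_id]
        cds_end = None
        if len(cds_sub):
            # distal-most CDS boundary over all transcripts of the union model
            cds_end = int(cds_sub.End.max()) if strand == "+" else int(cds_sub.Start.min())
        models.append(GeneModel(str(gene_id), chrom, strand, ivs, cds_end))
    genes_without_exons = set(df[gene_key].unique()) - set(exon_df[gene_key].unique())
    for gid in sorted(genes_without_exons):
        logger.warning("gene %s has zero exons; skipped", gid)
    return models


def _union_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def load_gene_models(annotation_path: Union[str, Path],
                     dialect: str = "gtf") -> list[GeneModel]:
    """Load gene models from GTF, GFF3 or BED12 into union-of-exons form.

    Parameters
    ----------
    annotation_path:
        Path to the annotation file.
    dialect:
        One of ``"gtf"``, ``"gff3"``, ``"bed12"``.

    Returns
    -------
    One :class:`GeneModel` per gene, sorted by gene_id. When a gene has
    multiple transcripts their exons are unioned and the 3'-most exon is the
    strand-aware most-distal exon of the union.
    """
    dialect = dialect.lower()
    if dialect == "gtf":
        _prevalidate_tab9(annotation_path)
        df = pr.read_gtf(str(annotation_path)).df
        if "gene_id" not in df.columns:
            raise ValueError(f"{annotation_path}: GTF records lack gene_id attribute")
        return _models_from_feature_frame(df, "gene_id")
    if dialect == "gff3":
        _prevalidate_tab9(annotation_path)
        df = pr.read_gff3(str(annotation_path)).df
        # map exon Parent (transcript) back to its gene via the transcript rows
        tx = df[df.Feature.isin(["mRNA", "transcript"])]
        parent_of_tx = dict(zip(tx.ID, tx.Parent)) if "ID" in df.columns else {}
        df = df.copy()
        df["gene_key"] = [
            parent_of_tx.get(p, p) for p in df.get("Parent", pd.Series([""] * len(df)))
        ]
        return _models_from_feature_frame(df, "gene_key")
    if dialect == "bed12":
        return _load_bed12(annotation_path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _load_bed12(path: Union[str, Path]) -> list[GeneModel]:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    per_gene: dict[str, dict] = {}
    for _, row in df.iterrows():
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = [(int(row.start) + st, int(row.start) + st + sz)
                 for st, sz in zip(starts, sizes)]
        cds_end = None
        if int(row.thickStart) != int(row.thickEnd):
            cds_end = int(row.thickEnd) if row.strand == "+" else int(row.thickStart)
        entry = per_gene.setdefault(str(row["name"]), {
            "chrom": str(row.chrom), "strand": str(row.strand),
            "exons": [], "cds_end": None})
        entry["exons"].extend(exons)
        if cds_end is not None:
            if entry["cds_end"] is None:
                entry["cds_end"] = cds_end
            else:
                entry["cds_end"] = (max(entry["cds_end"], cds_end)
                                    if row.strand == "+" else min(entry["cds_end"], cds_end))
    models = []
    for gid in sorted(per_gene):
        e = per_gene[gid]
        models.append(GeneModel(gid, e["chrom"], e["strand"],
                                _union_intervals(e["exons"]), e["cds_end"]))
    return models


def classify_position(gene: GeneModel, pos: int, strand: str) -> RegionClass:
    """Classify a genomic position relative to one gene.

    UTR3: inside the 3'-most exon, downstream (in transcription direction) of
    ``cds_end`` — or anywhere in the 3'-most exon if the gene has no CDS.
    UPSTREAM_EXON: any other exonic position. INTRON: between exons.
    INTERGENIC: outside the gene span.
    """
    if strand != gene.strand:
        raise ValueError(
            f"strand {strand} does not match gene {gene.gene_id} ({gene.strand})")
    if pos < gene.start or pos >= gene.end:
        return RegionClass.INTERGENIC
    ts, te = gene.three_prime_most_exon
    if ts <= pos < te:
        if gene.cds_end is None:
            return RegionClass.UTR3
        in_utr = pos >= gene.cds_end if gene.strand == "+" else pos < gene.cds_end
        return RegionClass.UTR3 if in_utr else RegionClass.UPSTREAM_EXON
    for s, e in gene.exons:
        if s <= pos < e:
            return RegionClass.UPSTREAM_EXON
    return RegionClass.INTRON


def extract_window(fasta: Union[str, Path, Fasta], chrom: str, pos: int,
                   strand: str, upstream: int, downstream: int) -> str:
    """Extract a strand-aware sense sequence window around a position.

    ``upstream``/``downstream`` are measured in transcription direction;
    on ``+`` the window is ``[pos-upstream, pos+downstream)``, on ``-`` it is
    the reverse complement of ``[pos+1-downstream, pos+1+upstream)``.
    Windows overlapping contig bounds are truncated, not padded.
    """
    if not isinstance(fasta, Fasta):
        fasta = Fasta(str(fasta))
    if chrom not in fasta:
        raise KeyError(f"unknown chromosome {chrom!r}")
    clen = len(fasta[chrom])
    if strand == "+":
        lo, hi = max(0, pos - upstream), min(clen, pos + downstream)
        return str(fasta[chrom][lo:hi]).upper() if hi > lo else ""
    lo, hi = max(0, pos + 1 - downstream), min(clen, pos + 1 + upstream)
    return reverse_complement(str(fasta[chrom][lo:hi]).upper()) if hi > lo else ""
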