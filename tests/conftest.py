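"""Shared fixtures: tiny on-disk annotation/FASTA files and oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    """Three genes: plus-strand coding, minus-strand coding, and a
    two-transcript gene whose transcripts share exon 1 but differ in their
    last exon (exercises the union-of-exons model)."""
    lines = []

    def rec(chrom, feat, start0, end0, strand, gene, tx):
        attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
        lines.append("\t".join([chrom, "toy", feat, str(start0 + 1), str(end0),
                                ".", strand, ".", attrs]))

    # gPlus: exons (100,200) (300,500); CDS ends at 380
    rec("chr1", "transcript", 100, 500, "+", "gPlus", "gPlus.1")
    rec("chr1", "exon", 100, 200, "+", "gPlus", "gPlus.1")
    rec("chr1", "exon", 300, 500, "+", "gPlus", "gPlus.1")
    rec("chr1", "CDS", 100, 200, "+", "gPlus", "gPlus.1")
    rec("chr1", "CDS", 300, 380, "+", "gPlus", "gPlus.1")
    # gMinus: exons (1000,1200) (1400,1500); 3'-most exon = leftmost;
    # CDS starts (genomically) at 1100 -> UTR3 = (1000,1100)
    rec("chr1", "transcript", 1000, 1500, "-", "gMinus", "gMinus.1")
    rec("chr1", "exon", 1000, 1200, "-", "gMinus", "gMinus.1")
    rec("chr1", "exon", 1400, 1500, "-", "gMinus", "gMinus.1")
    rec("chr1", "CDS", 1100, 1200, "-", "gMinus", "gMinus.1")
    rec("chr1", "CDS", 1400, 1500, "-", "gMinus", "gMinus.1")
    # gUnion: t1 last exon (2300,2400), t2 last exon (2500,2600)
    rec("chr2", "transcript", 2000, 2400, "+", "gUnion", "gUnion.1")
    rec("chr2", "exon", 2000, 2100, "+", "gUnion", "gUnion.1")
    rec("chr2", "exon", 2300, 2400, "+", "gUnion", "gUnion.1")
    rec("chr2", "transcript", 2000, 2600, "+", "gUnion", "gUnion.2")
    rec("chr2", "exon", 2000, 2100, "+", "gUnion", "gUnion.2")
    rec("chr2", "exon", 2500, 2600, "+", "gUnion", "gUnion.2")

    path = tmp_path_factory.mktemp("anno") / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory):
    """A 200-nt contig with a fixed pseudo-random, palindrome-poor sequence."""
    rng = np.random.default_rng(123)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    path = tmp_path_factory.mktemp("fa") / "toy.fa"
    path.write_text(">ctg\n" + "\n".join(seq[i:i + 60]
                                         for i in range(0, len(seq), 60)) + "\n")
    return path, seq


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by full hypergeometric enumeration with
    rational arithmetic — independent of the package implementation."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= p_obs:
            p += pk
    return p
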