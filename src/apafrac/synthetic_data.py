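"""Synthetic 3'-end-seq / RNA-seq generator with a planted ground truth.

Emulates the statistical structure the pipeline assumes about fractionated
3'-end sequencing data: multi-CPA-site genes (by default ~70% of genes carry
two 3'UTR sites, echoing the fraction of human genes with multiple sites),
negative-binomial per-gene read depths, a minority of genes (default 10%)
with a planted nuclear->cytoplasmic shift in proximal-isoform fraction
(directions 3:1 shorter-in-cytoplasm), PAS hexamers written into the genome
sequence upstream of every planted site (highly expressed sites carry the
canonical AATAAA with probability 0.9), marker genes with extreme nuclear
enrichment (MALAT1-like, XIST-like), and piecewise-constant two-isoform
3'UTR coverage for the coverage-APA stage.

Every stochastic operation takes an explicit seed; outputs are byte-stable
for a fixed seed and every emitted gene/site appears exactly once in the
returned truth ledger.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .site_quant import ATTAAA, CANONICAL_PAS, VARIANT_PAS

SAMPLES = ("nuclear", "cytoplasmic", "whole_cell")

_PAS_VOCAB = (CANONICAL_PAS, ATTAAA) + VARIANT_PAS


@dataclass
class SimConfig:
    """Study-condition parameters of the simulation.

    Defaults encode the fractionation setting the pipeline targets: most
    genes multi-site, a 10% minority of APA genes with planted shifts of
    0.08-0.40 in proximal fraction (3:1 biased to shorter-in-cytoplasm),
    overdispersed per-gene depths around 300 reads, and nuclear marker
    transcripts at 50x (MALAT1-like) and 400x (XIST-like) enrichment.
    """

    n_genes: int = 200
    p_multi_site: float = 0.70          # genes with >=2 UTR3 sites
    p_affected: float = 0.10            # of multi-site genes: planted fraction shift
    effect_low: float = 0.08
    effect_high: float = 0.40
    p_shorter: float = 0.75             # planted direction: shorter in cytoplasm
    depth_mean: float = 300.0
    depth_dispersion: float = 0.2       # NB: var = mu + disp*mu^2
    depth_fixed: Optional[int] = None   # overrides NB depth when set
    p_canonical_high: float = 0.9       # major site carries AATAAA
    cr_apa_fraction: float = 0.20       # genes that also carry an intronic site
    base_frac_range: tuple[float, float] = (0.2, 0.8)
    upstream_frac_range: tuple[float, float] = (0.1, 0.35)
    jitter: int = 10                    # read-position scatter around a site (nt)
    coverage_depth: float = 50.0        # mean long+short depth for bedGraph sim
    coverage_noise: bool = True
    pdui_base_range: tuple[float, float] = (0.35, 0.95)
    pdui_effect_range: tuple[float, float] = (0.25, 0.55)
    markers: dict[str, float] = field(
        default_factory=lambda: {"MALAT1": 50.0, "XIST": 400.0})
    marker_depth: int = 5000
    genes_per_chrom: int = 50
    gene_slot: int = 6500               # genomic span reserved per gene

    def validate(self) -> None:
        for name in ("p_multi_site", "p_affected", "p_shorter", "p_canonical_high",
                     "cr_apa_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _random_pas_window(rng: np.random.Generator, hexamer: Optional[str],
                       offset: Optional[int]) -> str:
    """A 40-nt sense window free of PAS hexamers except a planted one."""
    bases = np.array(list("ACGT"))
    for _ in range(200):
        win = list(rng.choice(bases, size=40))
        if hexamer is not None:
            i = offset + 40  # offset -40 -> index 0
            win[i:i + 6] = list(hexamer)
        seq = "".join(win)
        hits = [(j - 40, seq[j:j + 6]) for j in range(35) if seq[j:j + 6] in _PAS_VOCAB]
        if hexamer is None and not hits:
            return seq
        if hexamer is not None and hits == [(offset, hexamer)]:
            return seq
    raise RuntimeError("failed to synthesise a clean PAS window")


def _draw_pas(rng: np.random.Generator, high_expression: bool,
              p_canonical_high: float) -> tuple[str, Optional[int]]:
    """(hexamer or NONE, planted start offset) for one site."""
    if high_expression:
        hexamer = CANONICAL_PAS if rng.random() < p_canonical_high else ATTAAA
    else:
        u = rng.random()
        if u < 0.2:
            hexamer = CANONICAL_PAS
        elif u < 0.4:
            hexamer = ATTAAA
        elif u < 0.8:
            hexamer = str(rng.choice(list(VARIANT_PAS)))
        else:
            return "NONE", None
    return hexamer, int(rng.integers(-30, -16))  # start offset, fits in -40..-1


def simulate_genome(config: SimConfig, seed: int,
                    out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Generate a random genome with planted genes, sites and PAS hexamers.

    Returns the truth ledger; when ``out_dir`` is given also writes
    ``genome.fa`` and ``annotation.gtf`` (plus ``truth.json``).

    Gene layout (in transcription-direction coordinates within a fixed slot):
    2-4 exons, the 3'-most exon 700 nt long with the CDS ending 100 nt in,
    a proximal UTR site ~300 nt into that exon and a distal site 30 nt before
    its end; genes alternate between strands deterministically by index.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_total = config.n_genes + len(config.markers)
    n_chrom = int(np.ceil(n_total / config.genes_per_chrom))
    chrom_len = config.genes_per_chrom * config.gene_slot + 1000
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_seqs = {c: rng.integers(0, 4, size=chrom_len) for c in chrom_names}
    base_map = np.array(list("ACGT"))

    gene_names = [f"G{i:05d}" for i in range(config.n_genes)] + sorted(config.markers)
    truth: dict = {"seed": int(seed), "config": asdict(config), "genes": {},
                   "markers": dict(config.markers), "samples": list(SAMPLES)}

    gtf_lines: list[str] = []
    for gi, gene_id in enumerate(gene_names):
        is_marker = gene_id in config.markers
        chrom = chrom_names[gi // config.genes_per_chrom]
        g0 = (gi % config.genes_per_chrom) * config.gene_slot + 500
        strand = "+" if gi % 2 == 0 else "-"

        n_exons = 2 if is_marker else int(rng.integers(2, 5))
        exon_lens = [int(rng.integers(150, 301)) for _ in range(n_exons - 1)] + [700]
        intron_lens = [int(rng.integers(200, 401)) for _ in range(n_exons - 1)]
        # transcription-direction exon intervals
        tx_exons, u = [], 0
        for k in range(n_exons):
            tx_exons.append((u, u + exon_lens[k]))
            u += exon_lens[k]
            if k < n_exons - 1:
                u += intron_lens[k]
        glen = u
        last_s, last_e = tx_exons[-1]
        cds_end_tx = last_s + 100
        utr_tx = (cds_end_tx, last_e)

        multi = (not is_marker) and rng.random() < config.p_multi_site
        cr = (not is_marker) and n_exons >= 2 and rng.random() < config.cr_apa_fraction

        site_defs = []  # (tx_pos, role, region)
        distal_tx = last_e - 30
        proximal_tx = cds_end_tx + 200
        if multi:
            site_defs.append((proximal_tx, "proximal", "UTR3"))
        site_defs.append((distal_tx, "distal", "UTR3"))
        if cr:
            intron_mid_tx = tx_exons[0][1] + intron_lens[0] // 2
            site_defs.append((intron_mid_tx, "upstream", "INTRON"))

        def tx2gen(utx: int) -> int:
            return g0 + utx if strand == "+" else g0 + glen - 1 - utx

        base_frac = float(rng.uniform(*config.base_frac_range))
        affected = multi and rng.random() < config.p_affected
        effect = 0.0
        if affected:
            mag = float(rng.uniform(config.effect_low, config.effect_high))
            effect = mag if rng.random() < config.p_shorter else -mag
        up_frac = float(rng.uniform(*config.upstream_frac_range)) if cr else 0.0
        cr_affected = cr and rng.random() < config.p_affected
        cr_effect = 0.0
        if cr_affected:
            mag = float(rng.uniform(config.effect_low, config.effect_high))
            cr_effect = mag if rng.random() < config.p_shorter else -mag

        # planted coverage-model truth (UTR two-isoform mixture)
        pdui_nuc = float(rng.uniform(*config.pdui_base_range))
        pdui_cyt = pdui_nuc
        if affected:
            shift = float(rng.uniform(*config.pdui_effect_range))
            pdui_cyt = float(np.clip(pdui_nuc + (-shift if effect > 0 else shift),
                                     0.02, 0.98))
        pdui = {"nuclear": pdui_nuc, "cytoplasmic": pdui_cyt,
                "whole_cell": (pdui_nuc + pdui_cyt) / 2.0}

        sites = []
        for tx_pos, role, region in site_defs:
            if role == "distal":
                major = base_frac <= 0.5 or not multi
            elif role == "proximal":
                major = base_frac > 0.5
            else:
                major = False
            hexamer, offset = _draw_pas(rng, major, config.p_canonical_high)
            if is_marker:
                hexamer, offset = CANONICAL_PAS, -21
            pos = tx2gen(tx_pos)
            win = _random_pas_window(
                rng, None if hexamer == "NONE" else hexamer, offset)
            win_idx = np.array([("ACGT").index(b) for b in win])
            if strand == "+":
                chrom_seqs[chrom][pos - 40:pos] = win_idx
            else:
                comp = 3 - win_idx[::-1]
                chrom_seqs[chrom][pos + 1:pos + 41] = comp
            sites.append(dict(pos=int(pos), tx_pos=int(tx_pos), role=role,
                              region=region, pas=hexamer,
                              pas_offset=None if offset is None else int(offset)))

        exons_genomic = sorted(
            (min(tx2gen(s), tx2gen(e - 1)), max(tx2gen(s), tx2gen(e - 1)) + 1)
            for s, e in tx_exons)
        utr_genomic = (min(tx2gen(utr_tx[0]), tx2gen(utr_tx[1] - 1)),
                       max(tx2gen(utr_tx[0]), tx2gen(utr_tx[1] - 1)) + 1)
        cds_end_gen = tx2gen(cds_end_tx) if strand == "+" else tx2gen(cds_end_tx) + 1
        breakpoint_offset = proximal_tx - utr_tx[0]

        truth["genes"][gene_id] = dict(
            chrom=chrom, strand=strand, exons=[list(e) for e in exons_genomic],
            cds_end=int(cds_end_gen), utr=[int(utr_genomic[0]), int(utr_genomic[1])],
            sites=sites, multi_site=bool(multi), cr=bool(cr),
            is_marker=bool(is_marker),
            affected=bool(affected), effect=float(effect),
            base_frac=base_frac, upstream_frac=up_frac,
            cr_affected=bool(cr_affected), cr_effect=float(cr_effect),
            pdui=pdui, breakpoint_offset=int(breakpoint_offset),
            breakpoint_pos=int(tx2gen(proximal_tx)),
        )

        tx_id = f"{gene_id}.1"
        attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
        gene_start, gene_end = exons_genomic[0][0], exons_genomic[-1][1]
        gtf_lines.append("\t".join([chrom, "sim", "transcript", str(gene_start + 1),
                                    str(gene_end), ".", strand, ".", attrs]))
        for s, e in exons_genomic:
            gtf_lines.append("\t".join([chrom, "sim", "exon", str(s + 1), str(e),
                                        ".", strand, ".", attrs]))
        # CDS: everything upstream (tx direction) of cds_end within each exon
        for s, e in exons_genomic:
            if strand == "+":
                cs, ce = s, min(e, cds_end_gen)
            else:
                cs, ce = max(s, cds_end_gen), e
            if cs < ce:
                gtf_lines.append("\t".join([chrom, "sim", "CDS", str(cs + 1),
                                            str(ce), ".", strand, ".", attrs]))

    truth["chromosomes"] = {c: int(chrom_len) for c in chrom_names}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "genome.fa", "w") as fh:
            for c in chrom_names:
                fh.write(f">{c}\n")
                seq = "".join(base_map[chrom_seqs[c]])
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        with open(out_dir / "annotation.gtf", "w") as fh:
            fh.write("\n".join(gtf_lines) + "\n")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    truth["_sequences"] = {c: "".join(base_map[chrom_seqs[c]]) for c in chrom_names}
    truth["_gtf"] = "\n".join(gtf_lines) + "\n"
    return truth


# ---------------------------------------------------------------------------
# 3'-end read counts
# ---------------------------------------------------------------------------

def _nb_depth(rng: np.random.Generator, config: SimConfig) -> int:
    if config.depth_fixed is not None:
        return int(config.depth_fixed)
    disp = config.depth_dispersion
    mu = config.depth_mean
    if disp <= 0:
        return int(rng.poisson(mu))
    n = 1.0 / disp
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


def _sample_fracs(gene: dict) -> dict[str, float]:
    base, eff = gene["base_frac"], gene["effect"]
    return {"nuclear": base,
            "cytoplasmic": float(np.clip(base + eff, 0.02, 0.98)),
            "whole_cell": float(np.clip(base + eff / 2.0, 0.02, 0.98))}


def _upstream_fracs(gene: dict) -> dict[str, float]:
    base, eff = gene["upstream_frac"], gene["cr_effect"]
    return {"nuclear": base,
            "cytoplasmic": float(np.clip(base + eff, 0.02, 0.98)),
            "whole_cell": float(np.clip(base + eff / 2.0, 0.02, 0.98))}


def simulate_site_counts(truth: dict, seed: int,
                         out_dir: Optional[Union[str, Path]] = None
                         ) -> pd.DataFrame:
    """Draw per-sample 3'-end read positions for every planted site.

    Per gene and sample the total depth is negative-binomial (markers use
    their planted nuclear:cytoplasmic ratios instead); reads are split
    between upstream/proximal/distal sites by the planted fractions and
    their positions jittered up to +-jitter nt around the site, which
    exercises the clustering stage. Zero-depth genes are absent from the
    output. Returns a ``chrom,pos,strand,count,sample`` table; with
    ``out_dir`` also writes one BED6 per sample (score = read count).
    """
    config = SimConfig(**truth["config"])
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, str, int, str]] = []

    for gene_id in sorted(truth["genes"]):
        gene = truth["genes"][gene_id]
        chrom, strand = gene["chrom"], gene["strand"]
        fracs = _sample_fracs(gene)
        up_fracs = _upstream_fracs(gene)
        sites = {s["role"]: s for s in gene["sites"]}
        if gene["is_marker"]:
            ratio = truth["markers"][gene_id]
            depths = {"nuclear": config.marker_depth,
                      "cytoplasmic": max(int(round(config.marker_depth / ratio)), 0)}
            depths["whole_cell"] = (depths["nuclear"] + depths["cytoplasmic"]) // 2
        else:
            depths = {s: _nb_depth(rng, config) for s in SAMPLES}
        for sample in SAMPLES:
            depth = depths[sample]
            if depth <= 0:
                continue
            n_up = rng.binomial(depth, up_fracs[sample]) if "upstream" in sites else 0
            rest = depth - n_up
            if "proximal" in sites:
                n_prox = rng.binomial(rest, fracs[sample])
            else:
                n_prox = 0
            n_dist = rest - n_prox
            for role, n in (("upstream", n_up), ("proximal", n_prox),
                            ("distal", n_dist)):
                if role not in sites or n <= 0:
                    continue
                jit = rng.integers(-config.jitter, config.jitter + 1, size=n)
                pos, cnt = np.unique(sites[role]["pos"] + jit, return_counts=True)
                for p, c in zip(pos, cnt):
                    rows.append((chrom, int(p), strand, int(c), sample))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count", "sample"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample in SAMPLES:
            sub = df[df["sample"] == sample].sort_values(
                ["chrom", "pos", "strand"]).reset_index(drop=True)
            bed = pd.DataFrame({
                "chrom": sub.chrom, "start": sub.pos, "end": sub.pos + 1,
                "name": [f"{sample}_{i}" for i in range(len(sub))],
                "score": sub["count"], "strand": sub.strand})
            bed.to_csv(out_dir / f"ends_{sample}.bed", sep="\t",
                       header=False, index=False)
    return df


# ---------------------------------------------------------------------------
# 3'UTR coverage tracks
# ---------------------------------------------------------------------------

def simulate_coverage(truth: dict, seed: int,
                      out_dir: Optional[Union[str, Path]] = None,
                      samples: tuple[str, ...] = ("nuclear", "cytoplasmic")
                      ) -> dict[str, dict[str, np.ndarray]]:
    """Two-isoform 3'UTR coverage per sample from the planted PDUI truth.

    Per-base mean depth over the UTR (transcription direction, index i) is
    depth * (PDUI + (1-PDUI) * [i < breakpoint]); Poisson noise is added
    when configured. Returns {sample: {gene_id: depth vector (tx order)}};
    with ``out_dir`` also writes one bedGraph per sample.
    """
    config = SimConfig(**truth["config"])
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, np.ndarray]] = {s: {} for s in samples}
    for gene_id in sorted(truth["genes"]):
        gene = truth["genes"][gene_id]
        if gene["is_marker"] or not gene["multi_site"]:
            continue
        us, ue = gene["utr"]
        L = ue - us
        b = gene["breakpoint_offset"]
        for sample in samples:
            pdui = gene["pdui"][sample]
            mean = config.coverage_depth * (
                pdui + (1.0 - pdui) * (np.arange(L) < b))
            depth = (rng.poisson(mean).astype(float) if config.coverage_noise
                     else np.round(mean))
            out[sample][gene_id] = depth
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample in samples:
            lines = []
            for gene_id in sorted(out[sample]):
                gene = truth["genes"][gene_id]
                us, ue = gene["utr"]
                v = out[sample][gene_id]
                genomic = v if gene["strand"] == "+" else v[::-1]
                run_start = 0
                for i in range(1, len(genomic) + 1):
                    if i == len(genomic) or genomic[i] != genomic[run_start]:
                        lines.append(f"{gene['chrom']}\t{us + run_start}\t{us + i}"
                                     f"\t{genomic[run_start]:g}")
                        run_start = i
            with open(out_dir / f"coverage_{sample}.bedgraph", "w") as fh:
                fh.write("\n".join(lines) + "\n")
    return out


def simulate_all(config: SimConfig, seed: int,
                 out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Convenience wrapper: genome + site counts + coverage, one seed.

    Sub-seeds are derived deterministically (and kept below 2**31).
    """
    s_genome, s_counts, s_cov = (int(x) for x in
                                 np.random.default_rng(seed).integers(0, 2**31, 3))
    truth = simulate_genome(config, s_genome, out_dir=out_dir)
    counts = simulate_site_counts(truth, s_counts, out_dir=out_dir)
    coverage = simulate_coverage(truth, s_cov, out_dir=out_dir)
    truth["_counts"] = counts
    truth["_coverage"] = coverage
    return truth
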