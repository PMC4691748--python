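"""End-to-end orchestration on simulated or on-disk inputs.

Runs the full analysis in the order the method proceeds: gene models ->
site clustering/assignment/PAS annotation -> PAS frequency tables ->
UTR-APA and CR-APA differential tests (cytoplasmic vs nuclear, whole-cell
vs nuclear) -> depth-controlled robustness test -> coverage-based dPDUI with
annotation validation -> fraction QC, sample similarity and comparison
overlap. All result tables are written as TSV/JSON with stable formatting,
so a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import apa_test, coverage_apa, qc_overlap, site_quant, synthetic_data
from .genome_model import load_gene_models

logger = logging.getLogger("apafrac")

FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def gene_expression(sites: list[site_quant.CpaSite]) -> pd.DataFrame:
    """Gene x sample total read counts from assigned CPA sites."""
    rows: dict[str, dict[str, int]] = {}
    for s in sites:
        if not s.gene_id:
            continue
        acc = rows.setdefault(s.gene_id, {})
        for sample, c in s.counts.items():
            acc[sample] = acc.get(sample, 0) + c
    return pd.DataFrame(rows).T.fillna(0).astype(int).sort_index()


def utr_apa_between(sites_by_gene: dict[str, list[site_quant.CpaSite]],
                    sample_a: str, sample_b: str,
                    alpha: float = 0.01, min_change: float = 0.05
                    ) -> pd.DataFrame:
    pairs = []
    for gene_id in sorted(sites_by_gene):
        pair = apa_test.top_two_utr_isoforms(
            sites_by_gene[gene_id], ranking_samples=[sample_a, sample_b],
            sample_a=sample_a, sample_b=sample_b)
        if pair is not None:
            pairs.append(pair)
    return apa_test.test_utr_apa(pairs, alpha=alpha, min_change=min_change)


def group_sites_by_gene(sites: list[site_quant.CpaSite]
                        ) -> dict[str, list[site_quant.CpaSite]]:
    out: dict[str, list[site_quant.CpaSite]] = {}
    for s in sites:
        if s.gene_id:
            out.setdefault(s.gene_id, []).append(s)
    return out


def run_pipeline(config: Optional[synthetic_data.SimConfig], seed: int,
                 out_dir: Union[str, Path],
                 cluster_window: int = 24) -> dict:
    """Simulate inputs and run every analysis stage, writing results to disk.

    Returns a dict of the in-memory result tables. Deterministic for a
    fixed (config, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = synthetic_data.SimConfig()
    synthetic_data.simulate_all(config, seed, out_dir=out_dir)

    # --- site quantification from the generated files ---------------------
    models = load_gene_models(out_dir / "annotation.gtf", dialect="gtf")
    end_paths = {s: out_dir / f"ends_{s}.bed" for s in synthetic_data.SAMPLES}
    ends = site_quant.read_bed6_ends(end_paths)
    sites = site_quant.cluster_ends(ends, window=cluster_window)
    sites = site_quant.assign_sites(sites, models)
    fasta = Fasta(str(out_dir / "genome.fa"))
    sites = site_quant.annotate_pas(sites, fasta)
    site_table = site_quant.sites_to_frame(sites)
    _write(site_table, out_dir / "sites.tsv")

    pas_tables = {
        "site_frequency": site_quant.pas_frequencies(sites, "site_frequency"),
        "read_weighted": site_quant.pas_frequencies(
            sites, "read_weighted", reference_sample="whole_cell"),
    }
    with open(out_dir / "pas_frequencies.json", "w") as fh:
        json.dump(pas_tables, fh, indent=1, sort_keys=True)

    # --- differential representation tests --------------------------------
    by_gene = group_sites_by_gene(sites)
    utr_cyt = utr_apa_between(by_gene, "nuclear", "cytoplasmic")
    utr_whole = utr_apa_between(by_gene, "nuclear", "whole_cell")
    cr_cyt = apa_test.test_cr_apa(by_gene, "nuclear", "cytoplasmic")
    _write(utr_cyt, out_dir / "utr_apa_cyt_vs_nuc.tsv")
    _write(utr_whole, out_dir / "utr_apa_whole_vs_nuc.tsv")
    _write(cr_cyt, out_dir / "cr_apa_cyt_vs_nuc.tsv")

    saap_counts = saap_counts_from_sites(by_gene, "nuclear", "cytoplasmic")
    saap = (apa_test.saap_test(
        saap_counts, fraction_a="nuclear", fraction_b="cytoplasmic",
        seed=int(np.random.default_rng(seed).integers(2**31)))
        if len(saap_counts) else pd.DataFrame())
    _write(saap, out_dir / "saap_cyt_vs_nuc.tsv")

    # --- coverage-based dPDUI ---------------------------------------------
    known = site_table[site_table.region == "UTR3"]
    known_bed = pd.DataFrame({
        "chrom": known.chrom, "start": known.pos, "end": known.pos + 1,
        "name": known.site_id, "score": 0, "strand": known.strand})
    _write(known_bed, out_dir / "known_sites.bed")
    fits = []
    bedgraphs = {s: coverage_apa.read_bedgraph(out_dir / f"coverage_{s}.bedgraph")
                 for s in ("nuclear", "cytoplasmic")}
    for model in models:
        us, ue = model.annotated_utr3
        tracks = [coverage_apa.coverage_for_utr(
            bedgraphs[s], model.gene_id, model.chrom, us, ue, model.strand, s)
            for s in ("nuclear", "cytoplasmic")]
        fit = coverage_apa.fit_two_isoform_model(tracks)
        if fit is not None:
            fits.append(fit)
    pdui = coverage_apa.delta_pdui_test(fits, "nuclear", "cytoplasmic")
    pdui = (coverage_apa.annotate_validation(pdui, known_bed)
            if len(pdui) else pdui)
    _write(pdui, out_dir / "pdui_cyt_vs_nuc.tsv")

    # --- QC, similarity, overlap ------------------------------------------
    expr = gene_expression(sites)
    qc = qc_overlap.marker_enrichment(expr, nuclear_id="nuclear",
                                      cyto_id="cytoplasmic")
    with open(out_dir / "qc.json", "w") as fh:
        json.dump({"fold_enrichment": qc.fold_enrichment,
                   "thresholds": qc.thresholds,
                   "marker_pass": qc.marker_pass, "pass": qc.passed},
                  fh, indent=1, sort_keys=True)

    counts_mat = site_table.set_index("site_id")[
        [c for c in site_table.columns if c.startswith("count_")]]
    counts_mat.columns = [c.removeprefix("count_") for c in counts_mat.columns]
    corr, newick = qc_overlap.sample_similarity(counts_mat)
    corr.round(6).to_csv(out_dir / "sample_similarity.tsv", sep="\t")
    (out_dir / "dendrogram.newick").write_text(newick + "\n")

    event_sets = {
        "cyt_vs_nuc": events_from_results(utr_cyt),
        "whole_vs_nuc": events_from_results(utr_whole),
    }
    if all(event_sets.values()):
        overlap = qc_overlap.cross_overlap(event_sets)
        _write(qc_overlap.overlap_profile(overlap), out_dir / "overlap.tsv")
    else:
        overlap = pd.DataFrame()
        _write(overlap, out_dir / "overlap.tsv")

    return dict(sites=site_table, pas_tables=pas_tables, utr_cyt=utr_cyt,
                utr_whole=utr_whole, cr_cyt=cr_cyt, saap=saap, pdui=pdui,
                qc=qc, similarity=corr, newick=newick, overlap=overlap)


def saap_counts_from_sites(by_gene: dict[str, list[site_quant.CpaSite]],
                           sample_a: str, sample_b: str) -> pd.DataFrame:
    """Long proximal/distal count table for the depth-controlled test."""
    rows = []
    for gene_id in sorted(by_gene):
        pair = apa_test.top_two_utr_isoforms(
            by_gene[gene_id], ranking_samples=[sample_a, sample_b],
            sample_a=sample_a, sample_b=sample_b)
        if pair is None:
            continue
        rows.append(dict(gene_id=gene_id, library=f"lib_{sample_a}",
                         fraction=sample_a, proximal=pair.counts_a[0],
                         distal=pair.counts_a[1]))
        rows.append(dict(gene_id=gene_id, library=f"lib_{sample_b}",
                         fraction=sample_b, proximal=pair.counts_b[0],
                         distal=pair.counts_b[1]))
    return pd.DataFrame(rows)


def events_from_results(results: pd.DataFrame) -> dict[str, str]:
    """gene -> direction map of significant calls from a results table."""
    sig = results[results["call"] != apa_test.UNCHANGED]
    return dict(zip(sig["gene_id"], sig["call"]))
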