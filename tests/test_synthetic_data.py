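"""Determinism, round-trip consistency and truth-ledger completeness of the
synthetic-data generator."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from apafrac.genome_model import load_gene_models
from apafrac.qc_overlap import marker_enrichment
from apafrac.site_quant import CpaSite, call_pas
from apafrac.synthetic_data import (SAMPLES, SimConfig, simulate_all,
                                    simulate_coverage, simulate_genome,
                                    simulate_site_counts)

CFG = SimConfig(n_genes=40)


@pytest.fixture(scope="module")
def simdir(tmp_path_factory):
    d = tmp_path_factory.mktemp("sim")
    truth = simulate_all(CFG, seed=101, out_dir=d)
    return d, truth


class TestDeterminism:
    def test_rerun_is_byte_identical(self, simdir, tmp_path_factory):
        d1, _ = simdir
        d2 = tmp_path_factory.mktemp("sim2")
        simulate_all(SimConfig(n_genes=40), seed=101, out_dir=d2)
        files = ["genome.fa", "annotation.gtf", "truth.json",
                 "ends_nuclear.bed", "ends_cytoplasmic.bed",
                 "coverage_nuclear.bedgraph"]
        for name in files:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_different_seed_changes_counts(self, simdir):
        _, truth = simdir
        c1 = simulate_site_counts(truth, seed=1)
        c2 = simulate_site_counts(truth, seed=2)
        assert not c1.equals(c2)


class TestGenomeRoundTrip:
    def test_planted_pas_recovered_by_caller(self, simdir):
        """call_pas on the generated FASTA returns exactly the planted
        hexamer and offset for every site, on both strands."""
        d, truth = simdir
        fasta = Fasta(str(d / "genome.fa"))
        checked = 0
        for gene_id, gene in truth["genes"].items():
            for s in gene["sites"]:
                site = CpaSite("x", gene["chrom"], s["pos"], gene["strand"],
                               counts={"a": 1})
                got = call_pas(site, fasta)
                if s["pas"] == "NONE":
                    assert got.hexamer == "NONE"
                else:
                    assert (got.hexamer, got.offset) == (s["pas"], s["pas_offset"])
                checked += 1
        assert checked > 50

    def test_gtf_reproduces_planted_gene_structure(self, simdir):
        d, truth = simdir
        models = {g.gene_id: g for g in load_gene_models(d / "annotation.gtf")}
        assert set(models) == set(truth["genes"])
        for gene_id, gene in truth["genes"].items():
            m = models[gene_id]
            assert [list(e) for e in m.exons] == gene["exons"]
            assert m.strand == gene["strand"]
            assert m.cds_end == gene["cds_end"]
            assert list(m.annotated_utr3) == gene["utr"]

    def test_minus_strand_pas_only_on_sense_strand(self, simdir):
        d, truth = simdir
        fasta = Fasta(str(d / "genome.fa"))
        minus = [(g, s) for g in truth["genes"].values() if g["strand"] == "-"
                 for s in g["sites"] if s["pas"] == "AATAAA"]
        assert minus
        gene, s = minus[0]
        sense = call_pas(CpaSite("x", gene["chrom"], s["pos"], "-",
                                 counts={"a": 1}), fasta)
        anti = call_pas(CpaSite("x", gene["chrom"], s["pos"], "+",
                                counts={"a": 1}), fasta)
        assert sense.hexamer == "AATAAA"
        assert anti.hexamer != "AATAAA"


class TestSiteCounts:
    def test_truth_ledger_covers_every_emitted_position(self, simdir):
        """Every read position traces to exactly one planted site."""
        _, truth = simdir
        counts = simulate_site_counts(truth, seed=5)
        site_pos = {}
        for gene in truth["genes"].values():
            for s in gene["sites"]:
                site_pos.setdefault((gene["chrom"], gene["strand"]), []).append(
                    s["pos"])
        jit = CFG.jitter
        for (chrom, pos, strand), _ in counts.groupby(["chrom", "pos", "strand"]):
            near = [p for p in site_pos.get((chrom, strand), [])
                    if abs(p - pos) <= jit]
            assert len(near) == 1

    def test_zero_depth_genes_absent(self, simdir):
        _, truth = simdir
        cfg = SimConfig(**{**truth["config"], "depth_fixed": 0})
        t2 = dict(truth, config=cfg.__dict__)
        counts = simulate_site_counts(t2, seed=5)
        # only marker genes (which use their fixed marker depth) emit reads
        for gene_id, g in truth["genes"].items():
            if not g["is_marker"]:
                for s in g["sites"]:
                    assert not ((counts.chrom == g["chrom"])
                                & (abs(counts.pos - s["pos"]) <= CFG.jitter)
                                & (counts.strand == g["strand"])).any()

    def test_marker_genes_pass_their_own_qc(self, simdir):
        _, truth = simdir
        counts = simulate_site_counts(truth, seed=5)
        expr = {}
        for gene_id in truth["markers"]:
            g = truth["genes"][gene_id]
            sel = counts[(counts.chrom == g["chrom"])
                         & (counts.strand == g["strand"])
                         & (counts.pos.between(g["sites"][0]["pos"] - 20,
                                               g["sites"][0]["pos"] + 20))]
            expr[gene_id] = sel.groupby("sample")["count"].sum()
        table = pd.DataFrame(expr).T.fillna(0)
        report = marker_enrichment(table, nuclear_id="nuclear",
                                   cyto_id="cytoplasmic")
        assert report.passed

    def test_planted_shift_visible_in_cytoplasmic_fraction(self):
        cfg = SimConfig(n_genes=30, p_affected=1.0, p_shorter=1.0,
                        effect_low=0.3, effect_high=0.3, depth_fixed=1000,
                        p_multi_site=1.0)
        truth = simulate_genome(cfg, seed=7)
        counts = simulate_site_counts(truth, seed=8)
        for gene_id, g in truth["genes"].items():
            if g["is_marker"] or not g["affected"]:
                continue
            prox = next(s for s in g["sites"] if s["role"] == "proximal")
            frac = {}
            for sample in ("nuclear", "cytoplasmic"):
                sub = counts[(counts["sample"] == sample)
                             & (counts.chrom == g["chrom"])
                             & (counts.strand == g["strand"])]
                near = sub[abs(sub.pos - prox["pos"]) <= cfg.jitter]["count"].sum()
                total = sum(
                    sub[abs(sub.pos - s["pos"]) <= cfg.jitter]["count"].sum()
                    for s in g["sites"] if s["region"] == "UTR3")
                frac[sample] = near / total
            assert frac["cytoplasmic"] > frac["nuclear"]


class TestCoverage:
    def test_full_distal_usage_gives_flat_track(self, simdir):
        _, truth = simdir
        t2 = json.loads(json.dumps({k: v for k, v in truth.items()
                                    if not k.startswith("_")}))
        t2["config"]["coverage_noise"] = False
        for g in t2["genes"].values():
            g["pdui"] = {s: 1.0 for s in SAMPLES}
        cov = simulate_coverage(t2, seed=1)
        for vec in cov["nuclear"].values():
            assert len(np.unique(vec)) == 1

    def test_noiseless_step_matches_planted_pdui(self, simdir):
        _, truth = simdir
        t2 = json.loads(json.dumps({k: v for k, v in truth.items()
                                    if not k.startswith("_")}))
        t2["config"]["coverage_noise"] = False
        cov = simulate_coverage(t2, seed=1)
        depth = t2["config"]["coverage_depth"]
        for gene_id, vec in cov["cytoplasmic"].items():
            g = t2["genes"][gene_id]
            b = g["breakpoint_offset"]
            pdui = g["pdui"]["cytoplasmic"]
            assert vec[0] == pytest.approx(depth, abs=0.5 + 1e-9)
            assert vec[-1] == pytest.approx(depth * pdui, abs=0.5 + 1e-9)
            assert (vec[:b] >= vec[b:].max() - 1e-9).all()
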