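"""Fisher machinery, isoform-pair selection, calls, FDR and the
depth-controlled robustness test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from apafrac.apa_test import (LONGER_IN_B, SHORTER_IN_B, UNCHANGED, IsoformPair,
                              bh_fdr, fisher_exact_2x2, saap_test,
                              top_two_utr_isoforms)
# aliased so pytest does not collect the library functions as tests
from apafrac.apa_test import test_cr_apa as run_cr_apa
from apafrac.apa_test import test_utr_apa as run_utr_apa
from apafrac.genome_model import RegionClass
from apafrac.site_quant import CpaSite

from conftest import fisher_oracle


def utr_site(site_id, pos, counts, strand="+", region=RegionClass.UTR3):
    return CpaSite(site_id, "c", pos, strand, counts=counts, gene_id="g",
                   region=region)


class TestFisherExact:
    def test_perfect_independence_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_extreme_table_matches_enumeration(self):
        # only the two diagonal-extreme tables are as improbable: 2/C(20,10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2 / 184756, abs=1e-12)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_row_swap_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 40, 4)
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                fisher_exact_2x2([[c, d], [a, b]]), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        """Independent library cross-check on random tables."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, 4))
            ours = fisher_exact_2x2([[a, b], [c, d]])
            theirs = scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)

    def test_matches_exact_rational_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                float(fisher_oracle(a, b, c, d)), abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    @given(st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_p_in_unit_interval_and_column_swap_symmetric(self, a, b, c, d):
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(fisher_exact_2x2([[b, a], [d, c]]), abs=1e-12)


class TestTopTwoIsoforms:
    def test_two_highest_ranked_sites_selected(self):
        sites = [utr_site("s1", 100, {"a": 60, "b": 40}),
                 utr_site("s2", 300, {"a": 50, "b": 30}),
                 utr_site("s3", 500, {"a": 3, "b": 2})]
        pair = top_two_utr_isoforms(sites, ["a", "b"], "a", "b")
        assert (pair.proximal_site_id, pair.distal_site_id) == ("s1", "s2")
        assert pair.counts_a == (60, 50)

    def test_tie_for_second_place_prefers_proximal(self):
        sites = [utr_site("s1", 100, {"a": 100}),
                 utr_site("s2", 300, {"a": 10}),
                 utr_site("s3", 500, {"a": 10})]
        pair = top_two_utr_isoforms(sites, ["a"], "a", "b")
        assert pair.distal_site_id == "s2"

    def test_minus_strand_proximal_is_rightmost(self):
        sites = [utr_site("s1", 100, {"a": 50}, strand="-"),
                 utr_site("s2", 300, {"a": 60}, strand="-")]
        pair = top_two_utr_isoforms(sites, ["a"], "a", "b")
        assert pair.proximal_site_id == "s2"

    def test_fewer_than_two_expressed_utr_sites_excluded(self):
        sites = [utr_site("s1", 100, {"a": 50}),
                 utr_site("s2", 300, {"a": 0, "b": 0}),
                 utr_site("s3", 500, {"a": 9}, region=RegionClass.INTRON)]
        assert top_two_utr_isoforms(sites, ["a", "b"], "a", "b") is None

    def test_matches_brute_force_sort_and_take_two(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = rng.integers(2, 8)
            sites = [utr_site(f"s{i}", int(100 + 100 * i),
                              {"a": int(rng.integers(1, 50)),
                               "b": int(rng.integers(1, 50))})
                     for i in range(n)]
            pair = top_two_utr_isoforms(sites, ["a", "b"], "a", "b")
            ranked = sorted(sites, key=lambda s: (-(s.counts["a"] + s.counts["b"]),
                                                  s.pos))
            expect = {ranked[0].site_id, ranked[1].site_id}
            assert {pair.proximal_site_id, pair.distal_site_id} == expect


class TestUtrApa:
    def pair(self, ca, cb):
        return IsoformPair("g", "p", "d", ca, cb)

    def test_planted_shift_called_shorter_with_oracle_p(self):
        res = run_utr_apa([self.pair((50, 50), (80, 20))])
        row = res.iloc[0]
        assert row.delta == pytest.approx(0.30)
        assert row.p_value == pytest.approx(
            float(fisher_oracle(50, 50, 80, 20)), abs=1e-12)
        assert row.p_value == pytest.approx(1.3889170690330085e-05, abs=1e-12)
        assert row.call == SHORTER_IN_B

    def test_identical_counts_unchanged(self):
        res = run_utr_apa([self.pair((40, 60), (40, 60))])
        assert res.iloc[0].delta == 0.0
        assert res.iloc[0].call == UNCHANGED

    def test_small_change_below_threshold_unchanged(self):
        res = run_utr_apa([self.pair((52, 48), (50, 50))])
        assert abs(res.iloc[0].delta) < 0.05
        assert res.iloc[0].call == UNCHANGED

    def test_zero_total_flagged_low_coverage(self):
        res = run_utr_apa([self.pair((0, 0), (10, 10))])
        assert res.iloc[0].low_coverage
        assert res.iloc[0].p_value == 1.0
        assert res.iloc[0].call == UNCHANGED

    def test_swapping_samples_mirrors_delta_and_call(self):
        fwd = run_utr_apa([self.pair((50, 50), (80, 20))]).iloc[0]
        rev = run_utr_apa([self.pair((80, 20), (50, 50))]).iloc[0]
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
        assert fwd.delta == pytest.approx(-rev.delta)
        assert (fwd.call, rev.call) == (SHORTER_IN_B, LONGER_IN_B)


class TestCrApa:
    def gene(self, up_a, utr_a, up_b, utr_b):
        return {"g": [
            CpaSite("u", "c", 100, "+", counts={"a": up_a, "b": up_b},
                    gene_id="g", region=RegionClass.INTRON),
            CpaSite("t", "c", 900, "+", counts={"a": utr_a, "b": utr_b},
                    gene_id="g", region=RegionClass.UTR3)]}

    def test_upstream_shift_called_shorter(self):
        res = run_cr_apa(self.gene(30, 70, 60, 40), "a", "b")
        assert res.iloc[0].call == SHORTER_IN_B
        assert res.iloc[0].p_value == pytest.approx(
            float(fisher_oracle(30, 70, 60, 40)), abs=1e-12)

    def test_gene_without_upstream_sites_skipped(self):
        sites = {"g": [CpaSite("t", "c", 900, "+", counts={"a": 5, "b": 5},
                               gene_id="g", region=RegionClass.UTR3)]}
        assert len(run_cr_apa(sites, "a", "b")) == 0


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q, reject = bh_fdr([0.01, 0.02, 0.9], q=0.1)
        assert list(reject) == [True, True, False]
        assert q[0] == pytest.approx(0.03)
        assert q[1] == pytest.approx(0.03)
        assert q[2] == pytest.approx(0.9)

    def test_all_ones_reject_nothing(self):
        _, reject = bh_fdr([1.0, 1.0, 1.0], q=0.1)
        assert not reject.any()

    def test_single_p(self):
        q, reject = bh_fdr([0.04], q=0.05)
        assert reject[0] and q[0] == pytest.approx(0.04)

    def test_empty_input(self):
        q, reject = bh_fdr([], q=0.1)
        assert len(q) == 0 and len(reject) == 0


def saap_counts(n_null, effect_genes, depth, seed):
    """Two-library (nuclear/cytoplasmic) count table with planted shifts."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_null + len(effect_genes)):
        base = rng.uniform(0.3, 0.7)
        shift = effect_genes[i - n_null] if i >= n_null else 0.0
        pa = rng.binomial(depth, base)
        pb = rng.binomial(depth, np.clip(base + shift, 0.02, 0.98))
        rows.append(dict(gene_id=f"g{i:04d}", library="nuc", fraction="A",
                         proximal=pa, distal=depth - pa))
        rows.append(dict(gene_id=f"g{i:04d}", library="cyt", fraction="B",
                         proximal=pb, distal=depth - pb))
    return pd.DataFrame(rows)


class TestSaap:
    def test_fixed_seed_is_deterministic(self):
        counts = saap_counts(30, [0.3], 500, seed=1)
        r1 = saap_test(counts, n_subsample=1, seed=9)
        r2 = saap_test(counts, n_subsample=1, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_shift_rejected_with_correct_sign(self):
        counts = saap_counts(100, [0.30], 500, seed=2)
        res = saap_test(counts, n_subsample=20, fdr=0.10, seed=3)
        planted = res[res.gene_id == "g0100"].iloc[0]
        assert planted.call == SHORTER_IN_B
        assert planted.stat_mean > 0
        assert planted.stat_sd >= 0

    def test_null_rejection_rate_within_fdr(self):
        counts = saap_counts(300, [], 400, seed=4)
        res = saap_test(counts, n_subsample=5, fdr=0.10, seed=5)
        assert (res.call != UNCHANGED).mean() <= 0.10 + 3 * np.sqrt(
            0.10 * 0.90 / 300)

    def test_too_shallow_library_fails(self):
        counts = saap_counts(2, [], 10, seed=6)
        with pytest.raises(ValueError, match="too few"):
            saap_test(counts, seed=7)
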