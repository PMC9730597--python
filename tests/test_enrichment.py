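"""Permutation enrichment and the count-based marker-set GWAS test."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from regevo import Genome, RegionSet
from regevo.enrichment import (
    count_based_gwas_test,
    hypergeom_upper_tail,
    inside_outside_pvalues,
    permutation_enrichment,
    snp_density_profile,
)
from regevo.simulate import SimulationConfig, simulate_gwas

from conftest import make_regions


def enumeration_tail(t, n, k, c):
    """Oracle: P(X >= t) by direct summation of the hypergeometric pmf."""
    denom = comb(n, c)
    total = 0
    for x in range(t, min(k, c) + 1):
        if c - x <= n - k:
            total += comb(k, x) * comb(n - k, c - x)
    return total / denom


def snp_table(positions, pvalues, chrom="chr1"):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "pvalue": pvalues,
        }
    )


class TestHypergeometricTail:
    def test_worked_case(self):
        # N=10, K=5, c=4, T=3 -> [C(5,3)C(5,1)+C(5,4)C(5,0)]/C(10,4) = 55/210
        assert hypergeom_upper_tail(3, 10, 5, 4) == pytest.approx(55 / 210, abs=1e-12)

    def test_full_lattice_against_enumeration(self):
        for n in range(1, 13):
            for k in range(0, n + 1):
                for c in range(0, n + 1):
                    for t in range(0, min(k, c) + 1):
                        assert hypergeom_upper_tail(t, n, k, c) == pytest.approx(
                            enumeration_tail(t, n, k, c), abs=1e-12
                        )


class TestCountBasedGwasTest:
    genome = Genome("g", {"chr1": 100_000})

    def test_strict_inequality_fixture(self):
        # in-region p-values {0.001, 0.009999, 0.01, 0.5} -> T_count = 2
        gwas = snp_table(
            [100, 200, 300, 400, 50_000, 60_000],
            [0.001, 0.009999, 0.01, 0.5, 0.5, 0.5],
        )
        regions = make_regions([("chr1", 0, 1000)], self.genome)
        r = count_based_gwas_test(gwas, regions, window=0)
        assert r.n_snps_in_set == 4
        assert r.t_count == 2

    def test_worked_hypergeometric_via_snp_table(self):
        # N=10 SNPs, K=5 below cutoff, c=4 in region, T=3 of them significant
        pos = [10, 20, 30, 40, 1000, 1100, 1200, 1300, 1400, 1500]
        pvals = [0.001, 0.002, 0.003, 0.5, 0.004, 0.005, 0.9, 0.9, 0.9, 0.9]
        gwas = snp_table(pos, pvals)
        regions = make_regions([("chr1", 0, 100)], self.genome)
        r = count_based_gwas_test(gwas, regions, window=0)
        assert (r.n_total, r.k_genomewide, r.n_snps_in_set, r.t_count) == (10, 5, 4, 3)
        assert r.pvalue == pytest.approx(55 / 210, abs=1e-12)

    def test_window_widens_membership(self):
        gwas = snp_table([100, 5000], [0.001, 0.001])
        regions = make_regions([("chr1", 0, 1000)], self.genome)
        r0 = count_based_gwas_test(gwas, regions, window=0)
        r1 = count_based_gwas_test(gwas, regions, window=4500)
        assert r0.t_count == 1 and r1.t_count == 2

    def test_t_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        gwas = snp_table(rng.integers(0, 100_000, 500), rng.uniform(size=500))
        regions = make_regions([("chr1", 20_000, 60_000)], self.genome)
        ts = [count_based_gwas_test(gwas, regions, window=0, t_o=t).t_count
              for t in (0.001, 0.01, 0.1)]
        assert ts == sorted(ts)

    def test_empty_region_warns_p_one(self):
        gwas = snp_table([100], [0.5])
        regions = make_regions([("chr1", 90_000, 95_000)], self.genome)
        with pytest.warns(UserWarning, match="no SNPs"):
            r = count_based_gwas_test(gwas, regions, window=0)
        assert r.pvalue == 1.0

    def test_bad_cutoff_rejected(self):
        gwas = snp_table([100], [0.5])
        with pytest.raises(ValueError, match="t_o"):
            count_based_gwas_test(gwas, make_regions([("chr1", 0, 10)]), t_o=1.5)

    def test_null_type_one_error_calibrated(self):
        # uniform p-values; random region sets covering a large genome share
        cfg = SimulationConfig(seed=5, n_snps=10_000, gwas_effect=1.0)
        g = cfg.genome("cattle")
        gwas, _ = simulate_gwas(cfg, make_regions([("chr1", 0, 1000)], g), genome=g)
        rng = np.random.default_rng(17)
        n_sets = 150
        rej = 0
        for _ in range(n_sets):
            n_reg = rng.integers(300, 800)
            lens = rng.integers(20_000, 80_000, n_reg)
            chroms = [f"chr{c + 1}" for c in rng.integers(0, cfg.n_chroms, n_reg)]
            starts = [int(rng.integers(0, cfg.chrom_length - L)) for L in lens]
            rs = RegionSet(pd.DataFrame(
                {"chrom": chroms, "start": starts, "end": np.array(starts) + lens}), g)
            rej += count_based_gwas_test(gwas, rs, window=0).pvalue < 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_sets)
        assert abs(rej / n_sets - 0.05) <= half + 0.01

    def test_planted_enrichment_detected(self):
        cfg = SimulationConfig(seed=6, n_snps=100_000, gwas_effect=5.0)
        g = cfg.genome("cattle")
        rng = np.random.default_rng(2)
        chroms = [f"chr{c + 1}" for c in rng.integers(0, cfg.n_chroms, 100)]
        starts = rng.integers(0, cfg.chrom_length - 4000, 100)
        planted = RegionSet(pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + 4000}), g)
        gwas, _ = simulate_gwas(cfg, planted, genome=g)
        r = count_based_gwas_test(gwas, planted, window=0)
        assert r.significant
        assert r.pvalue < 1e-5


class TestPermutationEnrichment:
    def test_whole_genome_tiling_fold_one(self):
        g = Genome("t", {"chr1": 10_000})
        tiling = make_regions([("chr1", i * 100, (i + 1) * 100) for i in range(100)], g)
        r = permutation_enrichment(tiling, tiling, g, n_perm=20, seed=0)
        assert r.fold == pytest.approx(1.0)

    def test_empirical_p_floor(self):
        # query sits exactly on the only annotated island; nulls rarely hit it
        g = Genome("t", {"chr1": 1_000_000})
        ann = make_regions([("chr1", 0, 200)], g)
        query = make_regions([("chr1", 0, 100), ("chr1", 100, 200)], g)
        r = permutation_enrichment(query, ann, g, n_perm=999, seed=1)
        assert r.p_empirical == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self, genome, random_regions):
        q = random_regions(50, seed=1)
        a = random_regions(80, seed=2)
        r1 = permutation_enrichment(q, a, genome, n_perm=50, seed=9)
        r2 = permutation_enrichment(q, a, genome, n_perm=50, seed=9)
        assert r1 == r2

    def test_planted_overlap_enriched(self):
        g = Genome("t", {"chr1": 1_000_000})
        rng = np.random.default_rng(3)
        ann_starts = rng.choice(np.arange(0, 990_000, 10_000), 30, replace=False)
        ann = make_regions([("chr1", int(s), int(s) + 2000) for s in ann_starts], g)
        # place most query regions inside annotation
        q_starts = list(ann_starts[:25]) + list(rng.integers(0, 999_000, 15))
        q = make_regions([("chr1", int(s), int(s) + 500) for s in q_starts], g)
        r = permutation_enrichment(q, ann, g, n_perm=500, seed=4)
        assert r.fold > 1.5
        assert r.p_empirical <= 0.01

    def test_empty_annotation_warns(self, genome):
        q = make_regions([("chr1", 0, 100)], genome)
        empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]), genome)
        with pytest.warns(UserWarning, match="empty annotation"):
            r = permutation_enrichment(q, empty, genome, n_perm=10, seed=0)
        assert np.isnan(r.fold)


class TestSnpDensityProfile:
    def test_all_snps_inside(self):
        g = Genome("t", {"chr1": 10_000})
        res = make_regions([("chr1", 0, 1000)], g)
        gwas = snp_table([10, 500, 900], [0.5, 0.5, 0.5])
        out = snp_density_profile(gwas, res, max_dist=1000, bin_size=100)
        assert out.loc[0, "n_snps"] == 3
        assert out["n_snps"][1:].sum() == 0

    def test_empty_regions_rejected(self):
        empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.raises(ValueError, match="no reference regions"):
            snp_density_profile(snp_table([1], [0.5]), empty, 1000, 100)

    def test_uniform_snps_flat_profile(self):
        g = Genome("t", {"chr1": 1_000_000})
        res = make_regions([("chr1", 500_000, 501_000)], g)
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 1_000_000, 20_000)
        gwas = snp_table(pos, np.full(len(pos), 0.5))
        out = snp_density_profile(gwas, res, max_dist=10_000, bin_size=1000)
        # distance bins beyond 0: expected 2 flanks * 1000 bp * density
        expected = 2 * 1000 * 20_000 / 1_000_000
        body = out["n_snps"][1:]
        assert (np.abs(body - expected) < 5 * np.sqrt(expected)).all()


class TestInsideOutside:
    def test_planted_signal_detected(self):
        cfg = SimulationConfig(seed=8, n_snps=50_000, gwas_effect=5.0)
        g = cfg.genome("cattle")
        rng = np.random.default_rng(1)
        chroms = [f"chr{c + 1}" for c in rng.integers(0, cfg.n_chroms, 100)]
        starts = rng.integers(0, cfg.chrom_length - 5000, 100)
        planted = RegionSet(pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + 5000}), g)
        gwas, _ = simulate_gwas(cfg, planted, genome=g)
        _, p = inside_outside_pvalues(gwas, planted)
        assert p < 0.01

    def test_null_not_detected(self):
        cfg = SimulationConfig(seed=9, n_snps=20_000, gwas_effect=1.0)
        g = cfg.genome("cattle")
        planted = make_regions([("chr1", 0, 2_000_000)], g)
        gwas, _ = simulate_gwas(cfg, planted, genome=g)
        _, p = inside_outside_pvalues(gwas, planted)
        assert p > 0.01

    def test_degenerate_partitions_rejected(self):
        g = Genome("t", {"chr1": 1000})
        gwas = snp_table([10, 20], [0.5, 0.5])
        with pytest.raises(ValueError, match="outside"):
            inside_outside_pvalues(gwas, make_regions([("chr1", 0, 1000)], g))
        with pytest.raises(ValueError, match="inside"):
            inside_outside_pvalues(gwas, make_regions([("chr1", 500, 600)], g))


class TestOptions:
    def test_total_window_mode_is_half_per_side(self):
        g = Genome("g", {"chr1": 100_000})
        gwas = snp_table([100, 5000], [0.001, 0.001])
        regions = make_regions([("chr1", 0, 1000)], g)
        r_total = count_based_gwas_test(gwas, regions, window=9000, window_mode="total")
        r_side = count_based_gwas_test(gwas, regions, window=4500)
        assert (r_total.n_snps_in_set, r_total.t_count) == (
            r_side.n_snps_in_set, r_side.t_count)

    def test_bh_adjustment_monotone_and_bounded(self):
        from regevo.enrichment import adjust_pvalues_bh

        p = np.array([0.001, 0.01, 0.02, 0.8, 0.04])
        adj = adjust_pvalues_bh(p)
        assert (adj >= p).all() and (adj <= 1).all()
        # classic worked case: adjusted = p * n / rank with step-up monotonicity
        assert adj[0] == pytest.approx(0.005)
        assert adj[3] == pytest.approx(0.8)
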