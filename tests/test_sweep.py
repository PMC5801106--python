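"""Window scheme, diversity, ROD, Hp/ZHp, Hudson FST, region and gene calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscreen.sweep import (
    GenomeWindow,
    Region,
    SweepCallConfig,
    call_sweep_regions,
    compute_window_stats,
    genes_in_regions,
    make_windows,
    rod,
    site_pi,
    window_fst,
    window_hp,
    window_pi,
    zhp,
    _site_pi_vec,
)
from .conftest import make_gm


class TestMakeWindows:
    def test_sliding_scheme_enumeration(self):
        # 250 kb at 100-kb windows / 20-kb step: starts 0..240 kb -> 13 windows
        w = make_windows({"chr1": 250_000}, 100_000, 20_000)
        assert len(w) == 13
        assert (w[0].start, w[0].end) == (0, 100_000)
        assert (w[-1].start, w[-1].end) == (240_000, 250_000)

    def test_single_window_when_size_equals_length(self):
        assert len(make_windows({"chr1": 100_000}, 100_000, 100_000)) == 1

    def test_non_overlapping_tile_count(self):
        # 5-kb tiles over 1 Mb -> 200 windows
        assert len(make_windows({"chr1": 1_000_000}, 5_000)) == 200

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 1000}, 100, 200)

    def test_tiles_partition_snp_positions(self):
        # non-overlapping windows: per-chromosome window SNP counts sum to total
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(100_000, size=500, replace=False))
        gm = make_gm(rng.integers(0, 3, size=(500, 6)).astype(np.int8), pos=pos)
        cfg = SweepCallConfig(window_size=7_000, step=7_000, min_snps_per_window=1)
        stats = compute_window_stats(gm, cfg, chrom_lengths={"chr1": 100_000},
                                     strict_zhp=False)
        assert stats["n_snps"].sum() == 500


class TestSitePi:
    def test_two_sequences_that_differ(self):
        assert site_pi(1, 2) == pytest.approx(1.0)

    def test_monomorphic(self):
        assert site_pi(0, 10) == 0.0
        assert site_pi(10, 10) == 0.0

    def test_matches_brute_force_pairwise_oracle(self):
        # n = 10 alleles: mean over all 45 pairs of the differ indicator
        rng = np.random.default_rng(1)
        for ac in range(11):
            alleles = np.array([1] * ac + [0] * (10 - ac))
            pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
            oracle = np.mean([alleles[i] != alleles[j] for i, j in pairs])
            assert site_pi(ac, 10) == pytest.approx(oracle)

    def test_needs_two_alleles(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


class TestWindowPi:
    def test_empty_window_is_zero(self):
        assert window_pi(np.array([]), GenomeWindow("chr1", 0, 1000)) == 0.0

    def test_hand_arithmetic_single_site(self):
        # p = 0.5, n = 4 alleles, span 1 kb -> (2*0.25*4/3)/1000
        pis = _site_pi_vec(np.array([2]), np.array([4]))
        got = window_pi(pis, GenomeWindow("chr1", 0, 1000))
        assert got == pytest.approx(6.666666666666666e-4)

    def test_matches_haplotype_string_oracle(self):
        # 5 sites, 8 alleles: mean pairwise hamming distance over allele
        # "haplotypes" (assignment within a site is irrelevant to the mean)
        rng = np.random.default_rng(2)
        acs = rng.integers(0, 9, size=5)
        haplotypes = np.zeros((8, 5), dtype=int)
        for s, ac in enumerate(acs):
            haplotypes[:ac, s] = 1
        n = 8
        dists = [np.sum(haplotypes[i] != haplotypes[j])
                 for i in range(n) for j in range(i + 1, n)]
        span = 2_000
        oracle = sum(dists) / (n * (n - 1) / 2) / span
        pis = _site_pi_vec(acs.astype(float), np.full(5, 8.0))
        assert window_pi(pis, GenomeWindow("chr1", 0, span)) == pytest.approx(oracle)


class TestRod:
    def test_equal_diversity(self):
        assert rod(0.003, 0.003) == pytest.approx(0.0)

    def test_complete_sweep(self):
        assert rod(0.0, 0.004) == pytest.approx(1.0)

    def test_partial_sweep(self):
        assert rod(0.001, 0.004) == pytest.approx(0.75)

    def test_monomorphic_control_is_nan(self):
        assert np.isnan(rod(0.001, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rod(-0.1, 0.2)

    @given(st.floats(1e-6, 1e3), st.floats(1e-6, 1e3), st.floats(1e-3, 1e3))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, pi_h, pi_n, c):
        assert rod(c * pi_h, c * pi_n) == pytest.approx(rod(pi_h, pi_n), rel=1e-9)


class TestHpZhp:
    def test_balanced_snps_reach_maximum(self):
        maj = np.array([5, 5, 5])
        assert window_hp(maj, maj) == pytest.approx(0.5)

    def test_monomorphic_window_is_zero(self):
        assert window_hp(np.array([10, 10]), np.array([0, 0])) == 0.0

    def test_three_snp_hand_toy(self):
        # counts (9,1), (8,2), (7,3): 2*24*6/30^2 = 0.32
        assert window_hp(np.array([9, 8, 7]), np.array([1, 2, 3])) == pytest.approx(0.32)

    def test_empty_window_is_nan(self):
        assert np.isnan(window_hp(np.array([]), np.array([])))

    def test_zhp_matches_hand_zscores(self):
        hp = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        z = zhp(hp)
        mean, sd = 0.3, np.std(hp)
        assert z == pytest.approx((hp - mean) / sd)

    def test_zhp_moments_and_nan_passthrough(self):
        hp = np.array([0.1, np.nan, 0.3, 0.25, 0.4, np.nan])
        z = zhp(hp)
        scored = z[~np.isnan(hp)]
        assert scored.mean() == pytest.approx(0.0, abs=1e-12)
        assert scored.std(ddof=0) == pytest.approx(1.0)
        assert np.isnan(z[1]) and np.isnan(z[5])

    def test_degenerate_scan_errors(self):
        with pytest.raises(ValueError):
            zhp(np.array([0.3, 0.3, 0.3]))


class TestFst:
    def test_no_differentiation_is_near_zero(self):
        alt = np.array([10.0, 4.0, 7.0])
        n = np.array([20.0, 20.0, 20.0])
        got = window_fst(alt, n, alt, n)
        assert got == pytest.approx(0.0, abs=0.06)  # estimator bias at finite n

    def test_complete_differentiation(self):
        alt1 = np.array([20.0]); alt2 = np.array([0.0])
        n = np.array([20.0])
        assert window_fst(alt1, n, alt2, n) == pytest.approx(1.0)

    def test_single_site_hand_evaluation(self):
        # p1 = 0.2 (n1 = 20), p2 = 0.8 (n2 = 20): Hudson's formula by hand
        got = window_fst(np.array([4.0]), np.array([20.0]),
                         np.array([16.0]), np.array([20.0]))
        assert got == pytest.approx(0.5046439628482973)

    def test_no_scorable_sites_is_nan(self):
        assert np.isnan(window_fst(np.array([1.0]), np.array([1.0]),
                                   np.array([0.0]), np.array([2.0])))


def _stats_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi_high",
                                     "pi_none", "rod", "hp_high", "zhp_high", "fst"])
    df["scored"] = True
    df["terminal"] = False
    return df


class TestCallRegions:
    def test_no_hits_gives_empty_list(self):
        rows = [("chr1", i * 20_000, i * 20_000 + 100_000, 100,
                 0.004, 0.004, 0.0, 0.3, 0.0, 0.0) for i in range(10)]
        assert call_sweep_regions(_stats_frame(rows), SweepCallConfig()) == []

    def test_adjacent_hit_windows_merge(self):
        rows = [
            ("chr1", 0, 100_000, 100, 0.0001, 0.004, 0.97, 0.05, -2.0, 0.5),
            ("chr1", 20_000, 120_000, 100, 0.0001, 0.004, 0.97, 0.05, -1.8, 0.5),
            ("chr1", 40_000, 140_000, 100, 0.004, 0.004, 0.0, 0.3, 0.2, 0.0),
        ]
        regions = call_sweep_regions(_stats_frame(rows), SweepCallConfig())
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.start, r.end) == ("chr1", 0, 120_000)
        assert r.zhp_min == pytest.approx(-2.0)

    def test_unscored_windows_never_hit(self):
        rows = [("chr1", 0, 100_000, 100, 0.004, 0.004, 0.0, 0.3, 1.0, 0.0)
                for _ in range(5)]
        df = _stats_frame([("chr1", 100_000, 200_000, 5, 0.0, 0.004, 1.0, 0.01, -9.0, 0.9)]
                          + rows)
        df.loc[0, "scored"] = False
        assert call_sweep_regions(df, SweepCallConfig()) == []

    def test_planted_sweep_recovered_across_seeds(self):
        # headline recovery property: diversity_reduction 0.9 planted on a
        # 1-Mb chromosome with ~0.004/bp background diversity is found in
        # >= 19 of 20 seeded replicates
        from sweepscreen.sim import SimGenomeConfig, SweepRegion, simulate_genotypes
        planted = SweepRegion("chr1", 300_000, 400_000, 0.9)
        cfg = SweepCallConfig()
        hits = 0
        for seed in range(20):
            sim = SimGenomeConfig(seed=seed, n_chrom=1, chrom_length=1_000_000,
                                  n_snps_per_chrom=10_000, sweep_regions=[planted])
            gm, _ = simulate_genotypes(sim)
            stats = compute_window_stats(gm, cfg, chrom_lengths=sim.chrom_lengths())
            regions = call_sweep_regions(stats, cfg)
            if any(r.start < planted.end and planted.start < r.end for r in regions):
                hits += 1
        assert hits >= 19

    def test_null_rod_hit_rate_matches_quantile_rule(self):
        # without planted sweeps the ROD rule alone flags ~1% of windows
        from sweepscreen.sim import SimGenomeConfig, simulate_genotypes
        sim = SimGenomeConfig(seed=123, n_chrom=3, chrom_length=2_000_000,
                              n_snps_per_chrom=20_000)
        gm, _ = simulate_genotypes(sim)
        cfg = SweepCallConfig(zhp_threshold=-np.inf)  # isolate the ROD rule
        stats = compute_window_stats(gm, cfg, chrom_lengths=sim.chrom_lengths())
        regions = call_sweep_regions(stats, cfg)
        n_hit_windows = sum(r.n_windows for r in regions)
        frac = n_hit_windows / int(stats["scored"].sum())
        assert 0.002 <= frac <= 0.025  # binomial band around 1% of 300 windows


class TestGenesInRegions:
    GENES = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [50, 500, 50],
        "end": [150, 600, 150],
        "strand": ["+", "-", "+"],
        "description": ["in", "out", "other chrom"],
    })

    def test_overlap_and_exclusion(self):
        regions = [Region("chr1", 0, 200, -2.0, 2)]
        out = genes_in_regions(regions, self.GENES)
        assert [g.gene_id for g in out] == ["g1"]
        assert out[0].zhp_of_region == -2.0

    def test_snp_counts_match_direct_containment(self, tiny_gm):
        # tiny_gm positions: 5, 100, 250, 400, 900 on chr1
        regions = [Region("chr1", 0, 1000, -1.7, 1)]
        genes = pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["chr1"], "start": [90], "end": [401],
            "strand": ["+"], "description": [""],
        })
        out = genes_in_regions(regions, genes, tiny_gm)
        brute = sum(90 <= p < 401 for p in tiny_gm.pos)
        assert out[0].n_snps_in_gene == brute == 3

    def test_one_bp_overlap_counts(self):
        regions = [Region("chr1", 149, 160, -1.6, 1)]
        out = genes_in_regions(regions, self.GENES)
        assert [g.gene_id for g in out] == ["g1"]
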