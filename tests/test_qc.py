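"""Cleaning chain: twin dedup, call-rate filter, LD pruning, HWE, Q-Q."""

import numpy as np
import pytest

from pedstruct import (SimConfig, call_rate_filter, drop_mz_twins, hwe_exact,
                       ld_prune, qq_summary, simulate_study)
from pedstruct.qc import hwe_exact_pvalue

from .conftest import make_matrix


class TestDropMzTwins:
    def test_identical_pair_one_dropped(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(1, 60))
        d = np.vstack([base, base, rng.integers(0, 3, size=(2, 60))])
        g = make_matrix(d)
        g2, dropped = drop_mz_twins(g, None, seed=1)
        assert g2.n_samples == 3 and len(dropped) == 1
        assert dropped[0] in [("F1", "s1"), ("F1", "s2")]

    def test_no_pair_unchanged(self):
        rng = np.random.default_rng(1)
        g = make_matrix(rng.integers(0, 3, size=(5, 80)))
        g2, dropped = drop_mz_twins(g, None)
        assert g2.n_samples == 5 and dropped == []

    def test_triple_keeps_exactly_one(self):
        row = np.tile([0, 1, 2, 1], 15)
        other = np.tile([2, 0, 1, 0], 15)
        g = make_matrix(np.vstack([row, row, row, other]))
        g2, dropped = drop_mz_twins(g, None, seed=3)
        assert g2.n_samples == 2 and len(dropped) == 2

    def test_cross_family_pairs_ignored(self):
        row = np.tile([0, 1, 2, 1], 15)
        g = make_matrix(np.vstack([row, row]), fids=["F1", "F2"])
        g2, dropped = drop_mz_twins(g, None)
        assert g2.n_samples == 2 and dropped == []

    def test_threshold_validation(self):
        g = make_matrix(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            drop_mz_twins(g, None, identity_threshold=0.5)


class TestCallRateFilter:
    def test_low_rate_snp_removed(self):
        d = np.ones((100, 2), dtype=np.int8)
        d[:3, 0] = -1  # call rate 0.97 < 0.98
        g2 = call_rate_filter(make_matrix(d))
        assert list(g2.snps.snp_id) == ["rs2"]

    def test_complete_matrix_unchanged(self):
        g = make_matrix(np.ones((10, 4)))
        g2 = call_rate_filter(g)
        assert g2.dosages.shape == (10, 4)

    def test_snps_filtered_before_samples(self):
        # sample s1 misses only the bad SNP; filtering SNPs first rescues it
        d = np.ones((4, 4), dtype=np.int8)
        d[:3, 0] = -1          # SNP rs1: call rate 0.25
        d[0, 0] = -1           # s1's only missing value is in rs1
        g2 = call_rate_filter(make_matrix(d), min_snp_rate=0.5,
                              min_sample_rate=0.9)
        assert list(g2.snps.snp_id) == ["rs2", "rs3", "rs4"]
        assert g2.n_samples == 4  # s1 survives because rs1 went first

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = -1
        once = call_rate_filter(make_matrix(d))
        twice = call_rate_filter(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_empty_panel_error(self):
        d = np.full((4, 2), -1, dtype=np.int8)
        with pytest.raises(ValueError, match="empty panel"):
            call_rate_filter(make_matrix(d))


class TestLdPrune:
    def test_perfect_correlation_removes_later(self):
        g = make_matrix(np.array([[0, 0], [1, 1], [2, 2]]))
        g2 = ld_prune(g, min_pairs=2)
        assert list(g2.snps.snp_id) == ["rs1"]

    def test_independent_kept(self):
        g = make_matrix(np.array([[0, 2], [1, 1], [2, 0], [1, 1], [0, 2],
                                  [2, 1], [1, 0], [0, 1]]))
        r = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1]
        g2 = ld_prune(g, min_pairs=2)
        assert r ** 2 <= 0.5 and g2.n_snps == 2

    def test_five_snp_fixture_matches_manual_scan(self):
        rng = np.random.default_rng(11)
        base = rng.integers(0, 3, size=(40,))
        cols = [base,
                np.clip(base + (rng.random(40) < 0.1), 0, 2),   # ~r2 > 0.5 w/ 1
                rng.integers(0, 3, size=40),
                base[::-1],
                np.clip(base + rng.integers(-1, 2, size=40), 0, 2)]
        d = np.stack(cols, axis=1).astype(np.int8)
        g = make_matrix(d)

        # independent manual greedy scan over the full window
        kept = [True] * 5
        for a in range(5):
            for b in range(a + 1, 5):
                if kept[a] and kept[b]:
                    r = np.corrcoef(d[:, a], d[:, b])[0, 1]
                    if r ** 2 > 0.5:
                        kept[b] = False
        expect = [f"rs{j + 1}" for j in range(5) if kept[j]]
        g2 = ld_prune(g, window=5, step=1, min_pairs=2)
        assert list(g2.snps.snp_id) == expect

    def test_survivors_verified_exhaustively(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, size=(50, 60)).astype(np.int8)
        # plant correlated duplicates
        for j in range(0, 60, 7):
            d[:, j + 1] = np.clip(d[:, j] + (rng.random(50) < 0.05), 0, 2)
        g2 = ld_prune(make_matrix(d), window=10, step=3)
        x = g2.dosages.astype(float)
        m = g2.n_snps
        for a in range(m):
            for b in range(a + 1, min(a + 10, m)):
                r = np.corrcoef(x[:, a], x[:, b])[0, 1]
                assert r ** 2 <= 0.5 + 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(17)
        d = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
        once = ld_prune(make_matrix(d), window=8, step=2)
        twice = ld_prune(once, window=8, step=2)
        assert list(once.snps.snp_id) == list(twice.snps.snp_id)

    def test_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            ld_prune(make_matrix(np.zeros((3, 3))), window=1)


class TestHweExact:
    def test_two_sample_configurations(self):
        # n=2, one alt homozygote + one ref homozygote: enumeration over
        # het counts {0, 2} gives weights 2 and 4 -> p(obs het=0) = 1/3
        assert hwe_exact_pvalue(1, 0, 1) == pytest.approx(1 / 3)
        assert hwe_exact_pvalue(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_exact_pvalue(5, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 7) == 1.0

    def test_known_moderate_case(self):
        # independent full-enumeration oracle for one larger configuration
        def oracle(n0, n1, n2):
            from math import comb, factorial
            n, nalt = n0 + n1 + n2, n1 + 2 * n2
            hs = [h for h in range(0, min(nalt, 2 * n - nalt) + 1)
                  if (nalt - h) % 2 == 0 and (2 * n - nalt - h) >= 0
                  and (nalt - h) // 2 + h <= n]
            w = {h: 2 ** h * factorial(n)
                 / (factorial((nalt - h) // 2) * factorial(h)
                    * factorial(n - h - (nalt - h) // 2)) for h in hs}
            tot = sum(w.values())
            pobs = w[n1] / tot
            return sum(v for v in w.values() if v / tot <= pobs * (1 + 1e-12)) / tot

        for cfg in [(10, 5, 5), (3, 14, 3), (8, 2, 8), (0, 1, 9)]:
            assert hwe_exact_pvalue(*cfg) == pytest.approx(oracle(*cfg),
                                                           abs=1e-12)

    def test_matrix_interface_and_subset(self):
        d = np.array([[0, 2], [1, 1], [2, 0], [1, 1]], dtype=np.int8)
        g = make_matrix(d)
        res = hwe_exact(g, subset=[("F1", "s1"), ("F1", "s2"), ("F1", "s3")])
        assert res.table.shape[0] == 2
        assert np.all((res.pvalues > 0) & (res.pvalues <= 1))

    def test_null_calibration_on_panmictic_founders(self):
        # founder couples from a single population: exact-test rejections at
        # 0.05 should be near (slightly below) nominal
        cfg = SimConfig(n_families=50, family_size_range=(2, 2),
                        n_generations=1, n_snps=5_000, K=1,
                        admixture_alpha=(1.0,), fst=0.1, seed=11)
        sim = simulate_study(cfg)
        res = hwe_exact(sim.genotypes)
        frac = float((res.pvalues < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestQQSummary:
    def test_uniform_grid_matches_expectation(self):
        m = 200
        p = (np.arange(1, m + 1) - 0.5) / m
        qq = qq_summary(p)
        np.testing.assert_allclose(qq.table.observed, qq.table.expected,
                                   atol=1e-12)

    def test_extreme_pvalues_inflate(self):
        qq = qq_summary(np.full(100, 1e-8))
        assert qq.lambda_gc > 10

    def test_uniform_draws_near_unit_slope(self):
        p = np.random.default_rng(23).uniform(size=1000)
        assert 0.9 <= qq_summary(p).lambda_gc <= 1.1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            qq_summary([])
        with pytest.raises(ValueError):
            qq_summary([0.5, 0.0])
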