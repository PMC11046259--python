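import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from tebc.stats import (bh_fdr, cluster_permutation, equalize_trials,
                        pac_group_test, pte_shuffle_test, rm_anova_1way,
                        rm_anova_roi, signflip_monte_carlo)


class TestEqualizeTrials:
    def test_larger_set_subsampled(self):
        a, b = equalize_trials(np.arange(40), np.arange(100, 125), rng=0)
        assert a.size == b.size == 25
        assert np.array_equal(b, np.arange(100, 125))
        assert np.all(np.isin(a, np.arange(40)))
        assert np.unique(a).size == 25

    def test_equal_sets_unchanged(self):
        a, b = equalize_trials([1, 2, 3], [7, 8, 9], rng=0)
        assert list(a) == [1, 2, 3] and list(b) == [7, 8, 9]

    def test_seed_determinism(self):
        a1, _ = equalize_trials(np.arange(50), np.arange(10), rng=42)
        a2, _ = equalize_trials(np.arange(50), np.arange(10), rng=42)
        assert np.array_equal(a1, a2)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            equalize_trials([], [1, 2])


class TestSignFlip:
    def test_all_positive_diffs_significant(self):
        res = signflip_monte_carlo(np.full((8, 1), 0.5), n=20000, rng=0)
        assert res.p[0] < 0.025
        assert res.mask[0]

    def test_symmetric_diffs_not_significant(self):
        d = np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5])[:, None]
        res = signflip_monte_carlo(d, n=5000, rng=1)
        assert res.p[0] > 0.5
        assert not res.mask[0]

    def test_matches_exact_enumeration(self):
        # a clearly one-sided sample: enumeration p is small, so the +-0.003
        # tolerance is several Monte Carlo standard errors wide
        rng = np.random.default_rng(2)
        d = rng.normal(0.8, 0.4, 8)
        res = signflip_monte_carlo(d[:, None], n=20000, rng=3)
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=8)))
        null = signs @ d / 8
        obs = d.mean()
        p_hi = (null >= obs).mean()
        p_lo = (null <= obs).mean()
        exact = min(2 * min(p_hi, p_lo), 1.0)
        assert res.p[0] == pytest.approx(exact, abs=0.003)

    def test_positive_p_and_determinism(self):
        d = np.random.default_rng(4).normal(size=(5, 7))
        r1 = signflip_monte_carlo(d, n=2000, rng=9)
        r2 = signflip_monte_carlo(d, n=2000, rng=9)
        assert np.all(r1.p > 0)
        assert np.array_equal(r1.p, r2.p)


class TestBHFDR:
    def test_printed_example(self):
        mask = bh_fdr(np.array([0.001, 0.012, 0.03, 0.04, 0.8]), q=0.05)
        assert list(mask) == [True, True, True, True, False]

    def test_all_ones_no_rejection(self):
        assert not bh_fdr(np.ones(10), q=0.05).any()

    def test_single_test_reduces_to_threshold(self):
        assert bh_fdr(np.array([0.04]), q=0.05)[0]
        assert not bh_fdr(np.array([0.06]), q=0.05)[0]

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(1, 20))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            mine = bh_fdr(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(mine, ref)

    def test_nan_handling(self):
        mask = bh_fdr(np.array([0.001, np.nan, 0.9]), q=0.05)
        assert mask[0] and not mask[1] and not mask[2]


class TestClusterPermutation:
    def test_identical_conditions_empty(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(6, 3, 40))
        res = cluster_permutation(a, a.copy(), n_perm=100, rng=0)
        assert res.clusters == []

    def test_injected_offset_recovered(self):
        hits = 0
        coverage_ok = 0
        for seed in range(50):
            rng = np.random.default_rng(400 + seed)
            a = rng.normal(size=(8, 4, 60))
            b = rng.normal(size=(8, 4, 60))
            a[:, 2, 20:40] += 2.0  # high SNR contiguous injection
            res = cluster_permutation(a, b, n_perm=500, rng=seed)
            sig = [c for c in res.significant() if c.band == 2 and c.t_sum > 0]
            if sig:
                hits += 1
                span = max(c.stop for c in sig) - min(c.start for c in sig)
                inside = sum(min(c.stop, 40) - max(c.start, 20) for c in sig)
                if inside >= 0.8 * 20:
                    coverage_ok += 1
        assert hits >= 45
        assert coverage_ok >= 45

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        false_pos = 0
        n_datasets = 200
        for d in range(n_datasets):
            a = rng.normal(size=(8, 4, 50))
            b = rng.normal(size=(8, 4, 50))
            res = cluster_permutation(a, b, n_perm=500, rng=d)
            false_pos += bool(res.significant())
        lo, hi = sstats.binom.interval(0.99, n_datasets, 0.05)
        assert lo <= false_pos <= hi

    def test_cluster_p_plus_one_corrected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(8, 2, 30))
        b = rng.normal(size=(8, 2, 30))
        a[:, 0, 5:25] += 3.0
        res = cluster_permutation(a, b, n_perm=200, rng=1)
        for c in res.clusters:
            assert 0 < c.p <= 1
            assert c.p >= 1 / 201

    def test_contiguity_within_band(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(8, 2, 50))
        b = rng.normal(size=(8, 2, 50))
        a[:, 1, 10:20] += 3.0
        a[:, 1, 35:45] += 3.0
        res = cluster_permutation(a, b, n_perm=100, rng=2)
        pos = [c for c in res.clusters if c.band == 1 and c.t_sum > 0]
        assert len(pos) >= 2  # the two injections stay separate clusters

    def test_two_animals_minimum(self):
        with pytest.raises(ValueError, match="animals"):
            cluster_permutation(np.zeros((1, 2, 10)), np.zeros((1, 2, 10)))


class TestRmAnova:
    def test_all_equal_zero_f(self):
        res = rm_anova_roi(np.ones((5, 2, 3)))
        assert res["A"]["F"] == 0.0 and res["B"]["F"] == 0.0

    def test_additive_construction(self):
        # value = 2 * I(A==1) + subject offset: pure main effect, no interaction
        subj = np.arange(6)[:, None, None] * 0.5
        a_eff = np.array([0.0, 2.0])[None, :, None]
        y = np.broadcast_to(subj + a_eff, (6, 2, 2)).copy()
        res = rm_anova_roi(y)
        assert np.isinf(res["A"]["F"]) and res["A"]["p"] == 0.0
        assert res["AxB"]["F"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_partition_random_table(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(8, 2, 2))
        res = rm_anova_roi(y)
        # independent oracle: pingouin's two-way repeated-measures ANOVA
        import pandas as pd
        import pingouin as pg

        rows = [{"s": s, "A": a, "B": b, "y": y[s, a, b]}
                for s in range(8) for a in range(2) for b in range(2)]
        ref = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["A", "B"],
                          subject="s", detailed=True)
        for src, key in (("A", "A"), ("B", "B"), ("A * B", "AxB")):
            row = ref[ref["Source"] == src].iloc[0]
            assert res[key]["F"] == pytest.approx(row["F"], rel=1e-9)
            assert res[key]["p"] == pytest.approx(row["p_unc"], rel=1e-9)

    def test_missing_cells_error(self):
        y = np.ones((4, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_roi(y)

    def test_one_way_matches_two_level_paired_t(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(9, 2))
        res = rm_anova_1way(y)
        t, p = sstats.ttest_rel(y[:, 0], y[:, 1])
        assert res["F"] == pytest.approx(t**2, rel=1e-9)
        assert res["p"] == pytest.approx(p, rel=1e-9)


class TestPacGroupTest:
    def test_no_difference_no_rejection(self):
        post = np.random.default_rng(12).random((10, 3, 3))
        res = pac_group_test(post, post.copy())
        assert not res.mask.any()

    def test_uniform_shift_all_significant(self):
        rng = np.random.default_rng(13)
        pre = rng.random((10, 3, 3)) * 0.1
        post = pre + 0.2 + 1e-4 * rng.standard_normal(pre.shape)
        res = pac_group_test(post, pre)
        assert res.mask.all()

    def test_single_cell_recovery_with_fdr_control(self):
        recovered = 0
        false_total = 0
        n_runs = 30
        cells = (4, 4)
        for seed in range(n_runs):
            rng = np.random.default_rng(500 + seed)
            noise_sd = 0.05
            pre = 0.1 + noise_sd * rng.standard_normal((64,) + cells)
            post = 0.1 + noise_sd * rng.standard_normal((64,) + cells)
            post[:, 1, 2] += 3 * noise_sd / np.sqrt(64) * 8  # SNR 3 per-cell t~
            res = pac_group_test(post, pre, q=0.05)
            recovered += bool(res.mask[1, 2])
            false_total += res.mask.sum() - int(res.mask[1, 2])
        assert recovered >= 0.9 * n_runs
        assert false_total / n_runs <= 0.05 * 16 + 0.15

    def test_few_observations_skipped(self):
        post = np.random.default_rng(14).random((2, 2))
        res = pac_group_test(post, post * 0.5, min_obs=3)
        assert np.all(np.isnan(res.p))
        assert not res.mask.any()


class TestPTEShuffleTest:
    def _walk(self, rng, n_trials=12, n_time=300):
        return np.angle(np.exp(1j * np.cumsum(
            0.3 * rng.standard_normal((n_trials, n_time)), axis=1)))

    def test_antisymmetry_and_same_p(self):
        rng = np.random.default_rng(15)
        x, y = self._walk(rng), self._walk(rng)
        r1 = pte_shuffle_test([(x, y)], [10], n_shuffles=100, rng=5, window=None)
        r2 = pte_shuffle_test([(y, x)], [10], n_shuffles=100, rng=5, window=None)
        assert r1.dte[0] == -r2.dte[0]

    def test_null_calibration(self):
        any_sig = 0
        n_runs = 25
        for seed in range(n_runs):
            rng = np.random.default_rng(700 + seed)
            pairs = [(self._walk(rng), self._walk(rng)) for _ in range(3)]
            res = pte_shuffle_test(pairs, [10, 10, 10], n_shuffles=200,
                                   rng=seed, window=None)
            any_sig += bool(res.mask.any())
        lo, hi = sstats.binom.interval(0.995, n_runs, 0.05)
        assert any_sig <= hi

    def test_lagged_driver_significant(self):
        rng = np.random.default_rng(16)
        x = np.cumsum(0.25 * rng.standard_normal((15, 400)), axis=1)
        y = np.roll(x, 12, axis=1) + 0.1 * rng.standard_normal(x.shape)
        res = pte_shuffle_test([(np.angle(np.exp(1j * x)),
                                 np.angle(np.exp(1j * y)))], [20],
                               n_shuffles=200, rng=6, window=None)
        assert res.dte[0] > 0
        assert res.mask[0]
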