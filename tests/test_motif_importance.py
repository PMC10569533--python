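import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from mutcr import motif_importance as mi


class TestSelectImportant:
    def test_two_stage_counts(self):
        rng = np.random.default_rng(0)
        beta, x = rng.normal(size=100), rng.gamma(2, 1, 100)
        profile, idx = mi.select_important(beta, x)
        assert len(idx) == 1                      # ceil(0.1*ceil(0.1*100))
        assert (profile[idx] == beta[idx]).all()
        assert np.count_nonzero(profile) <= 1

    def test_hand_ranked_example(self):
        beta = np.array([3.0, -2.0, 1.0, 0.1, 0, 0, 0, 0, 0, 0])
        x = np.ones(10)
        profile, idx = mi.select_important(beta, x)
        assert list(idx) == [0]
        assert profile[0] == 3.0

    def test_all_zero_beta_gives_zero_profile(self):
        profile, idx = mi.select_important(np.zeros(50), np.ones(50))
        assert not profile.any()
        assert len(idx) == 1          # selection count is structural

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mi.select_important(np.array([]), np.array([]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=10_000))
    def test_matches_full_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 60))
        beta = np.round(rng.normal(size=p), 2)    # rounding provokes ties
        x = np.round(rng.gamma(2, 1, p), 1)
        _, idx = mi.select_important(beta, x)

        from math import ceil
        k1 = ceil(0.1 * p)
        contrib = [(-abs(b * xx), j) for j, (b, xx) in enumerate(zip(beta, x))]
        stage1 = sorted(j for _, j in sorted(contrib)[:k1])
        k2 = ceil(0.1 * k1)
        stage2 = sorted(j for _, j in sorted((-abs(beta[j]), j) for j in stage1)[:k2])
        assert list(idx) == stage2


class TestClustering:
    def test_two_planted_contexts_recovered(self, rng):
        a = np.zeros((80, 20)); a[:, :3] = 2.0 + rng.normal(0, 0.05, (80, 3))
        b = np.zeros((90, 20)); b[:, 10:13] = -1.5 + rng.normal(0, 0.05, (90, 3))
        profiles = np.vstack([a, b])
        truth = np.array([0] * 80 + [1] * 90)
        res = mi.cluster_regions(profiles, k_range=(2, 8), seed=0)
        assert res.k == 2
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_forced_k_and_small_cluster_dropped(self, rng):
        base = rng.normal(0, 0.01, (40, 5))
        outliers = 5 + rng.normal(0, 0.01, (9, 5))     # cluster of 9 -> dropped
        res = mi.cluster_regions(np.vstack([base, outliers]), k=2, seed=0)
        assert (res.labels[40:] == -1).all()
        res_k1 = mi.cluster_regions(base, k=1, seed=0)
        assert set(res_k1.labels) == {0}

    def test_fewer_regions_than_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            mi.cluster_regions(rng.normal(size=(4, 3)), k=9)

    def test_grouping_partitions_clusters(self, rng):
        means = pd.DataFrame(rng.normal(size=(12, 6)))
        groups = mi.group_clusters(means, n_groups=4)
        assert set(groups.index) == set(means.index)
        assert groups.nunique() == 4
        with pytest.raises(ValueError, match="fewer clusters"):
            mi.group_clusters(means, n_groups=13)

    def test_group_summary_partition_and_z(self, rng):
        profiles = rng.normal(size=(60, 8))
        labels = np.repeat([0, 1, 2], 20)
        groups = pd.Series([0, 0, 1], index=[0, 1, 2], name="group")
        D1 = rng.gamma(2, 1, 60)
        summary, weights, group_of_region = mi.group_summary(labels, groups, profiles, D1)
        assert summary["n_regions"].sum() == 60
        assert summary.loc[0, "n_regions"] == 40
        assert summary["mutation_z"].mean() == pytest.approx(0.0, abs=1e-12)


class TestStateFoldChange:
    def test_ratio_and_absent_state(self):
        group = pd.Series(["Quies"] * 4 + ["TssA"] * 6)
        allr = pd.Series(["Quies"] * 20 + ["TssA"] * 30 + ["Enh"] * 50)
        fc = mi.state_fold_change(group, allr)
        assert fc["Quies"] == pytest.approx(0.4 / 0.2)
        assert fc["Enh"] == 0.0

    def test_identical_composition_is_unity(self):
        s = pd.Series(["A", "B", "B", "C"] * 10)
        fc = mi.state_fold_change(s, s)
        assert np.allclose(fc, 1.0)


class TestSiteProfiles:
    def sites(self, mids):
        return pd.DataFrame({"chrom": "chr1", "start": mids, "stop": mids})

    def test_planted_spike_at_center(self):
        mids = np.arange(1000, 51_000, 500)
        muts = pd.DataFrame({"chrom": "chr1", "pos": mids})  # exactly at midpoints
        offsets, rate, n = mi.motif_site_profile(self.sites(mids), muts, window=100)
        assert rate[100] == pytest.approx(1.0)
        assert rate.sum() == pytest.approx(1.0)

    def test_uniform_mutations_flat_profile(self, rng):
        mids = np.arange(5000, 1_000_000, 90)[:10_000]
        muts = pd.DataFrame({"chrom": "chr1",
                             "pos": rng.integers(1, 1_000_000, size=200_000)})
        _, rate, n = mi.motif_site_profile(self.sites(mids), muts, window=20)
        assert n >= 10_000
        smooth = np.convolve(rate, np.ones(9) / 9, mode="valid")
        assert smooth.max() / smooth.min() < 1.5

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            mi.motif_site_profile(self.sites([])[:0],
                                  pd.DataFrame({"chrom": [], "pos": []}))

    def test_planted_rate_difference_detected(self, rng):
        hot = self.sites(np.arange(1000, 301_000, 300))
        cold = self.sites(np.arange(1_000_000, 1_300_000, 300))
        hot_mut = rng.integers(990, 300_990, size=30_000)
        cold_mut = rng.integers(1_000_000, 1_300_000, size=3_000)
        muts = pd.DataFrame({"chrom": "chr1",
                             "pos": np.concatenate([hot_mut, cold_mut])})
        r_hot = mi.site_mean_rates(hot, muts, flank=50)
        r_cold = mi.site_mean_rates(cold, muts, flank=50)
        t, p = mi.compare_motif_rates(r_hot, r_cold)
        assert t > 0 and p < 1e-6


class TestOneProportionZ:
    def test_hand_computed_example(self):
        # 70 successes of 100 vs p0=0.5: z = 0.2/sqrt(0.25/100) = 4
        z, p = mi.one_proportion_ztest(70, 100, 0.5)
        assert z == pytest.approx(4.0)
        assert p == pytest.approx(2 * stats.norm.sf(4.0), rel=1e-12)

    def test_one_sided_alternatives(self):
        z_l, p_l = mi.one_proportion_ztest(70, 100, 0.5, alternative="larger")
        assert p_l == pytest.approx(stats.norm.sf(4.0), rel=1e-12)
        _, p_s = mi.one_proportion_ztest(70, 100, 0.5, alternative="smaller")
        assert p_s == pytest.approx(stats.norm.cdf(4.0), rel=1e-12)
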