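import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from mutcr import region_classes
from mutcr.featurize import density_response
from mutcr.synthetic_data import SimulationConfig, simulate_cohort


class TestPoissonTails:
    def test_reference_values(self):
        pu, pl = region_classes.poisson_tails([0], [3.0])
        assert pu[0] == pytest.approx(1.0)          # whole support
        pu, _ = region_classes.poisson_tails([10], [5.0])
        assert pu[0] == pytest.approx(0.031828, abs=1e-5)
        _, pl = region_classes.poisson_tails([0], [5.0])
        assert pl[0] == pytest.approx(np.exp(-5), rel=1e-10)

    def test_zero_lambda_conventions(self):
        pu, pl = region_classes.poisson_tails([0, 3], [0.0, 0.0])
        assert pu[0] == 1.0 and pl[0] == 1.0
        assert pu[1] == 0.0 and pl[1] == 1.0     # impossible event observed

    def test_non_integer_observed_rejected(self):
        with pytest.raises(ValueError):
            region_classes.poisson_tails([1.5], [2.0])
        with pytest.raises(ValueError):
            region_classes.poisson_tails([1], [-2.0])

    @pytest.mark.parametrize("lam", [0.5, 5.0, 50.0])
    def test_matches_bruteforce_pmf_summation(self, lam):
        upper_k = int(lam + 50 * np.sqrt(lam) + 20)
        pmf = np.array([poisson.pmf(k, lam) for k in range(upper_k)])
        for obs in [0, 1, 2, int(lam), int(2 * lam) + 3]:
            pu, pl = region_classes.poisson_tails([obs], [lam])
            assert abs(pu[0] - pmf[obs:].sum()) < 1e-10
            assert abs(pl[0] - pmf[:obs + 1].sum()) < 1e-10

    def test_null_p_values_are_valid(self, rng):
        # kilobase-scale per-region depths: the discreteness of the Poisson
        # support keeps the strict-tail exceedance visibly below alpha
        lam = rng.lognormal(np.log(5), 1.0, size=5000)
        counts = rng.poisson(lam)
        pu, _ = region_classes.poisson_tails(counts, lam)
        for alpha in (0.01, 0.05, 0.1):
            assert (pu < alpha).mean() <= alpha


class TestBhFdr:
    def test_textbook_example(self):
        np.testing.assert_allclose(region_classes.bh_fdr([0.001, 0.02, 0.5]),
                                   [0.003, 0.03, 0.5])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(region_classes.bh_fdr([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(region_classes.bh_fdr([0.07]), [0.07])
        assert region_classes.bh_fdr([]).size == 0

    def test_matches_hand_rolled_step_up(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            got = region_classes.bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            np.testing.assert_allclose(got, adj, rtol=1e-12)


class TestPredictedCount:
    def test_inverse_of_density_example(self):
        # featurize example: C=5, l=2000, T=1e6 -> D=2.5 -> Y via mean/std
        lam = region_classes.predicted_count(
            y_pred=np.array([(np.log2(3.5) - 1.0) / 0.5]),
            mean=1.0, std=0.5, lengths=np.array([2000.0]), T=1e6)
        assert lam[0] == pytest.approx(5.0)

    def test_negative_log_density_clamped(self):
        lam = region_classes.predicted_count(np.array([-50.0]), 0.0, 1.0,
                                             np.array([1000.0]), 1e6)
        assert lam[0] == 0.0

    def test_round_trip_on_random_values(self, rng):
        counts = rng.integers(1, 500, 100)
        lengths = rng.integers(1000, 90_000, 100)
        T = counts.sum()
        dens = density_response(counts, lengths, T)
        lam = region_classes.predicted_count(dens.Y, dens.mean, dens.std, lengths, T)
        np.testing.assert_allclose(lam, counts, rtol=1e-9)


class TestClassify:
    def verdicts(self, p_upper, p_lower):
        n = len(p_upper)
        return pd.DataFrame({
            "region_id": range(n), "chrom": "chr1", "start": 0, "end": 1000,
            "state": "Quies", "observed": 5, "lambda_hat": 5.0,
            "p_upper": p_upper, "p_lower": p_lower,
        })

    def test_label_rules(self):
        df = self.verdicts([0.5, 1e-9, 0.05], [0.5, 1.0, 0.9])
        out = region_classes.classify(df)
        assert out.loc[0, "label"] == "independent"
        assert out.loc[1, "label"] == "related"       # BH-FDR tiny
        assert out.loc[2, "label"] == "ambiguous"     # neither rule

    def test_labels_partition_all_regions(self, rng):
        pu = rng.random(500)
        pl = 1 - pu + rng.random(500) * 0.1
        out = region_classes.classify(self.verdicts(pu, np.clip(pl, 0, 1)))
        assert out["label"].isin(region_classes.LABELS).all()
        assert len(out) == 500


class TestRecalibrateLambda:
    def test_corrects_systematic_bias(self, rng):
        lam_true = rng.lognormal(3, 1, 2000)
        counts = rng.poisson(lam_true)
        lam_biased = lam_true * 1.2
        flagged = np.zeros(2000, bool)
        lam_fixed = region_classes.recalibrate_lambda(lam_biased, counts, flagged)
        assert abs(np.log2(lam_fixed / lam_true).mean()) < 0.05

    def test_flagged_regions_do_not_drive_the_correction(self, rng):
        lam_true = np.full(1000, 50.0)
        counts = rng.poisson(lam_true)
        flagged = np.zeros(1000, bool)
        flagged[:100] = True
        counts[:100] *= 10  # gross outliers, all flagged
        lam_fixed = region_classes.recalibrate_lambda(lam_true.copy(), counts, flagged)
        assert abs(np.log2(lam_fixed[100:] / 50.0).mean()) < 0.05


class TestIterateRefinement:
    @pytest.fixture(scope="class")
    def spiked(self):
        cfg = SimulationConfig(n_regions=800, p_motifs=30, n_contexts=1, noise_sd=0.0,
                               spike_fraction=0.05, spike_multiplier=3.0,
                               total_mutation_target=80_000, seed=19)
        return simulate_cohort(cfg)

    def test_single_iteration_trains_once(self, spiked):
        counts = spiked.truth.counts_by_type[0]
        res = region_classes.iterate_refinement(
            spiked.features.values, counts,
            spiked.segmentation["length_bp"].to_numpy(), counts.sum(),
            test_mask=np.arange(800) < 80, max_iter=1, max_epochs=40)
        assert len(res.history) == 1

    def test_null_cohort_drop_rate_bounded(self):
        cfg = SimulationConfig(n_regions=800, p_motifs=30, n_contexts=1, noise_sd=0.0,
                               total_mutation_target=80_000, seed=23)
        c = simulate_cohort(cfg)
        counts = c.truth.counts_by_type[0]
        res = region_classes.iterate_refinement(
            c.features.values, counts, c.segmentation["length_bp"].to_numpy(),
            counts.sum(), test_mask=np.arange(800) < 80, max_iter=1,
            max_epochs=400, patience=60)
        # per-tail threshold 0.1 removes at most ~2*0.1 of a true null set,
        # less in practice because Poisson tails are discrete/conservative
        dropped = res.history.loc[0, "n_dropped"] / res.history.loc[0, "n_train"]
        assert dropped <= 0.25

    def test_all_regions_dropped_is_error(self, spiked):
        counts = spiked.truth.counts_by_type[0]
        with pytest.raises(ValueError, match="all regions"):
            region_classes.iterate_refinement(
                spiked.features.values, counts,
                spiked.segmentation["length_bp"].to_numpy(), counts.sum(),
                test_mask=np.arange(800) < 80, max_iter=2, removal_p=1.1,
                max_epochs=10)
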