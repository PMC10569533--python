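import numpy as np
import pytest

from mutcr import cr_model
from mutcr.featurize import density_response
from mutcr.synthetic_data import SimulationConfig, simulate_cohort


class TestBuild:
    def test_paper_scale_widths(self):
        arch = cr_model.build(2321, d3=15, d5=10)
        assert arch.hidden_sizes == (1160, 154, 232)
        assert arch.dropout_rates == (0.01, 0.01, 0.1)

    def test_small_p_clamped_to_one(self):
        arch = cr_model.build(10, d3=15, d5=30)
        assert all(w >= 1 for w in arch.hidden_sizes)

    def test_too_small_p_rejected(self):
        with pytest.raises(ValueError):
            cr_model.build(1)


class TestDotProductIdentity:
    """The defining contract: the prediction is literally beta(x) . x."""

    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(1)
        X = np.where(rng.random((600, 20)) < 0.7, 0.0, 5 + rng.gamma(2, 1, (600, 20)))
        beta = rng.normal(size=20)
        Y = X @ beta / (X @ beta).std()
        model = cr_model.CRModel(cr_model.build(20), seed=3, max_epochs=60)
        model.fit(X, Y)
        return model, X

    def test_identity_on_random_rows(self, trained):
        model, X = trained
        rng = np.random.default_rng(2)
        probe = np.where(rng.random((1000, 20)) < 0.5, 0.0, 5 + rng.gamma(2, 1, (1000, 20)))
        cw = model.context_weights(probe)
        manual = np.einsum("ij,ij->i", probe, cw.beta)
        np.testing.assert_allclose(cw.prediction, manual,
                                   atol=1e-5 * (1 + np.abs(manual).max()))

    def test_zero_row_predicts_zero(self, trained):
        model, _ = trained
        cw = model.context_weights(np.zeros((1, 20)))
        assert cw.prediction[0] == 0.0

    def test_hand_dot_product(self):
        beta = np.array([[0.5, 0.25]])
        x = np.array([[1.0, 2.0]])
        assert float(np.einsum("ij,ij->i", x, beta)[0]) == 1.0

    def test_width_mismatch_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError, match="width"):
            model.context_weights(np.zeros((3, 7)))


class TestTraining:
    def test_same_seed_same_result(self):
        rng = np.random.default_rng(5)
        X = rng.gamma(2, 1, (300, 12))
        Y = rng.normal(size=300)
        mask = np.zeros(300, bool)
        mask[:30] = True
        _, m1 = cr_model.train(X, Y, mask, seed=11, max_epochs=30)
        _, m2 = cr_model.train(X, Y, mask, seed=11, max_epochs=30)
        assert m1["test"]["mse"] == m2["test"]["mse"]

    def test_nan_rejected_before_training(self):
        X = np.ones((50, 4))
        X[0, 0] = np.nan
        model = cr_model.CRModel(cr_model.build(4))
        with pytest.raises(ValueError, match="NaN"):
            model.fit(X, np.zeros(50))

    def test_constant_target_learned(self):
        rng = np.random.default_rng(8)
        X = 5 + rng.gamma(2, 1, (400, 10))
        Y = np.full(400, 0.7)
        model = cr_model.CRModel(cr_model.build(10), seed=2, max_epochs=120)
        model.fit(X, Y)
        assert np.mean((model.predict(X) - 0.7) ** 2) < 0.01

    def test_warm_start_cannot_degrade(self):
        rng = np.random.default_rng(9)
        X = np.where(rng.random((500, 15)) < 0.6, 0.0, 5 + rng.gamma(2, 1, (500, 15)))
        beta = rng.normal(size=15)
        Y = X @ beta / (X @ beta).std() + rng.normal(0, 0.1, 500)
        first = cr_model.CRModel(cr_model.build(15), seed=4, max_epochs=150)
        first.fit(X, Y)
        mse_first = np.mean((first.predict(X) - Y) ** 2)
        second = cr_model.CRModel(cr_model.build(15), seed=5, max_epochs=20)
        second.fit(X, Y, init_from=first)
        assert np.mean((second.predict(X) - Y) ** 2) <= mse_first * 1.05

    def test_noise_degrades_heldout_fit_on_average(self):
        """Sanity: more latent noise, worse held-out correlation."""
        mean_r = []
        for noise in (0.05, 0.5, 2.0):
            rs = []
            for seed in (31, 32):
                cfg = SimulationConfig(n_regions=800, p_motifs=20, n_contexts=1,
                                       noise_sd=noise, total_mutation_target=80_000,
                                       seed=seed)
                c = simulate_cohort(cfg)
                counts = c.truth.counts_by_type[0]
                dens = density_response(counts, c.segmentation["length_bp"].to_numpy(),
                                        counts.sum())
                mask = np.zeros(800, bool)
                mask[::5] = True
                _, met = cr_model.train(c.features.values, dens.Y, mask,
                                        seed=seed, max_epochs=150, patience=20)
                rs.append(met["test"]["pearson_r"])
            mean_r.append(np.mean(rs))
        assert mean_r[0] > mean_r[1] > mean_r[2]


class TestCrossValidation:
    def setup_data(self):
        rng = np.random.default_rng(12)
        X = 5 + rng.gamma(2, 1, (260, 8))
        beta = rng.normal(size=8)
        Y = X @ beta
        Y = (Y - Y.mean()) / Y.std()
        return X, Y

    def test_region_scheme_reproducible(self):
        X, Y = self.setup_data()
        r1 = cr_model.crossvalidate(X, Y, folds=4, seed=3, max_epochs=20)
        r2 = cr_model.crossvalidate(X, Y, folds=4, seed=3, max_epochs=20)
        assert r1["test_mse"].tolist() == r2["test_mse"].tolist()
        assert len(r1) == 4

    def test_chromosome_scheme_leaves_whole_chromosomes_out(self):
        X, Y = self.setup_data()
        chroms = np.repeat([f"chr{i}" for i in range(13)], 20)
        res = cr_model.crossvalidate(X, Y, folds=5, scheme="chromosome",
                                     chromosomes=chroms, seed=1, max_epochs=10)
        assert res["n_test"].sum() == len(X)

    def test_too_few_units_rejected(self):
        X, Y = self.setup_data()
        with pytest.raises(ValueError, match="fewer"):
            cr_model.crossvalidate(X[:5], Y[:5], folds=10)
        with pytest.raises(ValueError, match="fewer chromosomes"):
            cr_model.crossvalidate(X, Y, folds=10, scheme="chromosome",
                                   chromosomes=np.repeat(["chr1", "chr2"], 130))


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    X = 5 + rng.gamma(2, 1, (200, 6))
    Y = rng.normal(size=200)
    model = cr_model.CRModel(cr_model.build(6), seed=1, max_epochs=20)
    model.fit(X, Y)
    model.save(tmp_path / "m")
    again = cr_model.CRModel.load(tmp_path / "m")
    np.testing.assert_array_equal(model.predict(X), again.predict(X))
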