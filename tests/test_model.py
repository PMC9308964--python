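"""Quantile network: pinball loss arithmetic, split mechanics, training
sanity, and recovery of the generator's known conditional quantiles."""

import numpy as np
import pandas as pd
import pytest

from socquant.model import (
    ModelSpec,
    SYNTHETIC_STUDY_TRAINING,
    Standardizer,
    TrainingConfig,
    pinball_loss,
    rmse_q50,
    split_data,
    total_loss,
    train,
)
from socquant.synthetic import SyntheticConfig, generate_sites, true_quantile_frame


class TestPinballLoss:
    @pytest.mark.parametrize(
        "y,yhat,tau,expected",
        [
            (3.0, 3.0, 0.5, 0.0),
            (5.0, 3.0, 0.9, 1.8),   # under-prediction penalised by tau
            (3.0, 5.0, 0.9, 0.2),   # over-prediction penalised by 1 - tau
        ],
    )
    def test_hand_values(self, y, yhat, tau, expected):
        assert pinball_loss(y, yhat, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.5])
    def test_tau_domain(self, tau):
        with pytest.raises(ValueError):
            pinball_loss(1.0, 0.0, tau)

    def test_total_is_sum_of_head_means(self, rng):
        y = rng.normal(2, 1, 64)
        heads = np.column_stack([y + rng.normal(0, 0.3, 64) for _ in range(5)])
        taus = (0.25, 0.5, 0.75, 0.9, 0.95)
        parts = [pinball_loss(y, heads[:, k], t) for k, t in enumerate(taus)]
        assert total_loss(y, heads, taus) == pytest.approx(sum(parts))
        assert total_loss(y, np.tile(y[:, None], (1, 5)), taus) == 0.0

    def test_constant_minimizer_is_empirical_quantile(self, rng):
        """Brute-force check that each head's loss over constant predictors is
        minimized at the sample quantile (n = 1001)."""
        y = rng.lognormal(0.5, 0.6, 1001)
        candidates = np.sort(y)
        for tau in (0.25, 0.5, 0.75, 0.9, 0.95):
            losses = np.mean(
                np.maximum(
                    tau * (y[None, :] - candidates[:, None]),
                    (tau - 1.0) * (y[None, :] - candidates[:, None]),
                ),
                axis=1,
            )
            best = candidates[np.argmin(losses)]
            assert best == pytest.approx(
                float(np.quantile(y, tau, method="inverted_cdf")), rel=1e-9
            )


class TestModelSpec:
    @pytest.mark.parametrize(
        "percentiles", [(0.5, 0.25), (0.25, 0.25), (0.0, 0.5), (0.5, 1.0)]
    )
    def test_percentiles_must_increase_in_unit_interval(self, percentiles):
        with pytest.raises(ValueError):
            ModelSpec(percentiles=percentiles)

    def test_needs_hidden_layer(self):
        with pytest.raises(ValueError):
            ModelSpec(hidden_layers=())


class TestSplitData:
    def test_test_fraction_and_disjointness(self):
        samples = generate_sites(SyntheticConfig(n_sites=1000, seed=5))
        pool, test, resamples = split_data(samples, 0.05, seed=1)
        assert len(test) == 50
        assert len(np.intersect1d(pool, test)) == 0
        train_idx, val_idx = resamples[0]
        assert set(val_idx) <= set(pool) and set(train_idx) <= set(pool)
        assert len(np.intersect1d(train_idx, val_idx)) == 0

    def test_out_of_bag_fraction(self):
        """Bootstrap leaves ~1/e of the pool out of bag."""
        samples = generate_sites(SyntheticConfig(n_sites=10_000, seed=6))
        pool, _, resamples = split_data(samples, 0.05, seed=2)
        _, val_idx = resamples[0]
        assert len(val_idx) / len(pool) == pytest.approx(np.exp(-1), abs=0.02)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_data(generate_sites(SyntheticConfig(n_sites=10, seed=1)), 0.05, 1)


class TestStandardizer:
    def test_zero_variance_rejected(self):
        frame = pd.DataFrame(
            {"mat": [1.0, 1.0], "tap": [1.0, 2.0], "elevation": [0.0, 5.0],
             "landcover": ["cropland", "forest"]}
        )
        with pytest.raises(ValueError):
            Standardizer().fit(frame)

    def test_roundtrip_serialization(self, sites):
        s = Standardizer().fit(sites)
        s2 = Standardizer.from_dict(s.to_dict())
        np.testing.assert_allclose(s.transform(sites.head()), s2.transform(sites.head()))


class TestTraining:
    def test_loss_decreases(self, sites):
        m = train(
            sites.head(2000), ModelSpec(),
            TrainingConfig(epochs=10, batch_size=128, learning_rate=0.003, seed=0),
        )
        assert m.loss_history[-1] <= m.loss_history[0]

    def test_seeded_determinism(self, sites):
        cfg = TrainingConfig(epochs=5, batch_size=128, learning_rate=0.003, seed=3)
        m1 = train(sites.head(1000), ModelSpec(), cfg)
        m2 = train(sites.head(1000), ModelSpec(), cfg)
        q1 = m1.predict_rows(sites.tail(100))
        q2 = m2.predict_rows(sites.tail(100))
        pd.testing.assert_frame_equal(q1, q2)

    def test_empty_training_set_rejected(self, sites):
        with pytest.raises(ValueError):
            train(sites.head(0))

    def test_median_recovery_against_generator_truth(
        self, site_config, sites, trained_model
    ):
        """Predicted q50 tracks the closed-form conditional median within 15%
        mean absolute relative error."""
        fresh = generate_sites(SyntheticConfig(n_sites=4000, seed=99))
        q50 = trained_model.predict_rows(fresh)["q50"].to_numpy()
        truth = true_quantile_frame(site_config, fresh, 0.5)
        assert np.mean(np.abs(q50 - truth) / truth) < 0.15

    def test_heldout_coverage(self, sites, split, trained_model):
        """Fraction of held-out observations under predicted q75/q90 is close
        to nominal."""
        _, test_idx, _ = split
        test = sites.iloc[test_idx]
        q = trained_model.predict_rows(test)
        y = test["soc_pct"].to_numpy()
        assert np.mean(y <= q["q75"].to_numpy()) == pytest.approx(0.75, abs=0.05)
        assert np.mean(y <= q["q90"].to_numpy()) == pytest.approx(0.90, abs=0.05)

    def test_landcover_effect_recovery(self, trained_model):
        """At matched climate the model's q75 for pasture/natural exceeds
        cropland's, mirroring the generator's class offsets."""
        base = {"mat": 10.0, "tap": 900.0, "elevation": 300.0}
        crop = pd.DataFrame([{**base, "landcover": "cropland"}])
        past = pd.DataFrame([{**base, "landcover": "pasture_natural"}])
        q_crop = trained_model.predict_rows(crop)["q75"].iloc[0]
        q_past = trained_model.predict_rows(past)["q75"].iloc[0]
        assert q_past > q_crop


class TestPrediction:
    def test_output_ordering_and_floor(self, trained_model, sites):
        q = trained_model.predict_rows(sites.head(500))
        arr = q.to_numpy()
        assert np.all(np.diff(arr, axis=1) >= 0)
        assert np.all(arr >= 0)

    def test_row_order_invariance(self, trained_model, sites):
        head = sites.head(50)
        fwd = trained_model.predict_rows(head)
        rev = trained_model.predict_rows(head.iloc[::-1]).iloc[::-1]
        np.testing.assert_allclose(fwd.to_numpy(), rev.to_numpy())

    def test_grid_prediction_single_cell(self, trained_model, site_config):
        from socquant.synthetic import generate_grid

        ds = generate_grid(1, 1, site_config, seed=8)
        out = trained_model.predict_grid(ds)
        assert set(out.data_vars) == {"q25", "q50", "q75", "q90", "q95"}
        assert out["q50"].shape == (1, 1)

    def test_save_load_roundtrip(self, trained_model, sites, tmp_path):
        from socquant.model import TrainedQuantileModel

        trained_model.save(tmp_path / "m")
        loaded = TrainedQuantileModel.load(tmp_path / "m")
        a = trained_model.predict_rows(sites.head(20))
        b = loaded.predict_rows(sites.head(20))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestRmse:
    def test_hand_value(self):
        # residuals 3 and 4 -> sqrt(25/2)
        assert np.sqrt(np.mean(np.array([3.0, 4.0]) ** 2)) == pytest.approx(3.5355, abs=1e-4)

    def test_perfect_and_baseline(self, trained_model, sites, split):
        _, test_idx, _ = split
        test = sites.iloc[test_idx]
        model_rmse = rmse_q50(trained_model, test)
        median_pred = np.median(sites["soc_pct"])
        baseline = float(np.sqrt(np.mean((test["soc_pct"] - median_pred) ** 2)))
        assert model_rmse < baseline

    def test_empty_test_set(self, trained_model, sites):
        with pytest.raises(ValueError):
            rmse_q50(trained_model, sites.head(0))
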