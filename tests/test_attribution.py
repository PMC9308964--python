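"""Sampled Shapley attribution: exact-enumeration oracle on a linear model,
local accuracy, symmetry and the percent-change summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from socquant.attribution import (
    contribution_change,
    shapley_sample,
    temperature_group,
    to_long_csv,
)

FEATURES = ["mat", "tap", "elevation", "landcover"]


class LinearModel:
    """Linear in three continuous covariates + a land-cover indicator; the
    second head doubles the first."""

    def __init__(self, w=(1.0, -2.0, 0.5, 3.0)):
        self.w = np.asarray(w)

    def _x(self, frame):
        return np.column_stack(
            [
                frame["mat"].to_numpy(float),
                frame["tap"].to_numpy(float),
                frame["elevation"].to_numpy(float),
                (frame["landcover"] == "forest").to_numpy(float),
            ]
        )

    def predict_rows(self, frame):
        base = self._x(frame) @ self.w
        return pd.DataFrame({"q50": base, "q75": 2.0 * base}, index=frame.index)


class ConstantModel:
    def predict_rows(self, frame):
        return pd.DataFrame({"q50": np.full(len(frame), 4.2)}, index=frame.index)


def exact_shapley_enumeration(model, instance, background, features):
    """Exact Shapley values by enumerating all 2^k coalitions, with absent
    features marginalized over the background sample."""

    def value(coalition):
        frames = background.copy()
        for f in coalition:
            frames[f] = instance[f]
        return model.predict_rows(frames).mean(axis=0)

    k = len(features)
    contributions = {f: 0.0 for f in features}
    from math import factorial

    for f in features:
        others = [g for g in features if g != f]
        for r in range(k):
            weight = factorial(r) * factorial(k - r - 1) / factorial(k)
            for coalition in itertools.combinations(others, r):
                gain = value(list(coalition) + [f]) - value(list(coalition))
                contributions[f] += weight * float(gain["q50"])
    return contributions


@pytest.fixture(scope="module")
def background(rng=np.random.default_rng(7)):
    return pd.DataFrame(
        {
            "mat": rng.normal(10, 5, 150),
            "tap": rng.normal(900, 300, 150),
            "elevation": rng.normal(400, 200, 150),
            "landcover": rng.choice(["cropland", "forest"], 150),
        }
    )


class TestShapleySample:
    def test_constant_model_zero_contributions(self, background):
        res = shapley_sample(ConstantModel(), background.head(2), background,
                            n_permutations=50, seed=1)
        np.testing.assert_allclose(res.contributions.to_numpy(), 0.0, atol=1e-12)

    def test_matches_exact_enumeration_for_linear_model(self, background):
        model = LinearModel()
        instance = background.iloc[0]
        exact = exact_shapley_enumeration(model, instance, background, FEATURES)
        res = shapley_sample(model, background.head(1), background,
                            n_permutations=2000, seed=2)
        got = res.contributions.xs(0, level="instance")["q50"]
        scale = max(abs(v) for v in exact.values())
        for f in FEATURES:
            assert got[f] == pytest.approx(exact[f], abs=0.05 * scale)

    def test_local_accuracy_within_monte_carlo_error(self, background):
        """base + sum(contributions) reproduces the prediction; the tolerance
        is a 3-sigma Monte-Carlo bound from the background spread."""
        model = LinearModel()
        res = shapley_sample(model, background.head(4), background,
                            n_permutations=2000, seed=3)
        gap = res.local_accuracy_gap()["q50"].to_numpy()
        bg_sd = model.predict_rows(background)["q50"].std()
        bound = 3.0 * bg_sd * np.sqrt(len(FEATURES) / 2000)
        assert np.all(np.abs(gap) < bound)

    def test_symmetry_of_identical_covariates(self, background):
        """Two covariates entering the model identically receive equal
        contributions up to sampling error."""

        class Symmetric(LinearModel):
            def predict_rows(self, frame):
                s = frame["mat"].to_numpy(float) + frame["tap"].to_numpy(float)
                return pd.DataFrame({"q50": s}, index=frame.index)

        bg = background.copy()
        bg["tap"] = bg["mat"].sample(frac=1.0, random_state=0).to_numpy()
        inst = bg.head(1).copy()
        inst["tap"] = inst["mat"]
        res = shapley_sample(Symmetric(), inst, bg, n_permutations=3000, seed=4)
        got = res.contributions.xs(inst.index[0], level="instance")["q50"]
        assert got["mat"] == pytest.approx(got["tap"], abs=0.1 * abs(got["mat"]) + 0.5)

    def test_seeded_determinism(self, background):
        a = shapley_sample(LinearModel(), background.head(2), background, 100, seed=5)
        b = shapley_sample(LinearModel(), background.head(2), background, 100, seed=5)
        pd.testing.assert_frame_equal(a.contributions, b.contributions)

    def test_empty_background_rejected(self, background):
        with pytest.raises(ValueError):
            shapley_sample(LinearModel(), background.head(1), background.head(0), 10, 1)


class TestContributionChange:
    def test_identical_heads_zero_change(self, background):
        class SameHeads(LinearModel):
            def predict_rows(self, frame):
                base = self._x(frame) @ self.w
                return pd.DataFrame({"q50": base, "q75": base}, index=frame.index)

        res = shapley_sample(SameHeads(), background.head(3), background, 200, seed=6)
        change = contribution_change(res, "q50", "q75")
        np.testing.assert_allclose(change.to_numpy(), 0.0, atol=1e-9)

    def test_doubled_head_is_plus_100_percent(self, background):
        res = shapley_sample(LinearModel(), background.head(3), background, 200, seed=7)
        change = contribution_change(res, "q50", "q75")
        np.testing.assert_allclose(change.to_numpy(), 100.0, atol=1e-9)

    def test_growing_landcover_influence_orders_changes(self):
        """When the generator widens the SOC dispersion by land cover, the
        land-cover contribution grows faster toward q90 than the climate
        contributions — the pattern the percent-change summary must expose."""
        from socquant.model import ModelSpec, TrainingConfig, train
        from socquant.synthetic import SyntheticConfig, generate_sites

        cfg = SyntheticConfig(
            n_sites=6000, seed=31,
            landcover_sigma_log={"cropland": 0.35, "pasture_natural": 0.55,
                                 "forest": 0.7},
        )
        sites = generate_sites(cfg)
        model = train(sites, ModelSpec(),
                      TrainingConfig(epochs=120, batch_size=128,
                                     learning_rate=0.003, seed=31,
                                     lr_final_fraction=0.05))
        rng = np.random.default_rng(32)
        inst = sites.iloc[rng.choice(len(sites), 20, replace=False)]
        bg = sites.iloc[rng.choice(len(sites), 100, replace=False)]
        res = shapley_sample(model, inst, bg, n_permutations=120, seed=33)
        change = contribution_change(res, "q50", "q90")
        assert change["landcover"] > change["mat"]
        assert change["landcover"] > change["tap"]


class TestHelpers:
    def test_temperature_groups(self):
        groups = temperature_group([5.0, 12.0, 25.0])
        assert list(groups) == ["cold", "intermediate", "warm"]

    def test_long_csv_roundtrip(self, background, tmp_path):
        res = shapley_sample(LinearModel(), background.head(2), background, 50, seed=8)
        path = tmp_path / "attr.csv"
        to_long_csv(res, path)
        long = pd.read_csv(path)
        assert set(long.columns) == {"instance", "covariate", "percentile",
                                     "contribution"}
        assert len(long) == 2 * 4 * 2
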