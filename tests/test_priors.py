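"""Shapley attribution backends and class-prior construction.

The independent oracles here are (a) the closed-form Shapley values of a
linear model, w_v * (x_v - ref_v), and (b) a test-local exhaustive subset
enumeration, both kept separate from the package's backends.
"""

import itertools
import math

import numpy as np
import pytest

from ddgen.netcore import CNNClassifier, ModelConfig
from ddgen.phantom import Dim3, VolumeSample
from ddgen.priors import (
    AttributionConfig,
    PriorSet,
    attribute_sample,
    build_class_priors,
    load_prior_set,
    resample_prior,
    save_prior_set,
)


class LinearToyModel:
    """logit_k = sum_v W[k, v] * x_v over a (2, 2, 3) grid."""

    def __init__(self, n_classes=2, shape=(2, 2, 3), seed=0):
        self.shape = shape
        rng = np.random.default_rng(seed)
        self.W = rng.normal(size=(n_classes, int(np.prod(shape))))

    def logits(self, volume):
        return self.W @ np.asarray(volume).ravel()

    def input_gradient(self, volume, target_class):
        return self.W[target_class].reshape(self.shape)


class ProductToyModel:
    """Non-linear, permutation-symmetric in the first two voxels:
    logit_0 = x_0 * x_1 + 0.5 * x_2 (flattened order)."""

    shape = (1, 1, 3)

    def logits(self, volume):
        x = np.asarray(volume).ravel()
        return np.array([x[0] * x[1] + 0.5 * x[2]])


def exhaustive_shapley(f, x, ref, target):
    """Test-local classical Shapley enumeration over all voxels."""
    x, ref = np.asarray(x, float), np.asarray(ref, float)
    idx = list(np.ndindex(x.shape))
    n = len(idx)
    out = np.zeros_like(x)
    for j, vox in enumerate(idx):
        phi = 0.0
        others = [i for i in range(n) if i != j]
        for size in range(n):
            for subset in itertools.combinations(others, size):
                v = ref.copy()
                for i in subset:
                    v[idx[i]] = x[idx[i]]
                base = f(v)[target]
                v[vox] = x[vox]
                with_j = f(v)[target]
                phi += (math.factorial(size) * math.factorial(n - size - 1)
                        / math.factorial(n)) * (with_j - base)
        out[vox] = phi
    return out


class TestAttributeSample:
    def test_input_equal_to_reference_gives_zero(self):
        model = LinearToyModel()
        x = np.random.default_rng(0).uniform(size=model.shape)
        sal = attribute_sample(model, x, x, 0)
        np.testing.assert_array_equal(sal.values, 0.0)

    def test_linear_model_closed_form(self):
        model = LinearToyModel(seed=3)
        rng = np.random.default_rng(1)
        x = rng.uniform(size=model.shape)
        ref = rng.uniform(size=model.shape)
        for k in range(2):
            sal = attribute_sample(model, x, ref, k,
                                   AttributionConfig(n_samples=4, seed=0))
            expect = model.W[k].reshape(model.shape) * (x - ref)
            np.testing.assert_allclose(sal.values, expect, atol=1e-12)

    def test_linear_model_matches_exhaustive_oracle(self):
        model = LinearToyModel(seed=5)
        rng = np.random.default_rng(2)
        x = rng.uniform(size=model.shape)
        ref = np.zeros(model.shape)
        oracle = exhaustive_shapley(model.logits, x, ref, 1)
        sampled = attribute_sample(model, x, ref, 1,
                                   AttributionConfig(n_samples=8, seed=1))
        exact = attribute_sample(model, x, ref, 1,
                                 AttributionConfig(method="exact"))
        np.testing.assert_allclose(sampled.values, oracle, rtol=0.02,
                                   atol=1e-12)
        np.testing.assert_allclose(exact.values, oracle, atol=1e-10)

    def test_symmetric_voxels_get_equal_attribution(self):
        model = ProductToyModel()
        x = np.array([0.8, 0.8, 0.4]).reshape(model.shape)
        ref = np.zeros(model.shape)
        exact = attribute_sample(model, x, ref, 0,
                                 AttributionConfig(method="exact")).values
        oracle = exhaustive_shapley(model.logits, x, ref, 0)
        np.testing.assert_allclose(exact, oracle, atol=1e-12)
        assert exact.ravel()[0] == pytest.approx(exact.ravel()[1], abs=1e-12)

    def test_completeness_on_a_small_network(self):
        cfg = ModelConfig(n_classes=2, input_dims=Dim3(8, 8, 8),
                          encoder_widths=[4], seed=2)
        model = CNNClassifier(cfg)
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(8, 8, 8))
        ref = np.zeros((8, 8, 8))
        sal = attribute_sample(model, x, ref, 0,
                               AttributionConfig(n_samples=64, seed=4))
        gap = model.logits(x)[0] - model.logits(ref)[0]
        assert sal.values.sum() == pytest.approx(gap, rel=0.02)

    def test_completeness_residual_shrinks_with_samples(self):
        """Monte-Carlo path sampling: the completeness residual's spread
        over repeats decreases as the sample count doubles twice."""
        cfg = ModelConfig(n_classes=2, input_dims=Dim3(8, 8, 8),
                          encoder_widths=[2], seed=6)
        model = CNNClassifier(cfg)
        rng = np.random.default_rng(7)
        x = rng.uniform(size=(8, 8, 8))
        ref = np.zeros((8, 8, 8))
        gap = model.logits(x)[0] - model.logits(ref)[0]
        stds = []
        for n in (4, 8, 16):
            residuals = [
                attribute_sample(model, x, ref, 0,
                                 AttributionConfig(n_samples=n, seed=s)
                                 ).values.sum() - gap
                for s in range(12)
            ]
            stds.append(np.std(residuals))
        assert stds[2] < stds[0]

    def test_reference_shape_mismatch(self):
        model = LinearToyModel()
        with pytest.raises(ValueError, match="reference"):
            attribute_sample(model, np.zeros(model.shape), np.zeros((1, 1, 1)),
                             0)


class _StubModel:
    """Predicts a fixed class per subject id; linear attribution."""

    class config:
        n_classes = 2

    def __init__(self, predictions):
        self.predictions = predictions
        self.W = np.ones(8)

    def logits(self, volume):
        key = round(float(np.asarray(volume).ravel()[0]), 6)
        pred = self.predictions.get(key, 0)
        out = np.zeros(2)
        out[pred] = 1.0
        return out + 1e-3 * self.W @ np.asarray(volume).ravel()

    def input_gradient(self, volume, target_class):
        return np.full((2, 2, 2), 1e-3)


class TestBuildClassPriors:
    def _samples(self):
        vols = [np.full((2, 2, 2), v) for v in (0.1, 0.2, 0.3, 0.4)]
        labels = [0, 0, 1, 1]
        return [
            VolumeSample(volume=v, label=l, domain="d",
                         subject_id=f"s{i}")
            for i, (v, l) in enumerate(zip(vols, labels))
        ]

    def test_two_sample_average_before_scaling(self):
        samples = self._samples()
        model = _StubModel({0.1: 0, 0.2: 0, 0.3: 1, 0.4: 1})
        ps = build_class_priors(model, samples, scale_mode="none")
        # attribution for sample with constant v against zero reference is
        # 1e-3 * v at every voxel; class averages follow
        np.testing.assert_allclose(
            ps.priors[0], np.full((2, 2, 2), 1e-3 * 0.15), atol=1e-12
        )
        np.testing.assert_allclose(
            ps.priors[1], np.full((2, 2, 2), 1e-3 * 0.35), atol=1e-12
        )
        assert ps.n_samples_used.tolist() == [2, 2]

    def test_maxabs_rescales_peak_to_one(self):
        prior = np.zeros((2, 2, 2))
        prior[0, 0, 0] = -2.0
        prior[1, 1, 1] = 1.0
        ps = PriorSet(priors=prior[None])
        from ddgen.priors import _maxabs

        scaled = _maxabs(prior)
        assert scaled[0, 0, 0] == -1.0
        assert scaled[1, 1, 1] == 0.5
        # idempotence
        np.testing.assert_array_equal(_maxabs(scaled), scaled)
        assert ps.n_classes == 1

    def test_class_without_correct_predictions_errors(self):
        samples = self._samples()
        model = _StubModel({0.1: 0, 0.2: 0, 0.3: 0, 0.4: 0})  # never class 1
        with pytest.raises(ValueError, match=r"\[1\]"):
            build_class_priors(model, samples)
        ps = build_class_priors(model, samples, fall_back_to_all=True)
        assert ps.n_samples_used[1] == 2

    def test_deterministic(self):
        samples = self._samples()
        model = _StubModel({0.1: 0, 0.2: 0, 0.3: 1, 0.4: 1})
        cfg = AttributionConfig(n_samples=4, seed=9)
        a = build_class_priors(model, samples, cfg)
        b = build_class_priors(model, samples, cfg)
        np.testing.assert_array_equal(a.priors, b.priors)


class TestResamplePrior:
    def test_constant_maps_to_constant(self):
        out = resample_prior(np.full((4, 4, 4), 2.5), (7, 5, 3))
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_identity_resample_is_bit_identical(self):
        x = np.random.default_rng(0).normal(size=(5, 6, 7))
        assert np.array_equal(resample_prior(x, (5, 6, 7)), x)

    def test_trilinear_center_of_corner_impulse(self):
        x = np.zeros((2, 2, 2))
        x[0, 0, 0] = 1.0
        out = resample_prior(x, (3, 3, 3))
        assert out[1, 1, 1] == pytest.approx(0.125)
        assert out[0, 0, 0] == pytest.approx(1.0)

    def test_rejects_degenerate_target(self):
        with pytest.raises(ValueError, match=">= 1"):
            resample_prior(np.zeros((4, 4, 4)), (0, 4, 4))


class TestPersistence:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        ps = PriorSet(priors=rng.normal(size=(3, 4, 4, 4)),
                      n_samples_used=np.array([5, 4, 3]),
                      source_model_id="baseline-a")
        save_prior_set(ps, tmp_path / "priors", seed=11)
        loaded = load_prior_set(tmp_path / "priors")
        assert loaded.n_classes == 3
        assert loaded.source_model_id == "baseline-a"
        assert loaded.n_samples_used.tolist() == [5, 4, 3]
        np.testing.assert_allclose(loaded.priors, ps.priors, atol=1e-6)
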