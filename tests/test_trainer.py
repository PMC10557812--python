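"""Training orchestration: stratified splits, augmentation, Mixup,
gradient accumulation, and the two training stages."""

import numpy as np
import pytest

from ddgen.losses import LossConfig
from ddgen.netcore import CNNClassifier, ModelConfig
from ddgen.phantom import Dim3, DomainSpec, VolumeSample, generate_cohort, make_atlas
from ddgen.priors import PriorSet
from ddgen.trainer import (
    AugmentPolicy,
    TrainConfig,
    augment,
    mixup_batch,
    stratified_folds,
    train_baseline,
    train_guided,
)
from .conftest import make_cohort_spec


class TestStratifiedFolds:
    def test_exact_divisibility_gives_equal_blocks(self):
        labels = {f"s{i}": i % 3 for i in range(30)}
        fa = stratified_folds(labels, k=5, seed=0)
        for f in range(5):
            block = [s for s, b in fa.fold_of_subject.items() if b == f]
            counts = np.bincount([labels[s] for s in block], minlength=3)
            assert counts.tolist() == [2, 2, 2]

    def test_roles_rotate_three_one_one(self):
        labels = {f"s{i}": i % 3 for i in range(30)}
        fa = stratified_folds(labels, k=5, seed=0)
        for f in range(5):
            roles = fa.roles[f]
            n = {r: sum(v == r for v in roles.values())
                 for r in ("train", "val", "test")}
            assert n == {"train": 18, "val": 6, "test": 6}
        # test blocks rotate: each subject is tested exactly once
        tested = set()
        for f in range(5):
            tested |= {s for s, r in fa.roles[f].items() if r == "test"}
        assert tested == set(labels)

    def test_deterministic(self):
        labels = {f"s{i}": i % 2 for i in range(20)}
        a = stratified_folds(labels, k=5, seed=3)
        b = stratified_folds(labels, k=5, seed=3)
        assert a.fold_of_subject == b.fold_of_subject

    def test_class_smaller_than_k_errors(self):
        labels = {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0, "f": 1}
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_folds(labels, k=5)

    def test_imbalanced_cohort_proportions_within_one_subject(self):
        counts = {0: 2524, 1: 1175, 2: 948}
        labels = {}
        i = 0
        for c, n in counts.items():
            for _ in range(n):
                labels[f"s{i}"] = c
                i += 1
        fa = stratified_folds(labels, k=5, seed=1)
        for f in range(5):
            block = [s for s, b in fa.fold_of_subject.items() if b == f]
            got = np.bincount([labels[s] for s in block], minlength=3)
            for c in range(3):
                ideal = counts[c] * len(block) / len(labels)
                assert abs(got[c] - ideal) <= 1.0


def _sample(seed=0, side=8):
    rng = np.random.default_rng(seed)
    return VolumeSample(volume=rng.uniform(size=(side,) * 3), label=1,
                        domain="d", subject_id="x")


class TestAugment:
    def test_noop_policy_only_rescales(self):
        s = _sample()
        policy = AugmentPolicy(per_transform_probability=0.0)
        out = augment(s, policy, seed=1)
        v = s.volume
        expect = (v - v.min()) / (v.max() - v.min())
        np.testing.assert_allclose(out.volume, expect, atol=1e-12)
        assert out.label == s.label and out.domain == s.domain

    def test_identity_crop_preserves_geometry(self):
        s = _sample(1)
        policy = AugmentPolicy(per_transform_probability=1.0,
                               contrast_range=(1.0, 1.0),
                               bias_field_amplitude=0.0,
                               crop_fraction=1.0)
        out = augment(s, policy, seed=2)
        assert out.volume.shape == s.volume.shape

    def test_deterministic_for_fixed_seed(self):
        s = _sample(2)
        policy = AugmentPolicy(per_transform_probability=0.7)
        a = augment(s, policy, seed=5).volume
        b = augment(s, policy, seed=5).volume
        assert np.array_equal(a, b)

    def test_output_dims_always_preserved(self):
        s = _sample(3)
        policy = AugmentPolicy(per_transform_probability=1.0,
                               crop_fraction=0.6)
        for seed in range(5):
            assert augment(s, policy, seed).volume.shape == s.volume.shape

    def test_tiny_crop_rejected(self):
        s = _sample(4)
        policy = AugmentPolicy(per_transform_probability=1.0,
                               crop_fraction=0.05)
        with pytest.raises(ValueError, match="2 voxels"):
            for seed in range(10):
                augment(s, policy, seed)


class TestMixup:
    def test_endpoint_lambda_keeps_batch(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(4, 3, 3, 3))
        y = np.eye(3)[[0, 1, 2, 0]]
        mx, my = mixup_batch(x, y, alpha=0.2, seed=1, lam=1.0)
        np.testing.assert_array_equal(mx, x)
        np.testing.assert_array_equal(my, y)

    def test_midpoint_of_constant_volumes(self):
        x = np.stack([np.zeros((2, 2, 2)), np.ones((2, 2, 2))])
        y = np.eye(2)
        mx, my = mixup_batch(x, y, alpha=0.2, seed=0, lam=0.5)
        np.testing.assert_allclose(mx, 0.5)
        np.testing.assert_allclose(my, 0.5)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            mixup_batch(np.zeros((2, 2, 2, 2)), np.eye(2), alpha=0.0)

    def test_seeded_draws_reproducible(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(6, 2, 2, 2))
        y = np.eye(3)[rng.integers(0, 3, 6)]
        a = mixup_batch(x, y, alpha=0.2, seed=9)
        b = mixup_batch(x, y, alpha=0.2, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


@pytest.fixture(scope="module")
def train_setup():
    dims = Dim3(12, 12, 12)
    atlas = make_atlas(dims, 4, seed=2)
    spec = make_cohort_spec(dims, atlas, n_per=4, seed=3)
    samples, _ = generate_cohort(spec, atlas)
    mc = ModelConfig(n_classes=3, input_dims=dims, encoder_widths=[4, 6],
                     seed=5)
    return samples, mc


class TestTraining:
    def test_zero_epochs_returns_initial_model(self, train_setup):
        samples, mc = train_setup
        tc = TrainConfig(epochs=0, steps_per_epoch=5, micro_batch=2,
                         accumulation_steps=1, seed=0)
        result = train_baseline(samples, tc, mc)
        init = CNNClassifier(mc)
        for k, v in init.params.items():
            np.testing.assert_array_equal(result.model.params[k], v)
        assert len(result.log) == 0

    def test_loss_decreases_on_separable_phantom(self, train_setup):
        samples, mc = train_setup
        tc = TrainConfig(epochs=5, steps_per_epoch=10, micro_batch=2,
                         accumulation_steps=2, learning_rate=1e-2, seed=1)
        result = train_baseline(samples, tc, mc)
        first = result.log[result.log.epoch == 0].wce.mean()
        last = result.log[result.log.epoch == 4].wce.mean()
        assert last < first

    def test_gradient_accumulation_equivalence(self, train_setup):
        """2 x 8 accumulated micro-batches produce the same first update
        as one batch of 16, for the plain and the guided objective."""
        samples, mc = train_setup
        prior_grids = np.random.default_rng(0).normal(
            size=(3,) + mc.feature_dims
        )
        priors = PriorSet(priors=np.stack(
            [p for p in prior_grids]
        ))
        for use_priors in (False, True):
            results = []
            for micro, accum in ((2, 8), (16, 1)):
                tc = TrainConfig(epochs=1, steps_per_epoch=1,
                                 micro_batch=micro,
                                 accumulation_steps=accum,
                                 learning_rate=1e-3, seed=42,
                                 loss=LossConfig(lambda_=0.01))
                if use_priors:
                    r = train_guided(samples, priors, tc, mc)
                else:
                    r = train_baseline(samples, tc, mc)
                results.append(r.model.state_dict())
            for k in results[0]:
                a, b = results[0][k], results[1][k]
                np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-10)

    def test_lambda_zero_guided_matches_baseline_exactly(self, train_setup):
        samples, mc = train_setup
        priors = PriorSet(
            priors=np.random.default_rng(1).normal(size=(3,) + mc.feature_dims)
        )
        tc0 = TrainConfig(epochs=1, steps_per_epoch=3, micro_batch=2,
                          accumulation_steps=2, learning_rate=1e-3, seed=7,
                          loss=LossConfig(lambda_=0.0))
        rb = train_baseline(samples, tc0, mc)
        rg = train_guided(samples, priors, tc0, mc)
        for k in rb.model.params:
            np.testing.assert_array_equal(rb.model.params[k],
                                          rg.model.params[k])
        np.testing.assert_allclose(rb.log.wce.values, rg.log.wce.values)

    def test_stage_two_initialization_is_independent(self, train_setup):
        _, mc = train_setup
        other = ModelConfig(n_classes=3, input_dims=mc.input_dims,
                            encoder_widths=mc.encoder_widths, seed=mc.seed + 1)
        a = CNNClassifier(mc).params["enc0.W"]
        b = CNNClassifier(other).params["enc0.W"]
        assert not np.allclose(a, b)

    def test_guided_requires_matching_class_count(self, train_setup):
        samples, mc = train_setup
        priors = PriorSet(priors=np.zeros((2,) + mc.feature_dims))
        tc = TrainConfig(epochs=1, steps_per_epoch=1, seed=0)
        with pytest.raises(ValueError, match="classes"):
            train_guided(samples, priors, tc, mc)

    def test_sim_component_logged_during_guided_training(self, train_setup):
        samples, mc = train_setup
        priors = PriorSet(
            priors=np.random.default_rng(2).normal(size=(3,) + mc.feature_dims)
        )
        tc = TrainConfig(epochs=1, steps_per_epoch=2, micro_batch=2,
                         accumulation_steps=1, learning_rate=1e-3, seed=3,
                         loss=LossConfig(lambda_=0.5))
        r = train_guided(samples, priors, tc, mc)
        assert (r.log.sim > 0).all()
        np.testing.assert_allclose(
            r.log.total.values,
            r.log.wce.values + 0.5 * r.log.sim.values,
            rtol=1e-12,
        )
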