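"""Loss functions, class weighting, GEM projection, and curriculum training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from cryosse.nn.unet import NetworkConfig, UNet3D
from cryosse.training import (
    Adam,
    ClassWeights,
    CurriculumPhase,
    TrainConfig,
    collect_flat_grads,
    combined_loss,
    compute_class_weights,
    gem_project,
    loss_and_logit_grad,
    sample_episodic_memory,
    train_curriculum,
)

EQUAL = ClassWeights(1 / 3, 1 / 3, 1 / 3)


def grids_with_freqs(freqs, n=1000):
    counts = np.round(np.asarray(freqs) * n).astype(int)
    labels = np.repeat([0, 1, 2], counts)
    return [labels.reshape(-1, 1, 1)]


class TestClassWeights:
    def test_inverse_frequency_example(self):
        w = compute_class_weights(grids_with_freqs([0.8, 0.1, 0.1]))
        np.testing.assert_allclose(w.as_array(), [0.0588, 0.4706, 0.4706], atol=1e-4)

    def test_uniform_frequencies_give_equal_weights(self):
        w = compute_class_weights(grids_with_freqs([1 / 3, 1 / 3, 1 / 3], n=999))
        np.testing.assert_allclose(w.as_array(), 1 / 3)

    def test_rare_classes_outweigh_background(self):
        w = compute_class_weights(grids_with_freqs([0.98, 0.01, 0.01], n=10000))
        assert w.w_background < w.w_helix and w.w_background < w.w_sheet

    def test_missing_class_raises_with_name(self):
        with pytest.raises(ValueError, match="sheet"):
            compute_class_weights([np.array([[[0, 1, 0, 1]]])])


class TestCombinedLoss:
    def test_perfect_one_hot_prediction_is_zero(self):
        truth = np.array([[[0, 1, 2]]])
        probs = np.eye(3)[truth]
        assert combined_loss(probs, truth, EQUAL, dice_weight=0.5) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_equal_weights_is_ln3(self):
        truth = np.array([[[0, 1, 2, 1]]])
        probs = np.full(truth.shape + (3,), 1 / 3)
        loss = combined_loss(probs, truth, EQUAL, dice_weight=0.0)
        assert loss == pytest.approx(np.log(3), abs=1e-6)

    def test_soft_dice_on_two_voxel_instance(self):
        # truth (helix, sheet); probs 0.5 on the true class of each voxel
        truth = np.array([[[1, 2]]])
        probs = np.array([[[[0.3, 0.5, 0.2], [0.25, 0.25, 0.5]]]])
        # hand evaluation of 1 - 2Σpt/(Σp+Σt) per class, averaged:
        # background: Σp=0.55, Σt=0, inter=0        → 1.0
        # helix:      Σp=0.75, Σt=1, inter=0.5      → 1 - 1.0/1.75
        # sheet:      Σp=0.70, Σt=1, inter=0.5      → 1 - 1.0/1.70
        expected = (1.0 + (1 - 1.0 / 1.75) + (1 - 1.0 / 1.70)) / 3
        loss = combined_loss(probs, truth, EQUAL, dice_weight=1.0)
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_lattice_mismatch_raises(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((2, 2, 2, 3)), np.zeros((2, 2, 3)), EQUAL, 0.5)

    def test_loss_nonnegative_and_zero_only_at_truth(self, rng):
        truth = rng.integers(0, 3, (4, 4, 4))
        probs = rng.dirichlet(np.ones(3), size=truth.shape)
        assert combined_loss(probs, truth, EQUAL, 0.5) > 0

    def test_upweighting_a_class_increases_its_error_cost(self):
        truth = np.array([[[1, 0]]])  # a mislabelled helix voxel + a perfect one
        probs = np.array([[[[0.8, 0.1, 0.1], [1.0, 0.0, 0.0]]]])
        cheap = combined_loss(probs, truth, ClassWeights(0.6, 0.2, 0.2), 0.0)
        dear = combined_loss(probs, truth, ClassWeights(0.2, 0.6, 0.2), 0.0)
        assert dear > cheap

    def test_logit_grad_matches_numerical(self, rng):
        logits = rng.normal(size=(3, 3, 2, 2)).astype(np.float32)
        truth = rng.integers(0, 3, (3, 2, 2))
        w = ClassWeights(0.2, 0.5, 0.3)
        loss, grad = loss_and_logit_grad(logits, truth, w, 0.4)
        eps = 1e-4
        for _ in range(10):
            idx = tuple(rng.integers(0, s) for s in logits.shape)
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            num = (loss_and_logit_grad(lp, truth, w, 0.4)[0]
                   - loss_and_logit_grad(lm, truth, w, 0.4)[0]) / (2 * eps)
            assert num == pytest.approx(grad[idx], abs=2e-4)


class TestGemProject:
    def test_nonconflicting_gradient_unchanged(self):
        g = np.array([1.0, 2.0])
        out = gem_project(g, np.array([1.0, 0.0]))
        np.testing.assert_array_equal(out, g)

    def test_fully_opposed_gradient_becomes_zero(self):
        g = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(gem_project(g, -g), 0.0, atol=1e-12)

    def test_closed_form_example(self):
        np.testing.assert_allclose(gem_project(np.array([1.0, -3.0]), np.array([0.0, 1.0])),
                                   [1.0, 0.0], atol=1e-12)

    def test_zero_memory_gradient_raises(self):
        with pytest.raises(ValueError):
            gem_project(np.ones(3), np.zeros(3))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_projection_is_nearest_feasible_point(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=4)
        m = rng.normal(size=4)
        out = gem_project(g, m)
        assert out @ m >= -1e-6
        res = minimize(lambda x: 0.5 * np.sum((x - g) ** 2), g,
                       constraints=[{"type": "ineq", "fun": lambda x: x @ m}],
                       method="SLSQP", options={"ftol": 1e-14, "maxiter": 500})
        np.testing.assert_allclose(out, res.x, atol=1e-6)


class TestEpisodicMemory:
    def test_seeded_sample_is_reproducible(self):
        pool = list(range(10))
        a = sample_episodic_memory(pool, 5, np.random.default_rng(3))
        b = sample_episodic_memory(pool, 5, np.random.default_rng(3))
        assert a == b and len(a) == 5 and len(set(a)) == 5

    def test_small_pool_returned_whole(self):
        assert sample_episodic_memory([1, 2, 3], 5, np.random.default_rng(0)) == [1, 2, 3]

    def test_curriculum_phase_invariants(self):
        with pytest.raises(ValueError):
            CurriculumPhase(2, (1,))
        assert CurriculumPhase(3, (1, 2, 3)).bins_included == (1, 2, 3)


def _toy_samples(rng, n, size=8):
    samples = []
    for _ in range(n):
        labels = np.zeros((size, size, size), dtype=np.int8)
        labels[2:5, 2:5, 2:5] = 1
        labels[5:7, 5:7, 5:7] = 2
        vol = (labels > 0).astype(np.float32) * 0.8 + rng.random((size, size, size)).astype(np.float32) * 0.2
        samples.append((vol, labels))
    return samples


class TestTrainCurriculum:
    def test_empty_bin1_raises(self):
        model = UNet3D(NetworkConfig(base_channels=2), seed=0)
        with pytest.raises(ValueError):
            train_curriculum(model, {1: [], 2: [], 3: []}, TrainConfig())

    def test_phase1_only_never_projects(self, rng):
        model = UNet3D(NetworkConfig(base_channels=2), seed=0)
        samples = _toy_samples(rng, 3)
        cfg = TrainConfig(epochs_per_phase=(1, 0, 0), seed=0)
        _, history = train_curriculum(model, {1: samples}, cfg)
        assert history["gem_projections"] == 0
        assert history["memory_sizes"] == [0, 0, 0]

    def test_seed_reproducible_loss_history(self, rng):
        samples = _toy_samples(rng, 4)
        bins = {1: samples[:2], 2: samples[2:3], 3: samples[3:]}
        histories = []
        for _ in range(2):
            model = UNet3D(NetworkConfig(base_channels=2), seed=5)
            _, h = train_curriculum(model, {k: list(v) for k, v in bins.items()},
                                    TrainConfig(epochs_per_phase=(1, 1, 1), seed=5))
            histories.append([e["train_loss"] for e in h["epochs"]])
        assert histories[0] == histories[1]

    def test_degenerate_curriculum_equals_plain_training(self, rng):
        """All data in Bin 1 with zero-epoch later phases must reproduce a
        plain (no curriculum, no GEM) training loop step for step."""
        samples = _toy_samples(rng, 3)
        cfg = TrainConfig(epochs_per_phase=(2, 0, 0), seed=9)
        model = UNet3D(NetworkConfig(base_channels=2), seed=9)
        _, history = train_curriculum(model, {1: list(samples)}, cfg)

        # independent plain loop on the public layer API
        plain = UNet3D(NetworkConfig(base_channels=2), seed=9)
        weights = compute_class_weights([l for _, l in samples])
        opt = Adam(plain, cfg.learning_rate)
        plain_rng = np.random.default_rng(cfg.seed)
        losses = []
        for _ in range(2):
            order = plain_rng.permutation(len(samples))
            total = 0.0
            for i in order:
                vol, lab = samples[i]
                plain.zero_grad()
                logits = plain.forward_logits(vol, training=True)
                loss, dl = loss_and_logit_grad(logits, lab, weights, cfg.dice_weight)
                plain.backward(dl)
                opt.step()
                total += loss
            losses.append(total / len(samples))
        assert losses == [e["train_loss"] for e in history["epochs"]]

    def test_gradient_accumulation_runs_and_reproduces(self, rng):
        samples = _toy_samples(rng, 5)
        losses = []
        for _ in range(2):
            model = UNet3D(NetworkConfig(base_channels=2), seed=2)
            _, h = train_curriculum(model, {1: list(samples)},
                                    TrainConfig(epochs_per_phase=(2, 0, 0),
                                                batch_size=2, seed=2))
            losses.append([e["train_loss"] for e in h["epochs"]])
        assert losses[0] == losses[1]

    def test_rotation_augmentation_keeps_labels_aligned(self, rng):
        from cryosse.training import _random_right_angle_rotation
        vol = rng.random((4, 6, 8)).astype(np.float32)
        labels = (vol > 0.5).astype(np.int8)
        v, l = _random_right_angle_rotation(vol, labels, rng)
        assert sorted(v.shape) == [4, 6, 8]
        assert v.shape == l.shape
        np.testing.assert_array_equal(l, (v > 0.5).astype(np.int8))

    def test_best_validation_checkpoint_restored(self, rng):
        from cryosse.training import _validation_f1
        samples = _toy_samples(rng, 4)
        model = UNet3D(NetworkConfig(base_channels=2, dropout_rate=0.0), seed=6)
        val = [samples[0]]
        cfg = TrainConfig(epochs_per_phase=(4, 0, 0), seed=6, select_best=True)
        _, history = train_curriculum(model, {1: list(samples)}, cfg, validation=val)
        assert "best_epoch" in history
        recorded = [e["val_f1"] for e in history["epochs"]]
        assert history["best_val_f1"] == max(recorded)
        # restored weights reproduce the recorded best validation score
        assert _validation_f1(model, val) == pytest.approx(history["best_val_f1"])

    def test_gem_used_in_later_phases_and_loss_decreases(self, rng):
        samples = _toy_samples(rng, 6)
        bins = {1: samples[:2], 2: samples[2:4], 3: samples[4:]}
        model = UNet3D(NetworkConfig(base_channels=2, dropout_rate=0.0), seed=3)
        cfg = TrainConfig(epochs_per_phase=(2, 2, 2), seed=3, learning_rate=3e-3)
        _, history = train_curriculum(model, bins, cfg,
                                      validation=[samples[0]])
        losses = [e["train_loss"] for e in history["epochs"]]
        assert np.isfinite(losses).all()
        assert losses[-1] < losses[0]
        assert history["memory_sizes"][1] > 0  # memory existed in phase 2
        assert all(np.isfinite(e["val_loss"]) for e in history["epochs"])
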