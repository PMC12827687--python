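"""Objectives: energy loss, lr scaling, micro-oracles, gradients, training."""

import math

import numpy as np
import pytest

from remap_energy.datasets import WorldConfig, make_datasets
from remap_energy.network import NetworkConfig, init_weights, run_batch
from remap_energy.training import (
    ObjectiveSpec,
    TrainingConfig,
    bce_categorization_loss,
    energy_gradients,
    energy_loss,
    infonce_loss,
    scaled_learning_rates,
    train_model,
)


def _trace_with_pre(pre_values, cfg):
    """Forge a trace whose recorded preactivations are the given constants."""
    from remap_energy.network import FixationTrace

    B, S = 1, 1 + cfg.steps_per_fixation
    pre = []
    for l, n in enumerate(cfg.layer_sizes):
        p = np.full((B, S, n), pre_values[l], dtype=float)
        p[:, 0] = 0.0  # warm-up
        pre.append(p)
    crops = np.zeros((B, 1, cfg.n_image_units))
    effs = np.zeros((B, 1, 2))
    return FixationTrace(pre=pre, crops=crops, efferences=effs, config=cfg)


class TestEnergyLoss:
    def test_zero_preactivations_zero_loss(self):
        cfg = NetworkConfig(crop_side=2, n_hidden_layers=1, hidden_size=2,
                            steps_per_fixation=6, scene_side=4)
        assert energy_loss(_trace_with_pre([0.0, 0.0], cfg)) == 0.0

    def test_constant_preactivation_gives_its_magnitude(self):
        cfg = NetworkConfig(crop_side=2, n_hidden_layers=1, hidden_size=2,
                            steps_per_fixation=6, scene_side=4)
        assert energy_loss(_trace_with_pre([-1.7, -1.7], cfg)) == pytest.approx(1.7)

    def test_two_unit_double_sum(self):
        """N = 2 units with preactivations +2 and −1 at each of 6 steps:
        L = (6·2 + 6·1)/(6·2) = 1.5."""
        from remap_energy.network import FixationTrace

        cfg = NetworkConfig(crop_side=1, n_hidden_layers=1, hidden_size=1,
                            steps_per_fixation=6, use_efference=False, scene_side=4)
        assert cfg.n_units_total == 2
        pre0 = np.full((1, 7, 1), 2.0)
        pre1 = np.full((1, 7, 1), -1.0)
        pre0[:, 0] = pre1[:, 0] = 0
        trace = FixationTrace(pre=[pre0, pre1], crops=np.zeros((1, 1, 1)),
                              efferences=np.zeros((1, 1, 2)), config=cfg)
        assert energy_loss(trace) == pytest.approx(1.5)

    def test_invariant_to_unit_and_batch_permutation(self, rng):
        cfg = NetworkConfig(crop_side=2, n_hidden_layers=1, hidden_size=5,
                            steps_per_fixation=3, scene_side=8)
        w = init_weights(cfg, 0)
        crops = rng.random((4, 2, 4))
        effs = rng.normal(0, 1, (4, 2, 2))
        trace = run_batch(crops, effs, w)
        base = energy_loss(trace)
        # permute batch
        perm = rng.permutation(4)
        trace_p = run_batch(crops[perm], effs[perm], w)
        assert energy_loss(trace_p) == pytest.approx(base)
        # permute hidden units consistently across all matrices
        p = rng.permutation(5)
        w2 = w.copy()
        w2.bu[0] = w.bu[0][p]
        w2.lat[0] = w.lat[0][p][:, p]
        w2.td[0] = w.td[0][:, p]
        w2.bias[1] = w.bias[1][p]
        assert energy_loss(run_batch(crops, effs, w2)) == pytest.approx(base)

    def test_empty_batch_rejected(self):
        cfg = NetworkConfig(crop_side=2, n_hidden_layers=1, hidden_size=2,
                            steps_per_fixation=3, scene_side=8)
        w = init_weights(cfg, 0)
        with pytest.raises(ValueError):
            run_batch(np.zeros((1, 0, 4)), np.zeros((1, 0, 2)), w)


class TestScaledLearningRates:
    def test_paper_scale_first_bottom_up_factor(self):
        """16,384-image-unit source into a 2,048 target → factor ≈ 0.125."""
        cfg = NetworkConfig(crop_side=128, n_hidden_layers=2, hidden_size=2048)
        w = init_weights(cfg, 0)
        lrs = scaled_learning_rates(w, 0.0005)
        assert lrs["bu1"] == pytest.approx(0.125 * 0.0005, rel=2e-3)
        for name in ("bu2", "lat1", "lat2", "td0", "td1"):
            assert lrs[name] == 0.0005

    def test_equal_width_layers_unscaled(self):
        cfg = NetworkConfig(crop_side=2, n_hidden_layers=2, hidden_size=6,
                            steps_per_fixation=2, scene_side=4)
        # input_dim = 6 = hidden_size → every factor is 1
        w = init_weights(cfg, 0)
        assert set(scaled_learning_rates(w, 0.1).values()) == {0.1}


class TestMicroOracles:
    def test_bce_at_half_probability_is_ln2(self):
        p = np.full((3, 5), 0.5)
        y = np.zeros((3, 5))
        y[:, 0] = 1
        assert bce_categorization_loss(p, y) == pytest.approx(math.log(2), rel=1e-6)

    def test_bce_single_class_closed_form(self):
        assert bce_categorization_loss(np.array([[0.8]]), np.array([[1.0]])) == \
            pytest.approx(-math.log(0.8), rel=1e-6)

    def test_bce_perfect_confident_prediction(self):
        p = np.array([[1.0, 0.0]])
        y = np.array([[1.0, 0.0]])
        assert bce_categorization_loss(p, y) <= 1e-6

    def test_bce_rejects_soft_labels(self):
        with pytest.raises(ValueError, match="multi-hot"):
            bce_categorization_loss(np.array([[0.5]]), np.array([[0.3]]))

    def test_infonce_uniform_similarities_ln9(self):
        """Equal similarity to the positive and all 8 negatives → ln 9."""
        a = np.array([1.0, 0.0])
        p = np.array([1.0, 1.0])
        negs = np.tile(p, (8, 1))
        assert infonce_loss(a, p, negs, 0.1) == pytest.approx(math.log(9), rel=1e-9)

    def test_infonce_one_negative_equal_sim_ln2(self):
        a = np.array([1.0, 0.0])
        p = np.array([0.0, 1.0])
        assert infonce_loss(a, p, p[None], 0.5) == pytest.approx(math.log(2), rel=1e-9)

    def test_infonce_separated_case_closed_form(self):
        """sim(a,p)=1, sim(a,nᵢ)=0, τ=0.1 → −ln(e¹⁰/(e¹⁰+8)) ≈ 3.63e−4."""
        a = np.array([1.0, 0.0])
        negs = np.tile(np.array([0.0, 1.0]), (8, 1))
        expected = -math.log(math.exp(10) / (math.exp(10) + 8))
        assert infonce_loss(a, a, negs, 0.1) == pytest.approx(expected, rel=1e-6)

    def test_infonce_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            infonce_loss(np.zeros(2), np.ones(2), np.ones((1, 2)))


class TestGradients:
    def test_energy_gradient_matches_finite_differences(self):
        """Autodiff-style BPTT gradient vs. central finite differences on a
        toy network: relative error ≤ 1e−4 on sampled weights."""
        cfg = NetworkConfig(crop_side=3, n_hidden_layers=2, hidden_size=4,
                            steps_per_fixation=3, scene_side=12)
        w = init_weights(cfg, 0)
        rng = np.random.default_rng(5)
        crops = rng.random((2, 3, 9))
        effs = rng.normal(0, 2, (2, 3, 2))
        _, grads = energy_gradients(run_batch(crops, effs, w), w)
        h = 1e-6
        checked = 0
        for name, g in grads.named().items():
            flat = w.named()[name].reshape(-1)
            gflat = g.reshape(-1)
            for _ in range(4):
                i = rng.integers(flat.size)
                orig = flat[i]
                flat[i] = orig + h
                up = energy_loss(run_batch(crops, effs, w))
                flat[i] = orig - h
                down = energy_loss(run_batch(crops, effs, w))
                flat[i] = orig
                fd = (up - down) / (2 * h)
                if abs(fd) < 1e-9 and abs(gflat[i]) < 1e-9:
                    continue
                assert abs(fd - gflat[i]) / max(abs(fd), abs(gflat[i])) <= 1e-4, name
                checked += 1
        assert checked >= 10


TINY_TRAIN_WORLD = WorldConfig(side=32, crop_side=16, n_fixations=4,
                               sequences_per_scene=3, n_texture_classes=4,
                               texture_prob=0.5)
TINY_TRAIN_NET = NetworkConfig(crop_side=16, n_hidden_layers=2, hidden_size=48,
                               steps_per_fixation=4, scene_side=32)


@pytest.fixture(scope="module")
def tiny_train_data():
    return make_datasets(40, 8, TINY_TRAIN_WORLD, seed=21)


class TestTrainModel:
    def test_log_length_matches_epochs(self, tiny_train_data):
        train, test = tiny_train_data
        tc = TrainingConfig(base_lr=0.002, batch_size=8, epochs=2,
                            objective="energy", seed=0)
        _, log = train_model(train, TINY_TRAIN_NET, tc, val_dataset=test)
        assert len(log.records) == 2

    def test_untrained_objective_returns_initialization(self, tiny_train_data):
        train, _ = tiny_train_data
        tc = TrainingConfig(epochs=1, objective="none", seed=3)
        w, log = train_model(train, TINY_TRAIN_NET, tc)
        ref = init_weights(
            TINY_TRAIN_NET,
            int(np.random.SeedSequence(3).generate_state(2, dtype=np.uint32)[0]),
        )
        assert np.array_equal(w.bu[0], ref.bu[0])
        assert log.records == []

    def test_deterministic_given_seed(self, tiny_train_data):
        train, test = tiny_train_data
        tc = TrainingConfig(base_lr=0.002, batch_size=8, epochs=2,
                            objective="energy", seed=9)
        w1, _ = train_model(train, TINY_TRAIN_NET, tc, val_dataset=test)
        w2, _ = train_model(train, TINY_TRAIN_NET, tc, val_dataset=test)
        for k in w1.named():
            assert np.array_equal(w1.named()[k], w2.named()[k])

    def test_energy_training_beats_untrained_and_decreases(self, tiny_train_data):
        train, test = tiny_train_data
        tc = TrainingConfig(base_lr=0.002, batch_size=8, epochs=12,
                            objective="energy", seed=1)
        w, log = train_model(train, TINY_TRAIN_NET, tc, val_dataset=test)
        frame = log.to_frame()
        assert frame.val_energy.iloc[-1] < frame.val_energy.iloc[0]
        crops, effs, _ = test.batch_arrays(list(range(8)))
        trained = energy_loss(run_batch(crops, effs, w))
        tc0 = TrainingConfig(epochs=1, objective="none", seed=1)
        w0, _ = train_model(train, TINY_TRAIN_NET, tc0)
        untrained = energy_loss(run_batch(crops, effs, w0))
        assert trained < untrained

    def test_objective_specificity_energy_lowest(self, tiny_train_data):
        """Networks trained on categorization or temporal contrastive
        objectives settle at higher energy than the energy-trained one."""
        train, test = tiny_train_data
        crops, effs, _ = test.batch_arrays(list(range(8)))
        spec = ObjectiveSpec(n_classes=4, n_negatives=4)
        finals = {}
        for objective, epochs in (("energy", 10), ("categorization", 4),
                                  ("contrastive", 4)):
            tc = TrainingConfig(base_lr=0.002, batch_size=8, epochs=epochs,
                                objective=objective, seed=2)
            w, _ = train_model(train, TINY_TRAIN_NET, tc, spec, val_dataset=test)
            finals[objective] = energy_loss(run_batch(crops, effs, w))
        assert finals["energy"] < finals["categorization"]
        assert finals["energy"] < finals["contrastive"]
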