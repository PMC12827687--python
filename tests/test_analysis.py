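"""Decoding, lesioning, feedback, similarity, spatial memory, clustering."""

import numpy as np
import pytest

from remap_energy.analysis import (
    ActivationMatrix,
    collect_activations,
    cluster_allocentric_units,
    feedback_inhibition_stats,
    fit_allocentric_decoder,
    hypothesis_correlation,
    hypothesis_matrices,
    ideal_inhibition,
    lesion_experiment,
    select_units_by_beta,
    similarity_matrix,
    SimilarityAnalysis,
    spatial_memory_analysis,
)
from remap_energy.controls import default_eval_indices, model_fixation_loss
from remap_energy.datasets import FixationSample
from remap_energy.estimators import AllocentricDecoder
from remap_energy.network import FixationTrace, NetworkConfig, init_weights, run_batch


class TestCollectActivations:
    def test_row_and_column_counts(self, tiny_data, tiny_weights):
        _, test = tiny_data
        mat = collect_activations(tiny_weights, test, max_sequences_per_scene=2)
        F = test.config.n_fixations
        cfg = tiny_weights.config
        assert mat.X.shape == (4 * 2 * F, cfg.n_hidden_total * cfg.steps_per_fixation)
        assert mat.alloc.shape == (mat.X.shape[0], 2)

    def test_zscoring_on_fit_rows(self, tiny_data, tiny_weights):
        _, test = tiny_data
        mat = collect_activations(tiny_weights, test)
        fit = fit_allocentric_decoder(mat, seed=0)
        kept = fit.kept_columns
        is_eval = np.isin(mat.scene_ids, fit.eval_scenes)
        Z = (mat.X[~is_eval][:, kept] - fit.column_mean[kept]) / fit.column_sd[kept]
        assert np.abs(Z.mean(axis=0)).max() < 1e-4
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-3


def _planted_matrix(n_scenes=30, rows_per_scene=7, n_units=20, T=2, noise=1.0,
                    plant=True, seed=0):
    """Activation matrix whose first two units (optionally) carry alloc_xy."""
    rng = np.random.default_rng(seed)
    n = n_scenes * rows_per_scene
    X = rng.normal(0, noise, (n, n_units * T))
    alloc = rng.uniform(10, 50, (n, 2))
    if plant:
        X[:, 0] = alloc[:, 0]
        X[:, 1] = alloc[:, 1]
    scene_ids = np.repeat([f"s{i}" for i in range(n_scenes)], rows_per_scene)
    return ActivationMatrix(
        X=X.astype(np.float32),
        alloc=alloc,
        scene_ids=scene_ids,
        sequence_index=np.zeros(n, dtype=int),
        fixation_index=np.tile(np.arange(rows_per_scene), n_scenes),
        n_hidden_total=n_units,
        steps_per_fixation=T,
    )


class TestAllocentricDecoding:
    def test_planted_code_reaches_perfect_r2(self):
        fit = fit_allocentric_decoder(_planted_matrix(noise=0.5), seed=1)
        assert np.all(fit.r2 > 0.999)

    def test_pure_noise_r2_near_zero(self):
        fit = fit_allocentric_decoder(
            _planted_matrix(n_scenes=100, rows_per_scene=10, plant=False, seed=2),
            seed=1,
        )
        assert np.all(np.abs(fit.r2) < 0.1)

    def test_cumulative_efference_oracle_is_exact(self, tiny_data):
        """Regressing alloc on the cumulative sum of efferences gives R² = 1:
        the model's decoder can never beat this path-integration oracle."""
        _, test = tiny_data
        feats, targets = [], []
        for seq in test.sequences:
            cum = np.vstack([np.zeros(2), np.cumsum(seq.efferences, axis=0)[:-1]])
            feats.append(cum)
            targets.append(seq.crop_centers)
        X = np.vstack(feats)
        y = np.vstack(targets).astype(float)
        dec = AllocentricDecoder().fit(X, y)
        assert np.all(dec.r2_per_coordinate(X, y) > 1 - 1e-9)

    def test_too_few_rows_refused(self):
        m = _planted_matrix(n_scenes=1, rows_per_scene=5)
        with pytest.raises(ValueError, match="rows"):
            fit_allocentric_decoder(m)

    def test_beta_selection_sorting_and_ties(self):
        fit = fit_allocentric_decoder(_planted_matrix(), seed=1)
        fit.unit_betas = np.array([3.0, 1.0, 2.0])
        assert np.array_equal(select_units_by_beta(fit, 2), [0, 2])
        fit.unit_betas = np.array([1.0, 1.0, 1.0])
        assert np.array_equal(select_units_by_beta(fit, 2), [0, 1])
        assert np.array_equal(select_units_by_beta(fit, 3), [0, 1, 2])
        with pytest.raises(ValueError, match="exceeds"):
            select_units_by_beta(fit, 4)

    def test_planted_units_receive_highest_betas(self):
        fit = fit_allocentric_decoder(_planted_matrix(noise=0.5), seed=1)
        assert set(select_units_by_beta(fit, 2)) == {0, 1}


class TestLesioning:
    def test_zero_unit_lesion_is_identity(self, tiny_data, tiny_weights):
        _, test = tiny_data
        rep = lesion_experiment(tiny_weights, test, np.array([], dtype=int), seed=0)
        assert np.array_equal(rep.loss_intact, rep.loss_targeted)

    def test_full_population_lesion_equals_zero_feedback_oracle(self, tiny_data):
        """Without bias terms, lesioning every hidden unit removes all
        feedback: layer-1 matches the zero-weight network exactly."""
        _, test = tiny_data
        cfg = NetworkConfig(crop_side=16, n_hidden_layers=2, hidden_size=32,
                            steps_per_fixation=3, scene_side=32, use_bias=False)
        w = init_weights(cfg, 5)
        idx = default_eval_indices(test)
        crops, effs, _ = test.batch_arrays(idx)
        mask = np.ones(cfg.n_hidden_total, dtype=bool)
        lesioned = model_fixation_loss(run_batch(crops, effs, w, mask))
        oracle = model_fixation_loss(run_batch(crops, effs, w.zero_like()))
        assert np.array_equal(lesioned, oracle)

    def test_full_population_lesion_with_bias_leaves_only_bias_feedback(
        self, tiny_data, tiny_weights
    ):
        """With biases, a full lesion reduces the layer-1 drive to input +
        layer-1 bias (the bias is not a hidden unit and survives)."""
        _, test = tiny_data
        H = tiny_weights.config.n_hidden_total
        idx = default_eval_indices(test)[:2]
        crops, effs, _ = test.batch_arrays(idx)
        mask = np.ones(H, dtype=bool)
        lesioned = run_batch(crops, effs, tiny_weights, mask)
        fb = lesioned.feedback_to_layer1()[:, 1:, :]
        C2 = tiny_weights.config.n_image_units
        expected = tiny_weights.bias[0][:C2]
        assert np.allclose(fb, expected[None, None, :])

    def test_out_of_range_ids_rejected(self, tiny_data, tiny_weights):
        _, test = tiny_data
        with pytest.raises(ValueError, match="out of range"):
            lesion_experiment(tiny_weights, test, np.array([10_000]), seed=0)

    def test_random_ids_disjoint_and_size_matched(self, tiny_data, tiny_weights):
        _, test = tiny_data
        targeted = np.array([0, 1, 2])
        rep = lesion_experiment(tiny_weights, test, targeted, seed=3)
        assert len(rep.random_ids) == 3
        assert not set(rep.random_ids) & set(targeted)


class TestFeedbackStats:
    def test_zero_feedback_distribution(self, tiny_data, tiny_net_config):
        _, test = tiny_data
        w = init_weights(tiny_net_config, 0).zero_like()
        stats = feedback_inhibition_stats(w, test)
        assert stats.mean == 0.0
        assert stats.ci == (0.0, 0.0)

    def test_sample_count(self, tiny_data, tiny_weights):
        _, test = tiny_data
        idx = default_eval_indices(test)
        stats = feedback_inhibition_stats(tiny_weights, test, idx)
        cfg = tiny_weights.config
        F = test.config.n_fixations
        assert stats.n == len(idx) * F * cfg.steps_per_fixation


class TestIdealInhibition:
    def test_negates_crop_and_cancels_exactly(self):
        crop = np.linspace(0.1, 0.9, 16)
        s = FixationSample(crop=crop, efference=np.zeros(2), alloc_xy=np.zeros(2))
        ideal = ideal_inhibition(s)
        assert ideal.shape == (4, 4)
        assert np.array_equal(ideal.ravel() + crop, np.zeros(16))

    def test_anticorrelated_with_crop(self):
        crop = np.random.default_rng(0).random(64)
        ideal = ideal_inhibition(crop).ravel()
        r = np.corrcoef(ideal, crop)[0, 1]
        assert r == pytest.approx(-1.0)


def _forged_trace(feedback_per_step, crops, cfg):
    """Trace whose layer-1 preactivation encodes crop + given feedback."""
    F = crops.shape[0]
    T = cfg.steps_per_fixation
    S = 1 + F * T
    pre0 = np.zeros((1, S, cfg.input_dim))
    for f in range(F):
        for t in range(T):
            s = 1 + f * T + t
            pre0[0, s, : cfg.n_image_units] = crops[f] + feedback_per_step[s - 1]
    return FixationTrace(
        pre=[pre0, np.zeros((1, S, cfg.hidden_size))],
        crops=crops[None],
        efferences=np.zeros((1, F, 2)),
        config=cfg,
    )


class TestSimilarityAnalysis:
    CFG = NetworkConfig(crop_side=4, n_hidden_layers=1, hidden_size=2,
                        steps_per_fixation=2, scene_side=16)

    def test_perfect_future_inhibition_scores_one(self, rng):
        F, T = 3, 2
        crops = rng.random((F, 16))
        fb = np.zeros((F * T, 16))
        for f in range(F):
            target = min(f + 1, F - 1)
            fb[f * T : (f + 1) * T] = -crops[target]
        trace = _forged_trace(fb, crops, self.CFG)
        M, undefined = similarity_matrix(trace)
        assert undefined == 0
        for f in range(F - 1):
            assert M[f * T, f + 1] == pytest.approx(1.0)

    def test_sign_flip_scores_minus_one(self, rng):
        crops = rng.random((2, 16))
        fb = np.tile(crops[1], (4, 1))  # feedback ≡ +crop_1 everywhere
        trace = _forged_trace(fb, crops, self.CFG)
        M, _ = similarity_matrix(trace)
        assert np.allclose(M[:, 1], -1.0)

    def test_independent_noise_has_small_entries(self, rng):
        cfg = NetworkConfig(crop_side=32, n_hidden_layers=1, hidden_size=2,
                            steps_per_fixation=2, scene_side=64)
        crops = rng.random((3, 1024))
        fb = rng.normal(0, 1, (6, 1024))
        M, _ = similarity_matrix(_forged_trace(fb, crops, cfg))
        assert np.quantile(np.abs(M), 0.99) < 0.12

    def test_constant_feedback_flagged_undefined(self, rng):
        crops = rng.random((2, 16))
        fb = rng.normal(0, 1, (4, 16))
        fb[0] = 0.25  # constant feedback image at step 0
        trace = _forged_trace(fb, crops, self.CFG)
        M, undefined = similarity_matrix(trace)
        assert undefined >= 2
        assert np.all(M[0] == 0)

    def test_hypothesis_matrix_construction(self):
        Hf, Hc = hypothesis_matrices(3, 2)
        assert Hf.shape == Hc.shape == (6, 3)
        assert Hf[0, 1] == 1 and Hf[1, 1] == 1 and Hf[:, 0].sum() == 0
        assert Hc[0, 0] == 1 and Hc[5, 2] == 1
        assert not np.any(Hf * Hc)

    def test_hypothesis_correlation_identities(self):
        Hf, _ = hypothesis_matrices(3, 2)
        analysis = SimilarityAnalysis(matrices=[Hf.copy(), Hf.copy(), Hf.copy()],
                                      n_fixations=3, steps_per_fixation=2)
        fit = hypothesis_correlation(analysis)
        assert fit.mean_r_future == pytest.approx(1.0)
        analysis_neg = SimilarityAnalysis(matrices=[-Hf, -Hf, -Hf],
                                          n_fixations=3, steps_per_fixation=2)
        assert hypothesis_correlation(analysis_neg).mean_r_future == pytest.approx(-1.0)

    def test_similarity_invariant_to_affine_feedback_rescale(self, rng):
        crops = rng.random((2, 16))
        fb = rng.normal(0, 1, (4, 16))
        M1, _ = similarity_matrix(_forged_trace(fb, crops, self.CFG))
        M2, _ = similarity_matrix(_forged_trace(3.0 * fb + 0.2, crops, self.CFG))
        assert np.allclose(M1, M2, atol=1e-9)


class TestSpatialMemory:
    def test_all_equal_losses_vanish(self, rng):
        coords = rng.uniform(0, 64, (10, 5, 2))
        table = spatial_memory_analysis(np.full((10, 5), 0.3), coords)
        filled = table.table[np.isfinite(table.table)]
        assert np.allclose(filled, 0.0)

    def test_planted_refixation_benefit(self, rng):
        """Pairs at short distance and lag 1 carry losses one sd below the
        mean → that cell is the most negative."""
        B, F = 60, 5
        coords = rng.uniform(0, 100, (B, F, 2))
        losses = rng.normal(1.0, 0.05, (B, F))
        # plant: wherever consecutive fixations are close, drop the loss
        planted = 0
        for b in range(B):
            for i in range(F - 1):
                if np.linalg.norm(coords[b, i + 1] - coords[b, i]) < 40:
                    losses[b, i + 1] -= 0.5
                    planted += 1
        assert planted > 10
        table = spatial_memory_analysis(losses, coords)
        assert np.nanargmin(table.table) == 0  # short distance, lag 1
        assert table.cell("short", 1) < -0.5

    def test_short_sequences_leave_long_lags_empty(self, rng):
        coords = rng.uniform(0, 64, (4, 3, 2))
        table = spatial_memory_analysis(rng.random((4, 3)), coords)
        assert np.isnan(table.table[:, 2]).all()  # lag 3 impossible with F = 3


class TestClustering:
    def test_two_planted_groups_recovered(self, rng):
        a = np.tile(np.linspace(0, 1, 36), (8, 1)) + rng.normal(0, 0.02, (8, 36))
        b = np.tile(np.linspace(1, 0, 36), (7, 1)) + rng.normal(0, 0.02, (7, 36))
        profiles = np.vstack([a, b])
        report = cluster_allocentric_units(profiles, k_range=range(2, 6), seed=0)
        assert report.k == 2
        labels = report.assignments
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_profiles_degenerate(self):
        profiles = np.tile(np.linspace(0, 1, 16), (6, 1))
        report = cluster_allocentric_units(profiles, seed=0)
        assert report.degenerate and report.k == 1

    def test_representatives_one_per_cluster(self, rng):
        profiles = rng.normal(0, 1, (12, 25))
        report = cluster_allocentric_units(profiles, k_range=range(2, 5), seed=1)
        assert len(report.representatives) == report.k
        for c, rep in enumerate(report.representatives):
            assert report.assignments[rep] == c
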