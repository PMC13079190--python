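"""Training loop contracts: augmentation, early stopping, determinism."""

import numpy as np
import pytest

import strokesym as ss
from strokesym.training import AdamW, augment, prepare_batch, split_dataset
from strokesym.nn.autodiff import Tensor


def _tiny_model_config(**kw):
    return dict(
        gcn_hidden=10, node_embed_dim=6, fused_node_dim=6, tcn_channels=10,
        d_model=12, d_k=6, fusion_dim=24, head_dims=(16, 12, 8), dropout=0.1,
        **kw,
    )


class TestAugment:
    def test_identity_when_all_magnitudes_zero(self, clean_sample, rng):
        out = augment(clean_sample, rng, flip_prob=0.0, max_shift=0,
                      noise_std=0.0, crop_range=(1.0, 1.0),
                      brightness=0.0, contrast=0.0)
        assert np.array_equal(out.keypoints.coords, clean_sample.keypoints.coords)
        assert out.handedness == clean_sample.handedness
        assert np.array_equal(out.rgb_features,
                              ss.render_rgb_features(clean_sample.keypoints))

    def test_flip_preserves_rule_labels_and_flips_handedness(self, rng):
        s = ss.generate_stroke(
            ss.default_template("forehand_drive"),
            ss.AsymmetryParams(shoulder_rot_asym=25.0, pelvic_tilt=7.0),
            seed=2, handedness="right",
        )
        out = augment(s, rng, flip_prob=1.0, max_shift=0, noise_std=0.0,
                      crop_range=(1.0, 1.0), brightness=0.0, contrast=0.0)
        assert out.handedness == "left"
        lab, _ = ss.classify_sequence(out.keypoints, body_height=s.body_height)
        risk, _ = ss.risk_level_sequence(out.keypoints, body_height=s.body_height)
        assert lab == s.y_asym
        assert risk == s.y_injury

    def test_temporal_jitter_preserves_length(self, clean_sample):
        for seed in range(6):
            out = augment(clean_sample, np.random.default_rng(seed),
                          flip_prob=0.0, max_shift=5, noise_std=0.0)
            assert out.keypoints.n_frames == clean_sample.keypoints.n_frames

    def test_augmentation_is_seeded(self, clean_sample):
        a = augment(clean_sample, np.random.default_rng(5))
        b = augment(clean_sample, np.random.default_rng(5))
        assert np.array_equal(a.keypoints.coords, b.keypoints.coords)
        assert np.array_equal(a.rgb_features, b.rgb_features)


class TestSplitsAndBatches:
    def test_split_fractions(self, small_cohort):
        samples, _ = small_cohort
        tr, val, te = split_dataset(samples, (0.7, 0.15, 0.15), seed=0)
        assert len(tr) + len(val) + len(te) == len(samples)
        assert len(tr) == round(0.7 * len(samples))

    def test_empty_split_rejected(self, small_cohort):
        samples, _ = small_cohort
        with pytest.raises(ValueError):
            split_dataset(samples[:2], (0.0, 0.5, 0.5), seed=0)

    def test_prepare_batch_shapes(self, small_cohort):
        samples, _ = small_cohort
        batch = prepare_batch(samples[:6])
        t = samples[0].keypoints.n_frames
        assert batch["coords"].shape == (6, t, 17, 3)
        assert batch["kin"].shape == (6, t - 4, 12)
        assert batch["rgb"].shape == (6, t, 256)
        assert batch["a_norm"].shape == (6, 17, 17)


class TestAdamW:
    def test_minimizes_quadratic_with_decay_shrinking_solution(self):
        x = Tensor(np.array([5.0]), requires_grad=True)
        opt = AdamW([x], lr=0.1, weight_decay=0.0)
        for _ in range(400):
            opt.zero_grad()
            loss = ((x - 2.0) ** 2.0).sum()
            loss.backward()
            opt.step()
        assert x.data[0] == pytest.approx(2.0, abs=1e-3)
        y = Tensor(np.array([5.0]), requires_grad=True)
        opt2 = AdamW([y], lr=0.1, weight_decay=0.5)
        for _ in range(800):
            opt2.zero_grad()
            ((y - 2.0) ** 2.0).sum().backward()
            opt2.step()
        assert 0.0 < y.data[0] < 2.0  # decay pulls below the unregularized optimum


@pytest.fixture(scope="module")
def mini_cohort():
    samples, _ = ss.generate_cohort(
        ss.CohortConfig(n_samples=40, seed=13, noise_std=0.005))
    return samples


class TestTrainLoop:
    def test_early_stopping_halts_exactly_patience_after_last_improvement(
        self, mini_cohort
    ):
        # learning rate 0 freezes the weights; after the batch-norm running
        # statistics settle the validation loss is constant, and training
        # must halt exactly `patience` epochs after the last improvement
        cfg = ss.TrainConfig(learning_rate=0.0, max_epochs=50, patience=10,
                             augment=False, batch_size=16, seed=3)
        state = ss.train(mini_cohort, ss.ModelConfig(**_tiny_model_config()), cfg)
        vals = state.history["val_loss"].to_numpy()
        best = np.minimum.accumulate(vals)
        last_improvement = 1 + int(np.flatnonzero(vals <= best).max())
        assert state.stopped_epoch == last_improvement + cfg.patience
        assert len(state.history) == state.stopped_epoch

    def test_history_tracks_positive_finite_task_weights(self, mini_cohort):
        cfg = ss.TrainConfig(max_epochs=2, augment=False, batch_size=16, seed=4)
        state = ss.train(mini_cohort, ss.ModelConfig(**_tiny_model_config()), cfg)
        h = state.history
        for col in ("w1", "w2", "sigma1", "sigma2"):
            assert np.all(np.isfinite(h[col])) and np.all(h[col] > 0)
        assert list(h["epoch"]) == [1, 2]

    def test_same_seed_identical_history(self, mini_cohort):
        cfg = ss.TrainConfig(max_epochs=2, augment=True, batch_size=16, seed=5)
        mc = ss.ModelConfig(**_tiny_model_config())
        h1 = ss.train(mini_cohort, mc, cfg).history
        h2 = ss.train(mini_cohort, mc, cfg).history
        assert np.allclose(h1["train_loss"], h2["train_loss"])
        assert np.allclose(h1["val_loss"], h2["val_loss"])

    def test_single_task_ablations_run(self, mini_cohort):
        for tasks in (("asym",), ("risk",)):
            cfg = ss.TrainConfig(max_epochs=1, augment=False, batch_size=16,
                                 tasks=tasks, seed=6)
            state = ss.train(mini_cohort, ss.ModelConfig(**_tiny_model_config()), cfg)
            assert len(state.history) == 1

    def test_invalid_tasks_rejected(self, mini_cohort):
        with pytest.raises(ValueError):
            ss.train(mini_cohort, train_config=ss.TrainConfig(tasks=("both",)))

    def test_checkpoint_round_trip(self, mini_cohort, tmp_path):
        cfg = ss.TrainConfig(max_epochs=1, augment=False, batch_size=16, seed=7)
        state = ss.train(mini_cohort, ss.ModelConfig(**_tiny_model_config()), cfg)
        path = tmp_path / "ckpt.npz"
        ss.save_checkpoint(state, path)
        back = ss.load_checkpoint(path)
        pa1, pr1 = ss.predict_proba(state, mini_cohort[:5])
        pa2, pr2 = ss.predict_proba(back, mini_cohort[:5])
        assert np.allclose(pa1, pa2) and np.allclose(pr1, pr2)
        assert back.history.equals(state.history)
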