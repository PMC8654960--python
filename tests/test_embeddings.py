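"""Sequence-embedding models: gradients, tasks, training, fine-tuning,
extraction, and bundle serialization."""

import numpy as np
import pytest

import vitalembed as ve
from vitalembed.embeddings import (
    TrainConfig,
    build_model,
    task_targets,
    train_embedding,
)
from vitalembed.nn import LSTMNet


def _ar1_windows(n, seed, rho=0.9, T=60, F=5):
    """Standardized AR(1) histories + futures for self-supervised targets."""
    rng = np.random.default_rng(seed)
    x = np.empty((n, T + F))
    x[:, 0] = rng.normal(size=n)
    sd = np.sqrt(1 - rho**2)
    for t in range(1, T + F):
        x[:, t] = rho * x[:, t - 1] + rng.normal(scale=sd, size=n)
    return x[:, :T], x[:, T:]


class TestBackprop:
    def test_gradients_match_numerical_differentiation(self):
        rng = np.random.default_rng(0)
        for act, out in (("linear", 3), ("sigmoid", 1)):
            net = LSTMNet(input_dim=2, hidden_dim=4, output_dim=out,
                          output_activation=act, seed=1)
            X = rng.normal(size=(4, 6, 2))
            Y = (rng.normal(size=(4, out)) if act == "linear"
                 else rng.integers(0, 2, size=(4, out)).astype(float))
            _, grads = net._loss_and_grads(X, Y)
            eps = 1e-6
            for key, P in net.params.items():
                flat = P.ravel()
                for idx in range(0, flat.size, max(1, flat.size // 5)):
                    old = flat[idx]
                    flat[idx] = old + eps
                    lp = net.loss(X, Y)
                    flat[idx] = old - eps
                    lm = net.loss(X, Y)
                    flat[idx] = old
                    num = (lp - lm) / (2 * eps)
                    assert grads[key].ravel()[idx] == pytest.approx(
                        num, rel=1e-4, abs=1e-7
                    )


class TestTaskTargets:
    def test_auto_target_is_the_history_itself(self):
        H, F = _ar1_windows(3, 0)
        np.testing.assert_array_equal(task_targets("auto", H), H)

    def test_next_target_is_the_future_block(self):
        H, F = _ar1_windows(3, 0)
        np.testing.assert_array_equal(task_targets("next", H, futures=F), F)

    def test_min_target_is_future_minimum(self):
        H, _ = _ar1_windows(1, 0)
        fut = np.array([[3.0, 1.0, 2.0, 5.0, 4.0]])
        assert task_targets("min", H, futures=fut)[0, 0] == 1.0

    def test_hypo_target_is_the_downstream_label(self):
        H, _ = _ar1_windows(4, 0)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        np.testing.assert_array_equal(
            task_targets("hypo", H, labels=y).ravel(), y
        )

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            build_model("SAO2", "contrastive", 8)


class TestBuildAndExtract:
    def test_rand_model_is_deterministic_in_seed(self):
        H, _ = _ar1_windows(5, 3)
        a = ve.extract(build_model("SAO2", "rand", 8, seed=4), H)
        b = ve.extract(build_model("SAO2", "rand", 8, seed=4), H)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("dim", [8, 200])
    def test_extraction_dimension_contract(self, dim):
        H, _ = _ar1_windows(3, 1)
        emb = ve.extract(build_model("SAO2", "rand", dim, seed=0), H)
        assert emb.shape == (3, dim)

    def test_extraction_is_pure(self):
        model = build_model("SAO2", "rand", 8, seed=2)
        H, _ = _ar1_windows(4, 5)
        np.testing.assert_array_equal(ve.extract(model, H), ve.extract(model, H))

    def test_input_arity_enforced(self):
        model = build_model("SAO2", "rand", 8, seed=0)
        with pytest.raises(ValueError):
            ve.extract(model, np.zeros((3, 59)))

    def test_rand_models_never_touch_training_data(self):
        model = build_model("SAO2", "rand", 8, seed=0)
        digest = model.net.weight_digest()
        with pytest.raises(ValueError):
            train_embedding(model, *(_ar1_windows(10, 0) * 2)[:4])
        assert model.net.weight_digest() == digest


class TestTraining:
    def test_auto_task_on_constant_cohort_reaches_near_zero_loss(self):
        H = np.zeros((200, 60))
        model = build_model("SAO2", "auto", 8, seed=0)
        model = train_embedding(
            model, H, task_targets("auto", H), H[:50], task_targets("auto", H[:50]),
            TrainConfig(max_epochs=10, patience=3, seed=0),
        )
        assert model.training_meta["best_val_loss"] < 1e-3

    def test_next_task_beats_mean_predictor_on_ar1(self):
        H, F = _ar1_windows(1500, 7, rho=0.9)
        vH, vF = _ar1_windows(400, 8, rho=0.9)
        model = build_model("SAO2", "next", 8, seed=0)
        model = train_embedding(
            model, H, task_targets("next", H, futures=F),
            vH, task_targets("next", vH, futures=vF),
            TrainConfig(max_epochs=20, patience=4, seed=0),
        )
        # the train-mean predictor scores the target variance (~1)
        assert model.training_meta["best_val_loss"] < vF.var()

    def test_best_checkpoint_has_minimal_recorded_val_loss(self):
        H, F = _ar1_windows(600, 9)
        vH, vF = _ar1_windows(200, 10)
        model = build_model("SAO2", "next", 8, seed=1)
        model = train_embedding(
            model, H, task_targets("next", H, futures=F),
            vH, task_targets("next", vH, futures=vF),
            TrainConfig(max_epochs=12, patience=12, seed=1),
        )
        curve_vals = [v for _, v in model.training_meta["curve"]]
        assert model.training_meta["best_val_loss"] <= min(curve_vals) + 1e-12

    def test_empty_training_set_raises(self):
        model = build_model("SAO2", "next", 8, seed=0)
        with pytest.raises(ValueError):
            train_embedding(model, np.empty((0, 60)), np.empty((0, 5)),
                            np.zeros((2, 60)), np.zeros((2, 5)))


class TestFineTune:
    def _pretrained(self):
        H, F = _ar1_windows(800, 11)
        vH, vF = _ar1_windows(200, 12)
        model = build_model("SAO2", "next", 8, seed=0, source_tag="A")
        model.norm = {"SAO2": (0.0, 1.0)}
        return train_embedding(
            model, H, task_targets("next", H, futures=F),
            vH, task_targets("next", vH, futures=vF),
            TrainConfig(max_epochs=10, patience=3, seed=0),
        )

    def test_zero_epochs_is_identity_on_extraction(self):
        pre = self._pretrained()
        H, _ = _ar1_windows(5, 13)
        tuned = ve.fine_tune(pre, "B", H, np.zeros((5, 5)), H,
                             np.zeros((5, 5)), TrainConfig(max_epochs=0))
        np.testing.assert_array_equal(ve.extract(pre, H), ve.extract(tuned, H))
        assert tuned.source_tag == "A->B"

    def test_warm_start_on_same_distribution_does_not_degrade(self):
        pre = self._pretrained()
        H, F = _ar1_windows(800, 11)
        vH, vF = _ar1_windows(200, 12)
        tuned = ve.fine_tune(
            pre, "A", H, task_targets("next", H, futures=F),
            vH, task_targets("next", vH, futures=vF),
            TrainConfig(max_epochs=5, patience=5, seed=1),
        )
        assert (tuned.training_meta["best_val_loss"]
                <= pre.training_meta["best_val_loss"] + 1e-6)


class TestJointModel:
    def test_head_covers_all_channels_and_extraction_dim_is_fixed(self):
        signals = ("SAO2", "ETCO2", "NIBPM")
        rng = np.random.default_rng(0)
        H = rng.normal(size=(300, 3, 60)) * 0.1
        F = rng.normal(size=(300, 3, 5)) * 0.1
        model = ve.train_joint_model(
            signals, H, F, H[:80], F[:80],
            norm={s: (0.0, 1.0) for s in signals}, source_tag="A",
            embedding_dim=8,
            config=TrainConfig(max_epochs=2, patience=2, seed=0),
        )
        assert model.net.output_dim == 3 * 5
        emb = ve.extract(model, H[:4])
        assert emb.shape == (4, 8)

    def test_missing_channel_stats_rejected(self):
        with pytest.raises(ValueError):
            ve.train_joint_model(
                ("SAO2", "ETCO2"), np.zeros((10, 2, 60)), np.zeros((10, 2, 5)),
                np.zeros((4, 2, 60)), np.zeros((4, 2, 5)),
                norm={"SAO2": (0.0, 1.0)}, source_tag="A", embedding_dim=4,
            )


class TestBundles:
    def test_round_trip_preserves_extraction(self, tmp_path):
        model = build_model("SAO2", "rand", 8, seed=3, source_tag="OR1")
        model.norm = {"SAO2": (96.5, 2.1)}
        path = ve.save_bundle(model, tmp_path / "m.npz")
        back = ve.load_bundle(path)
        H = np.random.default_rng(1).normal(size=(6, 60))
        np.testing.assert_array_equal(ve.extract(model, H), ve.extract(back, H))
        assert back.source_tag == "OR1" and back.norm["SAO2"] == (96.5, 2.1)
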