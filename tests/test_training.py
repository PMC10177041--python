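import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wtseg.networks import NetworkSpec, build_network, softmax
from wtseg.patches import AugmentationConfig, PatchSpec
from wtseg.taxonomy import UNANNOTATED
from wtseg.training import (
    PatchSampler,
    TrainingConfig,
    lr_schedule_from_history,
    masked_cross_entropy,
    plateau_scheduler,
    train,
)

from conftest import random_simplex


class TestMaskedCrossEntropy:
    def test_perfect_one_hot_prediction_is_zero(self):
        labels = np.array([[0, 1], [2, UNANNOTATED]])
        probs = np.zeros((2, 2, 3))
        for r in range(2):
            for c in range(2):
                if labels[r, c] != UNANNOTATED:
                    probs[r, c, labels[r, c]] = 1.0
                else:
                    probs[r, c] = 1 / 3
        assert masked_cross_entropy(probs, labels) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log_k(self):
        probs = np.full((4, 4, 15), 1 / 15)
        labels = np.random.default_rng(0).integers(0, 15, (4, 4))
        assert masked_cross_entropy(probs, labels) == pytest.approx(
            np.log(15), rel=1e-9
        )

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            probs = random_simplex(rng, (6, 5), 7)
            labels = rng.integers(0, 7, (6, 5)).astype(np.uint8)
            labels[rng.random((6, 5)) < 0.4] = UNANNOTATED
            if (labels == UNANNOTATED).all():
                continue
            total, n = 0.0, 0
            for r in range(6):
                for c in range(5):
                    if labels[r, c] != UNANNOTATED:
                        total += -np.log(probs[r, c, labels[r, c]])
                        n += 1
            assert masked_cross_entropy(probs, labels) == pytest.approx(
                total / n, abs=1e-6
            )

    def test_all_unannotated_batch_errors(self):
        probs = np.full((2, 2, 3), 1 / 3)
        labels = np.full((2, 2), UNANNOTATED)
        with pytest.raises(ValueError, match="resample"):
            masked_cross_entropy(probs, labels)

    def test_invariant_to_sample_order_within_batch(self):
        rng = np.random.default_rng(2)
        probs = random_simplex(rng, (4, 3, 3), 5)
        labels = rng.integers(0, 5, (4, 3, 3))
        perm = rng.permutation(4)
        assert masked_cross_entropy(probs, labels) == pytest.approx(
            masked_cross_entropy(probs[perm], labels[perm]), rel=1e-12
        )


class TestPlateauScheduler:
    def test_strict_improvement_keeps_rate(self):
        losses = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5]
        assert plateau_scheduler(losses, 0.0005, 0.5, 5) == 0.0005

    def test_five_stale_epochs_halve_rate(self):
        losses = [1.0] + [1.0] * 5
        assert plateau_scheduler(losses, 0.0005, 0.5, 5) == pytest.approx(0.00025)

    def test_two_plateaus_compose(self):
        losses = [1.0] + [1.0] * 5 + [1.0] * 5
        assert plateau_scheduler(losses, 0.0005, 0.5, 5) == pytest.approx(0.000125)

    def test_improvement_resets_counter(self):
        losses = [1.0, 1.0, 1.0, 1.0, 0.9, 0.9, 0.9, 0.9]
        assert plateau_scheduler(losses, 0.0005, 0.5, 5) == 0.0005

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.1, 3.0), min_size=0, max_size=30),
        st.integers(1, 6),
    )
    def test_rate_is_initial_times_power_of_factor(self, losses, patience):
        lr = plateau_scheduler(losses, 0.0005, 0.5, patience)
        k = round(np.log(0.0005 / lr) / np.log(2)) if lr < 0.0005 else 0
        assert lr == pytest.approx(0.0005 * 0.5**k)
        assert lr <= 0.0005


class TestNetworkContracts:
    @pytest.mark.parametrize(
        "family,shape",
        [("u-net", (412, 412)), ("dense-net", (128, 128)), ("u-net", (64, 64))],
    )
    def test_output_shape_and_simplex(self, family, shape):
        spec = NetworkSpec(family, shape, n_classes=15, preset="tiny", seed=0)
        model = build_network(spec)
        x = np.random.default_rng(0).random((1, *shape, 3), dtype=np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (1, *shape, 15)
        assert np.abs(probs.sum(axis=-1) - 1.0).max() < 1e-5

    def test_unsupported_family_errors(self):
        with pytest.raises(ValueError, match="family"):
            NetworkSpec("resnet", (64, 64))

    @pytest.mark.parametrize("family", ["u-net", "dense-net"])
    def test_analytic_gradients_match_numeric(self, family):
        spec = NetworkSpec(family, (8, 8), n_classes=4, preset="tiny", seed=0)
        model = build_network(spec)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 8, 8, 3)).astype(np.float32) * 0.1 + 0.5
        labels = rng.integers(0, 4, (2, 8, 8))
        onehot = np.eye(4)[labels]

        def loss():
            p = softmax(model.forward_logits(x))
            return float(-np.mean(np.sum(onehot * np.log(p + 1e-12), axis=-1)))

        p = softmax(model.forward_logits(x))
        d = ((p - onehot) / labels.size).astype(np.float32)
        for _, g in model.params():
            g[...] = 0.0
        model.backward(d)
        for pi in (0, len(model.params()) // 2, len(model.params()) - 2):
            par, grad = model.params()[pi]
            idx = tuple(rng.integers(0, s) for s in par.shape)
            eps = 1e-3
            old = float(par[idx])
            par[idx] = old + eps
            l1 = loss()
            par[idx] = old - eps
            l2 = loss()
            par[idx] = old
            numeric = (l1 - l2) / (2 * eps)
            assert numeric == pytest.approx(float(grad[idx]), rel=0.08, abs=2e-4)


@pytest.fixture(scope="module")
def tiny_samplers(small_cohort):
    _, images, _ = small_cohort
    spec = PatchSpec(shape=(32, 32), spacing=0.5)
    return (
        PatchSampler(images[:4], spec, AugmentationConfig()),
        PatchSampler(images[4:], spec, None),
    )


class TestTrainLoop:
    def test_loss_descends_on_easy_cohort(self, tiny_samplers):
        sampler, val = tiny_samplers
        model = build_network(NetworkSpec("u-net", (32, 32), 15, "tiny", seed=0))
        cfg = TrainingConfig(epochs=2, iterations_per_epoch=10, batch_size=4, seed=0)
        model, hist = train(model, sampler, val, cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.val_loss) == 2

    def test_trajectory_reproducible_from_seed(self, tiny_samplers):
        sampler, val = tiny_samplers
        cfg = TrainingConfig(epochs=2, iterations_per_epoch=5, batch_size=4, seed=3)
        runs = []
        for _ in range(2):
            model = build_network(
                NetworkSpec("dense-net", (32, 32), 15, "tiny", seed=3)
            )
            _, hist = train(model, sampler, val, cfg)
            runs.append((hist.train_loss, hist.val_loss))
        assert runs[0] == runs[1]

    def test_recorded_learning_rates_recomputable_from_history(self, tiny_samplers):
        sampler, val = tiny_samplers
        model = build_network(NetworkSpec("u-net", (32, 32), 15, "tiny", seed=1))
        cfg = TrainingConfig(
            epochs=4, iterations_per_epoch=2, batch_size=2, plateau_patience=1,
            seed=1, val_patches=4,
        )
        _, hist = train(model, sampler, val, cfg)
        assert hist.learning_rate == lr_schedule_from_history(
            hist.val_loss, cfg.initial_lr, cfg.decay_factor, cfg.plateau_patience
        )
        assert all(
            a >= b for a, b in zip(hist.learning_rate, hist.learning_rate[1:])
        )

    def test_divergence_aborts_with_diagnostics(self, tiny_samplers):
        sampler, val = tiny_samplers

        class Exploding:
            class spec:
                n_classes = 15
                family, preset = "u-net", "tiny"

            def params(self):
                return []

            def forward_logits(self, x):
                out = np.full((*x.shape[:3], 15), np.nan, dtype=np.float32)
                return out

            def backward(self, d):
                pass

        cfg = TrainingConfig(epochs=1, iterations_per_epoch=1, batch_size=2, seed=0)
        with pytest.raises((RuntimeError, ValueError)):
            train(Exploding(), sampler, val, cfg)
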