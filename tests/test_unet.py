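"""Tests of the encoder-decoder segmenter: shapes, loss, training contract."""

import numpy as np
import pytest

from fundus_vcdr import (
    SegModelConfig,
    TrainConfig,
    UNet,
    build_model,
    dice_loss,
    predict_labelmap,
    train_model,
)
from fundus_vcdr.synthetic import generate_samples


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(SegModelConfig(preset="small", input_size=32, rng_seed=0))


class TestArchitecture:
    def test_output_shape_and_softmax(self, tiny_model):
        x = np.random.default_rng(0).random((3, 32, 32)).astype(np.float32)
        probs = tiny_model.forward(x)
        assert probs.shape == (3, 32, 32)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_deterministic_initialization(self):
        cfg = SegModelConfig(preset="small", input_size=32, rng_seed=7)
        a, b = build_model(cfg), build_model(cfg)
        for (pa, _), (pb, _) in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)
        c = build_model(SegModelConfig(preset="small", input_size=32, rng_seed=8))
        assert any(not np.array_equal(pa, pc)
                   for (pa, _), (pc, _) in zip(a.params(), c.params()))

    def test_preset_parameter_ordering(self):
        counts = [build_model(SegModelConfig(preset=p, input_size=32 if p != "large" else 64,
                                             rng_seed=0)).num_params()
                  for p in ("small", "medium", "large")]
        assert counts[0] < counts[1] < counts[2]

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            SegModelConfig(preset="small", input_size=30)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            SegModelConfig(preset="huge")

    def test_save_load_roundtrip(self, tiny_model, tmp_path):
        x = np.random.default_rng(1).random((3, 32, 32)).astype(np.float32)
        before = tiny_model.forward(x)
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        after = UNet.load(path).forward(x)
        np.testing.assert_allclose(before, after, atol=1e-6)


class TestDiceLoss:
    def test_perfect_one_hot_is_near_zero(self):
        target = np.array([[0, 1], [2, 1]])
        probs = np.zeros((3, 2, 2), np.float32)
        for c in range(3):
            probs[c] = target == c
        assert dice_loss(probs, target) < 1e-5

    def test_uniform_prediction_closed_form(self):
        """Uniform 1/3 probabilities against an all-class-0 4x4 target:
        dice_0 = (2*16/3)/(16/3+16) = 0.5, dice_1 = dice_2 ~ 0,
        so the loss is 1 - 0.5/3 = 5/6."""
        target = np.zeros((4, 4), dtype=int)
        probs = np.full((3, 4, 4), 1 / 3, dtype=np.float32)
        assert dice_loss(probs, target) == pytest.approx(5 / 6, abs=1e-5)

    def test_pixel_permutation_invariance(self):
        rng = np.random.default_rng(0)
        target = rng.integers(0, 3, (4, 4))
        logits = rng.random((3, 4, 4)).astype(np.float32)
        probs = logits / logits.sum(axis=0)
        perm = rng.permutation(16)
        target_p = target.ravel()[perm].reshape(4, 4)
        probs_p = probs.reshape(3, 16)[:, perm].reshape(3, 4, 4)
        assert dice_loss(probs, target) == pytest.approx(
            dice_loss(probs_p, target_p), abs=1e-7)

    def test_bounded_zero_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            target = rng.integers(0, 3, (6, 6))
            logits = rng.random((3, 6, 6)).astype(np.float32)
            probs = logits / logits.sum(axis=0)
            assert 0.0 <= dice_loss(probs, target) <= 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((3, 4, 4)), np.zeros((5, 5)))

    def test_gradient_matches_finite_differences(self):
        """Analytic dL/dp agrees with central differences on a tiny raster."""
        rng = np.random.default_rng(3)
        target = rng.integers(0, 3, (3, 3))
        probs = rng.uniform(0.1, 1.0, (3, 3, 3)).astype(np.float64)
        probs /= probs.sum(axis=0)
        _, grad = dice_loss(probs, target, with_grad=True)
        eps = 1e-6
        for c in range(3):
            for i in range(3):
                for j in range(3):
                    p_hi, p_lo = probs.copy(), probs.copy()
                    p_hi[c, i, j] += eps
                    p_lo[c, i, j] -= eps
                    num = (dice_loss(p_hi, target) - dice_loss(p_lo, target)) / (2 * eps)
                    assert grad[c, i, j] == pytest.approx(num, abs=1e-4)


@pytest.fixture(scope="module")
def pairs():
    samples = generate_samples(1, 1, 99, image_size=128)
    return [(s.image, s.mask) for s in samples]


class TestTraining:
    def test_single_epoch_trace(self, pairs):
        model = build_model(SegModelConfig(preset="small", input_size=32,
                                           rng_seed=0))
        trace = train_model(model, pairs, TrainConfig(epochs=1, batch_size=2,
                                                      learning_rate=1e-3))
        assert len(trace) == 1 and 0 <= trace[0] <= 1

    def test_identical_seeds_identical_traces(self, pairs):
        traces = []
        for _ in range(2):
            model = build_model(SegModelConfig(preset="small", input_size=32,
                                               rng_seed=5))
            traces.append(train_model(
                model, pairs,
                TrainConfig(epochs=3, batch_size=1, learning_rate=1e-3,
                            rng_seed=5)))
        assert traces[0] == traces[1]

    def test_empty_dataset_raises(self):
        model = build_model(SegModelConfig(preset="small", input_size=32))
        with pytest.raises(ValueError):
            train_model(model, [], TrainConfig(epochs=1))

    def test_loss_decreases_on_fixture(self, pairs):
        model = build_model(SegModelConfig(preset="small", input_size=64,
                                           rng_seed=1))
        trace = train_model(model, pairs,
                            TrainConfig(epochs=15, batch_size=2,
                                        learning_rate=1e-3, rng_seed=1))
        assert trace[-1] < trace[0]


class TestPrediction:
    def test_labels_in_range_and_resized_back(self, tiny_model):
        image = np.random.default_rng(0).integers(0, 255, (50, 50, 3),
                                                  dtype=np.uint8)
        labels = predict_labelmap(tiny_model, image)
        assert labels.shape == (50, 50)
        assert set(np.unique(labels)) <= {0, 1, 2}

    def test_constant_image_constant_interior(self):
        """A constant input yields a spatially constant prediction away
        from the zero-padded borders (conv translation equivariance)."""
        model = build_model(SegModelConfig(preset="small", input_size=128,
                                           rng_seed=3))
        image = np.full((128, 128, 3), 127, dtype=np.uint8)
        labels = predict_labelmap(model, image)
        interior = labels[56:72, 56:72]
        assert (interior == interior[0, 0]).all()
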