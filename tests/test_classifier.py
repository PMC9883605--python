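import numpy as np
import pytest

from squigclass.classifier import (
    ConfigurationError,
    ModelConfig,
    build_classifier,
)
from squigclass.nn import bce_with_logits


SMALL = ModelConfig(input_length=200, initial_channels=8, n_stages=2,
                    blocks_per_stage=1, first_kernel=7, first_stride=2)


def test_forward_shape_and_range():
    model = build_classifier(ModelConfig(input_length=3000, n_stages=4), seed=0)
    X = np.random.default_rng(0).normal(size=(8, 3000)).astype(np.float32)
    p = model.forward(X)
    assert p.shape == (8,)
    assert np.all((p > 0) & (p < 1))


def test_channel_schedule_follows_growth():
    cfg = ModelConfig()
    assert cfg.stage_channels() == [20, 30, 45, 67]


def test_parameter_count_is_deterministic():
    a = build_classifier(SMALL, seed=0)
    b = build_classifier(SMALL, seed=1)
    assert a.n_parameters == b.n_parameters
    # identical seeds give identical weights
    c = build_classifier(SMALL, seed=0)
    for pa, pc in zip(a.parameters(), c.parameters()):
        assert np.array_equal(pa.value, pc.value)


def test_inference_is_deterministic_and_batch_equivariant():
    model = build_classifier(SMALL, seed=0)
    X = np.random.default_rng(1).normal(size=(12, 200)).astype(np.float32)
    p1 = model.forward(X)
    p2 = model.forward(X)
    assert np.array_equal(p1, p2)
    # concatenating batches == concatenating outputs (inference mode)
    split = np.concatenate([model.forward(X[:5]), model.forward(X[5:])])
    assert np.allclose(split, p1, atol=1e-6)


def test_training_mode_dropout_is_seeded():
    model = build_classifier(SMALL, seed=0)
    X = np.random.default_rng(1).normal(size=(6, 200)).astype(np.float32)
    model.reseed_dropout(123)
    p1 = model.forward(X, training=True)
    model.reseed_dropout(123)
    p2 = model.forward(X, training=True)
    assert np.array_equal(p1, p2)
    model.reseed_dropout(124)
    assert not np.array_equal(p1, model.forward(X, training=True))


def test_zero_dropout_training_forward_is_deterministic():
    cfg = ModelConfig(**{**vars(SMALL), "dropout_rate": 0.0})
    model = build_classifier(cfg, seed=0)
    X = np.random.default_rng(2).normal(size=(4, 200)).astype(np.float32)
    assert np.array_equal(model.forward(X, training=True),
                          model.forward(X, training=True))


def test_wrong_input_length_raises():
    model = build_classifier(SMALL, seed=0)
    with pytest.raises(ValueError, match="expected"):
        model.forward(np.zeros((2, 100), dtype=np.float32))


def test_too_short_input_rejected_at_build():
    with pytest.raises(ConfigurationError):
        build_classifier(ModelConfig(input_length=2, n_stages=4), seed=0)


def test_single_step_decreases_loss():
    model = build_classifier(SMALL, seed=0)
    rng = np.random.default_rng(3)
    X = rng.normal(size=(16, 200)).astype(np.float32)
    y = (rng.random(16) > 0.5).astype(float)
    opt = model.make_optimizer(1e-4)
    model.reseed_dropout(0)
    z = model.forward_logits(X, training=True)
    loss0, dz = bce_with_logits(z, y)
    opt.zero_grad()
    model.backward(dz)
    opt.step()
    model.reseed_dropout(0)  # same dropout masks: isolate the weight update
    loss1, _ = bce_with_logits(model.forward_logits(X, training=True), y)
    assert loss1 < loss0


def test_scaled_model_can_overfit_small_sample(simulated_pair):
    """Capacity check: the scaled 2-stage network must fit 64 labelled
    segments to >= 95% training accuracy within 200 optimization steps."""
    from squigclass.preprocess import PreprocessConfig, preprocess_dataset

    pcfg = PreprocessConfig(segment_length=1000, min_read_samples=2500,
                            segments_per_read_train=4, rng_seed=0)
    X, y, prov, _ = preprocess_dataset(simulated_pair[:8] + simulated_pair[-8:],
                                       pcfg, mode="train")
    assert len(X) == 64
    model = build_classifier(ModelConfig(input_length=1000, n_stages=2), seed=0)
    opt = model.make_optimizer(3e-3)
    acc = 0.0
    for _ in range(200):
        z = model.forward_logits(X, training=True)
        loss, dz = bce_with_logits(z, y)
        opt.zero_grad()
        model.backward(dz)
        opt.step()
        acc = np.mean((z >= 0) == (y == 1))
        if acc >= 0.95:
            break
    assert acc >= 0.95


def test_save_load_round_trip(tmp_path):
    model = build_classifier(SMALL, seed=0)
    X = np.random.default_rng(4).normal(size=(5, 200)).astype(np.float32)
    # a few training steps so running BN stats are non-trivial
    opt = model.make_optimizer(1e-3)
    y = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
    for _ in range(3):
        z = model.forward_logits(X, training=True)
        _, dz = bce_with_logits(z, y)
        opt.zero_grad()
        model.backward(dz)
        opt.step()
    before = model.forward(X)
    model.save(tmp_path / "m.npz")
    from squigclass.classifier import Classifier
    loaded = Classifier.load(tmp_path / "m.npz")
    assert np.allclose(loaded.forward(X), before, atol=1e-7)
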