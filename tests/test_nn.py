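import numpy as np
import pytest

import rtspect as r
from rtspect.nn import _ce_loss_grad, _encode_labels, _stratified_split


def hand_count_params(input_shape, conv_filters, kernel, fc_units, n_classes=3):
    """Layer-arithmetic oracle for the trainable-parameter count,
    computed independently of the network implementation."""
    H, W, C = input_shape
    total = 0
    ch = C
    for f in conv_filters:
        total += (kernel * kernel * ch + 1) * f          # conv
        cb = -(-f // 3)
        total += (3 * 3 * f + 1) * cb                    # branch a 3x3/2
        total += (f + 1) * cb + (3 * 3 * cb + 1) * cb    # branch b 1x1 + 3x3/2
        ch = 2 * cb + f                                  # pool branch passes f
        H, W = -(-H // 2), -(-W // 2)
    dim = H * W * ch
    for u in fc_units:
        total += (dim + 1) * u
        dim = u
    total += (dim + 1) * n_classes
    return total


def test_published_config_constants():
    cfg = r.published_config()
    assert cfg.conv_filters == (52, 104, 156, 208)
    assert cfg.kernel == 5
    assert cfg.fc_units == (713, 1019)
    assert cfg.dropout == pytest.approx(0.47)
    assert cfg.activation == "elu"
    assert cfg.optimizer == "adagrad"
    assert cfg.learning_rate == pytest.approx(0.006)
    assert cfg.epochs == 165
    assert cfg.val_fraction == pytest.approx(0.25)


def test_softmax_probabilities_sum_to_one():
    cfg = r.DecoderConfig(conv_filters=(4,), fc_units=(8,), epochs=0, seed=1)
    d = r.build_decoder(cfg, (16, 16, 3))
    x = np.random.default_rng(0).normal(size=(5, 16, 16, 3))
    probs = d.predict_proba(x)
    assert probs.shape == (5, 3)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)


@pytest.mark.parametrize("conv_filters,fc_units,shape", [
    ((4, 8), (16,), (16, 16, 3)),
    ((6,), (10, 7), (12, 12, 3)),
    ((52, 104, 156, 208), (713, 1019), (32, 32, 3)),
])
def test_parameter_count_matches_layer_arithmetic(conv_filters, fc_units, shape):
    cfg = r.DecoderConfig(conv_filters=conv_filters, fc_units=fc_units,
                          epochs=0, seed=0)
    d = r.build_decoder(cfg, shape)
    assert d.n_params() == hand_count_params(shape, conv_filters, cfg.kernel,
                                             fc_units)


def test_reduction_blocks_halve_spatial_size():
    cfg = r.DecoderConfig(conv_filters=(4, 4), fc_units=(8,), epochs=0, seed=0)
    d = r.build_decoder(cfg, (17, 17, 3))
    x = np.zeros((1, 17, 17, 3))
    h = x
    shapes = []
    for layer in d.layers:
        h = layer.forward(h)
        if h.ndim == 4:
            shapes.append(h.shape[1:3])
    assert (9, 9) in shapes and (5, 5) in shapes  # ceil(17/2), ceil(9/2)


def test_spatial_underflow_raises_with_block_name():
    cfg = r.DecoderConfig(conv_filters=(4,) * 5, fc_units=(8,), epochs=0, seed=0)
    with pytest.raises(ValueError, match="block 4"):
        r.build_decoder(cfg, (16, 16, 3))


def test_backward_matches_finite_differences():
    """Full-network gradient check of the hand-written backward pass."""
    cfg = r.DecoderConfig(conv_filters=(3,), fc_units=(6,), dropout=0.0,
                          epochs=0, seed=0)
    d = r.build_decoder(cfg, (8, 8, 3))
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 8, 8, 3))
    y = np.array([0, 2])

    logits = d.forward(x)
    _, dlog, _ = _ce_loss_grad(logits, y, 3)
    g = dlog
    for layer in reversed(d.layers):
        g = layer.backward(g)

    eps = 1e-6
    checks = [(d.layers[0].W, d.layers[0].dW, (1, 2, 1, 0)),
              (d.layers[0].b, d.layers[0].db, (2,)),
              (d.layers[-1].W, d.layers[-1].dW, (3, 1))]
    for W, dW, idx in checks:
        orig = W[idx]
        W[idx] = orig + eps
        l1, _, _ = _ce_loss_grad(d.forward(x), y, 3)
        W[idx] = orig - eps
        l2, _, _ = _ce_loss_grad(d.forward(x), y, 3)
        W[idx] = orig
        assert (l1 - l2) / (2 * eps) == pytest.approx(dW[idx], abs=1e-7)
    xi = (0, 4, 3, 1)
    xp = x.copy()
    xp[xi] += eps
    l1, _, _ = _ce_loss_grad(d.forward(xp), y, 3)
    xp[xi] -= 2 * eps
    l2, _, _ = _ce_loss_grad(d.forward(xp), y, 3)
    assert (l1 - l2) / (2 * eps) == pytest.approx(g[xi], abs=1e-7)


def test_training_solves_separable_toy(tiny_decoder):
    assert max(tiny_decoder.history["val_accuracy"]) >= 0.95


def test_zero_epochs_leaves_weights_unchanged(blob_data):
    X, y = blob_data
    cfg = r.DecoderConfig(conv_filters=(4,), fc_units=(8,), epochs=0, seed=3)
    d = r.build_decoder(cfg, X.shape[1:])
    before = d.get_weights()
    r.train(d, X, y, cfg)
    after = d.get_weights()
    assert all(np.array_equal(a, b) for a, b in zip(before, after))
    assert d.history["loss"] == []


def test_single_class_input_rejected(blob_data):
    X, y = blob_data
    cfg = r.DecoderConfig(conv_filters=(4,), fc_units=(8,), epochs=1, seed=0)
    d = r.build_decoder(cfg, X.shape[1:])
    with pytest.raises(ValueError):
        r.train(d, X, np.array(["fast"] * len(X)), cfg)


def test_training_deterministic_under_seed(blob_data):
    X, y = blob_data
    cfg = r.DecoderConfig(conv_filters=(4,), fc_units=(8,), dropout=0.2,
                          learning_rate=0.02, epochs=3, batch_size=32, seed=5)
    hists = []
    for _ in range(2):
        d = r.build_decoder(cfg, X.shape[1:])
        r.train(d, X, y, cfg)
        hists.append(d.history)
    assert hists[0]["loss"] == hists[1]["loss"]
    assert hists[0]["val_loss"] == hists[1]["val_loss"]


def test_checkpoint_restores_best_validation_loss(blob_data):
    """After training, the live weights reproduce the minimum recorded
    validation loss on the deterministic validation split."""
    X, y = blob_data
    cfg = r.DecoderConfig(conv_filters=(4,), fc_units=(8,), dropout=0.0,
                          learning_rate=0.05, epochs=8, batch_size=32, seed=2)
    d = r.build_decoder(cfg, X.shape[1:])
    r.train(d, X, y, cfg)
    y_idx, _ = _encode_labels(y)
    rng = np.random.default_rng(cfg.seed)
    _, va = _stratified_split(y_idx, cfg.val_fraction, rng)
    loss, _, _ = _ce_loss_grad(d.forward(X[va]), y_idx[va], 3)
    assert loss == pytest.approx(min(d.history["val_loss"]), abs=1e-9)


def test_evaluate_perfect_predictions(tiny_decoder, blob_data):
    X, y = blob_data
    m = r.evaluate(tiny_decoder, X, y)
    if m["accuracy"] == 1.0:  # trained to perfection on this toy
        assert np.allclose(m["confusion_matrix"], np.eye(3))
        assert m["macro"]["f1"] == 1.0
    assert set(m["per_class"]) == {"fast", "medium", "slow"}
    for stats in m["per_class"].values():
        assert {"precision", "recall", "f1", "support"} <= set(stats)
    assert 0 <= m["mean_correct_softmax"] <= 1


def test_evaluate_macro_f1_contingency_oracle(blob_data):
    """Macro F1 from evaluate matches a hand-computed contingency value
    for a decoder with stubbed, known predictions."""
    X, y = blob_data
    cfg = r.DecoderConfig(conv_filters=(4,), fc_units=(8,), epochs=0, seed=0)
    d = r.build_decoder(cfg, X.shape[1:])
    d.label_order = ("fast", "medium", "slow")
    n = len(y)
    y_idx, _ = _encode_labels(y)
    # predict class (true + 1) mod 3 for the first 30 samples, truth after
    pred = y_idx.copy()
    pred[:30] = (pred[:30] + 1) % 3
    probs = np.full((n, 3), 0.05)
    probs[np.arange(n), pred] = 0.9
    d.predict_proba = lambda x, **k: probs
    m = r.evaluate(d, X, y)

    f1s = []
    for c in range(3):
        tp = ((pred == c) & (y_idx == c)).sum()
        fp = ((pred == c) & (y_idx != c)).sum()
        fn = ((pred != c) & (y_idx == c)).sum()
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    assert m["macro"]["f1"] == pytest.approx(np.mean(f1s), abs=1e-12)


def test_evaluate_length_mismatch_rejected(tiny_decoder, blob_data):
    X, y = blob_data
    with pytest.raises(ValueError):
        r.evaluate(tiny_decoder, X, y[:-5])
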