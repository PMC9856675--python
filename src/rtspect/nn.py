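"""A compact convolutional decoder of response-speed category from topomaps.

The architecture alternates [5x5 convolution (ELU) -> inception-reduction]
blocks, then a fully connected stack with dropout and a 3-way softmax head.
An inception-reduction block runs three parallel stride-2 branches (3x3
convolution; 1x1 then 3x3 convolution; 3x3 max-pool) and concatenates them
on the feature axis, halving the spatial size.

Everything here — forward pass, backward pass, optimizers, the training
loop — is implemented directly on numpy arrays. Writing the backward pass
explicitly is what makes the saliency module possible: guided
backpropagation needs a modified rectifier backward rule, and GradCAM needs
the gradient of a class logit at an interior feature map, both of which the
`Decoder.input_gradient` hook exposes.

Arrays are NHWC: (batch, height, width, channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecoderConfig",
    "published_config",
    "Decoder",
    "build_decoder",
    "train",
    "evaluate",
]

LABEL_ORDER = ("fast", "medium", "slow")


# --------------------------------------------------------------------------
# configuration

@dataclass
class DecoderConfig:
    conv_filters: tuple = (52, 104, 156, 208)
    kernel: int = 5
    fc_units: tuple = (713, 1019)
    dropout: float = 0.47
    activation: str = "elu"
    optimizer: str = "adagrad"
    learning_rate: float = 0.006
    epochs: int = 165
    val_fraction: float = 0.25
    batch_size: int = 64
    seed: int = 0
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    min_lr: float = 1e-5

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        self.fc_units = tuple(int(u) for u in self.fc_units)
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def n_blocks(self) -> int:
        return len(self.conv_filters)


def published_config() -> DecoderConfig:
    """The published best configuration: 4 blocks of 52/104/156/208 5x5
    filters, FC 713/1019, dropout 0.47, ELU, Adagrad at 0.006, 165 epochs
    with a 25% validation split."""
    return DecoderConfig()


# --------------------------------------------------------------------------
# layers

def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


class _Layer:
    def params(self):
        return []

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, g, guided=False):
        raise NotImplementedError


class Conv2D(_Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, rng=None):
        self.k, self.s = int(kernel), int(stride)
        fan_in = self.k * self.k * in_ch
        std = np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0, std, (self.k, self.k, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        n, H, W, _ = x.shape
        pt, pb = _same_pad(H, self.k, self.s)
        pl, pr = _same_pad(W, self.k, self.s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        self._pads = (pt, pb, pl, pr)
        self._xp_shape = xp.shape
        cols = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        cols = cols[:, ::self.s, ::self.s]  # (n, Ho, Wo, c, k, k)
        self._cols = cols
        out = np.tensordot(cols, self.W, axes=([4, 5, 3], [0, 1, 2])) + self.b
        return out

    def backward(self, g, guided=False):
        self.dW[...] = np.transpose(
            np.tensordot(self._cols, g, axes=([0, 1, 2], [0, 1, 2])), (1, 2, 0, 3))
        self.db[...] = g.sum(axis=(0, 1, 2))
        dxp = np.zeros(self._xp_shape)
        n, Ho, Wo, _ = g.shape
        for i in range(self.k):
            for j in range(self.k):
                contrib = g @ self.W[i, j].T  # (n, Ho, Wo, in)
                dxp[:, i:i + self.s * Ho:self.s, j:j + self.s * Wo:self.s, :] += contrib
        pt, pb, pl, pr = self._pads
        H = self._xp_shape[1] - pt - pb
        W = self._xp_shape[2] - pl - pr
        return dxp[:, pt:pt + H, pl:pl + W, :]


class ELU(_Layer):
    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        self._x = x
        self._y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0)))
        return self._y

    def backward(self, g, guided=False):
        d = np.where(self._x > 0, 1.0, self._y + self.alpha)
        out = g * d
        if guided:
            out = out * (g > 0) * (self._y > 0)
        return out


class ReLU(_Layer):
    def forward(self, x, train=False, rng=None):
        self._y = np.maximum(x, 0)
        return self._y

    def backward(self, g, guided=False):
        out = g * (self._y > 0)
        if guided:
            out = out * (g > 0)
        return out


def make_activation(name: str) -> _Layer:
    if name == "elu":
        return ELU()
    if name == "relu":
        return ReLU()
    raise ValueError(f"unsupported activation {name!r}")


class MaxPool2D(_Layer):
    def __init__(self, pool=3, stride=2):
        self.p, self.s = pool, stride

    def forward(self, x, train=False, rng=None):
        n, H, W, C = x.shape
        pt, pb = _same_pad(H, self.p, self.s)
        pl, pr = _same_pad(W, self.p, self.s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                    constant_values=-np.inf)
        wins = np.lib.stride_tricks.sliding_window_view(xp, (self.p, self.p), axis=(1, 2))
        wins = wins[:, ::self.s, ::self.s]  # (n, Ho, Wo, C, p, p)
        n_, Ho, Wo, C_, _, _ = wins.shape
        flat = wins.reshape(n_, Ho, Wo, C_, -1)
        arg = flat.argmax(axis=-1)
        self._ctx = (x.shape, xp.shape, (pt, pl), arg)
        return flat.max(axis=-1)

    def backward(self, g, guided=False):
        x_shape, xp_shape, (pt, pl), arg = self._ctx
        n, Ho, Wo, C = g.shape
        dxp = np.zeros(xp_shape)
        ni, hi, wi, ci = np.indices((n, Ho, Wo, C))
        rows = hi * self.s + arg // self.p
        cols = wi * self.s + arg % self.p
        np.add.at(dxp, (ni, rows, cols, ci), g)
        return dxp[:, pt:pt + x_shape[1], pl:pl + x_shape[2], :]


class InceptionReduction(_Layer):
    """Three stride-2 branches concatenated on the feature axis.

    Branch widths are ceil(filters/3) each for the two convolutional
    branches; the pool branch passes the input channels through, so the
    output width is 2*ceil(filters/3) + in_channels.
    """

    def __init__(self, in_ch, filters, activation="elu", rng=None):
        cb = -(-filters // 3)
        self.branch_a = [Conv2D(in_ch, cb, 3, stride=2, rng=rng),
                         make_activation(activation)]
        self.branch_b = [Conv2D(in_ch, cb, 1, stride=1, rng=rng),
                         make_activation(activation),
                         Conv2D(cb, cb, 3, stride=2, rng=rng),
                         make_activation(activation)]
        self.branch_c = [MaxPool2D(3, 2)]
        self.out_ch = 2 * cb + in_ch
        self._splits = (cb, cb, in_ch)

    def params(self):
        out = []
        for br in (self.branch_a, self.branch_b, self.branch_c):
            for layer in br:
                out.extend(layer.params())
        return out

    def forward(self, x, train=False, rng=None):
        outs = []
        for br in (self.branch_a, self.branch_b, self.branch_c):
            h = x
            for layer in br:
                h = layer.forward(h, train=train, rng=rng)
            outs.append(h)
        return np.concatenate(outs, axis=-1)

    def backward(self, g, guided=False):
        a, b, _ = self._splits
        parts = (g[..., :a], g[..., a:a + b], g[..., a + b:])
        dx = None
        for br, gp in zip((self.branch_a, self.branch_b, self.branch_c), parts):
            h = gp
            for layer in reversed(br):
                h = layer.backward(h, guided=guided)
            dx = h if dx is None else dx + h
        return dx


class Flatten(_Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g, guided=False):
        return g.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, in_dim, out_dim, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0, std, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g, guided=False):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class Dropout(_Layer):
    def __init__(self, rate):
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if train and self.rate > 0:
            self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, g, guided=False):
        if self._mask is not None:
            return g * self._mask
        return g


# --------------------------------------------------------------------------
# decoder

class Decoder:
    """The assembled network plus its config, label order and history."""

    def __init__(self, layers, config: DecoderConfig, input_shape,
                 last_feature_index: int):
        self.layers = layers
        self.config = config
        self.input_shape = tuple(input_shape)
        self.last_feature_index = last_feature_index  # last 4-D feature map
        self.label_order: tuple[str, ...] = LABEL_ORDER
        self.history: dict[str, list] = {}

    # -- inference -------------------------------------------------------
    def forward(self, x, train=False, rng=None, record=False):
        h = np.asarray(x, dtype=float)
        outs = []
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
            if record:
                outs.append(h)
        if record:
            self._outs = outs
        return h

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x, batch_size=256):
        x = np.asarray(x, dtype=float)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self._softmax(self.forward(x[i:i + batch_size])))
        return np.concatenate(out) if out else np.empty((0, 3))

    def predict(self, x):
        probs = self.predict_proba(x)
        return np.array([self.label_order[i] for i in probs.argmax(axis=1)])

    # -- gradients -------------------------------------------------------
    def input_gradient(self, x, target: int, guided=False, capture=None):
        """Gradient of the target-class logit w.r.t. the input.

        Returns (dx, captured) where ``captured`` is (activation, gradient)
        at the output of layer index ``capture`` (None if not requested).
        Guided mode applies the rectifier backward rule inside activations.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        logits = self.forward(x, train=False, record=True)
        if not (0 <= target < logits.shape[1]):
            raise ValueError(f"target class {target} out of range")
        g = np.zeros_like(logits)
        g[:, target] = 1.0
        captured = None
        for i in range(len(self.layers) - 1, -1, -1):
            if capture is not None and i == capture:
                captured = (self._outs[i], g)
            g = self.layers[i].backward(g, guided=guided)
        return g, captured

    # -- bookkeeping -----------------------------------------------------
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        for (p, _), w in zip(self.params(), weights):
            p[...] = w

    def save_weights(self, path):
        np.savez_compressed(path, *[p for p, _ in self.params()])

    def load_weights(self, path):
        arrs = np.load(path)
        self.set_weights([arrs[k] for k in arrs.files])


def build_decoder(config: DecoderConfig, input_shape) -> Decoder:
    """Assemble an untrained decoder for images of ``input_shape`` (H, W, C).

    Raises if any reduction block would underflow the spatial grid.
    """
    H, W, C = input_shape
    rng = np.random.default_rng(config.seed)
    layers: list[_Layer] = []
    ch, h, w = C, H, W
    last_feature_index = -1
    for b, f in enumerate(config.conv_filters):
        layers.append(Conv2D(ch, f, config.kernel, stride=1, rng=rng))
        layers.append(make_activation(config.activation))
        if min(h, w) < 2:
            raise ValueError(
                f"spatial size {h}x{w} underflows at reduction block {b}")
        red = InceptionReduction(f, f, activation=config.activation, rng=rng)
        layers.append(red)
        ch = red.out_ch
        h, w = -(-h // 2), -(-w // 2)
        last_feature_index = len(layers) - 1
    layers.append(Flatten())
    dim = h * w * ch
    for u in config.fc_units:
        layers.append(Dense(dim, u, rng=rng))
        layers.append(make_activation(config.activation))
        layers.append(Dropout(config.dropout))
        dim = u
    layers.append(Dense(dim, len(LABEL_ORDER), rng=rng))
    return Decoder(layers, config, input_shape, last_feature_index)


# --------------------------------------------------------------------------
# optimizers

class _Optimizer:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr

    def step(self):
        raise NotImplementedError


class SGD(_Optimizer):
    def step(self):
        for p, g in self.params:
            p -= self.lr * g


class Adagrad(_Optimizer):
    def __init__(self, params, lr, eps=1e-7):
        super().__init__(params, lr)
        self.eps = eps
        self.acc = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for (p, g), a in zip(self.params, self.acc):
            a += g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


class Adam(_Optimizer):
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


_OPTIMIZERS = {"sgd": SGD, "adagrad": Adagrad, "adam": Adam}


# --------------------------------------------------------------------------
# training / evaluation

def _encode_labels(labels, order=LABEL_ORDER):
    labels = np.asarray(labels)
    present = [c for c in order if c in set(labels)]
    extra = sorted(set(labels) - set(order))
    classes = tuple(present + extra)
    idx = {c: i for i, c in enumerate(classes)}
    return np.array([idx[c] for c in labels]), classes


def _stratified_split(y, val_fraction, rng):
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def _ce_loss_grad(logits, y_idx, n_classes):
    probs = Decoder._softmax(logits)
    n = len(y_idx)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), y_idx] + eps))
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y_idx] = 1.0
    return loss, (probs - onehot) / n, probs


def train(decoder: Decoder, topomaps, labels, config: DecoderConfig | None = None,
          groups=None) -> Decoder:
    """Train in place with cross-entropy; returns the decoder.

    Splits off ``val_fraction`` of the data (stratified by class, or by
    ``groups`` when given for a subject-wise split), checkpoints the weights
    at the best validation loss, and halves the learning rate after
    ``plateau_patience`` epochs without improvement (floored at ``min_lr``).
    Deterministic for a fixed config seed.
    """
    cfg = config or decoder.config
    X = np.asarray(topomaps, dtype=float)
    y_idx, classes = _encode_labels(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    n_out = decoder.layers[-1].b.shape[0]
    if len(classes) > n_out:
        raise ValueError(f"{len(classes)} classes but {n_out} output units")
    decoder.label_order = classes + tuple(
        f"unused{i}" for i in range(n_out - len(classes)))
    rng = np.random.default_rng(cfg.seed)
    if groups is not None:
        uniq = np.unique(groups)
        rng.shuffle(uniq)
        n_val_g = max(1, int(round(cfg.val_fraction * len(uniq))))
        val_mask = np.isin(groups, uniq[:n_val_g])
        tr, va = np.flatnonzero(~val_mask), np.flatnonzero(val_mask)
    else:
        tr, va = _stratified_split(y_idx, cfg.val_fraction, rng)

    opt = _OPTIMIZERS[cfg.optimizer](decoder.params(), cfg.learning_rate)
    hist = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_loss, best_weights, stall = np.inf, decoder.get_weights(), 0

    for _epoch in range(cfg.epochs):
        order = rng.permutation(tr)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            bidx = order[i:i + cfg.batch_size]
            logits = decoder.forward(X[bidx], train=True, rng=rng)
            loss, dlogits, probs = _ce_loss_grad(logits, y_idx[bidx], n_out)
            ep_loss += loss * len(bidx)
            ep_correct += int((probs.argmax(axis=1) == y_idx[bidx]).sum())
            g = dlogits
            for layer in reversed(decoder.layers):
                g = layer.backward(g)
            opt.step()
        hist["loss"].append(ep_loss / len(order))
        hist["accuracy"].append(ep_correct / len(order))

        v_logits = decoder.forward(X[va])
        v_loss, _, v_probs = _ce_loss_grad(v_logits, y_idx[va], n_out)
        hist["val_loss"].append(float(v_loss))
        hist["val_accuracy"].append(float((v_probs.argmax(axis=1) == y_idx[va]).mean()))

        if v_loss < best_loss - 1e-9:
            best_loss, best_weights, stall = v_loss, decoder.get_weights(), 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                opt.lr = max(cfg.min_lr, opt.lr * cfg.plateau_factor)
                stall = 0

    if hist["val_loss"]:
        decoder.set_weights(best_weights)
    decoder.history = hist
    return decoder


def evaluate(decoder: Decoder, topomaps, labels) -> dict:
    """Per-class precision/recall/F1 (+ macro/weighted), normalized confusion
    matrix, per-class average precision, and the mean softmax score of the
    correct class."""
    from sklearn.metrics import (average_precision_score, confusion_matrix,
                                 precision_recall_fscore_support)

    y_idx, classes = _encode_labels(labels, order=decoder.label_order)
    if set(classes) - set(decoder.label_order):
        raise ValueError("labels contain classes unknown to the decoder")
    probs = decoder.predict_proba(np.asarray(topomaps, dtype=float))
    if len(probs) != len(y_idx):
        raise ValueError("label/prediction length mismatch")
    preds = probs.argmax(axis=1)
    labels_present = list(range(len(classes)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, support = precision_recall_fscore_support(
            y_idx, preds, labels=labels_present, zero_division=0)
        pm, rm, fm, _ = precision_recall_fscore_support(
            y_idx, preds, labels=labels_present, average="macro", zero_division=0)
        pw, rw, fw, _ = precision_recall_fscore_support(
            y_idx, preds, labels=labels_present, average="weighted", zero_division=0)
    cm = confusion_matrix(y_idx, preds, labels=labels_present, normalize="true")
    ap = {}
    for i, c in enumerate(classes):
        pos = (y_idx == i).astype(int)
        ap[c] = float(average_precision_score(pos, probs[:, i])) if pos.any() else np.nan
    return {
        "per_class": {c: {"precision": float(p[i]), "recall": float(r[i]),
                          "f1": float(f1[i]), "support": int(support[i])}
                      for i, c in enumerate(classes)},
        "macro": {"precision": float(pm), "recall": float(rm), "f1": float(fm)},
        "weighted": {"precision": float(pw), "recall": float(rw), "f1": float(fw)},
        "accuracy": float((preds == y_idx).mean()),
        "confusion_matrix": cm,
        "average_precision": ap,
        "mean_correct_softmax": float(probs[np.arange(len(y_idx)), y_idx].mean()),
        "classes": classes,
    }
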