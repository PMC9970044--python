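"""Shallow 1D-CNN classifier for fused time-frequency beat vectors.

Architecture (for the default 480-sample input):

    input 480x1
    -> conv1d  4 ch, kernel 21, stride 1, SAME -> 480x4   -> maxpool/2 -> 240x4
    -> conv1d 16 ch, kernel 23, stride 1, SAME -> 240x16  -> maxpool/2 -> 120x16
    -> conv1d 32 ch, kernel 25, stride 1, SAME -> 120x32  -> avgpool/2 -> 60x32
    -> conv1d 64 ch, kernel 27, stride 1, SAME -> 60x64
    -> flatten 3840 -> dense 128 (ReLU) -> dense 5 (softmax)

The wide kernels with unit stride give each feature a large receptive
field while the three stride-2 pools keep the model shallow and small.
Training minimises multiclass cross-entropy with Adam.  The network is
implemented directly on numpy (im2col convolutions running on BLAS
matmuls), which makes runs bit-reproducible for a given seed.

Class order is fixed as [N, A, V, L, R]: normal, atrial premature,
premature ventricular, left and right bundle branch block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FusedFeature
from .preprocess import BEAT_CLASSES

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "cross_entropy",
    "train",
    "predict",
    "evaluate",
    "stratified_split",
    "save_model",
    "load_model",
]

CLASS_ORDER = list(BEAT_CLASSES)

#: (channels, kernel_len, stride, padding, pool_kind, pool_len, pool_stride)
DEFAULT_CONV_BLOCKS = [
    (4, 21, 1, "same", "max", 2, 2),
    (16, 23, 1, "same", "max", 2, 2),
    (32, 25, 1, "same", "avg", 2, 2),
    (64, 27, 1, "same", "none", 0, 0),
]


@dataclass
class ModelSpec:
    input_len: int = 480
    conv_blocks: list = field(default_factory=lambda: [list(b) for b in DEFAULT_CONV_BLOCKS])
    dense_units: int = 128
    n_classes: int = 5
    conv_activation: str = "relu"
    seed: int = 0

    @property
    def n_pools(self) -> int:
        return sum(1 for b in self.conv_blocks if b[4] != "none")

    @property
    def flatten_width(self) -> int:
        down = 2 ** self.n_pools
        if self.input_len % down:
            raise ValueError(
                f"input_len must be divisible by {down} "
                f"({self.n_pools} stride-2 pooling layers); got {self.input_len}"
            )
        return self.input_len // down * self.conv_blocks[-1][0]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 128
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    split_fraction: float = 0.7
    split_strategy: str = "stratified_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# layers (numpy, float32, im2col)
# ---------------------------------------------------------------------------

def _conv1d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray | None):
    """SAME-padded stride-1 1D convolution; returns (y, im2col cache)."""
    B, L, Cin = x.shape
    K, _, Cout = W.shape
    p = (K - 1) // 2
    xp = np.pad(x, ((0, 0), (p, K - 1 - p), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # B,L,Cin,K
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B * L, K * Cin)
    y = cols @ W.reshape(K * Cin, Cout)
    if b is not None:
        y += b
    return y.reshape(B, L, Cout), cols


class _Conv1D:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (k * cin + k * cout))
        self.W = rng.uniform(-limit, limit, size=(k, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        y, self._cols = _conv1d_same(x, self.W, self.b)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, Cout = dy.shape
        K, Cin, _ = self.W.shape
        dy_flat = dy.reshape(B * L, Cout)
        self.dW[...] = (self._cols.T @ dy_flat).reshape(K, Cin, Cout)
        self.db[...] = dy_flat.sum(axis=0)
        # gradient wrt input = SAME conv of dy with kernel flipped in tap
        # order and transposed in channels (exact for odd K, stride 1)
        W_hat = np.ascontiguousarray(self.W[::-1].transpose(0, 2, 1))
        dx, _ = _conv1d_same(dy, W_hat, None)
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _Pool2:
    """Length-2, stride-2 pooling; kind 'max' or 'avg'."""

    def __init__(self, kind: str):
        self.kind = kind

    def forward(self, x):
        B, L, C = x.shape
        xr = x.reshape(B, L // 2, 2, C)
        if self.kind == "max":
            self._idx = xr.argmax(axis=2)
            return xr.max(axis=2)
        return xr.mean(axis=2)

    def backward(self, dy):
        B, L2, C = dy.shape
        if self.kind == "max":
            dxr = np.zeros((B, L2, 2, C), dtype=dy.dtype)
            np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        else:
            dxr = np.repeat(dy[:, :, None, :] * 0.5, 2, axis=2)
        return dxr.reshape(B, L2 * 2, C)

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (nin + nout))
        self.W = rng.uniform(-limit, limit, size=(nin, nout)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Network:
    def __init__(self, spec: ModelSpec):
        rng = np.random.default_rng(spec.seed)
        self.layers: list = []
        cin = 1
        length = spec.input_len
        self.shape_ledger: list[tuple[str, tuple[int, int]]] = [("input", (length, cin))]
        for cout, k, stride, pad, pool, plen, pstride in spec.conv_blocks:
            if stride != 1 or pad != "same":
                raise ValueError("only stride-1 SAME convolutions are supported")
            self.layers.append(_Conv1D(cin, cout, k, rng))
            self.shape_ledger.append((f"conv{k}x1/{cout}", (length, cout)))
            if spec.conv_activation == "relu":
                self.layers.append(_ReLU())
            cin = cout
            if pool != "none":
                if (plen, pstride) != (2, 2):
                    raise ValueError("only 2/2 pooling is supported")
                if length % 2:
                    raise ValueError("pooling requires an even length")
                self.layers.append(_Pool2(pool))
                length //= 2
                self.shape_ledger.append((f"{pool}pool2", (length, cout)))
        self.layers.append(_Flatten())
        flat = length * cin
        self.shape_ledger.append(("flatten", (flat, 1)))
        self.layers.append(_Dense(flat, spec.dense_units, rng))
        self.layers.append(_ReLU())
        self.shape_ledger.append(("dense", (spec.dense_units, 1)))
        self.out = _Dense(spec.dense_units, spec.n_classes, rng)
        self.shape_ledger.append(("softmax", (spec.n_classes, 1)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, :, None].astype(np.float32)
        for layer in self.layers:
            h = layer.forward(h)
        return _softmax(self.out.forward(h))

    def backward(self, probs: np.ndarray, y_onehot: np.ndarray) -> None:
        d = (probs - y_onehot).astype(np.float32) / probs.shape[0]
        d = self.out.backward(d)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.out.params())
        return out

    def n_parameters(self) -> int:
        return sum(int(p.size) for p, _ in self.params())


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    spec: ModelSpec
    network: _Network
    class_order: list[str] = field(default_factory=lambda: list(CLASS_ORDER))
    training_history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})

    @property
    def layer_shapes(self) -> list[tuple[str, tuple[int, int]]]:
        return self.network.shape_ledger

    def n_parameters(self) -> int:
        return self.network.n_parameters()


def build_model(spec: ModelSpec | None = None) -> TrainedModel:
    """Instantiate the (untrained) network and its layer-shape ledger."""
    spec = spec or ModelSpec()
    spec.flatten_width  # validates divisibility, raises otherwise
    return TrainedModel(spec=spec, network=_Network(spec))


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-12) -> float:
    """Mean multiclass cross-entropy -1/N sum_i sum_c y_ic log p_ic.

    Probabilities are clipped at ``eps`` before the log.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    p = np.clip(y_pred, eps, None)
    return float(-(y_true * np.log(p)).sum() / y_true.shape[0])


def _to_matrix(features: list[FusedFeature], input_len: int) -> np.ndarray:
    X = np.empty((len(features), input_len), dtype=np.float32)
    for i, f in enumerate(features):
        if f.vector.size != input_len:
            raise ValueError(
                f"feature {i} has length {f.vector.size}, model expects {input_len}"
            )
        X[i] = f.vector
    return X


def _labels_to_idx(features: list[FusedFeature], class_order: list[str]) -> np.ndarray:
    idx = np.empty(len(features), dtype=np.int64)
    for i, f in enumerate(features):
        if f.label is None:
            raise ValueError(f"feature {i} is unlabeled")
        idx[i] = class_order.index(f.label)
    return idx


def stratified_split(features: list[FusedFeature], fraction: float,
                     seed: int = 0) -> tuple[list[FusedFeature], list[FusedFeature]]:
    """Per-class random split; every present class needs >= 2 examples."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, f in enumerate(features):
        by_class.setdefault(f.label, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for sym in sorted(by_class):
        idx = np.array(by_class[sym])
        if idx.size < 2:
            raise ValueError(
                f"class {sym!r} has only {idx.size} example(s); stratified "
                "split needs at least 2 per class"
            )
        rng.shuffle(idx)
        k = max(1, min(idx.size - 1, int(round(fraction * idx.size))))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    train_idx.sort()
    test_idx.sort()
    return [features[i] for i in train_idx], [features[i] for i in test_idx]


def train(features: list[FusedFeature], config: TrainConfig | None = None,
          spec: ModelSpec | None = None, model: TrainedModel | None = None) -> TrainedModel:
    """Fit the CNN on labeled fused features.

    Deterministic for a given ``config.seed``/``spec.seed`` pair (weights,
    shuffling and therefore the whole history are reproducible).  The
    per-epoch history records the mean minibatch loss and the training
    accuracy accumulated over the epoch's forward passes.
    """
    config = config or TrainConfig()
    if config.optimizer != "adam":
        raise ValueError("only the adam optimizer is implemented")
    if model is None:
        spec = spec or ModelSpec(seed=config.seed)
        model = build_model(spec)
    spec = model.spec
    X = _to_matrix(features, spec.input_len)
    y = _labels_to_idx(features, model.class_order)
    if np.unique(y).size < 2:
        raise ValueError("training needs at least two classes present")
    Y = np.eye(spec.n_classes, dtype=np.float32)[y]

    net = model.network
    opt = _Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, weights, correct = [], [], 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            probs = net.forward(X[sel])
            losses.append(cross_entropy(Y[sel], probs))
            weights.append(sel.size)
            correct += int((probs.argmax(axis=1) == y[sel]).sum())
            net.backward(probs, Y[sel])
            opt.step()
        model.training_history["loss"].append(
            float(np.average(losses, weights=weights)))
        model.training_history["accuracy"].append(correct / n)
    return model


def predict(model: TrainedModel, features: list[FusedFeature],
            batch_size: int = 256) -> tuple[np.ndarray, list[str]]:
    """Row-stochastic probability matrix plus argmax class symbols.

    Ties break to the lowest class index (numpy argmax convention).
    """
    X = _to_matrix(features, model.spec.input_len)
    probs = np.vstack([
        model.network.forward(X[i:i + batch_size])
        for i in range(0, X.shape[0], batch_size)
    ]) if X.shape[0] else np.empty((0, model.spec.n_classes))
    labels = [model.class_order[int(k)] for k in probs.argmax(axis=1)]
    return probs, labels


def evaluate(model: TrainedModel, features: list[FusedFeature]) -> dict:
    """Accuracy, per-class precision/recall and the 5x5 confusion matrix.

    Confusion rows are true classes, columns predicted, both in the fixed
    [N, A, V, L, R] order.
    """
    if not features:
        raise ValueError("evaluate requires at least one labeled feature")
    y_true = _labels_to_idx(features, model.class_order)
    _, pred_syms = predict(model, features)
    y_pred = np.array([model.class_order.index(s) for s in pred_syms])
    k = model.spec.n_classes
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (y_true, y_pred), 1)
    support = conf.sum(axis=1)
    predicted = conf.sum(axis=0)
    diag = np.diag(conf)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, diag / np.maximum(support, 1), np.nan)
        precision = np.where(predicted > 0, diag / np.maximum(predicted, 1), np.nan)
    return {
        "accuracy": float(diag.sum() / conf.sum()),
        "per_class": {
            sym: {"precision": float(precision[i]), "recall": float(recall[i]),
                  "support": int(support[i])}
            for i, sym in enumerate(model.class_order)
        },
        "confusion_matrix": conf,
        "class_order": list(model.class_order),
    }


# ---------------------------------------------------------------------------
# serialization: npz weights + JSON spec sidecar
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.network.params())}
    np.savez(directory / "weights.npz", **arrays)
    spec = model.spec
    (directory / "model_spec.json").write_text(json.dumps({
        "input_len": spec.input_len,
        "conv_blocks": spec.conv_blocks,
        "dense_units": spec.dense_units,
        "n_classes": spec.n_classes,
        "conv_activation": spec.conv_activation,
        "seed": spec.seed,
        "class_order": model.class_order,
        "training_history": model.training_history,
    }, indent=2))


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "model_spec.json").read_text())
    spec = ModelSpec(
        input_len=meta["input_len"], conv_blocks=meta["conv_blocks"],
        dense_units=meta["dense_units"], n_classes=meta["n_classes"],
        conv_activation=meta["conv_activation"], seed=meta["seed"],
    )
    model = build_model(spec)
    model.class_order = meta["class_order"]
    model.training_history = meta["training_history"]
    with np.load(directory / "weights.npz") as data:
        for i, (p, _) in enumerate(model.network.params()):
            p[...] = data[f"p{i}"]
    return model
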