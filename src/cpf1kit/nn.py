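"""Small convolutional classifiers for Cpf1 activity and specificity.

Both networks share one shape: a single one-hot input matrix, one valid
(unpadded) convolution layer with ReLU, one non-overlapping 2x2 sum-pooling
layer (trailing odd rows/columns truncated), a flatten layer, one fully
connected ReLU layer, and a 2-unit softmax head whose positive-class
probability is reported as "the score".  Training is plain minibatch
gradient descent with momentum on the 2-class cross-entropy loss
(learning rate 0.005, momentum 0.9, batch size 40 by default).

The on-target net takes the 16 x 26 order-2 encoding (50 filters of 5 x 5,
conv maps 12 x 22, pooled 6 x 11, flatten 3300, dense 650).  The off-target
net takes the 12 x 27 mismatch encoding (35 filters of 7 x 7, conv maps
6 x 21, pooled 3 x 10 with the last column dropped, flatten 1050, dense
300).  All flatten sizes are derived from the layer arithmetic, never
hard-coded.

Implemented directly in numpy: im2col convolution, reshape-based pooling,
hand-derived backward pass.  Everything is float32 and fully seeded, so a
run is reproducible bit-for-bit.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetSpec",
    "TrainedClassifier",
    "conv_valid",
    "sum_pool",
    "build_on_target_net",
    "build_off_target_net",
    "build_order1_net",
    "train_classifier",
    "predict",
    "flatten_receptive_field",
    "save_classifier",
    "load_classifier",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class NetSpec:
    """Architecture and optimizer hyperparameters of one classifier."""

    input_shape: tuple[int, int]
    n_filters: int
    kernel: tuple[int, int]
    pool: tuple[int, int] = (2, 2)
    dense_units: int = 650
    output_units: int = 2
    learning_rate: float = 0.005
    momentum: float = 0.9
    batch_size: int = 40
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.input_shape
        kh, kw = self.kernel
        if kh > rows or kw > cols:
            raise ValueError(
                f"kernel {self.kernel} does not fit input {self.input_shape}"
            )
        if min(self.pool) < 1:
            raise ValueError("pool dimensions must be >= 1")

    @property
    def conv_shape(self) -> tuple[int, int]:
        """Feature-map shape after valid convolution."""
        return (
            self.input_shape[0] - self.kernel[0] + 1,
            self.input_shape[1] - self.kernel[1] + 1,
        )

    @property
    def pooled_shape(self) -> tuple[int, int]:
        """Feature-map shape after truncating sum pooling."""
        return (self.conv_shape[0] // self.pool[0], self.conv_shape[1] // self.pool[1])

    @property
    def flatten_size(self) -> int:
        pr, pc = self.pooled_shape
        return self.n_filters * pr * pc


def build_on_target_net(seed: int = 0, **overrides) -> "TrainedClassifier":
    """Untrained on-target activity classifier (order-2 16x26 input)."""
    spec = NetSpec(
        input_shape=(16, 26), n_filters=50, kernel=(5, 5), dense_units=650,
        seed=seed, **overrides,
    )
    return TrainedClassifier.initialize(spec)


def build_off_target_net(seed: int = 0, **overrides) -> "TrainedClassifier":
    """Untrained off-target specificity classifier (mismatch 12x27 input)."""
    spec = NetSpec(
        input_shape=(12, 27), n_filters=35, kernel=(7, 7), dense_units=300,
        seed=seed, **overrides,
    )
    return TrainedClassifier.initialize(spec)


def build_order1_net(seed: int = 0, **overrides) -> "TrainedClassifier":
    """Order-1 variant: 4x27 input, 4x1 convolution, 1x2 pooling."""
    spec = NetSpec(
        input_shape=(4, 27), n_filters=50, kernel=(4, 1), pool=(1, 2),
        dense_units=650, seed=seed, **overrides,
    )
    return TrainedClassifier.initialize(spec)


def conv_valid(x: np.ndarray, filters: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Valid-mode cross-correlation + bias + ReLU.

    Parameters
    ----------
    x : (n, H, W) batch of single-channel inputs
    filters : (F, kh, kw) filter bank
    biases : (F,)

    Returns
    -------
    (n, F, H-kh+1, W-kw+1) feature maps.
    """
    x = np.asarray(x)
    single = x.ndim == 2
    if single:
        x = x[None]
    n, H, W = x.shape
    F, kh, kw = filters.shape
    if kh > H or kw > W:
        raise ValueError(f"kernel ({kh}, {kw}) larger than input ({H}, {W})")
    patches = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (n, oh, ow, kh, kw)
    oh, ow = patches.shape[1], patches.shape[2]
    cols = patches.reshape(n * oh * ow, kh * kw)
    out = cols @ filters.reshape(F, kh * kw).T + biases
    out = np.maximum(out, 0.0)
    maps = out.reshape(n, oh, ow, F).transpose(0, 3, 1, 2)
    return maps[0] if single else maps


def sum_pool(maps: np.ndarray, pool: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Non-overlapping sum pooling over the trailing two axes.

    Trailing rows/columns that do not fill a complete block are truncated
    (floor division), so a 6 x 21 map pooled 2x2 becomes 3 x 10.
    """
    ph, pw = pool
    maps = np.asarray(maps)
    h, w = maps.shape[-2], maps.shape[-1]
    th, tw = (h // ph) * ph, (w // pw) * pw
    trimmed = maps[..., :th, :tw]
    shape = maps.shape[:-2] + (th // ph, ph, tw // pw, pw)
    return trimmed.reshape(shape).sum(axis=(-3, -1))


def _init_params(spec: NetSpec) -> dict[str, np.ndarray]:
    """Seeded uniform (Glorot-scaled) init; output layer and biases start at
    zero so an untrained net scores every input exactly 0.5."""
    rng = np.random.default_rng(spec.seed)
    kh, kw = spec.kernel
    fan = kh * kw

    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(np.float32)

    return {
        "conv_w": glorot((spec.n_filters, kh, kw), fan, fan),
        "conv_b": np.zeros(spec.n_filters, dtype=np.float32),
        "dense1_w": glorot((spec.flatten_size, spec.dense_units),
                           spec.flatten_size, spec.dense_units),
        "dense1_b": np.zeros(spec.dense_units, dtype=np.float32),
        "dense2_w": np.zeros((spec.dense_units, spec.output_units), dtype=np.float32),
        "dense2_b": np.zeros(spec.output_units, dtype=np.float32),
    }


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedClassifier:
    """A NetSpec plus its (possibly trained) weights and decision threshold."""

    spec: NetSpec
    params: dict[str, np.ndarray]
    threshold: float = 0.5
    loss_history: list[float] = field(default_factory=list)

    @classmethod
    def initialize(cls, spec: NetSpec) -> "TrainedClassifier":
        return cls(spec=spec, params=_init_params(spec))

    # ---- forward pieces -------------------------------------------------

    def _check_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        return X

    def flatten_activations(self, X: np.ndarray) -> np.ndarray:
        """(n, flatten_size) activations of the flatten layer.

        Flatten order is map-major, then row-major within each pooled map.
        """
        X = self._check_inputs(X)
        maps = conv_valid(X, self.params["conv_w"], self.params["conv_b"])
        pooled = sum_pool(maps, self.spec.pool)
        return pooled.reshape(X.shape[0], -1)

    def head_scores(self, flat: np.ndarray) -> np.ndarray:
        """Positive-class probabilities from flatten activations."""
        h = np.maximum(flat @ self.params["dense1_w"] + self.params["dense1_b"], 0.0)
        p = _softmax(h @ self.params["dense2_w"] + self.params["dense2_b"])
        return p[:, 1]

    def predict_proba(self, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Two-class probabilities, order-preserving and batch-invariant."""
        X = self._check_inputs(X)
        out = np.empty((X.shape[0], self.spec.output_units), dtype=np.float32)
        for i in range(0, X.shape[0], chunk):
            flat = self.flatten_activations(X[i : i + chunk])
            h = np.maximum(flat @ self.params["dense1_w"] + self.params["dense1_b"], 0.0)
            out[i : i + chunk] = _softmax(
                h @ self.params["dense2_w"] + self.params["dense2_b"]
            )
        return out


def predict(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class scores in [0, 1], one per input, input order preserved."""
    return clf.predict_proba(X)[:, 1]


def _forward_backward(clf: TrainedClassifier, Xb: np.ndarray, yb: np.ndarray):
    """Loss and parameter gradients for one minibatch."""
    spec = clf.spec
    p = clf.params
    n = Xb.shape[0]
    F, (kh, kw) = spec.n_filters, spec.kernel

    patches = sliding_window_view(Xb, (kh, kw), axis=(1, 2))
    oh, ow = patches.shape[1], patches.shape[2]
    cols = patches.reshape(n * oh * ow, kh * kw).astype(np.float32)
    pre = cols @ p["conv_w"].reshape(F, kh * kw).T + p["conv_b"]
    act = np.maximum(pre, 0.0)
    maps = act.reshape(n, oh, ow, F).transpose(0, 3, 1, 2)
    pooled = sum_pool(maps, spec.pool)
    flat = pooled.reshape(n, -1)

    h_pre = flat @ p["dense1_w"] + p["dense1_b"]
    h = np.maximum(h_pre, 0.0)
    logits = h @ p["dense2_w"] + p["dense2_b"]
    probs = _softmax(logits)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), yb] + eps).mean()

    # backward
    dlogits = probs.copy()
    dlogits[np.arange(n), yb] -= 1.0
    dlogits /= n
    grads = {}
    grads["dense2_w"] = h.T @ dlogits
    grads["dense2_b"] = dlogits.sum(axis=0)
    dh = dlogits @ p["dense2_w"].T
    dh[h_pre <= 0] = 0.0
    grads["dense1_w"] = flat.T @ dh
    grads["dense1_b"] = dh.sum(axis=0)
    dflat = dh @ p["dense1_w"].T

    ph, pw = spec.pool
    pr, pc = spec.pooled_shape
    dpooled = dflat.reshape(n, F, pr, pc)
    # sum-pool backward: broadcast each pooled gradient over its block,
    # zero on truncated rows/cols
    dmaps = np.zeros_like(maps)
    dmaps[:, :, : pr * ph, : pc * pw] = (
        dpooled[:, :, :, None, :, None]
        .repeat(ph, axis=3)
        .repeat(pw, axis=5)
        .reshape(n, F, pr * ph, pc * pw)
    )
    dact = dmaps.transpose(0, 2, 3, 1).reshape(n * oh * ow, F)
    dact[pre <= 0] = 0.0
    grads["conv_w"] = (dact.T @ cols).reshape(F, kh, kw)
    grads["conv_b"] = dact.sum(axis=0)
    return loss, grads


def train_classifier(
    clf: TrainedClassifier,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int | None = None,
    seed: int | None = None,
) -> TrainedClassifier:
    """Train by seeded minibatch gradient descent with momentum.

    Returns a new classifier; the input classifier's weights are left
    untouched.  Deterministic given (data order, seed, epochs): the same
    call twice yields bit-identical predictions.
    """
    spec = clf.spec
    X = clf._check_inputs(X)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    y = y.astype(np.int64)
    epochs = spec.epochs if epochs is None else epochs
    seed = spec.seed if seed is None else seed

    params = {k: v.copy() for k, v in clf.params.items()}
    out = TrainedClassifier(spec=spec, params=params, threshold=clf.threshold)
    if epochs == 0:
        return out
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    lr, mu, bs = spec.learning_rate, spec.momentum, spec.batch_size
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            loss, grads = _forward_backward(out, X[idx], y[idx])
            epoch_loss += loss * len(idx)
            for k, g in grads.items():
                velocity[k] = mu * velocity[k] - lr * g.astype(np.float32)
                params[k] += velocity[k]
        history.append(epoch_loss / n)
    out.loss_history = history
    return out


def flatten_receptive_field(neuron_index: int, spec: NetSpec) -> set[tuple[int, int]]:
    """Input cells that can influence one flatten-layer neuron.

    Flatten order is map-major then row-major within a map.  The neuron at
    pooled cell (r, c) sees conv rows [ph*r, ph*r+ph-1], each conv row x
    spanning input rows [x, x+kh-1]; likewise for columns.  Depends only on
    the architecture, never on weights.
    """
    if not 0 <= neuron_index < spec.flatten_size:
        raise IndexError(
            f"neuron index {neuron_index} out of range [0, {spec.flatten_size})"
        )
    pr, pc = spec.pooled_shape
    ph, pw = spec.pool
    kh, kw = spec.kernel
    within = neuron_index % (pr * pc)
    r, c = divmod(within, pc)
    rows = range(ph * r, ph * r + kh + ph - 1)
    cols = range(pw * c, pw * c + kw + pw - 1)
    return {(i, j) for i in rows for j in cols}


def receptive_field_mask(neuron_index: int, spec: NetSpec) -> np.ndarray:
    """0/1 indicator mask of ``flatten_receptive_field`` on the input shape."""
    mask = np.zeros(spec.input_shape, dtype=np.int64)
    for i, j in flatten_receptive_field(neuron_index, spec):
        mask[i, j] = 1
    return mask


# ---- serialization ------------------------------------------------------


def save_classifier(clf: TrainedClassifier, path) -> None:
    """Serialize spec + weights + threshold to a single portable .npz file."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "spec": asdict(clf.spec),
        "threshold": clf.threshold,
        "loss_history": list(map(float, clf.loss_history)),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **clf.params)


def load_classifier(path) -> TrainedClassifier:
    """Load a classifier saved by :func:`save_classifier`; round-trips are
    bit-exact for predictions."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta.get('format_version')!r}"
            )
        sd = meta["spec"]
        spec = NetSpec(
            input_shape=tuple(sd["input_shape"]), n_filters=sd["n_filters"],
            kernel=tuple(sd["kernel"]), pool=tuple(sd["pool"]),
            dense_units=sd["dense_units"], output_units=sd["output_units"],
            learning_rate=sd["learning_rate"], momentum=sd["momentum"],
            batch_size=sd["batch_size"], epochs=sd["epochs"], seed=sd["seed"],
        )
        params = {k: data[k] for k in data.files if k != "__meta__"}
    clf = TrainedClassifier(spec=spec, params=params, threshold=meta["threshold"])
    clf.loss_history = meta["loss_history"]
    return clf
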