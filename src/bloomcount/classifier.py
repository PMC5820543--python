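"""CNN patch classifier for bloom / non-bloom candidate images.

The network is the classic small-patch architecture used for 36x36 RGB
candidates: input, two convolution layers, two max-pooling layers and
two fully connected layers (seven layers in all), softmax over the two
classes.  It is implemented directly on numpy (im2col convolutions,
mini-batch SGD with step learning-rate decay and L2 weight decay), which
keeps training bitwise reproducible for a fixed seed on one platform.

Class convention: label ``1`` = bloom, ``0`` = non-bloom; class scores
are ordered ``[non-bloom, bloom]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .scene_io import DetectedBloom

__all__ = [
    "CnnSpec",
    "TrainConfig",
    "ConfusionCounts",
    "SmallCnn",
    "build_cnn",
    "train",
    "classify_patches",
    "predict_proba",
    "confusion_summary",
    "save_model",
    "load_model",
]

BLOOM, NONBLOOM = 1, 0


@dataclass(frozen=True)
class CnnSpec:
    """Shape of the 7-layer network (kernel/filter counts configurable)."""

    input_size: int = 36
    input_channels: int = 3
    conv1_filters: int = 20
    conv1_kernel: int = 5
    conv2_filters: int = 50
    conv2_kernel: int = 5
    pool: int = 2
    fc_units: int = 256
    n_classes: int = 2

    def __post_init__(self):
        if self.n_classes != 2:
            raise ValueError("the classifier is a 2-class (bloom / non-bloom) network")
        if min(self.conv1_filters, self.conv2_filters, self.fc_units) < 1:
            raise ValueError("layer sizes must be positive")
        if self.pool < 1 or self.conv1_kernel < 1 or self.conv2_kernel < 1:
            raise ValueError("kernel and pool sizes must be positive")
        s1 = self.input_size - self.conv1_kernel + 1
        if s1 < self.pool or s1 % self.pool:
            raise ValueError("conv1/pool sizes incompatible with the input size")
        s2 = s1 // self.pool - self.conv2_kernel + 1
        if s2 < self.pool or s2 % self.pool:
            raise ValueError("conv2/pool sizes incompatible with the input size")

    @property
    def flat_features(self) -> int:
        s1 = (self.input_size - self.conv1_kernel + 1) // self.pool
        s2 = (s1 - self.conv2_kernel + 1) // self.pool
        return s2 * s2 * self.conv2_filters

    @property
    def n_parameters(self) -> int:
        k1 = self.conv1_kernel ** 2
        k2 = self.conv2_kernel ** 2
        return (self.conv1_filters * (self.input_channels * k1 + 1)
                + self.conv2_filters * (self.conv1_filters * k2 + 1)
                + self.fc_units * (self.flat_features + 1)
                + self.n_classes * (self.fc_units + 1))


@dataclass(frozen=True)
class TrainConfig:
    """The training schedule: 30 epochs of mini-batch SGD, initial
    learning rate 0.01 decreased by a factor of 10 every 10 epochs,
    batch 256, L2 regularization 0.01, with a snapshot of the weights
    kept at the early-stop epoch (the loss plateaus there)."""

    epochs: int = 30
    initial_learning_rate: float = 0.01
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    batch_size: int = 256
    l2_regularization: float = 0.01
    early_snapshot_epoch: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_decay_every,
               self.early_snapshot_epoch) < 1:
            raise ValueError("epochs, batch size and schedule lengths must be positive")
        if self.initial_learning_rate <= 0 or self.lr_decay_factor <= 0:
            raise ValueError("learning rate and decay must be positive")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index."""
        return self.initial_learning_rate * self.lr_decay_factor ** (
            (epoch - 1) // self.lr_decay_every)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; fields read actual_predicted."""

    bloom_bloom: int
    bloom_nonbloom: int
    nonbloom_bloom: int
    nonbloom_nonbloom: int

    def __post_init__(self):
        if min(self.bloom_bloom, self.bloom_nonbloom,
               self.nonbloom_bloom, self.nonbloom_nonbloom) < 0:
            raise ValueError("confusion counts must be non-negative")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*OH*OW, C*k*k) patch matrix for a valid, stride-1
    convolution."""
    sw = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,OH,OW,k,k
    n, c, oh, ow = sw.shape[:4]
    return sw.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)


def _col2im(dcol: np.ndarray, shape, k: int) -> np.ndarray:
    """Scatter-add the im2col gradient back to input shape (N, C, H, W)."""
    n, c, h, w = shape
    oh, ow = h - k + 1, w - k + 1
    dcol = dcol.reshape(n, oh, ow, c, k, k)
    dx = np.zeros(shape, dtype=dcol.dtype)
    for p in range(k):
        for q in range(k):
            dx[:, :, p:p + oh, q:q + ow] += dcol[:, :, :, :, p, q].transpose(0, 3, 1, 2)
    return dx


def _pool_forward(x: np.ndarray, s: int):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5) \
          .reshape(n, c, h // s, w // s, s * s)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, in_shape, s: int):
    n, c, h, w = in_shape
    dwin = np.zeros((n, c, h // s, w // s, s * s), dtype=dout.dtype)
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    return dwin.reshape(n, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5) \
               .reshape(n, c, h, w)


class SmallCnn:
    """The 7-layer patch classifier.  Parameters live in ``params``
    (a dict of float32 arrays); ``snapshot`` holds the early-epoch copy
    kept by :func:`train`."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        self.snapshot: dict[str, np.ndarray] | None = None
        rng = np.random.default_rng(seed)
        c, f1, f2 = spec.input_channels, spec.conv1_filters, spec.conv2_filters
        k1, k2 = spec.conv1_kernel, spec.conv2_kernel

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "W1": he((f1, c, k1, k1), c * k1 * k1),
            "b1": np.zeros(f1, dtype=np.float32),
            "W2": he((f2, f1, k2, k2), f1 * k2 * k2),
            "b2": np.zeros(f2, dtype=np.float32),
            "W3": he((spec.fc_units, spec.flat_features), spec.flat_features),
            "b3": np.zeros(spec.fc_units, dtype=np.float32),
            "W4": he((spec.n_classes, spec.fc_units), spec.fc_units),
            "b4": np.zeros(spec.n_classes, dtype=np.float32),
        }

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, need_cache: bool):
        p, s = self.params, self.spec.pool
        cache = {}
        col1 = _im2col(x, self.spec.conv1_kernel)
        w1 = p["W1"].reshape(p["W1"].shape[0], -1)
        n = x.shape[0]
        o1 = x.shape[2] - self.spec.conv1_kernel + 1
        a1 = (col1 @ w1.T + p["b1"]).reshape(n, o1, o1, -1).transpose(0, 3, 1, 2)
        r1 = np.maximum(a1, 0)
        p1, idx1 = _pool_forward(r1, s)

        col2 = _im2col(p1, self.spec.conv2_kernel)
        w2 = p["W2"].reshape(p["W2"].shape[0], -1)
        o2 = p1.shape[2] - self.spec.conv2_kernel + 1
        a2 = (col2 @ w2.T + p["b2"]).reshape(n, o2, o2, -1).transpose(0, 3, 1, 2)
        r2 = np.maximum(a2, 0)
        p2, idx2 = _pool_forward(r2, s)

        flat = p2.reshape(n, -1)
        h = flat @ p["W3"].T + p["b3"]
        rh = np.maximum(h, 0)
        logits = rh @ p["W4"].T + p["b4"]
        if need_cache:
            cache.update(x=x, col1=col1, a1=a1, r1shape=r1.shape, idx1=idx1,
                         p1=p1, col2=col2, a2=a2, r2shape=r2.shape, idx2=idx2,
                         p2shape=p2.shape, flat=flat, h=h, rh=rh)
        return logits, cache

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class scores (logits) for ``(N, C, H, W)`` float32 input."""
        return self._forward(x, need_cache=False)[0]

    def _backward(self, probs, y_onehot, cache):
        p, s = self.params, self.spec.pool
        n = probs.shape[0]
        grads = {}
        dlogits = (probs - y_onehot).astype(np.float32) / np.float32(n)
        grads["W4"] = dlogits.T @ cache["rh"]
        grads["b4"] = dlogits.sum(0)
        drh = dlogits @ p["W4"]
        dh = drh * (cache["h"] > 0)
        grads["W3"] = dh.T @ cache["flat"]
        grads["b3"] = dh.sum(0)
        dflat = dh @ p["W3"]
        dp2 = dflat.reshape(cache["p2shape"])
        dr2 = _pool_backward(dp2, cache["idx2"], cache["r2shape"], s)
        da2 = dr2 * (cache["a2"] > 0)
        df2 = da2.transpose(0, 2, 3, 1).reshape(-1, da2.shape[1])
        grads["W2"] = (df2.T @ cache["col2"]).reshape(p["W2"].shape)
        grads["b2"] = df2.sum(0)
        dcol2 = df2 @ p["W2"].reshape(p["W2"].shape[0], -1)
        dp1 = _col2im(dcol2, cache["p1"].shape, self.spec.conv2_kernel)
        dr1 = _pool_backward(dp1, cache["idx1"], cache["r1shape"], s)
        da1 = dr1 * (cache["a1"] > 0)
        df1 = da1.transpose(0, 2, 3, 1).reshape(-1, da1.shape[1])
        grads["W1"] = (df1.T @ cache["col1"]).reshape(p["W1"].shape)
        grads["b1"] = df1.sum(0)
        return grads

    def load_snapshot(self) -> None:
        """Swap in the parameters saved at the early-snapshot epoch."""
        if self.snapshot is None:
            raise ValueError("no snapshot available; train the model first")
        self.params = {k: v.copy() for k, v in self.snapshot.items()}


def build_cnn(spec: CnnSpec = CnnSpec(), seed: int = 0) -> SmallCnn:
    """Build the 7-layer network with He-initialized weights."""
    return SmallCnn(spec, seed=seed)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _prep(patches: np.ndarray) -> np.ndarray:
    """(N, H, W, C) uint8/float patches -> centered float32 (N, C, H, W)."""
    x = np.asarray(patches)
    if x.ndim == 3:
        x = x[None]
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    x = x.astype(np.float32, copy=False)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)) - np.float32(0.5)


def predict_proba(model: SmallCnn, patches, batch_size: int = 512) -> np.ndarray:
    """Softmax class probabilities, ordered [non-bloom, bloom]."""
    x = _prep(patches)
    out = np.empty((len(x), model.spec.n_classes), dtype=np.float32)
    for i in range(0, len(x), batch_size):
        out[i:i + batch_size] = _softmax(model.forward(x[i:i + batch_size]))
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(model: SmallCnn, patches, labels, cfg: TrainConfig = TrainConfig(),
          test_patches=None, test_labels=None) -> pd.DataFrame:
    """Train with mini-batch SGD under the step-decay schedule.

    Returns the per-epoch curves (train/test accuracy per class, mean
    loss, learning rate) as a DataFrame and stores a parameter snapshot
    at ``cfg.early_snapshot_epoch`` on the model.  Deterministic for a
    fixed ``cfg.rng_seed``.
    """
    x = _prep(patches)
    y = np.asarray(labels, dtype=np.int64)
    if len(x) != len(y):
        raise ValueError("patches and labels must align")
    if len(x) < cfg.batch_size:
        warnings.warn("fewer samples than the batch size; using one smaller batch")
    xt = _prep(test_patches) if test_patches is not None else None
    yt = np.asarray(test_labels, dtype=np.int64) if test_labels is not None else None

    rng = np.random.default_rng(cfg.rng_seed)
    p = model.params
    l2 = np.float32(cfg.l2_regularization)
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        lr = np.float32(cfg.learning_rate(epoch))
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = x[sel], y[sel]
            logits, cache = model._forward(xb, need_cache=True)
            probs = _softmax(logits)
            eps = np.float32(1e-12)
            data_loss = float(-np.log(probs[np.arange(len(yb)), yb] + eps).mean())
            reg_loss = 0.5 * float(l2) * sum(
                float((p[k] ** 2).sum()) for k in ("W1", "W2", "W3", "W4"))
            losses.append(data_loss + reg_loss)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1
            grads = model._backward(probs, onehot, cache)
            for k in p:
                g = grads[k]
                if k.startswith("W"):
                    g = g + l2 * p[k]
                p[k] -= lr * g

        row = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": float(lr)}
        acc = _per_class_accuracy(model, x, y)
        row["train_acc_bloom"], row["train_acc_nonbloom"] = acc
        if xt is not None:
            acc = _per_class_accuracy(model, xt, yt)
            row["test_acc_bloom"], row["test_acc_nonbloom"] = acc
        else:
            row["test_acc_bloom"] = row["test_acc_nonbloom"] = np.nan
        rows.append(row)
        if epoch == cfg.early_snapshot_epoch or (epoch == cfg.epochs
                                                 and model.snapshot is None):
            model.snapshot = {k: v.copy() for k, v in p.items()}
    cols = ["epoch", "train_acc_bloom", "train_acc_nonbloom",
            "test_acc_bloom", "test_acc_nonbloom", "loss", "lr"]
    return pd.DataFrame(rows, columns=cols)


def _per_class_accuracy(model, x, y, batch_size: int = 512):
    pred = np.empty(len(x), dtype=np.int64)
    for i in range(0, len(x), batch_size):
        pred[i:i + batch_size] = model.forward(x[i:i + batch_size]).argmax(axis=1)
    out = []
    for cls in (BLOOM, NONBLOOM):
        m = y == cls
        out.append(float((pred[m] == cls).mean()) if m.any() else np.nan)
    return out


# ---------------------------------------------------------------------------
# classification and confusion arithmetic
# ---------------------------------------------------------------------------


def classify_patches(model: SmallCnn, candidates) -> list[DetectedBloom]:
    """Keep candidates whose bloom probability is strictly above 0.5."""
    if not candidates:
        return []
    probs = predict_proba(model, np.stack([c.patch for c in candidates]))
    out = []
    for cand, pr in zip(candidates, probs[:, BLOOM]):
        if pr > 0.5:
            out.append(DetectedBloom(image_id=cand.image_id,
                                     pixel=(float(cand.center[0]), float(cand.center[1])),
                                     position3d=None,
                                     classifier_score=float(pr)))
    return out


def confusion_summary(counts: ConfusionCounts) -> dict:
    """Over/underestimation arithmetic on a 2x2 confusion table.

    ``predicted_bloom`` counts everything the classifier called a bloom;
    ``actual_bloom`` is the actual-bloom row sum.  The printed per-class
    precision/recall figures of this kind of table are ambiguous about
    orientation, so the ratios are reported with explicit
    numerator/denominator names instead.
    """
    actual = counts.bloom_bloom + counts.bloom_nonbloom
    if actual == 0:
        raise ValueError("over/underestimation undefined with zero actual blooms")
    predicted = counts.bloom_bloom + counts.nonbloom_bloom
    pct = int(np.round(100.0 * (predicted - actual) / actual))
    ratios = {
        "correct_of_predicted_bloom":
            counts.bloom_bloom / predicted if predicted else np.nan,
        "detected_of_actual_bloom": counts.bloom_bloom / actual,
        "correct_of_predicted_nonbloom":
            counts.nonbloom_nonbloom / (counts.nonbloom_nonbloom + counts.bloom_nonbloom)
            if counts.nonbloom_nonbloom + counts.bloom_nonbloom else np.nan,
        "detected_of_actual_nonbloom":
            counts.nonbloom_nonbloom / (counts.nonbloom_nonbloom + counts.nonbloom_bloom)
            if counts.nonbloom_nonbloom + counts.nonbloom_bloom else np.nan,
    }
    return {
        "predicted_bloom": predicted,
        "actual_bloom": actual,
        "over_under_pct": pct,
        "ratios": ratios,
    }


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: SmallCnn, path) -> None:
    spec = model.spec
    meta = np.array([spec.input_size, spec.input_channels, spec.conv1_filters,
                     spec.conv1_kernel, spec.conv2_filters, spec.conv2_kernel,
                     spec.pool, spec.fc_units, spec.n_classes], dtype=np.int64)
    np.savez(path, _spec=meta, **model.params)


def load_model(path) -> SmallCnn:
    with np.load(path) as data:
        meta = data["_spec"]
        spec = CnnSpec(*[int(v) for v in meta])
        model = SmallCnn(spec)
        model.params = {k: data[k].copy() for k in data.files if k != "_spec"}
    return model
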