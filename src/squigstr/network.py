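"""Four-class convolutional classifier over repeat images.

Architecture (for unit length R; heights act on the 50 signal bins):

    input  50 x R x 3
    conv   32 filters 4x1, stride 1, same padding, ReLU
    pool   max 2x1 (ceiling)            -> 25 x R x 32
    conv   64 filters 3x1, stride 1, same padding, ReLU
    pool   max 2x1 (ceiling)            -> 13 x R x 64
    flatten                             -> 832*R values
    dense  512, ReLU
    dense  4 softmax logits             (not / in / del-in / ins-in repeat)

Filters are one column wide: convolution mixes signal bins within a window
position, never across the R unit positions, until the dense layers.
Training minimizes softmax cross-entropy with Adam under a staged learning
rate (0.005 before epoch n, 0.001 before 10n, 0.0005 before 100n, 0.0001
after; n defaults to 5).

Implemented directly on NumPy arrays (forward, backprop, Adam); the layer
sizes above are fixed by the method, only R varies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .events import N_BINS
from .imaging import TrainingSet

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "ConvNet",
    "TrainHistory",
    "build_model",
    "train",
    "predict",
    "learning_rate",
    "save_model",
    "load_model",
]

N_CLASSES = 4


@dataclass(frozen=True)
class ModelSpec:
    """Layer constants of the classifier; only ``unit_len`` is variable."""

    unit_len: int
    n_bins: int = N_BINS
    conv1_filters: int = 32
    conv1_kernel: int = 4
    conv2_filters: int = 64
    conv2_kernel: int = 3
    fc1_units: int = 512
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.unit_len < 2:
            raise ValueError(
                "unit length must be >= 2 (homopolymer repeats are not supported)"
            )

    @property
    def flatten_len(self) -> int:
        h = -(-self.n_bins // 2)        # after pool1, ceiling
        h = -(-h // 2)                  # after pool2, ceiling
        return h * self.unit_len * self.conv2_filters


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; ``lr_n`` is the n of the staged LR schedule."""

    batch_size: int = 512
    epochs: int = 500
    lr_n: int = 5
    seed: int = 0
    schedule_unit: str = "epoch"   # or "step": reinterpret the schedule in optimizer steps
    validation_fraction: float = 0.0


def learning_rate(step: int, n: int) -> float:
    """Staged schedule: 0.005 before n, 0.001 before 10n, 0.0005 before 100n, then 0.0001."""
    if step < n:
        return 0.005
    if step < 10 * n:
        return 0.001
    if step < 100 * n:
        return 0.0005
    return 0.0001


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _conv1d_h(x: np.ndarray, w: np.ndarray, b: np.ndarray, pad: tuple[int, int]):
    """Same-padded conv along the bin axis. x: (N,C,H,W), w: (F,C,K) -> (N,F,H,W)."""
    xp = np.pad(x, ((0, 0), (0, 0), pad, (0, 0)))
    win = sliding_window_view(xp, w.shape[2], axis=2)  # (N,C,H,W,K)
    y = np.tensordot(win, w, axes=([1, 4], [1, 2]))     # (N,H,W,F)
    y = np.transpose(y, (0, 3, 1, 2))
    return y + b[None, :, None, None], win


def _conv1d_h_backward(dy, win, w, x_shape, pad):
    db = dy.sum(axis=(0, 2, 3))
    dw = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))  # (F,C,K)
    N, C, H, W = x_shape
    dxp = np.zeros((N, C, H + pad[0] + pad[1], W), dtype=dy.dtype)
    for k in range(w.shape[2]):
        t = np.tensordot(dy, w[:, :, k], axes=([1], [0]))  # (N,H,W,C)
        dxp[:, :, k : k + H, :] += np.transpose(t, (0, 3, 1, 2))
    return dxp[:, :, pad[0] : pad[0] + H, :], dw, db


def _maxpool2_h(x: np.ndarray):
    """Max pool 2x1 along H with ceiling (odd tail row pools alone)."""
    N, C, H, W = x.shape
    Ho = -(-H // 2)
    if H % 2:
        x = np.concatenate([x, np.full((N, C, 1, W), -np.inf, dtype=x.dtype)], axis=2)
    xr = x.reshape(N, C, Ho, 2, W)
    arg = xr.argmax(axis=3)
    y = np.take_along_axis(xr, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, (arg, H)


def _maxpool2_h_backward(dy, cache):
    arg, H = cache
    N, C, Ho, W = dy.shape
    dxr = np.zeros((N, C, Ho, 2, W), dtype=dy.dtype)
    np.put_along_axis(dxr, arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
    return dxr.reshape(N, C, Ho * 2, W)[:, :, :H, :]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """The classifier's parameters and forward/backward passes."""

    PARAM_NAMES = ("w1", "b1", "w2", "b2", "wf1", "bf1", "wf2", "bf2")

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.pad1 = ((s.conv1_kernel - 1) // 2, s.conv1_kernel // 2)
        self.pad2 = ((s.conv2_kernel - 1) // 2, s.conv2_kernel // 2)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.w1 = he((s.conv1_filters, 3, s.conv1_kernel), 3 * s.conv1_kernel)
        self.b1 = np.zeros(s.conv1_filters, dtype=np.float32)
        self.w2 = he((s.conv2_filters, s.conv1_filters, s.conv2_kernel), s.conv1_filters * s.conv2_kernel)
        self.b2 = np.zeros(s.conv2_filters, dtype=np.float32)
        self.wf1 = he((s.flatten_len, s.fc1_units), s.flatten_len)
        self.bf1 = np.zeros(s.fc1_units, dtype=np.float32)
        self.wf2 = he((s.fc1_units, s.n_classes), s.fc1_units)
        self.bf2 = np.zeros(s.n_classes, dtype=np.float32)

    # -- passes ------------------------------------------------------------

    def _prep(self, images: np.ndarray) -> np.ndarray:
        """(N, 50, R, 3) uint8 -> (N, 3, 50, R) float32 in [0, 1]."""
        x = np.asarray(images)
        if x.ndim != 4 or x.shape[1] != self.spec.n_bins or x.shape[2] != self.spec.unit_len:
            raise ValueError(
                f"expected images of shape (N, {self.spec.n_bins}, "
                f"{self.spec.unit_len}, 3) for unit length {self.spec.unit_len}, "
                f"got {x.shape}"
            )
        return np.ascontiguousarray(np.transpose(x, (0, 3, 1, 2)), dtype=np.float32) / 255.0

    def forward(self, images: np.ndarray, record_shapes: bool = False):
        x = self._prep(images)
        shapes = [("input", x.shape[1:])] if record_shapes else None
        z1, win1 = _conv1d_h(x, self.w1, self.b1, self.pad1)
        a1 = np.maximum(z1, 0.0)
        p1, cache1 = _maxpool2_h(a1)
        z2, win2 = _conv1d_h(p1, self.w2, self.b2, self.pad2)
        a2 = np.maximum(z2, 0.0)
        p2, cache2 = _maxpool2_h(a2)
        flat = p2.reshape(p2.shape[0], -1)
        h = flat @ self.wf1 + self.bf1
        ah = np.maximum(h, 0.0)
        logits = ah @ self.wf2 + self.bf2
        if record_shapes:
            shapes += [
                ("conv1", z1.shape[1:]),
                ("pool1", p1.shape[1:]),
                ("conv2", z2.shape[1:]),
                ("pool2", p2.shape[1:]),
                ("flatten", (flat.shape[1],)),
                ("fc1", (ah.shape[1],)),
                ("logits", (logits.shape[1],)),
            ]
        cache = (x, z1, win1, cache1, p1, z2, win2, cache2, p2, flat, h, ah)
        return (logits, cache, shapes) if record_shapes else (logits, cache)

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        x, z1, win1, cache1, p1, z2, win2, cache2, p2, flat, h, ah = cache
        grads: dict[str, np.ndarray] = {}
        grads["wf2"] = ah.T @ dlogits
        grads["bf2"] = dlogits.sum(axis=0)
        dah = dlogits @ self.wf2.T
        dh = dah * (h > 0)
        grads["wf1"] = flat.T @ dh
        grads["bf1"] = dh.sum(axis=0)
        dflat = dh @ self.wf1.T
        dp2 = dflat.reshape(p2.shape)
        da2 = _maxpool2_h_backward(dp2, cache2)
        dz2 = da2 * (z2 > 0)
        dp1, grads["w2"], grads["b2"] = _conv1d_h_backward(dz2, win2, self.w2, p1.shape, self.pad2)
        da1 = _maxpool2_h_backward(dp1, cache1)
        dz1 = da1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv1d_h_backward(dz1, win1, self.w1, x.shape, self.pad1)
        return grads

    def shape_report(self) -> dict[str, tuple[int, ...]]:
        """Per-layer output dims from an actual forward pass with a dummy image."""
        dummy = np.zeros((1, self.spec.n_bins, self.spec.unit_len, 3), dtype=np.uint8)
        _, _, shapes = self.forward(dummy, record_shapes=True)
        return dict(shapes)

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name in self.PARAM_NAMES:
            h.update(np.ascontiguousarray(getattr(self, name)).tobytes())
        return h.hexdigest()


def build_model(unit_len: int, seed: int = 0) -> tuple[ConvNet, dict[str, tuple[int, ...]]]:
    """Instantiate a seeded model for a unit length; returns (model, shape report)."""
    model = ConvNet(ModelSpec(unit_len=unit_len), seed=seed)
    return model, model.shape_report()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": self.epoch,
                "lr": self.lr,
                "loss": self.loss,
                "accuracy": self.accuracy,
                "val_accuracy": self.val_accuracy or [np.nan] * len(self.epoch),
            }
        ).to_csv(path, sep="\t", index=False)


class _Adam:
    def __init__(self, model: ConvNet, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model, self.beta1, self.beta2, self.eps = model, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(model, k)) for k in model.PARAM_NAMES}
        self.v = {k: np.zeros_like(getattr(model, k)) for k in model.PARAM_NAMES}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in self.model.PARAM_NAMES:
            g = grads[k].astype(np.float32)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p = getattr(self.model, k)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: ConvNet, ts: TrainingSet, config: TrainingConfig) -> TrainHistory:
    """Train on the balanced plan: each epoch sees the repeat set plus one chunk.

    Deterministic for a fixed config seed.  Raises on single-class data and
    aborts with diagnostics if the loss goes non-finite.
    """
    if ts.unit_len != model.spec.unit_len:
        raise ValueError(
            f"training set unit length {ts.unit_len} != model unit length {model.spec.unit_len}"
        )
    present = np.unique(ts.labels)
    if present.size < 2:
        raise ValueError(f"training set has a single class ({present.tolist()}); need >= 2")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model)
    history = TrainHistory()

    val_idx = np.array([], dtype=np.int64)
    train_mask = np.ones(ts.labels.size, dtype=bool)
    if config.validation_fraction > 0:
        n_val = int(round(config.validation_fraction * ts.labels.size))
        val_idx = rng.choice(ts.labels.size, size=n_val, replace=False)
        train_mask[val_idx] = False

    step = 0
    for epoch in range(config.epochs):
        idx = ts.epoch_indices(epoch)
        idx = idx[train_mask[idx]]
        idx = rng.permutation(idx)
        losses, correct, seen = [], 0, 0
        epoch_lr = learning_rate(epoch, config.lr_n)
        for lo in range(0, idx.size, config.batch_size):
            batch = idx[lo : lo + config.batch_size]
            lr = epoch_lr if config.schedule_unit == "epoch" else learning_rate(step, config.lr_n)
            logits, cache = model.forward(ts.images[batch])
            probs = _softmax(logits)
            y = ts.labels[batch].astype(np.int64)
            loss = float(-np.mean(np.log(probs[np.arange(y.size), y] + 1e-12)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step} "
                    f"(lr={lr}, batch={batch.size}); aborting"
                )
            dlogits = probs
            dlogits[np.arange(y.size), y] -= 1.0
            dlogits /= y.size
            grads = model.backward(cache, dlogits.astype(np.float32))
            opt.step(grads, lr)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y).sum())
            seen += y.size
            step += 1
        history.epoch.append(epoch)
        history.lr.append(epoch_lr if config.schedule_unit == "epoch" else lr)
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / max(seen, 1))
        if val_idx.size:
            val_labels, _ = predict(model, ts.images[val_idx])
            history.val_accuracy.append(
                float(np.mean(val_labels == ts.labels[val_idx].astype(np.int64)))
            )
    return history


def predict(model: ConvNet, images: np.ndarray, batch_size: int = 2048):
    """Class labels (argmax; ties break to the lowest index) and probabilities."""
    images = np.asarray(images)
    labels = np.empty(images.shape[0], dtype=np.int64)
    probs = np.empty((images.shape[0], model.spec.n_classes), dtype=np.float64)
    for lo in range(0, images.shape[0], batch_size):
        logits, _ = model.forward(images[lo : lo + batch_size])
        p = _softmax(logits)
        probs[lo : lo + batch_size] = p
        labels[lo : lo + batch_size] = p.argmax(axis=1)
    return labels, probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_model(path: str, model: ConvNet, group_id: str, norm_version: str = "median-mad-1.4826-clip5") -> None:
    meta = {
        "version": _CHECKPOINT_VERSION,
        "unit_len": model.spec.unit_len,
        "group_id": group_id,
        "norm_version": norm_version,
    }
    arrays = {k: getattr(model, k) for k in ConvNet.PARAM_NAMES}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str) -> tuple[ConvNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        model = ConvNet(ModelSpec(unit_len=int(meta["unit_len"])))
        for k in ConvNet.PARAM_NAMES:
            setattr(model, k, z[k].astype(np.float32))
    return model, meta
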