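"""Trainable readout heads over reservoir state vectors.

Two heads are provided: a multinomial softmax (ridge-penalized) linear
readout, and a lightweight convolutional network that exploits the
(n_rows, n_frames) grid layout of the states. Both are deterministic given
their seed and train by full-batch optimization. Class activation maps and
16-level conductance quantization of trained weights (differential-pair
sign convention) model inference mapped back onto the physical device
array.

The CNN is intentionally tiny (< 5k parameters): conv 3x3x8 -> ReLU ->
2x2 max-pool -> conv 3x3x16 -> ReLU -> global average pool -> dense
softmax, trained by full-batch gradient descent with a fixed step. Grids
too small for the pooled double-conv stack fall back to a single conv.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.ndimage
import scipy.optimize

from .reservoir import ReservoirStateVector

__all__ = [
    "LabeledStateSet",
    "ReadoutModel",
    "LinearReadout",
    "CNNReadout",
    "QuantizedModel",
    "train_linear",
    "train_cnn",
    "predict",
    "cam",
    "quantize_weights",
    "train_val_split",
]

logger = logging.getLogger(__name__)

LABEL_MODES = {"stage3": 3, "snore2": 2, "joint6": 6}


def _as_matrix(states) -> np.ndarray:
    if isinstance(states, np.ndarray):
        return np.atleast_2d(states)
    return np.vstack([s.currents for s in states])


def _as_grids(states, layout=None) -> np.ndarray:
    x = _as_matrix(states)
    if layout is None:
        if not isinstance(states, np.ndarray) and hasattr(states[0], "layout"):
            layout = states[0].layout
        else:
            raise ValueError("grid layout required for array input")
    return x.reshape(-1, *layout)


@dataclass
class LabeledStateSet:
    """Reservoir states with per-state class labels."""

    states: list[ReservoirStateVector] | np.ndarray
    labels: np.ndarray
    label_mode: Literal["stage3", "snore2", "joint6"] = "stage3"
    class_names: tuple[str, ...] | None = None
    layout: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.states) != self.labels.size:
            raise ValueError("states and labels differ in length")
        n_classes = LABEL_MODES[self.label_mode]
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= n_classes):
            raise ValueError(f"labels outside the {self.label_mode} class set")
        if self.class_names is None:
            defaults = {"stage3": ("wake", "light", "deep"),
                        "snore2": ("no-snore", "snore"),
                        "joint6": ("wake/no-snore", "wake/snore",
                                   "light/no-snore", "light/snore",
                                   "deep/no-snore", "deep/snore")}
            self.class_names = defaults[self.label_mode]
        if self.layout is None and len(self.states) and hasattr(
                self.states[0], "layout"):
            self.layout = self.states[0].layout

    @property
    def X(self) -> np.ndarray:
        return _as_matrix(self.states)

    @property
    def n_classes(self) -> int:
        return LABEL_MODES[self.label_mode]

    def subset(self, idx: np.ndarray) -> "LabeledStateSet":
        states = ([self.states[i] for i in idx]
                  if not isinstance(self.states, np.ndarray)
                  else self.states[idx])
        return LabeledStateSet(states, self.labels[idx], self.label_mode,
                               self.class_names, self.layout)


def train_val_split(data: LabeledStateSet, val_frac: float = 0.2,
                    seed: int = 0) -> tuple[LabeledStateSet, LabeledStateSet]:
    """Stratified, seed-controlled train/validation split."""
    rng = np.random.default_rng(seed)
    tr_idx, va_idx = [], []
    for c in np.unique(data.labels):
        idx = np.flatnonzero(data.labels == c)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_frac * idx.size)))
        va_idx.extend(idx[:n_val])
        tr_idx.extend(idx[n_val:])
    return data.subset(np.sort(tr_idx)), data.subset(np.sort(va_idx))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Linear readout
# ---------------------------------------------------------------------------

@dataclass
class LinearReadout:
    """Multinomial softmax readout with L2-penalized weights.

    Inputs are standardized internally (stored mean/scale); ``W`` has shape
    (n_features, n_classes) on the standardized scale.
    """

    kind: str
    W: np.ndarray
    b: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    l2: float
    class_names: tuple[str, ...]
    layout: tuple[int, int] | None
    train_accuracy: float = 0.0
    meta: dict = field(default_factory=dict)

    def transform(self, states) -> np.ndarray:
        return (_as_matrix(states) - self.mu) / self.sd

    def logits(self, states) -> np.ndarray:
        return self.transform(states) @ self.W + self.b

    @property
    def weight_tensors(self) -> dict[str, np.ndarray]:
        return {"W": self.W}


def softmax_loss_grad(W: np.ndarray, b: np.ndarray, X: np.ndarray,
                      y: np.ndarray, l2: float
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalized multinomial cross-entropy and its analytic gradient.

    ``J = sum_i -log p(y_i | x_i) + (l2/2) ||W||^2`` (bias unpenalized).
    """
    n, _ = X.shape
    p = _softmax(X @ W + b)
    ll = -np.log(np.clip(p[np.arange(n), y], 1e-300, None)).sum()
    loss = ll + 0.5 * l2 * float((W ** 2).sum())
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    gW = X.T @ d + l2 * W
    gb = d.sum(axis=0)
    return loss, gW, gb


def train_linear(data: LabeledStateSet, l2: float = 1.0) -> LinearReadout:
    """Fit the multinomial softmax readout by L-BFGS to tight tolerance.

    Deterministic (zero initialization, full-batch quasi-Newton). The
    returned model records the training-set accuracy.
    """
    y = data.labels
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = data.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    n, d = Xs.shape
    c = data.n_classes

    def fun(theta):
        W = theta[:d * c].reshape(d, c)
        b = theta[d * c:]
        loss, gW, gb = softmax_loss_grad(W, b, Xs, y, l2)
        return loss, np.concatenate([gW.ravel(), gb])

    res = scipy.optimize.minimize(
        fun, np.zeros(d * c + c), jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "gtol": 1e-9, "ftol": 1e-15})
    W = res.x[:d * c].reshape(d, c)
    b = res.x[d * c:]
    acc = float((np.argmax(Xs @ W + b, axis=1) == y).mean())
    return LinearReadout("linear", W, b, mu, sd, l2, data.class_names,
                         data.layout, acc, {"converged": bool(res.success)})


# ---------------------------------------------------------------------------
# Lightweight CNN readout
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, k: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation. x: (N,C,H,W), k: (O,C,3,3) -> (N,O,H-2,W-2)."""
    win = np.lib.stride_tricks.sliding_window_view(x, k.shape[2:],
                                                   axis=(2, 3))
    return np.einsum("nchwij,ocij->nohw", win, k,
                     optimize=True) + b[:, None, None]


def _conv_backward(x: np.ndarray, k: np.ndarray, dout: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    win = np.lib.stride_tricks.sliding_window_view(x, k.shape[2:],
                                                   axis=(2, 3))
    dk = np.einsum("nchwij,nohw->ocij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    kh, kw = k.shape[2:]
    pad = np.pad(dout, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    pwin = np.lib.stride_tricks.sliding_window_view(pad, (kh, kw),
                                                    axis=(2, 3))
    dx = np.einsum("nohwij,ocij->nchw", pwin, k[:, :, ::-1, ::-1],
                   optimize=True)
    return dx, dk, db


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, :2 * h2, :2 * w2].reshape(n, c, h2, 2, w2, 2)
    out = xc.max(axis=(3, 5))
    mask = xc == out[:, :, :, None, :, None]
    return out, (mask, x.shape, h2, w2)

def _pool_backward(dout: np.ndarray, cache) -> np.ndarray:
    mask, shape, h2, w2 = cache
    n, c = shape[:2]
    dx = np.zeros(shape)
    spread = mask * dout[:, :, :, None, :, None] / mask.sum(
        axis=(3, 5), keepdims=True)
    dx[:, :, :2 * h2, :2 * w2] = spread.reshape(n, c, 2 * h2, 2 * w2)
    return dx


@dataclass
class CNNReadout:
    """Tiny conv-net readout over the reservoir state grid."""

    kind: str
    params: dict[str, np.ndarray]
    arch: str                      # "double" or "single"
    mu: float
    sd: float
    class_names: tuple[str, ...]
    layout: tuple[int, int]
    train_accuracy: float = 0.0
    training_curve: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        z1 = _conv_forward(x, p["k1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        if self.arch == "double":
            p1, pc = _pool_forward(a1)
            z2 = _conv_forward(p1, p["k2"], p["b2"])
            a2 = np.maximum(z2, 0.0)
        else:
            p1, pc, z2, a2 = None, None, None, a1
        feat = a2.mean(axis=(2, 3))
        logits = feat @ p["Wd"] + p["bd"]
        if want_cache:
            return logits, (x, z1, a1, p1, pc, z2, a2, feat)
        return logits

    def logits(self, states) -> np.ndarray:
        x = (_as_grids(states, self.layout) - self.mu) / self.sd
        return self._forward(x[:, None, :, :])

    def final_maps(self, states) -> np.ndarray:
        """Post-ReLU feature maps feeding the global average pool."""
        x = (_as_grids(states, self.layout) - self.mu) / self.sd
        _, cache = self._forward(x[:, None, :, :], want_cache=True)
        return cache[6]

    @property
    def weight_tensors(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.params.items()
                if k in ("k1", "k2", "Wd")}


def _init_cnn(layout, n_classes, seed, n_c1=8, n_c2=16):
    h, w = layout
    rng = np.random.default_rng(seed)
    arch = "double" if (h - 2) // 2 >= 3 and (w - 2) // 2 >= 3 else "single"
    if arch == "single":
        logger.warning("grid %s too small for pooled double conv; "
                       "falling back to a single conv layer", layout)
    params = {
        "k1": rng.normal(0, np.sqrt(2.0 / 9), (n_c1, 1, 3, 3)),
        "b1": np.zeros(n_c1),
    }
    feat_dim = n_c1
    if arch == "double":
        params["k2"] = rng.normal(0, np.sqrt(2.0 / (9 * n_c1)),
                                  (n_c2, n_c1, 3, 3))
        params["b2"] = np.zeros(n_c2)
        feat_dim = n_c2
    params["Wd"] = rng.normal(0, np.sqrt(1.0 / feat_dim),
                              (feat_dim, n_classes))
    params["bd"] = np.zeros(n_classes)
    return params, arch


def train_cnn(data: LabeledStateSet, epochs: int = 300, lr: float = 0.2,
              seed: int = 0, batch_size: int | None = None) -> CNNReadout:
    """Train the lightweight CNN by gradient descent.

    Full-batch with a fixed step by default (deterministic given the
    seed); pass ``batch_size`` for the mini-batch variant. Records the
    per-epoch loss curve.
    """
    if data.layout is None:
        raise ValueError("CNN readout needs the (n_rows, n_frames) layout")
    y = data.labels
    grids = _as_grids(data.states, data.layout)
    mu = float(grids.mean())
    sd = float(grids.std()) or 1.0
    x = ((grids - mu) / sd)[:, None, :, :]
    n = x.shape[0]
    model = CNNReadout("cnn", *_init_cnn(data.layout, data.n_classes, seed),
                       mu=mu, sd=sd, class_names=data.class_names,
                       layout=data.layout)
    rng = np.random.default_rng(seed + 1)
    for _ in range(epochs):
        if batch_size is None:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = [perm[i:i + batch_size]
                       for i in range(0, n, batch_size)]
        epoch_loss = 0.0
        for idx in batches:
            loss, grads = _cnn_loss_grads(model, x[idx], y[idx])
            epoch_loss += loss * idx.size / n
            for key, g in grads.items():
                model.params[key] -= lr * g
        model.training_curve.append(epoch_loss)
    pred = np.argmax(model._forward(x), axis=1)
    model.train_accuracy = float((pred == y).mean())
    return model


def _cnn_loss_grads(model: CNNReadout, x: np.ndarray, y: np.ndarray):
    p = model.params
    logits, cache = model._forward(x, want_cache=True)
    _, z1, a1, p1, pc, z2, a2, feat = cache
    n = x.shape[0]
    probs = _softmax(logits)
    loss = float(-np.log(np.clip(probs[np.arange(n), y],
                                 1e-300, None)).mean())
    d = probs.copy()
    d[np.arange(n), y] -= 1.0
    d /= n
    grads = {"Wd": feat.T @ d, "bd": d.sum(axis=0)}
    dfeat = d @ p["Wd"].T
    hw = a2.shape[2] * a2.shape[3]
    da2 = (dfeat[:, :, None, None] / hw) * np.ones_like(a2)
    if model.arch == "double":
        dz2 = da2 * (z2 > 0)
        dp1, grads["k2"], grads["b2"] = _conv_backward(p1, p["k2"], dz2)
        da1 = _pool_backward(dp1, pc)
    else:
        da1 = da2
    dz1 = da1 * (z1 > 0)
    _, grads["k1"], grads["b1"] = _conv_backward(x, p["k1"], dz1)
    return loss, grads


ReadoutModel = LinearReadout | CNNReadout


# ---------------------------------------------------------------------------
# Prediction, CAM, quantization
# ---------------------------------------------------------------------------

def predict(model, states) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class labels and per-class softmax scores."""
    logits = model.logits(states)
    scores = _softmax(logits)
    return np.argmax(scores, axis=1), scores


def cam(model, state) -> np.ndarray:
    """Class activation maps, one (n_rows, n_frames) grid per class.

    Linear model: the class weight vector reshaped to the grid, elementwise
    multiplied with the (standardized) state grid, so the maps sum (plus
    bias) to the class logits. CNN: global-average-pooling CAM — the
    class-weighted sum of the final conv maps, bilinearly upsampled to the
    state grid.
    """
    if model.layout is None:
        raise ValueError("model has no grid layout")
    h, w = model.layout
    if isinstance(model, LinearReadout):
        xs = model.transform([state] if hasattr(state, "currents")
                             else state).ravel()
        grid = xs.reshape(h, w)
        return np.stack([(model.W[:, c].reshape(h, w)) * grid
                         for c in range(model.W.shape[1])])
    maps = model.final_maps([state] if hasattr(state, "currents")
                            else state)[0]          # (C, h', w')
    n_classes = model.params["Wd"].shape[1]
    cams = []
    for c in range(n_classes):
        m = np.tensordot(model.params["Wd"][:, c], maps, axes=1)
        zoom = (h / m.shape[0], w / m.shape[1])
        cams.append(scipy.ndimage.zoom(m, zoom, order=1))
    return np.stack(cams)


@dataclass
class QuantizedModel:
    """Readout with weights mapped onto discrete conductance levels.

    Symmetric uniform per-tensor quantization to ``n_levels`` magnitude
    levels; the sign is carried separately, modeling a two-device
    differential conductance pair (physical conductances are
    non-negative). Biases stay unquantized — they live in the digital
    periphery, not the array.
    """

    base: ReadoutModel
    n_levels: int
    level_values: dict[str, np.ndarray]
    quantized: dict[str, np.ndarray]
    accuracy_delta: float | None = None

    def logits(self, states) -> np.ndarray:
        saved = {}
        tensors = self.base.weight_tensors
        for name, q in self.quantized.items():
            saved[name] = tensors[name].copy()
            tensors[name][...] = q
        try:
            return self.base.logits(states)
        finally:
            for name, w in saved.items():
                tensors[name][...] = w

    @property
    def class_names(self):
        return self.base.class_names

    @property
    def layout(self):
        return self.base.layout


def quantize_weights(model: ReadoutModel, n_levels: int = 16,
                     eval_data: LabeledStateSet | None = None
                     ) -> QuantizedModel:
    """Quantize trained weights to ``n_levels`` conductance magnitudes.

    Per tensor, the level grid is ``k * max|w| / (n_levels - 1)`` for
    ``k = 0 .. n_levels-1``; each weight maps to the nearest level with its
    sign kept, so the per-weight error is at most half the level spacing.
    If ``eval_data`` is given, the accuracy change after quantization is
    recorded (quantized minus float, in accuracy points).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    levels, quant = {}, {}
    for name, w in model.weight_tensors.items():
        m = np.abs(w).max()
        if m == 0:
            levels[name] = np.zeros(n_levels)
            quant[name] = w.copy()
            continue
        delta = m / (n_levels - 1)
        levels[name] = np.arange(n_levels) * delta
        quant[name] = np.sign(w) * np.round(np.abs(w) / delta) * delta
    qm = QuantizedModel(model, n_levels, levels, quant)
    if eval_data is not None:
        yhat_f, _ = predict(model, eval_data.states)
        yhat_q, _ = predict(qm, eval_data.states)
        acc_f = float((yhat_f == eval_data.labels).mean())
        acc_q = float((yhat_q == eval_data.labels).mean())
        qm.accuracy_delta = acc_q - acc_f
    return qm
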