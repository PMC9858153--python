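"""ConvMixer classifier: patch embedding, depthwise/pointwise mixer blocks with
residual connections, global pooling head, and its SGDM training loop.

The ConvMixer operates on equal-resolution patch tokens throughout: a strided
p x p convolution embeds the image into an h-channel grid, then ``depth``
mixer blocks alternate spatial mixing (depthwise convolution, wrapped in a
residual connection) with channel mixing (pointwise 1 x 1 convolution), each
followed by GELU and batch normalization.  Global average pooling yields an
h-vector fed to a softmax head.  Defaults follow the configuration used for
BCG spectrogram images: patch 5, hidden dimension 32, depth 7, trained with
SGD momentum (batch 64, 7 epochs, initial learning rate 0.001).

Implemented directly on the NumPy layers in :mod:`bcgmixer.nn`; gradients are
exact backpropagation, verified against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn

__all__ = [
    "ConvMixerConfig",
    "TrainConfig",
    "MixerBlock",
    "ConvMixerModel",
    "build_convmixer",
    "count_parameters",
    "forward",
    "train",
    "ConvMixerClassifier",
]


@dataclass
class ConvMixerConfig:
    """Architecture hyperparameters."""

    input_size: tuple[int, int, int] = (224, 224, 3)  # (H, W, C)
    patch_size: int = 5
    hidden_dim: int = 32
    depth: int = 7
    depthwise_kernel: int = 5  # same padding
    n_classes: int = 2
    prose_residual: bool = False  # add the residual before the activation

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.hidden_dim < 1 or self.depth < 1:
            raise ValueError("patch_size, hidden_dim and depth must be >= 1")
        if self.depthwise_kernel % 2 != 1:
            raise ValueError("depthwise_kernel must be odd (same padding)")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        h, w, c = self.input_size
        if h < self.patch_size or w < self.patch_size:
            raise ValueError("input smaller than one patch")


@dataclass
class TrainConfig:
    """SGDM training hyperparameters."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 7
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


class MixerBlock:
    """One ConvMixer block.

    Default (reference) ordering wraps the residual around
    [depthwise -> GELU -> BN]; the ``prose_residual`` variant adds the block
    input to the raw depthwise output before the activation.  Either way the
    block finishes with pointwise 1x1 convolution -> GELU -> BN, and the
    spatial size never changes.
    """

    def __init__(self, hidden: int, kernel: int, prose_residual: bool,
                 rng: np.random.Generator, dtype=np.float32):
        self.dw = nn.DepthwiseConv2d(hidden, kernel, rng, dtype)
        self.act1 = nn.GELU()
        self.bn1 = nn.BatchNorm2d(hidden, dtype=dtype)
        self.pw = nn.PointwiseConv2d(hidden, hidden, rng, dtype)
        self.act2 = nn.GELU()
        self.bn2 = nn.BatchNorm2d(hidden, dtype=dtype)
        self.prose_residual = prose_residual
        self._res = nn._Buffered()  # persistent buffers for the residual adds

    def forward_spatial(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """The residual spatial-mixing stage only."""
        if self.prose_residual:
            t = self.dw.forward(x, training)
            s = self._res._buf("sum", t.shape, t.dtype)
            np.add(t, x, out=s)
            s = self.act1.forward(s, training)
            return self.bn1.forward(s, training)
        t = self.dw.forward(x, training)
        t = self.act1.forward(t, training)
        t = self.bn1.forward(t, training)
        u = self._res._buf("sum", t.shape, t.dtype)
        np.add(x, t, out=u)
        return u

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        u = self.forward_spatial(x, training)
        v = self.pw.forward(u, training)
        v = self.act2.forward(v, training)
        return self.bn2.forward(v, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        du = self.pw.backward(self.act2.backward(self.bn2.backward(dout)))
        if self.prose_residual:
            dt = self.act1.backward(self.bn1.backward(du))
            dx = self._res._buf("dsum", dt.shape, dt.dtype)
            np.add(self.dw.backward(dt), dt, out=dx)
            return dx
        dt = self.dw.backward(self.act1.backward(self.bn1.backward(du)))
        dx = self._res._buf("dsum", dt.shape, dt.dtype)
        np.add(du, dt, out=dx)
        return dx

    def parameters(self):
        ps = []
        for layer in (self.dw, self.bn1, self.pw, self.bn2):
            ps.extend(layer.parameters())
        return ps


class ConvMixerModel:
    """The assembled network: stem -> depth x mixer block -> pool -> head."""

    def __init__(self, cfg: ConvMixerConfig, rng: np.random.Generator, dtype=np.float32):
        h_in, w_in, c_in = cfg.input_size
        self.cfg = cfg
        self.dtype = dtype
        self.stem = nn.PatchEmbed(c_in, cfg.hidden_dim, cfg.patch_size, rng, dtype)
        self.stem_act = nn.GELU()
        self.stem_bn = nn.BatchNorm2d(cfg.hidden_dim, dtype=dtype)
        self.blocks = [
            MixerBlock(cfg.hidden_dim, cfg.depthwise_kernel, cfg.prose_residual, rng, dtype)
            for _ in range(cfg.depth)
        ]
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Linear(cfg.hidden_dim, cfg.n_classes, rng, dtype)

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, C, H, W) float; returns (N, n_classes) logits."""
        z = self.stem.forward(x, training)
        z = self.stem_act.forward(z, training)
        z = self.stem_bn.forward(z, training)
        for block in self.blocks:
            z = block.forward(z, training)
        z = self.pool.forward(z, training)
        return self.head.forward(z, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        d = self.pool.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        d = self.stem_bn.backward(d)
        d = self.stem_act.backward(d)
        return self.stem.backward(d)

    def parameters(self) -> list[nn.Param]:
        ps = []
        for layer in (self.stem, self.stem_bn):
            ps.extend(layer.parameters())
        for block in self.blocks:
            ps.extend(block.parameters())
        ps.extend(self.head.parameters())
        return ps

    def bn_layers(self) -> list[nn.BatchNorm2d]:
        return [self.stem_bn] + [bn for blk in self.blocks for bn in (blk.bn1, blk.bn2)]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learned state (weights + BN running stats) for checkpointing."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i:03d}"] = p.value
        bns = [self.stem_bn] + [bn for blk in self.blocks for bn in (blk.bn1, blk.bn2)]
        for i, bn in enumerate(bns):
            out[f"bn_{i:02d}_mean"] = bn.running_mean
            out[f"bn_{i:02d}_var"] = bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = arrays[f"param_{i:03d}"]
        bns = [self.stem_bn] + [bn for blk in self.blocks for bn in (blk.bn1, blk.bn2)]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = arrays[f"bn_{i:02d}_mean"]
            bn.running_var[...] = arrays[f"bn_{i:02d}_var"]


def build_convmixer(cfg: ConvMixerConfig, seed: int = 0, dtype=np.float32) -> ConvMixerModel:
    """Construct a ConvMixer with Glorot-uniform initial weights."""
    return ConvMixerModel(cfg, np.random.default_rng(seed), dtype=dtype)


def count_parameters(model: ConvMixerModel) -> int:
    """Number of trainable scalars (weights, biases, BN gamma/beta)."""
    return int(sum(p.value.size for p in model.parameters()))


def _to_nchw(images: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(N, H, W, C) uint8 [0,255] or float [0,1] -> (N, C, H, W) float."""
    x = np.asarray(images)
    if x.ndim != 4:
        raise ValueError(f"expected a (N, H, W, C) image batch, got shape {x.shape}")
    if x.dtype == np.uint8:
        x = x.astype(dtype) / 255.0
    else:
        x = x.astype(dtype, copy=False)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def forward(
    model: ConvMixerModel,
    images: np.ndarray,
    channel_means: Optional[np.ndarray] = None,
    batch_size: int = 64,
) -> np.ndarray:
    """Class probabilities for a batch of (N, H, W, C) images in [0, 1].

    Runs in inference mode (batch norm uses running statistics), so outputs
    are deterministic and independent across batch items.
    """
    x = _to_nchw(images, model.dtype)
    if x.shape[0] < 1:
        raise ValueError("empty batch")
    h, w, c = model.cfg.input_size
    if x.shape[1:] != (c, h, w):
        raise ValueError(f"images of shape {images.shape[1:]} do not match input size {model.cfg.input_size}")
    if channel_means is not None:
        x = x - np.asarray(channel_means, dtype=model.dtype)[None, :, None, None]
    out = np.empty((x.shape[0], model.cfg.n_classes), dtype=np.float64)
    for lo in range(0, x.shape[0], batch_size):
        logits = model.forward_logits(x[lo : lo + batch_size], training=False)
        out[lo : lo + batch_size] = nn.softmax(logits.astype(np.float64))
    return out


def train(
    model: ConvMixerModel,
    images: np.ndarray,
    labels: np.ndarray,
    tc: TrainConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Train in place with SGD momentum; returns (history, channel_means).

    ``labels`` are integer class indices.  A ``validation_fraction`` of the
    data is held out for per-epoch validation accuracy; inputs are
    per-channel zero-centered using means computed on the training portion.
    History rows carry (iteration, epoch, loss, train_acc, val_acc), with
    validation accuracy filled in on the last iteration of each epoch.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if images.shape[0] != n:
        raise ValueError("images and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least two classes")
    if tc.batch_size > n:
        raise ValueError("minibatch size exceeds the number of training items")

    rng = np.random.default_rng(tc.seed)
    perm = rng.permutation(n)
    n_val = int(round(tc.validation_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[train_idx]).size < 2:
        raise ValueError("training split must contain at least two classes")

    x_all = _to_nchw(images, model.dtype)
    means = x_all[train_idx].mean(axis=(0, 2, 3))
    x_all = x_all - means[None, :, None, None]

    params = model.parameters()
    opt = nn.SGDMomentum(params, lr=tc.learning_rate, momentum=tc.momentum)
    rows = []
    iteration = 0
    for epoch in range(1, tc.epochs + 1):
        order = rng.permutation(train_idx)
        for lo in range(0, order.size, tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            xb, yb = x_all[idx], y[idx]
            logits = model.forward_logits(xb, training=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits.astype(model.dtype))
            opt.step()
            iteration += 1
            acc = float(np.mean(np.argmax(logits, axis=1) == yb))
            rows.append(
                {"iteration": iteration, "epoch": epoch, "loss": loss,
                 "train_acc": acc, "val_acc": np.nan}
            )
        if n_val > 0:
            probs = _predict_centered(model, x_all[val_idx], tc.batch_size)
            rows[-1]["val_acc"] = float(np.mean(np.argmax(probs, axis=1) == y[val_idx]))
    # Finalize batch-norm moments as population statistics over the training
    # split: with few minibatches the EMA never approaches the true moments,
    # which would corrupt every inference-mode prediction.
    for bn in model.bn_layers():
        bn.begin_collect()
    for lo in range(0, train_idx.size, tc.batch_size):
        model.forward_logits(x_all[train_idx[lo : lo + tc.batch_size]], training=True)
    for bn in model.bn_layers():
        bn.end_collect()
    return pd.DataFrame(rows), means


def _predict_centered(model: ConvMixerModel, x_centered: np.ndarray, batch_size: int) -> np.ndarray:
    out = np.empty((x_centered.shape[0], model.cfg.n_classes), dtype=np.float64)
    for lo in range(0, x_centered.shape[0], batch_size):
        logits = model.forward_logits(x_centered[lo : lo + batch_size], training=False)
        out[lo : lo + batch_size] = nn.softmax(logits.astype(np.float64))
    return out


class ConvMixerClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn style wrapper around the NumPy ConvMixer.

    Consumes image batches of shape (N, H, W, C) -- uint8 in [0, 255] or
    float in [0, 1] -- and arbitrary label values.  Deterministic for a fixed
    ``random_state`` (weight init, shuffling and the validation split all
    derive from it).

    Examples
    --------
    >>> clf = ConvMixerClassifier(hidden_dim=8, depth=2, epochs=2)
    >>> clf.fit(images, labels).predict(images[:4])  # doctest: +SKIP
    """

    def __init__(
        self,
        patch_size: int = 5,
        hidden_dim: int = 32,
        depth: int = 7,
        depthwise_kernel: int = 5,
        prose_residual: bool = False,
        learning_rate: float = 0.001,
        momentum: float = 0.9,
        batch_size: int = 64,
        epochs: int = 7,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.hidden_dim = hidden_dim
        self.depth = depth
        self.depthwise_kernel = depthwise_kernel
        self.prose_residual = prose_residual
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        if X.ndim != 4:
            raise ValueError("X must be a (N, H, W, C) image batch")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes to fit a classifier")
        h, w, c = X.shape[1], X.shape[2], X.shape[3]
        cfg = ConvMixerConfig(
            input_size=(h, w, c),
            patch_size=self.patch_size,
            hidden_dim=self.hidden_dim,
            depth=self.depth,
            depthwise_kernel=self.depthwise_kernel,
            n_classes=int(self.classes_.size),
            prose_residual=self.prose_residual,
        )
        self.model_ = build_convmixer(cfg, seed=self.random_state)
        tc = TrainConfig(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            batch_size=min(self.batch_size, X.shape[0]),
            epochs=self.epochs,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )
        self.history_, self.channel_means_ = train(self.model_, X, y_idx, tc)
        self.n_features_in_ = h * w * c
        return self

    def predict_proba(self, X):
        self._check_fitted()
        return forward(self.model_, X, self.channel_means_, batch_size=self.batch_size)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def save(self, path: str | Path) -> None:
        """Checkpoint weights, BN statistics and channel means to .npz."""
        self._check_fitted()
        arrays = self.model_.state_arrays()
        arrays["channel_means"] = self.channel_means_
        arrays["classes"] = np.asarray(self.classes_)
        np.savez(path, **arrays)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted; call fit() first")
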