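"""Pixel classification of field images with a small fully connected net.

Each pixel is represented by the 27 RGB values of its 3×3 neighborhood
and classified plant/background by a multilayer perceptron with two
hidden layers of 1,024 and 512 ReLU units, a sigmoid output unit,
dropout rates 0.45 and 0.35 on the hidden layers, binary cross-entropy
loss and the Adam optimizer (learning rate 0.001), trained for 20
epochs with batch size 1,024.  A pixel is classified as plant when its
predicted probability is strictly greater than the 0.5 cutoff.

The network is implemented directly on numpy: forward/backward passes
are a handful of matrix products, which keeps the trained model free
of any deep-learning runtime and bit-reproducible for a fixed seed on
a given BLAS.  A green-contrast thresholding baseline and optional
binary-mask postprocessing (median blur, erosion, dilation) are also
provided; postprocessing is off by default.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import as_float_image
from .training_data import FEATURE_COLUMNS, features_labels, green_contrast, neighborhood_features


@dataclass
class SegmenterConfig:
    hidden_sizes: tuple[int, int] = (1024, 512)
    dropout: tuple[float, float] = (0.45, 0.35)
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 1024
    cutoff: float = 0.5
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7

    def __post_init__(self):
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")
        if any(s <= 0 for s in self.hidden_sizes) or self.batch_size <= 0:
            raise ValueError("sizes must be positive")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class PixelSegmenter:
    """A trained 27 → 1024 → 512 → 1 pixel classifier."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: SegmenterConfig
    history: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray, chunk: int = 65536) -> np.ndarray:
        """Plant probability per feature row (dropout disabled)."""
        x = np.asarray(features, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != len(FEATURE_COLUMNS):
            raise ValueError(f"expected n×27 features, got {x.shape}")
        out = np.empty(x.shape[0], dtype=np.float32)
        for lo in range(0, x.shape[0], chunk):
            h = x[lo : lo + chunk]
            h = np.maximum(h @ self.weights[0] + self.biases[0], 0.0)
            h = np.maximum(h @ self.weights[1] + self.biases[1], 0.0)
            z = h @ self.weights[2] + self.biases[2]
            out[lo : lo + chunk] = _sigmoid(z[:, 0])
        return out.astype(np.float64)

    def save(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        np.savez(
            os.path.join(outdir, "weights.npz"),
            **{f"W{i}": w for i, w in enumerate(self.weights)},
            **{f"b{i}": b for i, b in enumerate(self.biases)},
        )
        cfg = asdict(self.config)
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump({"config": cfg, "history": self.history}, fh, indent=1)

    @classmethod
    def load(cls, outdir: str | os.PathLike) -> "PixelSegmenter":
        with np.load(os.path.join(outdir, "weights.npz")) as data:
            n_layers = sum(1 for k in data.files if k.startswith("W"))
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
        with open(os.path.join(outdir, "config.json")) as fh:
            meta = json.load(fh)
        cfg = meta["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        cfg["dropout"] = tuple(cfg["dropout"])
        return cls(weights=weights, biases=biases, config=SegmenterConfig(**cfg), history=meta["history"])


def _init_params(cfg: SegmenterConfig, rng: np.random.Generator):
    sizes = [len(FEATURE_COLUMNS), *cfg.hidden_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        # He initialization, suited to ReLU layers
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float32)
        weights.append(w)
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return weights, biases


def train_segmenter(train, val=None, config: SegmenterConfig | None = None) -> PixelSegmenter:
    """Train the pixel classifier on a labeled feature table.

    ``train``/``val`` are labeled feature tables (DataFrames with f00..f26
    and label columns) or ``(X, y)`` pairs.  Training minimizes binary
    cross-entropy with Adam; dropout is active only during training.
    The per-epoch training loss and validation accuracy are recorded in
    the returned model's history.
    """
    cfg = config or SegmenterConfig()
    x, y = train if isinstance(train, tuple) else features_labels(train)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.shape[0] == 0:
        raise ValueError("empty training table")
    if len(np.unique(y)) < 2 and cfg.epochs > 0:
        raise ValueError("training data contains a single class")
    xv = yv = None
    if val is not None:
        xv, yv = val if isinstance(val, tuple) else features_labels(val)
        xv = np.asarray(xv, dtype=np.float32)
        yv = np.asarray(yv, dtype=np.float64)

    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_params(cfg, rng)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    step = 0
    history = {"loss": [], "val_accuracy": []}
    n = x.shape[0]
    keep = [1.0 - d for d in cfg.dropout]

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            b = xb.shape[0]

            # forward with inverted dropout on hidden activations
            h1 = np.maximum(xb @ weights[0] + biases[0], 0.0)
            d1 = (rng.random(h1.shape) < keep[0]).astype(np.float32) / keep[0]
            h1d = h1 * d1
            h2 = np.maximum(h1d @ weights[1] + biases[1], 0.0)
            d2 = (rng.random(h2.shape) < keep[1]).astype(np.float32) / keep[1]
            h2d = h2 * d2
            z = (h2d @ weights[2] + biases[2])[:, 0]
            # BCE via the numerically stable softplus form
            loss = float(np.mean(np.maximum(z, 0.0) - z * yb + np.log1p(np.exp(-np.abs(z)))))
            losses.append(loss)

            dz = ((_sigmoid(z) - yb) / b).astype(np.float32)[:, None]
            g_w2 = h2d.T @ dz
            g_b2 = dz.sum(axis=0)
            dh2 = (dz @ weights[2].T) * d2 * (h2 > 0)
            g_w1 = h1d.T @ dh2
            g_b1 = dh2.sum(axis=0)
            dh1 = (dh2 @ weights[1].T) * d1 * (h1 > 0)
            g_w0 = xb.T @ dh1
            g_b0 = dh1.sum(axis=0)

            step += 1
            for params, grads, ms, vs in (
                (weights, [g_w0, g_w1, g_w2], m_w, v_w),
                (biases, [g_b0, g_b1, g_b2], m_b, v_b),
            ):
                for i, g in enumerate(grads):
                    ms[i] = cfg.adam_beta1 * ms[i] + (1 - cfg.adam_beta1) * g
                    vs[i] = cfg.adam_beta2 * vs[i] + (1 - cfg.adam_beta2) * g * g
                    m_hat = ms[i] / (1 - cfg.adam_beta1**step)
                    v_hat = vs[i] / (1 - cfg.adam_beta2**step)
                    params[i] -= (cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)).astype(
                        np.float32
                    )
        history["loss"].append(float(np.mean(losses)))
        if xv is not None and len(xv):
            model = PixelSegmenter(weights, biases, cfg, history)
            acc = float(np.mean((model.predict_proba(xv) > cfg.cutoff) == (yv > 0.5)))
            history["val_accuracy"].append(acc)

    return PixelSegmenter(weights=weights, biases=biases, config=cfg, history=history)


def predict_mask(model: PixelSegmenter, image: np.ndarray, cutoff: float | None = None) -> np.ndarray:
    """Segment an RGB image into a binary plant mask.

    Features are the same 27-value 3×3 neighborhoods used in training;
    a pixel is plant iff its probability is strictly greater than the
    cutoff (ties go to background).
    """
    arr = as_float_image(image)
    cut = model.config.cutoff if cutoff is None else cutoff
    h, w, _ = arr.shape
    feats = neighborhood_features(arr).reshape(-1, 27)
    proba = model.predict_proba(feats)
    return (proba > cut).astype(np.uint8).reshape(h, w)


def threshold_segment(image: np.ndarray, level: float = 0.04) -> np.ndarray:
    """Green-contrast thresholding baseline: mask = contrast > level."""
    if not np.isfinite(level):
        raise ValueError("threshold level must be finite")
    return (green_contrast(image) > level).astype(np.uint8)


def postprocess_mask(mask: np.ndarray, ops=()) -> np.ndarray:
    """Apply an ordered list of binary-mask cleanup operations.

    ``ops`` is a sequence of ``(name, kernel_size)`` pairs with name in
    {"median_blur", "erode", "dilate"} and odd kernel size ≥ 1.  An
    empty list is the identity.
    """
    m = (np.asarray(mask) > 0).astype(np.uint8)
    for name, k in ops:
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel size must be odd and ≥ 1, got {k}")
        if k == 1:
            continue
        if name == "median_blur":
            m = ndimage.median_filter(m, size=k)
        elif name == "erode":
            m = ndimage.binary_erosion(m, structure=np.ones((k, k), bool)).astype(np.uint8)
        elif name == "dilate":
            m = ndimage.binary_dilation(m, structure=np.ones((k, k), bool)).astype(np.uint8)
        else:
            raise ValueError(f"unknown postprocessing op {name!r}")
    return m
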