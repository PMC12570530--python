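"""Multi-path convolutional feature extractor with feature integration.

The extractor is a small directed graph rather than a sequential stack:

    input -> Conv1 -> { Pool1, Conv2 }
    Conv2 -> Pool2 -> Pool3
    Pool1 -> Conv3 -> Pool4
    { Pool2, Pool3, Pool4 } -> Feature Integrator

Three convolutional layers (512 filters 5x5, 1024 filters 7x7, 512
filters 7x7 at full scale, ReLU, same zero padding, stride 1) and four
2x2 stride-2 max-pooling layers. The Feature Integrator global-average-
pools each of the three tapped maps per channel and concatenates the
channel vectors in the fixed order (Pool2, Pool3, Pool4), giving a
2560-long feature vector at full scale. The classification head proper
is the fuzzy C-means module; this module only learns and emits features.

Because the downstream head is a clusterer, convolution weights are
learned through a *temporary* linear softmax head on the integrated
feature vector (cross-entropy, plain SGD); the head is discarded after
training. A ``scale`` factor in (0, 1] multiplies all filter counts
(ceiling-rounded) for desk-scale runs.

Everything is NumPy: convolution is im2col + matmul and the backward
pass is written out layer by layer, so a fixed seed gives bitwise
reproducible training on a single thread.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imgio import GrayImage

__all__ = [
    "RECNNConfig",
    "TrainedExtractor",
    "build_recnn",
    "forward_features",
    "forward_features_batch",
    "train_extractor",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class RECNNConfig:
    conv1_filters: int = 512
    conv1_kernel: int = 5
    conv2_filters: int = 1024
    conv2_kernel: int = 7
    conv3_filters: int = 512
    conv3_kernel: int = 7
    pool_kernel: int = 2
    scale: float = 1.0
    input_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.scale <= 1.0):
            raise ValueError("scale must be in (0, 1]")
        if self.input_size % 4 != 0:
            raise ValueError(
                "input_size must be divisible by 4 (two 2x2 pooling "
                "stages on each path)"
            )
        if self.input_size < 8:
            raise ValueError("input_size too small")
        if self.pool_kernel != 2:
            raise ValueError("only 2x2 pooling is supported")

    def scaled(self, n_filters: int) -> int:
        return max(1, math.ceil(n_filters * self.scale))

    @property
    def c1(self) -> int:
        return self.scaled(self.conv1_filters)

    @property
    def c2(self) -> int:
        return self.scaled(self.conv2_filters)

    @property
    def c3(self) -> int:
        return self.scaled(self.conv3_filters)

    @property
    def feature_length(self) -> int:
        """Integrated vector length: Pool2 + Pool3 (c2 each) + Pool4 (c3)."""
        return 2 * self.c2 + self.c3

    @property
    def n_conv_layers(self) -> int:
        return 3

    @property
    def n_pool_layers(self) -> int:
        return 4


@dataclass
class TrainedExtractor:
    """Layer weights plus training metadata; forward is deterministic."""

    cfg: RECNNConfig
    weights: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def conv_layer_shapes(self) -> list[tuple[int, int]]:
        """(filter count, kernel size) per convolutional layer."""
        return [
            (self.weights["W1"].shape[0], self.weights["W1"].shape[2]),
            (self.weights["W2"].shape[0], self.weights["W2"].shape[2]),
            (self.weights["W3"].shape[0], self.weights["W3"].shape[2]),
        ]


# ---------------------------------------------------------------- layers


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded stride-1 convolution. x: (N,C,H,W), W: (F,C,k,k)."""
    n, c, h, w = x.shape
    f, _, k, _ = W.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    out = cols @ W.reshape(f, -1).T + b  # (N, H*W, F)
    out = out.transpose(0, 2, 1).reshape(n, f, h, w)
    return out, (cols, x.shape, W.shape)


def _relu(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, out > 0


def _pool2(x: np.ndarray):
    """2x2 stride-2 max pool; first maximum wins on ties."""
    n, f, h, w = x.shape
    xr = (
        x.reshape(n, f, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, f, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool2_backward(dout: np.ndarray, cache):
    idx, xshape = cache
    n, f, h, w = xshape
    dxr = np.zeros((n, f, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = (
        dxr.reshape(n, f, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, f, h, w)
    )
    return dx


def _gap(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=(2, 3))


def _gap_backward(dout: np.ndarray, shape) -> np.ndarray:
    n, f, h, w = shape
    return np.broadcast_to(dout[:, :, None, None], shape) / (h * w)


# --------------------------------------------------------------- graph


def build_recnn(cfg: RECNNConfig) -> TrainedExtractor:
    """Seeded He-style initialization of the three conv layers."""
    rng = np.random.default_rng(cfg.seed)

    def he(f, c, k):
        std = math.sqrt(2.0 / (c * k * k))
        return rng.normal(0.0, std, size=(f, c, k, k))

    weights = {
        "W1": he(cfg.c1, 1, cfg.conv1_kernel),
        "b1": np.zeros(cfg.c1),
        "W2": he(cfg.c2, cfg.c1, cfg.conv2_kernel),
        "b2": np.zeros(cfg.c2),
        "W3": he(cfg.c3, cfg.c1, cfg.conv3_kernel),
        "b3": np.zeros(cfg.c3),
    }
    return TrainedExtractor(cfg=cfg, weights=weights,
                            meta={"epochs": 0, "loss_curve": [], "seed": cfg.seed})


def _forward_graph(model: TrainedExtractor, x: np.ndarray, need_cache: bool):
    """Run the multi-path graph on a batch x of shape (N, 1, H, W)."""
    W = model.weights
    z1, cc1 = _conv_forward(x, W["W1"], W["b1"])
    a1, m1 = _relu(z1)
    p1, cp1 = _pool2(a1)
    z2, cc2 = _conv_forward(a1, W["W2"], W["b2"])
    a2, m2 = _relu(z2)
    p2, cp2 = _pool2(a2)
    p3, cp3 = _pool2(p2)
    z3, cc3 = _conv_forward(p1, W["W3"], W["b3"])
    a3, m3 = _relu(z3)
    p4, cp4 = _pool2(a3)
    feat = np.concatenate([_gap(p2), _gap(p3), _gap(p4)], axis=1)
    if not need_cache:
        return feat, None
    cache = dict(cc1=cc1, m1=m1, cp1=cp1, cc2=cc2, m2=m2, cp2=cp2,
                 cp3=cp3, cc3=cc3, m3=m3, cp4=cp4,
                 shapes=dict(p2=p2.shape, p3=p3.shape, p4=p4.shape))
    return feat, cache


def _conv_grads(dout: np.ndarray, cache, W: np.ndarray):
    """Weight/bias/input gradients of the same-padded convolution."""
    cols, xshape, wshape = cache
    n, c, h, w = xshape
    f, _, k, _ = wshape
    p = k // 2
    dmat = dout.reshape(n, f, h * w).transpose(0, 2, 1)
    dW = np.einsum("nif,nij->fj", dmat, cols).reshape(wshape)
    db = dmat.sum(axis=(0, 1))
    dcols = dmat @ W.reshape(f, -1)
    # dcols: (N, H*W, C*k*k) -> scatter-add back into padded input
    dcols = dcols.reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    dx = dxp[:, :, p : p + h, p : p + w]
    return dW, db, dx


def _backward_graph(model: TrainedExtractor, dfeat: np.ndarray, cache):
    cfg = model.cfg
    c2, c3 = cfg.c2, cfg.c3
    dg2 = dfeat[:, :c2]
    dg3 = dfeat[:, c2 : 2 * c2]
    dg4 = dfeat[:, 2 * c2 :]
    sh = cache["shapes"]

    W = model.weights
    dp4 = _gap_backward(dg4, sh["p4"])
    da3 = _pool2_backward(dp4, cache["cp4"]) * cache["m3"]
    dW3, db3, dp1 = _conv_grads(da3, cache["cc3"], W["W3"])

    dp3 = _gap_backward(dg3, sh["p3"])
    dp2 = _gap_backward(dg2, sh["p2"]) + _pool2_backward(dp3, cache["cp3"])
    da2 = _pool2_backward(dp2, cache["cp2"]) * cache["m2"]
    dW2, db2, da1_from2 = _conv_grads(da2, cache["cc2"], W["W2"])

    da1 = da1_from2 + _pool2_backward(dp1, cache["cp1"])
    da1 *= cache["m1"]
    dW1, db1, _ = _conv_grads(da1, cache["cc1"], W["W1"])
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2, "W3": dW3, "b3": db3}


def _as_batch(imgs, input_size: int) -> np.ndarray:
    arrs = []
    for im in imgs:
        px = im.pixels if isinstance(im, GrayImage) else np.asarray(im, dtype=np.float64)
        if px.shape != (input_size, input_size):
            raise ValueError(
                f"image shape {px.shape} does not match input_size {input_size}"
            )
        arrs.append(px)
    return np.stack(arrs)[:, None, :, :]


def forward_features_batch(model: TrainedExtractor, imgs) -> np.ndarray:
    """Integrated feature vectors for a batch; shape (N, feature_length)."""
    x = _as_batch(imgs, model.cfg.input_size)
    feat, _ = _forward_graph(model, x, need_cache=False)
    return feat


def forward_features(model: TrainedExtractor, img: GrayImage) -> np.ndarray:
    """Integrated feature vector of one image (length cfg.feature_length)."""
    return forward_features_batch(model, [img])[0]


# ------------------------------------------------------------- training


def _softmax_ce(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def train_extractor(
    model: TrainedExtractor,
    imgs,
    labels,
    epochs: int = 5,
    lr: float = 3e-3,
    seed: int = 0,
    batch_size: int = 16,
    betas: tuple[float, float] = (0.9, 0.999),
    eps: float = 1e-8,
) -> TrainedExtractor:
    """Learn conv weights through a temporary linear softmax head.

    The head maps the integrated feature vector to class logits, the
    cross-entropy gradient is backpropagated through the whole graph
    with Adam, and the head is discarded afterwards. Head inputs pass
    through per-batch channel standardization (batch normalization
    without a learned affine), which equalizes gradient scales across
    channels — raw global-average-pooled responses span orders of
    magnitude — and keeps logits bounded as the features evolve.
    ``epochs=0`` returns a copy with unchanged weights. Raises on
    single-class input or a non-finite loss.
    """
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    cfg = model.cfg
    W = {k: v.copy() for k, v in model.weights.items()}
    out = TrainedExtractor(cfg=cfg, weights=W, meta=dict(model.meta))
    out.meta.update({"epochs": epochs, "seed": seed, "loss_curve": []})
    if epochs == 0:
        return out

    rng = np.random.default_rng(seed)
    nfeat, ncls = cfg.feature_length, len(classes)
    Wh = rng.normal(0.0, math.sqrt(2.0 / nfeat), size=(nfeat, ncls))
    bh = np.zeros(ncls)
    x_all = _as_batch(imgs, cfg.input_size)
    n = x_all.shape[0]

    params = dict(out.weights)
    params["Wh"], params["bh"] = Wh, bh
    m1 = {k: np.zeros_like(v) for k, v in params.items()}
    m2 = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2 = betas
    step = 0

    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            xb, yb = x_all[sel], y[sel]
            feat, cache = _forward_graph(out, xb, need_cache=True)
            # batch-standardize head inputs (no learned affine)
            mu_b = feat.mean(axis=0)
            sd_b = np.sqrt(feat.var(axis=0) + 1e-5)
            feat_n = (feat - mu_b) / sd_b
            logits = feat_n @ params["Wh"] + params["bh"]
            loss, dlogits = _softmax_ce(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; reduce lr")
            epoch_loss += loss * len(sel)
            dfn = dlogits @ params["Wh"].T
            dfeat = (
                dfn - dfn.mean(axis=0) - feat_n * (dfn * feat_n).mean(axis=0)
            ) / sd_b
            grads = _backward_graph(out, dfeat, cache)
            grads["Wh"] = feat_n.T @ dlogits
            grads["bh"] = dlogits.sum(axis=0)
            step += 1
            for k, g in grads.items():
                m1[k] = b1 * m1[k] + (1 - b1) * g
                m2[k] = b2 * m2[k] + (1 - b2) * g * g
                mhat = m1[k] / (1 - b1**step)
                vhat = m2[k] / (1 - b2**step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        out.meta["loss_curve"].append(epoch_loss / n)
    return out


# ---------------------------------------------------------- persistence


def save_checkpoint(model: TrainedExtractor, path: str | Path) -> None:
    """Single-file .npz checkpoint with the config embedded as JSON."""
    cfg_json = json.dumps(vars(model.cfg) | {}, default=float)
    meta_json = json.dumps(model.meta, default=float)
    np.savez(path, __config__=np.array(cfg_json), __meta__=np.array(meta_json),
             **model.weights)


def load_checkpoint(path: str | Path) -> TrainedExtractor:
    with np.load(path, allow_pickle=False) as data:
        cfg_d = json.loads(str(data["__config__"]))
        for key in ("conv1_filters", "conv1_kernel", "conv2_filters",
                    "conv2_kernel", "conv3_filters", "conv3_kernel",
                    "pool_kernel", "input_size", "seed"):
            cfg_d[key] = int(cfg_d[key])
        meta = json.loads(str(data["__meta__"]))
        weights = {k: data[k] for k in data.files if not k.startswith("__")}
    return TrainedExtractor(cfg=RECNNConfig(**cfg_d), weights=weights, meta=meta)
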