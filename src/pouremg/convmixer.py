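"""ConvMixer classifier for sEMG windows, with handcrafted-feature fusion.

The network treats a 4-channel, N-sample window as a single-plane image
of height 4 and width N:

1. **Patch embedding** — a 2-D convolution whose kernel spans all 4
   electrode rows and ``p`` time samples, applied with stride ``p``:
   the window collapses into floor(N/p) non-overlapping patches, each
   linearly embedded into ``h`` dimensions, followed by GELU and batch
   normalization.  (At N = 481 and p = 13 this yields 37 patches.)
2. **Mixer blocks** (depth ``d``) — a depthwise convolution (groups =
   channel count, same padding, large kernel) mixes information along
   the time axis independently per embedding channel, wrapped in a
   residual connection; a pointwise (1x1) convolution then mixes across
   channels.  Every convolution is followed by GELU activation and
   batch normalization ``y = (x - mu)/sqrt(var + eps) * gamma + beta``.
3. **Head** — global average pooling over patch positions; optionally
   the pooled ``h``-vector is concatenated with the standardized
   16-dimensional handcrafted feature vector (late fusion) before the
   linear classifier.

Everything — forward pass, backpropagation, batch-norm statistics and
the Adam optimizer — is implemented directly on numpy arrays, so
training is exactly reproducible from a seed on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import erf

from .features import FeatureScaler, fit_scaler
from .signal_io import SignalWindow

__all__ = [
    "ModelConfig",
    "BatchNormParams",
    "TrainReport",
    "ConvMixerNet",
    "FeatureDenseNet",
    "batch_normalize",
    "gelu",
    "train_model",
    "predict",
    "save_model",
    "load_model",
    "softmax",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow common ConvMixer practice scaled to 4 x 481 windows;
    all are configuration-exposed because no canonical values exist for
    this task.
    """

    n_classes: int
    hidden_dim: int = 64
    depth: int = 4
    kernel_size: int = 9
    patch_size: int = 13
    fusion_mode: str = "late_concat"  # or "none"
    bn_epsilon: float = 1e-5
    residual: bool = True
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    n_feature_dims: int = 16
    n_input_channels: int = 4

    def __post_init__(self) -> None:
        if min(self.n_classes, self.hidden_dim, self.depth, self.patch_size) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.fusion_mode not in ("none", "late_concat"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.bn_epsilon <= 0:
            raise ValueError("bn_epsilon must be > 0")

    def validate_input_length(self, n: int) -> None:
        if self.patch_size > n:
            raise ValueError(f"patch_size {self.patch_size} > window length {n}")
        if n // self.patch_size < 4:
            raise ValueError(
                f"patch_size {self.patch_size} leaves fewer than 4 patches of {n} samples"
            )


@dataclass
class BatchNormParams:
    """Per-channel normalization constants (running mean/variance plus the
    learned affine scale and shift)."""

    mu: np.ndarray
    var: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu", "var", "gamma", "beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.var < 0):
            raise ValueError("variance must be >= 0")
        if not (np.all(np.isfinite(self.gamma)) and np.all(np.isfinite(self.beta))):
            raise ValueError("gamma/beta must be finite")


def batch_normalize(x: np.ndarray, params: BatchNormParams, eps: float = 1e-5) -> np.ndarray:
    """Elementwise ``(x - mu)/sqrt(var + eps) * gamma + beta`` with the
    channel axis second (shape (B, C) or (B, C, T))."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    x = np.asarray(x, dtype=float)
    shape = (1, -1) + (1,) * (x.ndim - 2)
    mu = params.mu.reshape(shape)
    var = params.var.reshape(shape)
    gamma = params.gamma.reshape(shape)
    beta = params.beta.reshape(shape)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


# ---------------------------------------------------------------------------
# Layers: each holds params/grads dicts; forward caches what backward needs.


class _Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


class _PatchEmbed(_Layer):
    """Strided 2-D convolution collapsing the electrode axis: kernel and
    stride both (n_channels, p)."""

    def __init__(self, n_ch: int, p: int, h: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_ch, self.p, self.h = n_ch, p, h
        fan_in = n_ch * p
        self.params["W"] = rng.standard_normal((fan_in, h)) * np.sqrt(2.0 / fan_in)
        self.params["b"] = np.zeros(h)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, n = x.shape
        n_patches = n // self.p
        xp = (
            x[:, :, : n_patches * self.p]
            .reshape(b, c, n_patches, self.p)
            .transpose(0, 2, 1, 3)
            .reshape(b, n_patches, c * self.p)
        )
        self._cache = (xp, x.shape)
        y = xp @ self.params["W"] + self.params["b"]
        return y.transpose(0, 2, 1)  # (B, h, P)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        gt = g.transpose(0, 2, 1)  # (B, P, h)
        self.grads["W"] = np.einsum("bpi,bph->ih", xp, gt)
        self.grads["b"] = gt.sum(axis=(0, 1))
        dxp = gt @ self.params["W"].T  # (B, P, c*p)
        b, c, n = x_shape
        n_patches = dxp.shape[1]
        dx = np.zeros(x_shape)
        dx[:, :, : n_patches * self.p] = (
            dxp.reshape(b, n_patches, c, self.p).transpose(0, 2, 1, 3).reshape(b, c, -1)
        )
        return dx


class _Gelu(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._cache = x
        return gelu(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * _gelu_grad(self._cache)


class _BatchNorm(_Layer):
    """Batch normalization over all axes but the channel axis (axis 1).

    Training uses batch statistics and maintains running estimates
    (momentum 0.1, biased variance); inference uses the running values.
    """

    def __init__(self, c: int, eps: float) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = 0.1
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mu = np.zeros(c)
        self.running_var = np.ones(c)

    def _bshape(self, ndim: int):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mu = (1 - self.momentum) * self.running_mu + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mu, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mu.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (x_hat, inv_std, axes, shape, training)
        return self.params["gamma"].reshape(shape) * x_hat + self.params["beta"].reshape(shape)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x_hat, inv_std, axes, shape, training = self._cache
        self.grads["gamma"] = (g * x_hat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gamma = self.params["gamma"].reshape(shape)
        if not training:
            return g * gamma * inv_std.reshape(shape)
        m = g.size // g.shape[1]
        gxh = g * gamma
        return inv_std.reshape(shape) * (
            gxh
            - gxh.mean(axis=axes, keepdims=True)
            - x_hat * (gxh * x_hat).mean(axis=axes, keepdims=True)
        )


class _DepthwiseConv1d(_Layer):
    """Per-channel (groups = C) 1-D convolution with same padding: channel c
    of the output depends on channel c of the input only."""

    def __init__(self, c: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = k
        self.pad = (k - 1) // 2
        self.params["W"] = rng.standard_normal((c, k)) * np.sqrt(2.0 / k)
        self.params["b"] = np.zeros(c)

    def _windows(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        return np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.size == 0:
            raise ValueError("empty input")
        win = self._windows(x)
        self._cache = win
        return np.einsum("bctk,ck->bct", win, self.params["W"]) + self.params["b"][None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        win = self._cache
        self.grads["W"] = np.einsum("bct,bctk->ck", g, win)
        self.grads["b"] = g.sum(axis=(0, 2))
        gwin = self._windows(g)  # same symmetric padding (k odd)
        return np.einsum("bctk,ck->bct", gwin, self.params["W"][:, ::-1])


class _PointwiseConv(_Layer):
    """1x1 convolution = per-position linear map across channels."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.standard_normal((c_out, c_in)) * np.sqrt(2.0 / c_in)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._cache = x
        return np.einsum("oc,bct->bot", self.params["W"], x) + self.params["b"][None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] = np.einsum("bot,bct->oc", g, x)
        self.grads["b"] = g.sum(axis=(0, 2))
        return np.einsum("oc,bot->bct", self.params["W"], g)


class _Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.params["b"] = np.zeros(d_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] = x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class _MixerBlock:
    """x <- x + BN(GELU(DWConv(x))); x <- BN(GELU(PWConv(x)))."""

    def __init__(self, h: int, k: int, eps: float, residual: bool, rng) -> None:
        self.residual = residual
        self.dw = _DepthwiseConv1d(h, k, rng)
        self.dw_act = _Gelu()
        self.dw_bn = _BatchNorm(h, eps)
        self.pw = _PointwiseConv(h, h, rng)
        self.pw_act = _Gelu()
        self.pw_bn = _BatchNorm(h, eps)

    @property
    def layers(self):
        return [self.dw, self.dw_act, self.dw_bn, self.pw, self.pw_act, self.pw_bn]

    def depthwise_stage(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        t = self.dw_bn.forward(self.dw_act.forward(self.dw.forward(x, training), training), training)
        return x + t if self.residual else t

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        t = self.depthwise_stage(x, training)
        return self.pw_bn.forward(self.pw_act.forward(self.pw.forward(t, training), training), training)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.pw.backward(self.pw_act.backward(self.pw_bn.backward(g)))
        gd = self.dw.backward(self.dw_act.backward(self.dw_bn.backward(g)))
        return g + gd if self.residual else gd


class ConvMixerNet:
    """The full classifier.  ``forward`` maps a batch of raw windows (and
    optionally standardized feature vectors) to K logits per window."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.embed = _PatchEmbed(c.n_input_channels, c.patch_size, c.hidden_dim, rng)
        self.embed_act = _Gelu()
        self.embed_bn = _BatchNorm(c.hidden_dim, c.bn_epsilon)
        self.blocks = [
            _MixerBlock(c.hidden_dim, c.kernel_size, c.bn_epsilon, c.residual, rng)
            for _ in range(c.depth)
        ]
        head_in = c.hidden_dim + (c.n_feature_dims if c.fusion_mode == "late_concat" else 0)
        self.classifier = _Dense(head_in, c.n_classes, rng)
        self.scaler: FeatureScaler | None = None

    # -- parameter plumbing ------------------------------------------------
    @property
    def layers(self) -> list[_Layer]:
        out = [self.embed, self.embed_act, self.embed_bn]
        for blk in self.blocks:
            out.extend(blk.layers)
        out.append(self.classifier)
        return out

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"{i}.{name}", layer, name

    # -- forward / backward ------------------------------------------------
    def forward(
        self, x: np.ndarray, features: np.ndarray | None = None, training: bool = False
    ) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        self.config.validate_input_length(x.shape[2])
        e = self.embed_bn.forward(
            self.embed_act.forward(self.embed.forward(x, training), training), training
        )
        for blk in self.blocks:
            e = blk.forward(e, training)
        pooled = e.mean(axis=2)
        self._pool_t = e.shape[2]
        if self.config.fusion_mode == "late_concat":
            if features is None:
                raise ValueError("fusion_mode='late_concat' requires feature vectors")
            features = np.atleast_2d(np.asarray(features, dtype=float))
            if features.shape != (x.shape[0], self.config.n_feature_dims):
                raise ValueError(
                    f"feature shape {features.shape} != "
                    f"({x.shape[0]}, {self.config.n_feature_dims})"
                )
            if self.scaler is not None:
                features = self.scaler.transform(features)
            z = np.concatenate([pooled, features], axis=1)
        else:
            z = pooled
        return self.classifier.forward(z, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.classifier.backward(dlogits)
        dpooled = dz[:, : self.config.hidden_dim]
        g = np.repeat(dpooled[:, :, None], self._pool_t, axis=2) / self._pool_t
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        self.embed.backward(self.embed_act.backward(self.embed_bn.backward(g)))

    def predict_proba(self, x: np.ndarray, features: np.ndarray | None = None) -> np.ndarray:
        return softmax(self.forward(x, features, training=False))


class FeatureDenseNet:
    """Small dense head over the 16 handcrafted features alone — the
    features-only counterpart of the fused model (no raw windows)."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.fc1 = _Dense(config.n_feature_dims, h, rng)
        self.act = _Gelu()
        self.fc2 = _Dense(h, config.n_classes, rng)
        self.scaler: FeatureScaler | None = None

    @property
    def layers(self):
        return [self.fc1, self.act, self.fc2]

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{i}.{name}", layer, name

    def forward(self, x, features=None, training: bool = False) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features if features is not None else x, dtype=float))
        if self.scaler is not None:
            f = self.scaler.transform(f)
        return self.fc2.forward(self.act.forward(self.fc1.forward(f, training), training), training)

    def backward(self, dlogits: np.ndarray) -> None:
        self.fc1.backward(self.act.backward(self.fc2.backward(dlogits)))

    def predict_proba(self, x, features=None) -> np.ndarray:
        return softmax(self.forward(x, features, training=False))


# ---------------------------------------------------------------------------
# Training


class _Adam:
    def __init__(self, net, lr: float) -> None:
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[name]) for key, layer, name in net.parameters()}
        self.v = {key: np.zeros_like(layer.params[name]) for key, layer, name in net.parameters()}

    def step(self) -> None:
        self.t += 1
        for key, layer, name in self.net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            m_hat = self.m[key] / (1 - self.beta1**self.t)
            v_hat = self.v[key] / (1 - self.beta2**self.t)
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = softmax(logits)
    b = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(b), y] + 1e-12)))
    d = p.copy()
    d[np.arange(b), y] -= 1.0
    return loss, d / b


@dataclass
class TrainReport:
    """Per-epoch training record plus the trained network."""

    epoch_loss: list[float]
    val_accuracy: list[float]
    config: ModelConfig
    seed: int
    model: object = field(repr=False, default=None)

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[-1] if self.val_accuracy else float("nan")


def _as_window_array(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        return windows.astype(float)
    return np.stack([w.samples if isinstance(w, SignalWindow) else np.asarray(w) for w in windows])


def train_model(
    windows,
    labels,
    config: ModelConfig,
    features: np.ndarray | None = None,
    val_windows=None,
    val_labels=None,
    val_features: np.ndarray | None = None,
    model_class=ConvMixerNet,
    log_path=None,
) -> TrainReport:
    """Train by mini-batch Adam on softmax cross-entropy.

    Weight initialisation, the feature scaler and the epoch shuffles are
    all derived from ``config.seed``, so a run is fully reproducible.
    The feature scaler is fitted on the training features only.
    """
    x = _as_window_array(windows) if model_class is ConvMixerNet else None
    y = np.asarray(labels, dtype=int)
    n = len(y)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("need at least 2 classes in the training set")
    if y.max() >= config.n_classes or y.min() < 0:
        raise ValueError("labels out of range for config.n_classes")
    missing = set(range(config.n_classes)) - set(present.tolist())
    if missing:
        raise ValueError(f"classes absent from training set: {sorted(missing)}")

    needs_features = model_class is FeatureDenseNet or config.fusion_mode == "late_concat"
    if needs_features and features is None:
        raise ValueError("this configuration requires handcrafted feature vectors")

    net = model_class(config)
    if needs_features:
        net.scaler = fit_scaler(np.asarray(features, dtype=float))
    optimizer = _Adam(net, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    log_lines = []
    epoch_loss: list[float] = []
    val_acc: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            xb = x[idx] if x is not None else None
            fb = np.asarray(features)[idx] if features is not None else None
            logits = net.forward(xb if xb is not None else fb, fb, training=True)
            loss, dlogits = _softmax_ce(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            net.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        epoch_loss.append(float(np.mean(losses)))
        if val_labels is not None:
            pred, _ = predict(net, val_windows, val_features)
            val_acc.append(float(np.mean(pred == np.asarray(val_labels))))
        line = f"epoch={epoch} loss={epoch_loss[-1]:.6f}" + (
            f" val_acc={val_acc[-1]:.4f}" if val_acc else ""
        )
        log_lines.append(line)
    if log_path is not None:
        Path(log_path).write_text("\n".join(log_lines) + "\n")
    return TrainReport(epoch_loss, val_acc, config, config.seed, model=net)


def predict(model, windows, features: np.ndarray | None = None, batch_size: int = 256):
    """Class indices and per-class probability rows for a set of windows."""
    if isinstance(model, FeatureDenseNet):
        probs = model.predict_proba(None, np.asarray(features, dtype=float))
    else:
        x = _as_window_array(windows)
        if features is not None:
            features = np.asarray(features, dtype=float)
            if features.shape[0] != x.shape[0]:
                raise ValueError("feature/window count mismatch")
        chunks = []
        for s in range(0, x.shape[0], batch_size):
            fb = features[s : s + batch_size] if features is not None else None
            chunks.append(model.predict_proba(x[s : s + batch_size], fb))
        probs = np.concatenate(chunks, axis=0)
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# Checkpointing


def save_model(model, path) -> None:
    """Single-file .npz checkpoint: weights, running BN stats, scaler and a
    JSON echo of the configuration."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for key, layer, name in model.parameters():
        arrays[f"param/{key}"] = layer.params[name]
    for i, layer in enumerate(model.layers):
        if isinstance(layer, _BatchNorm):
            arrays[f"bn/{i}/mu"] = layer.running_mu
            arrays[f"bn/{i}/var"] = layer.running_var
    if model.scaler is not None:
        arrays["scaler/location"] = model.scaler.location
        arrays["scaler/scale"] = model.scaler.scale
    meta = {"config": asdict(model.config), "class": type(model).__name__}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path):
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = ModelConfig(**meta["config"])
        cls = {"ConvMixerNet": ConvMixerNet, "FeatureDenseNet": FeatureDenseNet}[meta["class"]]
        model = cls(config)
        for key, layer, name in model.parameters():
            layer.params[name] = data[f"param/{key}"]
        for i, layer in enumerate(model.layers):
            if isinstance(layer, _BatchNorm):
                layer.running_mu = data[f"bn/{i}/mu"]
                layer.running_var = data[f"bn/{i}/var"]
        if "scaler/location" in data:
            model.scaler = FeatureScaler(data["scaler/location"], data["scaler/scale"])
    return model
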