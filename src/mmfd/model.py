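"""Two-branch 1D-CNN fusion classifier, implemented in NumPy.

Architecture: two parallel branches (time branch over sub-frame statistics,
frequency branch over binned spectra), each a stack of
``Conv1D -> BatchNorm -> ReLU -> MaxPool -> Dropout`` blocks ending in global
average pooling; the pooled vectors ``z_t`` and ``z_f`` are concatenated and
classified by ``FC(m) -> ReLU -> Dropout -> FC(n) -> ReLU -> FC(K) ->
softmax``.  Ablation variants drop one branch: ``no_freq`` uses ``z = z_t``,
``no_time`` uses ``z = z_f``.

Training minimizes cross-entropy plus an L2 penalty on weight matrices
(biases and batch-norm parameters excluded) with Adam, mini-batch shuffling
per epoch, and early stopping on validation loss with best-weight restore.
Everything is seeded, so training is reproducible bit-for-bit on one device.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from mmfd.features import FeatureDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "FusionModel",
    "build_model",
    "forward",
    "train",
    "predict",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("full", "no_freq", "no_time")


@dataclass(frozen=True)
class ModelConfig:
    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    pool_size: int = 2
    dropout: float = 0.3
    fusion_hidden: tuple[int, int] = (128, 64)  # (m, n)
    n_classes: int = 3
    t_features: int = 24  # F_t: channels * stats
    f_features: int = 6  # F_f: channels

    def __post_init__(self) -> None:
        if len(self.conv_filters) < 1:
            raise ValueError("need at least one conv block")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    l2: float = 1e-4
    epochs: int = 50
    batch_size: int = 64
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Layer:
    """Minimal layer protocol: forward caches what backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    decayable: list[bool]  # True where L2 applies (weight matrices only)

    def __init__(self) -> None:
        self.params, self.grads, self.decayable = [], [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(_Layer):
    """Same-padded 1-D convolution over (B, T, C_in) -> (B, T, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * c_in))  # He init
        self.W = rng.normal(0.0, scale, size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decayable = [True, False]

    def forward(self, x, train, rng):
        B, T, C = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p - (1 - k % 2)), (0, 0)))
        cols = np.stack([xp[:, i : i + T, :] for i in range(k)], axis=2)  # (B,T,k,C)
        self._cols = cols.reshape(B, T, k * C)
        self._in_shape = x.shape
        Wr = self.W.reshape(k * C, -1)
        return self._cols @ Wr + self.b

    def backward(self, grad):
        B, T, C = self._in_shape
        k = self.kernel
        p = k // 2
        Wr = self.W.reshape(k * C, -1)
        self.grads[0][...] = (
            self._cols.reshape(-1, k * C).T @ grad.reshape(-1, grad.shape[-1])
        ).reshape(self.W.shape)
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dcols = (grad @ Wr.T).reshape(B, T, k, C)
        dxp = np.zeros((B, T + 2 * p - (1 - k % 2), C))
        for i in range(k):
            dxp[:, i : i + T, :] += dcols[:, :, i, :]
        return dxp[:, p : p + T, :]


class BatchNorm(_Layer):
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.decayable = [False, False]

    def forward(self, x, train, rng):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_sd
        self._m = x.shape[0] * x.shape[1]
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.grads[0][...] = (grad * self._xhat).sum(axis=(0, 1))
        self.grads[1][...] = grad.sum(axis=(0, 1))
        m = self._m
        dxhat = grad * self.gamma
        return (
            self._inv_sd
            / m
            * (m * dxhat - dxhat.sum(axis=(0, 1)) - self._xhat * (dxhat * self._xhat).sum(axis=(0, 1)))
        )


class ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool(_Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train, rng):
        B, T, C = x.shape
        n = T // self.size
        if n < 1:
            raise ValueError("input shorter than the pooling receptive field")
        xr = x[:, : n * self.size, :].reshape(B, n, self.size, C)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        B, T, C = self._in_shape
        n = grad.shape[1]
        dxr = np.zeros((B, n, self.size, C))
        bi, ni, ci = np.meshgrid(np.arange(B), np.arange(n), np.arange(C), indexing="ij")
        dxr[bi, ni, self._arg, ci] = grad
        dx = np.zeros((B, T, C))
        dx[:, : n * self.size, :] = dxr.reshape(B, n * self.size, C)
        return dx


class Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GlobalAvgPool(_Layer):
    """(B, T, C) -> (B, C); makes branch output independent of T."""

    def forward(self, x, train, rng):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._T, axis=1) / self._T


class CoordChannel(_Layer):
    """Append fixed positional-encoding channels along the axis.

    Global average pooling makes a conv branch (nearly) translation-invariant,
    which would erase purely positional structure such as the location of a
    spectral peak; value-encoded coordinates (one linear ramp plus sin/cos
    pairs at ``n_waves`` dyadic frequencies) let filters express position
    while keeping the pooled output length-independent.
    """

    N_WAVES = 3

    @classmethod
    def n_extra(cls) -> int:
        return 1 + 2 * cls.N_WAVES

    def forward(self, x, train, rng):
        B, T, _ = x.shape
        c = np.linspace(0.0, 1.0, T)
        enc = [c]
        for j in range(self.N_WAVES):
            enc.append(np.sin(2 * np.pi * (2**j) * c))
            enc.append(np.cos(2 * np.pi * (2**j) * c))
        coords = np.broadcast_to(np.stack(enc, axis=1)[None, :, :], (B, T, len(enc)))
        self._n = len(enc)
        return np.concatenate([x, coords], axis=2)

    def backward(self, grad):
        return grad[:, :, : -self._n]


class Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decayable = [True, False]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _make_branch(c_in: int, config: ModelConfig, rng: np.random.Generator) -> list[_Layer]:
    layers: list[_Layer] = [CoordChannel()]
    c_in = c_in + CoordChannel.n_extra()
    for c_out in config.conv_filters:
        layers += [
            Conv1D(c_in, c_out, config.kernel_size, rng),
            BatchNorm(c_out),
            ReLU(),
            MaxPool(config.pool_size),
            Dropout(config.dropout),
        ]
        c_in = c_out
    layers.append(GlobalAvgPool())
    return layers


class FusionModel:
    """Untrained/trained network container; see module docstring."""

    def __init__(self, config: ModelConfig, variant: str = "full", seed: int = 0) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.config = config
        self.variant = variant
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, VARIANTS.index(variant)]))
        d_branch = config.conv_filters[-1]
        self.time_branch = _make_branch(config.t_features, config, rng) if variant != "no_time" else []
        self.freq_branch = _make_branch(config.f_features, config, rng) if variant != "no_freq" else []
        d_fused = d_branch * ((variant == "full") + 1) if variant == "full" else d_branch
        m, n = config.fusion_hidden
        self.head: list[_Layer] = [
            Dense(d_fused, m, rng),
            ReLU(),
            Dropout(config.dropout),
            Dense(m, n, rng),
            ReLU(),
            Dense(n, config.n_classes, rng),
        ]

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list[_Layer]:
        return self.time_branch + self.freq_branch + self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def decay_mask(self) -> list[bool]:
        return [d for layer in self.layers for d in layer.decayable]

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        extra = iter(state[len(params) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(extra).copy()
                layer.running_var = next(extra).copy()

    # -- computation -------------------------------------------------------
    def _run(self, layers: list[_Layer], x, train, rng):
        for layer in layers:
            x = layer.forward(x, train, rng)
        return x

    def forward_logits(
        self, X_t: np.ndarray | None, X_f: np.ndarray | None, train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        parts = []
        if self.time_branch:
            if X_t is None:
                raise ValueError("variant requires X_t")
            if X_t.shape[-1] != self.config.t_features:
                raise ValueError(
                    f"X_t has {X_t.shape[-1]} features, model expects {self.config.t_features}"
                )
            parts.append(self._run(self.time_branch, X_t, train, rng))
        if self.freq_branch:
            if X_f is None:
                raise ValueError("variant requires X_f")
            if X_f.shape[-1] != self.config.f_features:
                raise ValueError(
                    f"X_f has {X_f.shape[-1]} features, model expects {self.config.f_features}"
                )
            parts.append(self._run(self.freq_branch, X_f, train, rng))
        self._split = parts[0].shape[-1] if len(parts) == 2 else None
        z = np.concatenate(parts, axis=-1) if len(parts) > 1 else parts[0]
        return self._run(self.head, z, train, rng)

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        if self._split is not None:
            gt, gf = grad[:, : self._split], grad[:, self._split :]
        elif self.time_branch:
            gt, gf = grad, None
        else:
            gt, gf = None, grad
        if self.time_branch:
            g = gt
            for layer in reversed(self.time_branch):
                g = layer.backward(g)
        if self.freq_branch:
            g = gf
            for layer in reversed(self.freq_branch):
                g = layer.backward(g)


def build_model(config: ModelConfig, variant: str = "full", seed: int = 0) -> FusionModel:
    """Construct an untrained model for the given ablation variant."""
    return FusionModel(config, variant=variant, seed=seed)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(model: FusionModel, X_t, X_f, train: bool = False, rng=None) -> np.ndarray:
    """Class-probability matrix (rows sum to 1); deterministic in eval mode."""
    return _softmax(model.forward_logits(X_t, X_f, train=train, rng=rng))


def predict(model: FusionModel, dataset: FeatureDataset) -> np.ndarray:
    """Argmax class per row; ties resolve to the lowest class index."""
    probs = forward(model, dataset.X_t, dataset.X_f, train=False)
    return probs.argmax(axis=1)


def parameter_count(model: FusionModel) -> int:
    return int(sum(p.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    model: FusionModel
    history: dict[str, list[float]] = field(default_factory=dict)
    epochs_run: int = 0
    best_epoch: int = 0

    @property
    def variant(self) -> str:
        return self.model.variant


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_grad(model: FusionModel, logits: np.ndarray, y: np.ndarray, l2: float):
    B = len(y)
    probs = _softmax(logits)
    ce = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))
    penalty = 0.0
    if l2 > 0:
        for layer in model.layers:
            for p, d in zip(layer.params, layer.decayable):
                if d:
                    penalty += float(np.sum(p * p))
    grad = probs.copy()
    grad[np.arange(B), y] -= 1.0
    grad /= B
    return ce + l2 * penalty, grad


def _eval_loss_acc(model: FusionModel, dataset: FeatureDataset, l2: float) -> tuple[float, float]:
    logits = model.forward_logits(dataset.X_t, dataset.X_f, train=False)
    loss, _ = _loss_and_grad(model, logits, dataset.y, l2)
    acc = float(np.mean(logits.argmax(axis=1) == dataset.y))
    return float(loss), acc


def train(
    model: FusionModel,
    train_set: FeatureDataset,
    val_set: FeatureDataset,
    tc: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Mini-batch Adam on cross-entropy + L2, with early stopping.

    Stops when validation loss fails to improve for ``tc.patience`` epochs and
    restores the best-validation parameters.  Seeded shuffling and dropout
    make runs reproducible bit-for-bit.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty split")
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 17]))
    params = model.parameters()
    adam = _Adam(params, tc.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0
    bad_epochs = 0
    n = len(train_set)

    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            Xt = train_set.X_t[idx]
            Xf = train_set.X_f[idx]
            y = train_set.y[idx]
            logits = model.forward_logits(Xt, Xf, train=True, rng=rng)
            loss, grad = _loss_and_grad(model, logits, y, tc.l2)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // tc.batch_size}: "
                    f"lr={tc.learning_rate}, l2={tc.l2}"
                )
            model.backward(grad)
            grads = model.gradients()
            if tc.l2 > 0:
                for g, p, d in zip(grads, params, model.decay_mask()):
                    if d:
                        g += 2.0 * tc.l2 * p
            adam.step(params, grads)
            epoch_losses.append(loss)

        val_loss, val_acc = _eval_loss_acc(model, val_set, tc.l2)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)

        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tc.patience:
                break

    model.set_state(best_state)
    return TrainedModel(
        model=model,
        history=history,
        epochs_run=len(history["train_loss"]),
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path, trained: TrainedModel, extra_meta: dict | None = None) -> None:
    """Single-file checkpoint: architecture config + flat parameter arrays."""
    model = trained.model
    meta = {
        "version": _CHECKPOINT_VERSION,
        "variant": model.variant,
        "seed": model.seed,
        "config": {
            "conv_filters": list(model.config.conv_filters),
            "kernel_size": model.config.kernel_size,
            "pool_size": model.config.pool_size,
            "dropout": model.config.dropout,
            "fusion_hidden": list(model.config.fusion_hidden),
            "n_classes": model.config.n_classes,
            "t_features": model.config.t_features,
            "f_features": model.config.f_features,
        },
        "history": trained.history,
        "epochs_run": trained.epochs_run,
        "best_epoch": trained.best_epoch,
        "extra": extra_meta or {},
    }
    state = model.get_state()
    arrays = {f"arr_{i}": a for i, a in enumerate(state)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    cfg = meta["config"]
    config = ModelConfig(
        conv_filters=tuple(cfg["conv_filters"]),
        kernel_size=cfg["kernel_size"],
        pool_size=cfg["pool_size"],
        dropout=cfg["dropout"],
        fusion_hidden=tuple(cfg["fusion_hidden"]),
        n_classes=cfg["n_classes"],
        t_features=cfg["t_features"],
        f_features=cfg["f_features"],
    )
    model = FusionModel(config, variant=meta["variant"], seed=meta["seed"])
    model.set_state(state)
    return TrainedModel(
        model=model,
        history=meta["history"],
        epochs_run=meta["epochs_run"],
        best_epoch=meta["best_epoch"],
    )
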