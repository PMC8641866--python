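"""Training loop: pixel-wise cross-entropy, Adam, plateau LR decay.

Defaults follow the published recipe: Adam with beta1 = 0.9,
beta2 = 0.999, eps = 1e-8, learning rate 0.001, L2 weight decay 0.0005,
batches of 32 randomly sampled 48x48 patches, 200 epochs, learning rate
attenuated on a validation-loss plateau. The plateau patience/factor and
the per-epoch patch budget are not part of the recipe and are exposed as
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .datasets import PatchSpec, sample_patches
from .model import RFARN, NetworkConfig
from .nn import Tensor

LOSS_EPS = 1e-7


@dataclass
class TrainConfig:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    weight_decay: float = 0.0005
    batch_size: int = 32
    epochs: int = 200
    patches_per_epoch: int = 4096
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    min_lr: float = 1e-6
    val_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("lr", "beta1", "beta2", "adam_eps", "batch_size", "epochs",
                     "patches_per_epoch", "plateau_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)


def bce_loss(pred, truth) -> Tensor:
    """Mean binary cross-entropy over all pixels.

    Predictions are clamped to [1e-7, 1 - 1e-7] before the logarithms so
    the loss is finite even for saturated outputs.
    """
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred))
    t = np.asarray(truth.data if isinstance(truth, Tensor) else truth,
                   dtype=p.data.dtype)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    q = nn.clip(p, LOSS_EPS, 1.0 - LOSS_EPS)
    one = Tensor(np.asarray(1.0, dtype=p.data.dtype))
    ll = Tensor(t) * nn.log(q) + (one - Tensor(t)) * nn.log(one - q)
    return -mean_t(ll)


def mean_t(x: Tensor) -> Tensor:
    return nn.mean(x)


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` epochs without
    improvement of the monitored loss; never below ``min_lr``."""

    def __init__(self, optimizer: nn.Adam, patience: int = 10, factor: float = 0.5,
                 min_lr: float = 1e-6):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float):
        if not np.isfinite(val_loss):
            raise ValueError("validation loss must be finite")
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.optimizer.lr


class NaNLossError(RuntimeError):
    """Raised when the loss turns non-finite; the model retains the last
    finite parameter state (the offending step is never applied)."""


def _epoch_patches(samples, n, spec, rng):
    """Freshly sample ``n`` aligned (patch, truth) pairs across samples."""
    xs, ys = [], []
    idx = rng.integers(0, len(samples), size=n)
    counts = np.bincount(idx, minlength=len(samples))
    for si, cnt in enumerate(counts):
        if cnt == 0:
            continue
        pairs = sample_patches(samples[si], int(cnt), spec,
                               seed=int(rng.integers(0, 2 ** 31)))
        for p, t in pairs:
            xs.append(p)
            ys.append(t)
    order = rng.permutation(len(xs))
    x = np.stack(xs)[order].astype(np.float32) / 255.0
    y = np.stack(ys)[order].astype(np.float32)
    return x, y


def train_model(model: RFARN | None, samples, train_cfg: TrainConfig | None = None,
                net_cfg: NetworkConfig | None = None, verbose: bool = False):
    """Train on freshly sampled patch batches; fully seed-reproducible.

    A ``val_frac`` share of each epoch's patches is held out to drive the
    plateau scheduler. Returns ``(model, TrainHistory)``.
    """
    train_cfg = train_cfg or TrainConfig()
    if model is None:
        model = RFARN(net_cfg)
    if not samples:
        raise ValueError("at least one training sample is required")
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr,
                  betas=(train_cfg.beta1, train_cfg.beta2),
                  eps=train_cfg.adam_eps, weight_decay=train_cfg.weight_decay)
    sched = PlateauScheduler(opt, train_cfg.plateau_patience,
                             train_cfg.plateau_factor, train_cfg.min_lr)
    spec = PatchSpec(size=model.config.patch_size, stride=5)
    history = TrainHistory()
    n_val = max(1, int(round(train_cfg.val_frac * train_cfg.patches_per_epoch)))
    model.train()
    for epoch in range(train_cfg.epochs):
        x, y = _epoch_patches(samples, train_cfg.patches_per_epoch + n_val, spec, rng)
        xv, yv = x[:n_val], y[:n_val]
        xt, yt = x[n_val:], y[n_val:]
        losses = []
        bs = train_cfg.batch_size
        for i in range(0, len(xt), bs):
            xb, yb = xt[i:i + bs], yt[i:i + bs]
            pred = model(xb)
            loss = bce_loss(pred, yb[:, None])
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise NaNLossError(f"non-finite loss at epoch {epoch}, step {i // bs}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
        model.eval()
        vpred = model(xv)
        val = float(bce_loss(vpred, yv[:, None]).data)
        model.train()
        lr_now = sched.step(val)
        history.loss.append(float(np.mean(losses)))
        history.val_loss.append(val)
        history.lr.append(lr_now)
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {history.loss[-1]:.4f}  "
                  f"val {val:.4f}  lr {lr_now:.2e}")
    return model, history


def overfit_single_patch(patch: np.ndarray, truth: np.ndarray,
                         net_cfg: NetworkConfig | None = None,
                         steps: int = 200, lr: float = 0.001,
                         batch_repeat: int = 4):
    """Drive the loss down on one repeated patch (capacity sanity check).

    Returns ``(model, losses)``; the patch is expected on the [0, 1]
    network input scale.
    """
    net_cfg = net_cfg or NetworkConfig(base_channels=8)
    model = RFARN(net_cfg)
    opt = nn.Adam(model.parameters(), lr=lr)
    x = np.repeat(np.asarray(patch, dtype=np.float32)[None], batch_repeat, axis=0)
    y = np.repeat(np.asarray(truth, dtype=np.float32)[None, None], batch_repeat, axis=0)
    losses = []
    model.train()
    for _ in range(steps):
        loss = bce_loss(model(x), y)
        losses.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    return model, losses
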