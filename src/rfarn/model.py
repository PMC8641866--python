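"""Reverse Fusion Attention Residual Network (RFARN).

The network is a four-stage residual encoder / three-stage decoder with:

* a *side-input pyramid* — average-pooled copies of the 48x48 input patch
  (48, 24, 12, 6 px) injected at each encoder stage;
* *residual encoder blocks* — 3x3 conv -> BN -> ReLU -> dilated 3x3 conv
  (rate 2) -> BN -> ReLU, plus a shortcut, followed by 2x2 max pooling;
* *reverse channel attention* (RCAM) on every skip connection: a coarse
  prediction from the deeper scale is upsampled, turned into reverse
  weights ``1 - sigmoid(logits)`` that emphasise weakly-predicted regions
  (vessel edges, thin vessels), multiplied into the shallow features, and
  re-mixed across channels through a softmax channel-affinity matrix;
* *reverse spatial attention* (RSAM) between decoding stages: a pixel
  attention mask from the fused encoder/decoder signal gates the decoder
  features, spatially softmax-normalised, and is added back residually;
* a 1x1 convolution + sigmoid head giving per-pixel vessel probability.

All computation runs on the :mod:`rfarn.nn` autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``pyramid_sizes`` must halve at each level and ``patch_size`` must be
    divisible by ``2**(depth-1)`` so the pooled scales line up with the
    side inputs.
    """

    patch_size: int = 48
    pyramid_sizes: tuple = (48, 24, 12, 6)
    depth: int = 4
    base_channels: int = 32
    dilation: int = 2
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if len(self.pyramid_sizes) != self.depth:
            raise ValueError("pyramid_sizes length must equal depth")
        if self.pyramid_sizes[0] != self.patch_size:
            raise ValueError("first pyramid level must equal patch_size")
        for a, b in zip(self.pyramid_sizes, self.pyramid_sizes[1:]):
            if b * 2 != a:
                raise ValueError("pyramid_sizes must decrease by factor 2")
        if self.patch_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError("patch_size must be divisible by 2**(depth-1)")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @property
    def stage_channels(self) -> list:
        return [self.base_channels * 2 ** i for i in range(self.depth)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pyramid_sizes"] = list(self.pyramid_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "pyramid_sizes" in d:
            d["pyramid_sizes"] = tuple(d["pyramid_sizes"])
        return cls(**d)


# ---------------------------------------------------------------------------
# functional pieces (testable without building the full network)
# ---------------------------------------------------------------------------

def build_side_pyramid(patch: np.ndarray, config: NetworkConfig) -> list:
    """Average-pool the input patch down to every pyramid scale."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (config.patch_size, config.patch_size):
        raise ValueError(
            f"patch shape {patch.shape} does not match patch_size {config.patch_size}")
    levels = []
    for size in config.pyramid_sizes:
        f = config.patch_size // size
        lvl = patch.reshape(size, f, size, f).mean(axis=(1, 3)) if f > 1 else patch.copy()
        levels.append(lvl)
    return levels


def reverse_weight(logits):
    """Reverse attention weights ``1 - sigmoid(logits)``, strictly in (0,1)."""
    if isinstance(logits, Tensor):
        one = Tensor(np.asarray(1.0, dtype=logits.data.dtype))
        return one - nn.sigmoid(logits)
    logits = np.asarray(logits, dtype=np.float64)
    return 1.0 - nn._stable_sigmoid(logits)


def channel_affinity(avg_pool, max_pool):
    """Channel-affinity matrix: softmax over the first index of the outer
    product ``avg_i * max_j`` (each column sums to one)."""
    if isinstance(avg_pool, Tensor) or isinstance(max_pool, Tensor):
        # batched tensors (N, C): outer product -> (N, C, C)
        a = avg_pool if isinstance(avg_pool, Tensor) else Tensor(avg_pool)
        m = max_pool if isinstance(max_pool, Tensor) else Tensor(max_pool)
        N, C = a.shape
        outer = nn.matmul(nn.reshape(a, (N, C, 1)), nn.reshape(m, (N, 1, C)))
        return nn.softmax(outer, axis=1)
    avg_pool = np.asarray(avg_pool, dtype=np.float64)
    max_pool = np.asarray(max_pool, dtype=np.float64)
    if avg_pool.shape != max_pool.shape:
        raise ValueError("pooled vectors must have equal length")
    outer = np.outer(avg_pool, max_pool)
    e = np.exp(outer - outer.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class ResidualEncoderBlock(nn.Module):
    """3x3 conv -> BN -> ReLU -> dilated 3x3 conv -> BN -> ReLU, + shortcut.

    The shortcut is identity when channel counts match, a 1x1 projection
    otherwise. ``forward`` returns both the full-resolution features and
    their 2x2 max-pooled version.
    """

    def __init__(self, in_ch: int, out_ch: int, rng, dilation: int = 2):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, dilation=dilation)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.project = None
        if in_ch != out_ch:
            self.project = nn.Conv2d(in_ch, out_ch, 1, rng)

    def __call__(self, x: Tensor):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = nn.relu(self.bn2(self.conv2(h)))
        shortcut = self.project(x) if self.project is not None else x
        features = h + shortcut
        pooled = nn.max_pool2d(features)
        return features, pooled


class RCAM(nn.Module):
    """Reverse channel attention bridging a deep scale onto the skip above it.

    deep (C x H x W) -> 1x1 conv -> 2x2/2 deconv -> logits (1 x 2H x 2W);
    reverse weights gate the shallow features into edge features B-hat;
    a softmax channel-affinity built from global average/max pooling of
    B-hat, passed through sigmoid and a learnable per-channel scale, remixes
    B-hat across channels; the result is added back to the shallow features.
    """

    def __init__(self, deep_ch: int, shallow_ch: int, rng):
        super().__init__()
        self.squeeze = nn.Conv2d(deep_ch, 1, 1, rng)
        self.up = nn.ConvTranspose2d(1, 1, rng)
        self.register("rho", Tensor(np.ones(shallow_ch, dtype=nn.DTYPE),
                                    requires_grad=True))

    def __call__(self, deep: Tensor, shallow: Tensor, return_state: bool = False):
        N, C, Hs, Ws = shallow.shape
        if deep.shape[2] * 2 != Hs or deep.shape[3] * 2 != Ws:
            raise ValueError("deep feature map must be half the shallow resolution")
        logits = self.up(self.squeeze(deep))            # (N,1,Hs,Ws)
        rw = reverse_weight(logits)                     # broadcast over channels
        bhat = rw * shallow                             # edge features
        avg = nn.global_avg_pool(bhat)                  # (N,C)
        mx = nn.global_max_pool(bhat)
        cb = channel_affinity(avg, mx)                  # (N,C,C), columns sum to 1
        ab = nn.sigmoid(cb) * nn.reshape(self.rho, (1, 1, C))
        bflat = nn.reshape(bhat, (N, C, Hs * Ws))
        mixed = nn.matmul(_transpose12(ab), bflat)      # (N,C,HW)
        mixed = nn.reshape(mixed, (N, C, Hs, Ws))
        out = mixed + shallow
        if return_state:
            return out, {"reverse_weights": rw.data, "channel_affinity": cb.data,
                         "edge_features": bhat.data}
        return out


def _transpose12(t: Tensor) -> Tensor:
    """Swap the last two axes of a (N, C, C) tensor."""
    data = np.swapaxes(t.data, 1, 2)
    out = Tensor(data, parents=(t,))
    out._backward = lambda g: t._accumulate(np.swapaxes(g, 1, 2))
    return out


class DecoderBlock(nn.Module):
    """2x2/2 deconv, concatenate the skip, then two 3x3 conv + ReLU."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(in_ch, out_ch, rng)
        self.conv1 = nn.Conv2d(out_ch + skip_ch, out_ch, 3, rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.up(x)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError("skip spatial size must be twice the input size")
        h = nn.concat([up, skip], axis=1)
        h = nn.relu(self.conv1(h))
        h = nn.relu(self.conv2(h))
        return h


class RSAM(nn.Module):
    """Reverse spatial attention between decoding stages.

    The deeper encoder features are squeezed to one channel and upsampled
    to the decoder resolution; summed with the decoder features they yield
    a pixel attention mask (1x1 conv + sigmoid). The mask gates the
    1x1-convolved decoder features; each channel is then softmax-normalised
    over its spatial positions and the result is added back to the decoder
    features.
    """

    def __init__(self, enc_ch: int, dec_ch: int, rng):
        super().__init__()
        self.squeeze = nn.Conv2d(enc_ch, 1, 1, rng)
        self.up = nn.ConvTranspose2d(1, 1, rng)
        self.mask_conv = nn.Conv2d(dec_ch, 1, 1, rng)
        self.dec_conv = nn.Conv2d(dec_ch, dec_ch, 1, rng)

    def __call__(self, encoder_feat: Tensor, decoder_feat: Tensor,
                 return_state: bool = False):
        N, C, H, W = decoder_feat.shape
        if encoder_feat.shape[2] * 2 != H or encoder_feat.shape[3] * 2 != W:
            raise ValueError("decoder resolution must be twice the encoder resolution")
        residual = self.up(self.squeeze(encoder_feat))  # (N,1,H,W)
        fused = decoder_feat + residual                 # broadcast over channels
        mask = nn.sigmoid(self.mask_conv(fused))        # (N,1,H,W)
        d = self.dec_conv(decoder_feat)                 # (N,C,H,W)
        gated = mask * d
        flat = nn.reshape(gated, (N, C, H * W))
        sb = nn.softmax(flat, axis=2)                   # each channel sums to 1
        sb_map = nn.reshape(sb, (N, C, H, W))
        out = sb_map + decoder_feat
        if return_state:
            return out, {"mask": mask.data, "spatial_affinity": sb.data}
        return out


class RFARN(nn.Module):
    """Full network: side-input pyramid, residual encoders, RCAM skips,
    decoders with RSAM in between, sigmoid head."""

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        self.config = config or NetworkConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        chans = cfg.stage_channels
        self.side_convs = _ModuleList(
            [nn.Conv2d(1, (1 if i == 0 else chans[i - 1]), 3, rng)
             for i in range(cfg.depth)])
        self.encoders = _ModuleList(
            [ResidualEncoderBlock((1 if i == 0 else chans[i - 1]), chans[i], rng,
                                  dilation=cfg.dilation)
             for i in range(cfg.depth)])
        self.rcams = _ModuleList(
            [RCAM(chans[i + 1], chans[i], rng) for i in range(cfg.depth - 1)])
        self.decoders = _ModuleList(
            [DecoderBlock(chans[i + 1], chans[i], chans[i], rng)
             for i in reversed(range(cfg.depth - 1))])
        self.rsams = _ModuleList(
            [RSAM(chans[i + 1], chans[i], rng) for i in reversed(range(cfg.depth - 1))])
        self.head = nn.Conv2d(chans[0], cfg.out_channels, 1, rng)

    def __call__(self, patches: np.ndarray | Tensor) -> Tensor:
        """Forward a batch of patches (N, H, W) or (N, 1, H, W) to vessel
        probabilities (N, 1, H, W)."""
        cfg = self.config
        if isinstance(patches, Tensor):
            x = patches
        else:
            arr = np.asarray(patches, dtype=nn.DTYPE)
            if arr.ndim == 3:
                arr = arr[:, None]
            x = Tensor(arr)
        if x.shape[2] != cfg.patch_size or x.shape[3] != cfg.patch_size:
            raise ValueError(
                f"expected {cfg.patch_size}x{cfg.patch_size} patches, got "
                f"{x.shape[2]}x{x.shape[3]}")

        # side pyramid (pure-data average pooling of the raw input)
        sides = []
        data = x.data
        N = data.shape[0]
        for size in cfg.pyramid_sizes:
            f = cfg.patch_size // size
            if f > 1:
                lvl = data.reshape(N, 1, size, f, size, f).mean(axis=(3, 5))
            else:
                lvl = data
            sides.append(Tensor(np.ascontiguousarray(lvl, dtype=nn.DTYPE)))

        # encoder with side-input fusion
        feats = []
        h = None
        for i in range(cfg.depth):
            side = self.side_convs[i](sides[i])
            h = side if h is None else h + side
            features, pooled = self.encoders[i](h)
            feats.append(features)
            h = pooled

        # RCAM-refined skip connections
        skips = [self.rcams[i](feats[i + 1], feats[i]) for i in range(cfg.depth - 1)]

        # decoder with RSAM between stages
        d = feats[-1]
        for j, dec in enumerate(self.decoders):
            scale = cfg.depth - 2 - j            # skip index for this stage
            d_in = d if j == 0 else self.rsams[j - 1](enc_prev, d)
            d = dec(d_in, skips[scale])
            enc_prev = feats[scale + 1]
        d = self.rsams[-1](feats[1], d)

        return nn.sigmoid(self.head(d))


class _ModuleList(nn.Module):
    def __init__(self, modules):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._items = list(modules)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)

    def __iter__(self):
        return iter(self._items)


def rfarn_forward(patches: np.ndarray, config: NetworkConfig | None = None,
                  model: RFARN | None = None) -> np.ndarray:
    """Deterministic inference: probabilities (N, H, W) strictly in (0, 1)."""
    if model is None:
        model = RFARN(config)
    was_training = model.training
    model.eval()
    out = model(patches).data[:, 0]
    if was_training:
        model.train()
    return out


def model_summary(config: NetworkConfig | None = None) -> str:
    """Human-readable parameter table."""
    model = RFARN(config)
    lines = [f"{'parameter':50s} {'shape':>18s} {'count':>10s}"]
    total = 0
    for name, p in model.named_parameters().items():
        n = p.data.size
        total += n
        lines.append(f"{name:50s} {str(p.data.shape):>18s} {n:>10d}")
    lines.append(f"{'total':50s} {'':>18s} {total:>10d}")
    return "\n".join(lines)
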