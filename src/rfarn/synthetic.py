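"""Seed-reproducible synthetic fundus images with known vessel trees.

The generator emulates the image properties the enhancement pipeline
targets — a reddish background under a radial illumination fall-off,
vessels that darken mainly the green channel with modest contrast,
additive Gaussian sensor noise, and a circular field of view — so every
stage (preprocessing, training, inference, evaluation) can be exercised
without downloading any benchmark data. Vessel trees are grown by a
random branching walk: from seed points near a disc-like origin, each
branch advances with bounded angular jitter, stamps discs of its current
width, spawns children with a fixed per-step probability, and thins by a
decay factor per branch generation.

It does not attempt photorealism: no optic disc texture, no pathology
(hemorrhages, exudates), no vessel central reflex, and no inter-image
illumination variability beyond the seeded noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .datasets import FundusSample


@dataclass
class SynthConfig:
    """Generator parameters (intensities on the 0-255 scale).

    Defaults render 128x128 images — large enough for 48x48 patches and
    sliding-window inference while keeping full pipeline runs quick; pass
    ``size=(584, 565)`` for DRIVE-sized phantoms.
    """

    size: tuple = (128, 128)
    n_trees: int = 4
    branch_prob: float = 0.05
    max_depth: int = 4
    width_root: float = 2.6
    width_decay: float = 0.7
    vessel_contrast: float = 45.0
    illumination_gradient: float = 1.5
    noise_sigma: float = 8.0
    fov_radius_frac: float = 0.94
    seed: int = 0

    def __post_init__(self):
        self.size = tuple(int(s) for s in self.size)
        if min(self.size) < 64:
            raise ValueError("size must be at least 64x64")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must lie in [0, 1]")
        if not 0 < self.width_decay < 1:
            raise ValueError("width_decay must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size"] = list(self.size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "size" in d:
            d["size"] = tuple(d["size"])
        return cls(**d)


def _stamp_disc(mask: np.ndarray, r: float, c: float, radius: float):
    H, W = mask.shape
    rad = max(radius, 0.5)
    r0, r1 = int(max(0, r - rad - 1)), int(min(H, r + rad + 2))
    c0, c1 = int(max(0, c - rad - 1)), int(min(W, c + rad + 2))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= ((yy - r) ** 2 + (xx - c) ** 2) <= rad ** 2


def generate_vessel_mask(cfg: SynthConfig) -> np.ndarray:
    """Grow ``n_trees`` branching vessel trees into a binary mask."""
    H, W = cfg.size
    mask = np.zeros((H, W), dtype=bool)
    if cfg.n_trees == 0:
        warnings.warn("n_trees is 0: returning an empty vessel mask")
        return mask.astype(np.uint8)
    rng = np.random.default_rng(cfg.seed)
    center = np.array([H / 2, W / 2])
    fov_radius = cfg.fov_radius_frac * min(H, W) / 2
    # disc-like origin offset toward one side of the FOV
    origin = center + np.array([0.0, -0.55 * fov_radius])
    max_steps = int(0.8 * min(H, W))
    step = 1.0

    stack = []
    for t in range(cfg.n_trees):
        angle = rng.uniform(-np.pi, np.pi)
        start = origin + rng.normal(0, 2.0, size=2)
        stack.append((start[0], start[1], angle, cfg.width_root, 0, max_steps))
    while stack:
        r, c, angle, width, depth, budget = stack.pop()
        for _ in range(budget):
            _stamp_disc(mask, r, c, width / 2)
            angle += rng.normal(0.0, 0.18)
            r += step * np.sin(angle)
            c += step * np.cos(angle)
            if np.hypot(r - center[0], c - center[1]) > fov_radius + 2:
                break
            if depth < cfg.max_depth and rng.random() < cfg.branch_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                child_angle = angle + sign * rng.uniform(0.4, 0.9)
                stack.append((r, c, child_angle, width * cfg.width_decay,
                              depth + 1, budget // 2))
            budget -= 1
    return mask.astype(np.uint8)


def _fov_mask(cfg: SynthConfig) -> np.ndarray:
    H, W = cfg.size
    yy, xx = np.mgrid[0:H, 0:W]
    radius = cfg.fov_radius_frac * min(H, W) / 2
    return (((yy - H / 2) ** 2 + (xx - W / 2) ** 2) <= radius ** 2).astype(np.uint8)


def render_fundus(mask: np.ndarray, cfg: SynthConfig) -> FundusSample:
    """Render a vessel mask into a noisy, unevenly illuminated RGB phantom."""
    H, W = cfg.size
    mask = np.asarray(mask)
    if mask.shape != (H, W):
        raise ValueError("mask size does not match the configuration")
    rng = np.random.default_rng(cfg.seed + 104729)   # independent noise stream
    yy, xx = np.mgrid[0:H, 0:W]
    radius = cfg.fov_radius_frac * min(H, W) / 2
    dist = np.hypot(yy - H / 2, xx - W / 2) / radius
    # radial illumination: 1 at the centre, 1/gradient at the FOV edge
    illum = 1.0 - (1.0 - 1.0 / cfg.illumination_gradient) * np.clip(dist, 0, 1)

    base = np.empty((H, W, 3), dtype=np.float64)
    base[:, :, 0] = 185.0
    base[:, :, 1] = 105.0
    base[:, :, 2] = 55.0
    image = base * illum[:, :, None]
    vessels = mask.astype(bool)
    image[:, :, 1][vessels] -= cfg.vessel_contrast
    image[:, :, 0][vessels] -= 0.5 * cfg.vessel_contrast
    if cfg.noise_sigma > 0:
        image += rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    fov = _fov_mask(cfg)
    image *= fov[:, :, None]
    image = np.clip(image, 0.0, 255.0)
    return FundusSample(image=image, truth=mask.astype(np.uint8), fov=fov,
                        id="synth", dataset="SYNTH")


def generate_sample(cfg: SynthConfig, index: int = 0) -> FundusSample:
    """Pure function of (cfg, index): derived seed is ``cfg.seed + index``."""
    sub = SynthConfig.from_dict({**cfg.to_dict(), "seed": cfg.seed + index})
    sample = render_fundus(generate_vessel_mask(sub), sub)
    sample.id = f"{index + 1:02d}"
    return sample


def make_dataset(n: int, cfg: SynthConfig | None = None, out_dir=None) -> list:
    """Generate ``n`` samples; optionally write a DRIVE-style PNG layout
    (images/, 1st_manual/, mask/) loadable by ``datasets.load_dataset``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or SynthConfig()
    samples = [generate_sample(cfg, i) for i in range(n)]
    if out_dir is not None:
        out = Path(out_dir)
        for sub in ("images", "1st_manual", "mask"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        for s in samples:
            iio.imwrite(out / "images" / f"{s.id}_synth.png",
                        np.round(s.image).astype(np.uint8))
            iio.imwrite(out / "1st_manual" / f"{s.id}_manual.png",
                        (s.truth * 255).astype(np.uint8))
            iio.imwrite(out / "mask" / f"{s.id}_mask.png",
                        (s.fov * 255).astype(np.uint8))
    return samples
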