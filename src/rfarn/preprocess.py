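"""Fundus image enhancement: multiscale retinex with color restoration.

A fundus photograph is modelled as the product of a reflectance component
(the tissue itself) and an incident-illumination component. Working in
the log domain, a single-scale retinex (SSR) estimates reflectance as

    R_sigma(x, y) = log(P + eps) - log(G_sigma * P + eps),

where ``G_sigma`` is a unit-sum Gaussian surround. Small surrounds favour
local detail, large surrounds favour global tonal balance, so several
scales are combined with weights ``W_m`` (multiscale retinex, MSR) and a
per-channel color-restoration gain

    C_i = beta * [log(alpha * P_i + eps) - log(sum_j P_j + eps)]

re-weights the result toward the original chromaticity (MSRCR). The
enhanced log-domain image is mapped back to 0-255 either by a per-channel
mean +/- k*std affine stretch ("simplest color balance", the default,
robust to isolated outliers) or by global min-max.

The full pipeline for network input is: MSRCR enhancement, weighted
RGB-to-gray conversion (0.299 R + 0.587 G + 0.114 B), dataset-level
Z-score standardisation, and min-max rescaling to 0-255.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

#: weights of the RGB -> gray conversion (they sum to exactly 1.000)
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: truncation of the Gaussian surround, in standard deviations
SURROUND_TRUNCATE = 3.0


class DegenerateInputError(ValueError):
    """Raised when an operation is undefined on the given input
    (e.g. a constant image fed to a normaliser)."""


@dataclass
class MSRCRConfig:
    """MSRCR parameters.

    sigmas
        Gaussian surround scales in pixels. The canonical small/medium/
        large triple (15, 80, 250) balances local contrast against tonal
        fidelity.
    weights
        Non-negative per-scale weights; normalised to sum to 1.
    cr_alpha, cr_beta
        Color-restoration gains (125 and 46, the customary values).
    epsilon
        Positive floor inside every logarithm; guards the dark background.
    rescale
        "meanstd" (clip mean +/- rescale_k * std to 0-255, default) or
        "minmax" (global per-channel min-max).
    """

    sigmas: tuple = (15.0, 80.0, 250.0)
    weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    cr_alpha: float = 125.0
    cr_beta: float = 46.0
    epsilon: float = 1.0
    rescale: str = "meanstd"
    rescale_k: float = 2.0

    def __post_init__(self):
        self.sigmas = tuple(float(s) for s in self.sigmas)
        if len(self.sigmas) < 1:
            raise ValueError("at least one surround scale is required")
        if len(self.weights) != len(self.sigmas):
            raise ValueError("weights and sigmas must have equal length")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("surround scales must be positive")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.weights = tuple(w / w.sum())
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.rescale not in ("meanstd", "minmax"):
            raise ValueError(f"unknown rescale policy {self.rescale!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigmas"] = list(self.sigmas)
        d["weights"] = list(self.weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MSRCRConfig":
        d = dict(d)
        for k in ("sigmas", "weights"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class NormalizationStats:
    """Frozen dataset-level mean/std (population) for Z-score reuse."""

    mean: float
    std: float

    def __post_init__(self):
        if self.std < 0:
            raise ValueError("std must be non-negative")


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if (image < 0).any():
        raise ValueError("image contains negative intensities")
    return image


def gaussian_surround(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Unit-sum truncated Gaussian surround (separable, reflective padding)."""
    return ndimage.gaussian_filter(np.asarray(channel, dtype=np.float64),
                                   sigma=sigma, mode="reflect",
                                   truncate=SURROUND_TRUNCATE)


def single_scale_retinex(channel: np.ndarray, sigma: float,
                         epsilon: float = 1.0) -> np.ndarray:
    """Log-domain reflectance at one surround scale."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    channel = np.asarray(channel, dtype=np.float64)
    if (channel < 0).any():
        raise ValueError("channel contains negative intensities")
    surround = gaussian_surround(channel, sigma)
    return np.log(channel + epsilon) - np.log(surround + epsilon)


def multi_scale_retinex(channel: np.ndarray, config: MSRCRConfig) -> np.ndarray:
    """Weighted sum of SSR maps over the configured scales."""
    out = np.zeros(np.asarray(channel).shape, dtype=np.float64)
    for w, sigma in zip(config.weights, config.sigmas):
        if w == 0:
            continue
        out += w * single_scale_retinex(channel, sigma, config.epsilon)
    return out


def color_restoration(image: np.ndarray, cr_alpha: float = 125.0,
                      cr_beta: float = 46.0, epsilon: float = 1.0) -> np.ndarray:
    """Per-channel chromaticity gain C_i (HxWx3, finite everywhere)."""
    image = _validate_rgb(image)
    total = image.sum(axis=2, keepdims=True)
    return cr_beta * (np.log(cr_alpha * image + epsilon) - np.log(total + epsilon))


def _rescale_channel(values: np.ndarray, policy: str, k: float) -> np.ndarray:
    if policy == "minmax":
        lo, hi = values.min(), values.max()
        if hi == lo:
            return np.full_like(values, 127.5)
        return (values - lo) / (hi - lo) * 255.0
    mu, sd = values.mean(), values.std()
    if sd == 0:
        return np.full_like(values, 127.5)
    lo, hi = mu - k * sd, mu + k * sd
    return np.clip((values - lo) / (hi - lo) * 255.0, 0.0, 255.0)


def msrcr_enhance(image: np.ndarray, config: MSRCRConfig | None = None) -> np.ndarray:
    """MSRCR enhancement: C_i * MSR_i per channel, rescaled to 0-255."""
    config = config or MSRCRConfig()
    image = _validate_rgb(image)
    gains = color_restoration(image, config.cr_alpha, config.cr_beta, config.epsilon)
    out = np.empty_like(image)
    for c in range(3):
        msr = multi_scale_retinex(image[:, :, c], config)
        out[:, :, c] = _rescale_channel(gains[:, :, c] * msr, config.rescale,
                                        config.rescale_k)
    return out


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Weighted grayscale conversion 0.299 R + 0.587 G + 0.114 B."""
    image = _validate_rgb(image)
    wr, wg, wb = GRAY_WEIGHTS
    return wr * image[:, :, 0] + wg * image[:, :, 1] + wb * image[:, :, 2]


def zscore_normalize(images, stats: NormalizationStats | None = None):
    """Standardise a collection of grayscale images to pooled mean 0, std 1.

    With ``stats`` given, applies the frozen statistics (for test images);
    otherwise computes population statistics over all pixels of the
    collection and returns them for reuse.
    """
    arrays = [np.asarray(im, dtype=np.float64) for im in images]
    if not arrays:
        raise ValueError("empty image collection")
    if stats is None:
        pooled = np.concatenate([a.ravel() for a in arrays])
        mu = float(pooled.mean())
        sd = float(pooled.std())
        if sd == 0:
            raise DegenerateInputError("constant input: Z-score is undefined")
        stats = NormalizationStats(mean=mu, std=sd)
    if stats.std == 0:
        raise DegenerateInputError("zero std in normalization stats")
    out = [(a - stats.mean) / stats.std for a in arrays]
    return out, stats


def minmax_rescale(image: np.ndarray) -> np.ndarray:
    """Affine map to [0, 255]; the minimum maps to 0, the maximum to 255."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise DegenerateInputError("constant image: min-max rescale is undefined")
    return (image - lo) / (hi - lo) * 255.0


def preprocess_image(image: np.ndarray, config: MSRCRConfig | None = None,
                     stats: NormalizationStats | None = None) -> np.ndarray:
    """Full pipeline for one image: MSRCR -> gray -> Z-score -> min-max.

    ``stats`` should be the dataset-level statistics frozen on the
    training split; if omitted they are computed from this image alone.
    """
    enhanced = msrcr_enhance(image, config)
    gray = rgb_to_gray(enhanced)
    normed, _ = zscore_normalize([gray], stats=stats)
    return minmax_rescale(normed[0])


def preprocess_dataset(images, config: MSRCRConfig | None = None,
                       stats: NormalizationStats | None = None):
    """Preprocess a collection with shared (dataset-level) statistics.

    Returns ``(grays_0_255, stats)``; pass the returned stats back in to
    preprocess held-out images with the training-split normalisation.
    """
    grays = [rgb_to_gray(msrcr_enhance(im, config)) for im in images]
    normed, stats = zscore_normalize(grays, stats=stats)
    return [minmax_rescale(g) for g in normed], stats
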