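"""Dataset IO, patch extraction, sliding-window tiling and splits.

Supports the on-disk layouts of the three public fundus benchmarks —
DRIVE (TIFF images, GIF manual labels and FOV masks), STARE (PPM images
and ``ah`` labels, no official FOV) and CHASE_DB1 (JPG images, PNG first
human observer labels) — plus a DRIVE-style PNG layout written by the
synthetic generator. Coordinates are 0-based ``(row, col)`` of the
top-left corner with half-open extents throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass
class FundusSample:
    """One fundus image with vessel ground truth and field-of-view mask."""

    image: np.ndarray            # H x W x 3, 0-255
    truth: np.ndarray            # H x W in {0, 1}
    fov: np.ndarray              # H x W in {0, 1}
    id: str = ""
    dataset: str = "SYNTH"
    enhanced: np.ndarray | None = None   # preprocessed grayscale plane

    def __post_init__(self):
        h, w = self.image.shape[:2]
        if self.truth.shape != (h, w) or self.fov.shape != (h, w):
            raise ValueError(f"sample {self.id!r}: truth/fov shape mismatch")
        for name, m in (("truth", self.truth), ("fov", self.fov)):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"sample {self.id!r}: {name} is not binary")

    @property
    def plane(self) -> np.ndarray:
        """The grayscale plane patches are drawn from (preprocessed if set)."""
        if self.enhanced is not None:
            return self.enhanced
        from .preprocess import rgb_to_gray
        return rgb_to_gray(self.image)


@dataclass
class PatchSpec:
    """Patch geometry: 48x48 patches; test-time sliding stride of 5 px."""

    size: int = 48
    stride: int = 5

    def __post_init__(self):
        if self.size < 1 or self.stride < 1:
            raise ValueError("size and stride must be >= 1")


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    scheme: str = "fixed"

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


class DatasetLoadError(RuntimeError):
    pass


def _read_binary(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 4:          # animated containers (GIF) add a frame axis
        arr = arr[0]
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def _read_rgb(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 4:
        arr = arr[0]
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.float64)


_LAYOUTS = {
    "drive": {
        "images": ("images", ("*.tif", "*.png")),
        "truth": ("1st_manual", ("*.gif", "*.png")),
        "fov": ("mask", ("*.gif", "*.png")),
    },
    "stare": {
        "images": ("stare-images", ("*.ppm",)),
        "truth": ("labels-ah", ("*.ppm",)),
        "fov": ("masks", ("*.ppm", "*.png")),
    },
    "chase": {
        "images": (".", ("Image_*.jpg",)),
        "truth": (".", ("Image_*_1stHO.png",)),
        "fov": ("masks", ("*.png",)),
    },
    "synth": {
        "images": ("images", ("*.png",)),
        "truth": ("1st_manual", ("*.png",)),
        "fov": ("mask", ("*.png",)),
    },
}


def _sample_id(path: Path) -> str:
    stem = path.stem
    m = re.match(r"Image_(\w+?)(?:_1stHO|_2ndHO)?$", stem)   # CHASE naming
    if m:
        return m.group(1)
    m = re.match(r"([A-Za-z0-9]+)", stem)
    return m.group(1) if m else stem


def _find(root: Path, subdir: str, patterns) -> dict:
    d = root / subdir if subdir != "." else root
    out = {}
    if not d.is_dir():
        return out
    for pat in patterns:
        for p in sorted(d.glob(pat)):
            if "_1stHO" in p.stem and pat == "Image_*.jpg":
                continue
            out.setdefault(_sample_id(p), p)
    return out


def load_dataset(root, layout: str = "synth") -> list:
    """Load every sample under ``root`` following the named layout.

    Ground-truth and FOV rasters are binarised at 127 (8-bit). STARE and
    CHASE layouts synthesize an all-ones FOV when no mask directory exists.
    """
    layout = layout.lower()
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    root = Path(root)
    spec = _LAYOUTS[layout]
    images = _find(root, *spec["images"])
    truths = _find(root, *spec["truth"])
    fovs = _find(root, *spec["fov"])
    if not images:
        raise DatasetLoadError(f"no images found under {root} for layout {layout!r}")
    samples = []
    for sid, ipath in images.items():
        if sid not in truths:
            raise DatasetLoadError(f"sample {sid!r}: missing ground truth")
        image = _read_rgb(ipath)
        truth = _read_binary(truths[sid])
        if sid in fovs:
            fov = _read_binary(fovs[sid])
        elif layout in ("stare", "chase"):
            fov = np.ones(truth.shape, dtype=np.uint8)
        else:
            raise DatasetLoadError(f"sample {sid!r}: missing FOV mask")
        if truth.shape != image.shape[:2]:
            raise DatasetLoadError(f"sample {sid!r}: truth size mismatch")
        samples.append(FundusSample(image=image, truth=truth, fov=fov,
                                    id=sid, dataset=layout.upper()))
    return samples


def sample_patches(sample: FundusSample, n: int, spec: PatchSpec | None = None,
                   seed: int = 0, min_fov_frac: float = 0.5):
    """Draw ``n`` random training patches (uniform over valid corners).

    Corners with less than ``min_fov_frac`` of the patch inside the FOV
    are rejected and resampled, so training is not dominated by the black
    camera border. Returns ``[(patch, truth_patch), ...]`` plus alignment
    is guaranteed; the same seed reproduces the same corners.
    """
    spec = spec or PatchSpec()
    plane = sample.plane
    H, W = plane.shape
    k = spec.size
    if H < k or W < k:
        raise ValueError(f"image {H}x{W} smaller than patch size {k}")
    rng = np.random.default_rng(seed)
    area = float(k * k)
    out = []
    guard = 0
    while len(out) < n:
        r = int(rng.integers(0, H - k + 1))
        c = int(rng.integers(0, W - k + 1))
        if sample.fov[r:r + k, c:c + k].sum() / area < min_fov_frac:
            guard += 1
            if guard > 1000 * max(n, 1):
                raise RuntimeError("could not find patches inside the FOV")
            continue
        out.append((plane[r:r + k, c:c + k].copy(),
                    sample.truth[r:r + k, c:c + k].copy()))
    return out


def window_starts(length: int, size: int, stride: int) -> list:
    """Corner coordinates {0, s, 2s, ...} plus a final flush-to-edge start."""
    if length <= size:
        return [0]
    starts = list(range(0, length - size + 1, stride))
    if starts[-1] != length - size:
        starts.append(length - size)
    return starts


def sliding_windows(image: np.ndarray, spec: PatchSpec | None = None):
    """Enumerate test-time windows; pixels beyond the image are zero-filled.

    Returns ``[((row, col), patch), ...]`` with half-open extents; every
    image pixel is covered by at least one window.
    """
    spec = spec or PatchSpec()
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape
    k = spec.size
    padded = np.zeros((max(H, k), max(W, k)), dtype=np.float64)
    padded[:H, :W] = image
    out = []
    for r in window_starts(H, k, spec.stride):
        for c in window_starts(W, k, spec.stride):
            out.append(((r, c), padded[r:r + k, c:c + k].copy()))
    return out


def stitch_predictions(patches, coords, shape) -> np.ndarray:
    """Average overlapping patch predictions back into an HxW map.

    Zero-padded canvas regions (windows hanging off the image on small
    images) are discarded by cropping to ``shape``.
    """
    if len(patches) == 0:
        raise ValueError("empty patch list")
    H, W = shape
    k = np.asarray(patches[0]).shape[0]
    canvas = np.zeros((max(H, k), max(W, k)), dtype=np.float64)
    coverage = np.zeros_like(canvas)
    for patch, (r, c) in zip(patches, coords):
        canvas[r:r + k, c:c + k] += patch
        coverage[r:r + k, c:c + k] += 1.0
    covered = coverage > 0
    canvas[covered] /= coverage[covered]
    return canvas[:H, :W]


def make_splits(samples, scheme: str = "fixed", train_frac: float = 0.5,
                seed: int = 0) -> list:
    """Build train/test split plans.

    ``fixed`` partitions the (sorted) ids once — the first
    ``train_frac`` fraction trains, the rest tests, mirroring the fixed
    20/20 DRIVE and 20/8 CHASE protocols. ``leave_one_out`` returns one
    fold per sample (19 train / 1 test on the 20-image STARE set), each
    id tested exactly once.
    """
    ids = [s.id for s in samples]
    if scheme == "fixed":
        n_train = int(round(train_frac * len(ids)))
        return [SplitPlan(train_ids=ids[:n_train], test_ids=ids[n_train:],
                          scheme="fixed")]
    if scheme == "leave_one_out":
        if len(ids) < 2:
            raise ValueError("leave-one-out needs at least 2 samples")
        return [SplitPlan(train_ids=[j for j in ids if j != i], test_ids=[i],
                          scheme="leave_one_out") for i in ids]
    raise ValueError(f"unknown split scheme {scheme!r}")


def predict_image(model, plane: np.ndarray, spec: PatchSpec | None = None,
                  scale: float = 255.0, batch_size: int = 64) -> np.ndarray:
    """Sliding-window inference over one preprocessed grayscale plane.

    ``plane`` is on the 0-255 preprocessing scale; it is divided by
    ``scale`` before entering the network. Overlaps are averaged.
    """
    spec = spec or PatchSpec()
    windows = sliding_windows(plane, spec)
    coords = [w[0] for w in windows]
    patches = np.stack([w[1] for w in windows]).astype(np.float32) / scale
    model.eval()
    preds = []
    for i in range(0, len(patches), batch_size):
        out = model(patches[i:i + batch_size]).data[:, 0]
        preds.extend(out)
    return stitch_predictions(preds, coords, plane.shape)
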