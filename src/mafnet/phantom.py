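"""Synthetic ultrasound-like phantoms with ground-truth lesion masks.

Each phantom is a smooth background echo texture containing one or more
hypoechoic (darker) elliptical lesions, degraded by multiplicative
gamma-distributed speckle (mean 1) and Gaussian blur — the three artifacts
that make clinical ultrasound segmentation hard: low contrast, speckle
noise and blurred boundaries.  An RGB "dermoscopy-like" variant tints the
same phantom over a skin-tone gradient so the 3-channel input path can be
exercised.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError

# imageio is imported lazily inside write_dataset so purely in-memory use
# does not require it at import time.


@dataclass
class PhantomConfig:
    n_images: int = 32
    size: int = 256
    lesions_per_image: tuple[int, int] = (1, 3)
    lesion_axis_fraction: tuple[float, float] = (0.05, 0.25)
    contrast_drop: float = 0.5
    speckle_shape: float | None = 5.0  # gamma shape k; None disables speckle
    speckle_kind: str = "gamma"  # or "rayleigh"
    blur_sigma: float = 1.0
    seed: int = 0
    rgb: bool = False
    hyperechoic: bool = False  # bright lesions instead of dark

    def __post_init__(self):
        if self.n_images < 1 or self.size < 8:
            raise ConfigurationError("n_images >= 1 and size >= 8 required")
        lo, hi = self.lesions_per_image
        if lo < 0 or hi < lo:
            raise ConfigurationError(f"bad lesions_per_image range {self.lesions_per_image}")
        flo, fhi = self.lesion_axis_fraction
        if not (0 < flo <= fhi):
            raise ConfigurationError(f"bad lesion_axis_fraction range {self.lesion_axis_fraction}")
        if fhi >= 0.5:
            raise ConfigurationError(
                f"lesion_axis_fraction upper bound {fhi} >= 0.5: ellipse cannot fit the image")
        if not (0.0 <= self.contrast_drop < 1.0):
            raise ConfigurationError("contrast_drop must be in [0, 1)")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be positive (or None to disable)")
        if self.speckle_kind not in ("gamma", "rayleigh"):
            raise ConfigurationError(f"unknown speckle_kind {self.speckle_kind!r}")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be nonnegative")


@dataclass
class ImageSample:
    image: np.ndarray  # (C, H, W) float in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    """Smooth echo texture: heavily blurred white noise around mid-gray."""
    field = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8.0)
    std = field.std()
    if std > 0:
        field = field / std
    return np.clip(0.6 + 0.08 * field, 0.2, 0.95)


def _render_lesions(rng: np.random.Generator, cfg: PhantomConfig) -> np.ndarray:
    """Union of k random rotated ellipses, fully inside the frame."""
    size = cfg.size
    lo, hi = cfg.lesions_per_image
    k = int(rng.integers(lo, hi + 1))
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(k):
        a = rng.uniform(*cfg.lesion_axis_fraction) * size
        b = rng.uniform(*cfg.lesion_axis_fraction) * size
        theta = rng.uniform(0, math.pi)
        margin = max(a, b) + 1
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _speckle(rng: np.random.Generator, cfg: PhantomConfig, shape: tuple) -> np.ndarray:
    """Multiplicative noise field with mean 1."""
    if cfg.speckle_shape is None:
        return np.ones(shape)
    k = cfg.speckle_shape
    if cfg.speckle_kind == "gamma":
        return rng.gamma(shape=k, scale=1.0 / k, size=shape)
    # Rayleigh with scale chosen so the mean is 1; k rescales the spread
    ray = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=shape)
    return 1.0 + (ray - 1.0) / math.sqrt(k)


def generate_phantoms(cfg: PhantomConfig) -> list[ImageSample]:
    """Generate ``cfg.n_images`` phantom image/mask pairs (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for i in range(cfg.n_images):
        bg = _background(rng, cfg.size)
        lesions = _render_lesions(rng, cfg)
        attenuation = 1.0 + cfg.contrast_drop if cfg.hyperechoic else 1.0 - cfg.contrast_drop
        img = np.where(lesions, bg * attenuation, bg)
        img = img * _speckle(rng, cfg, img.shape)
        if cfg.blur_sigma > 0:
            img = gaussian_filter(img, sigma=cfg.blur_sigma)
        img = np.clip(img, 0.0, 1.0)
        if cfg.rgb:
            # skin-tone gradient plus a red-shifted tint of the texture
            grad = np.linspace(0.9, 1.0, cfg.size)[None, :] * np.ones((cfg.size, 1))
            image = np.stack([
                np.clip(img * 1.00 * grad, 0, 1),
                np.clip(img * 0.78 * grad, 0, 1),
                np.clip(img * 0.62 * grad, 0, 1),
            ])
        else:
            image = img[None]
        samples.append(ImageSample(image=image.astype(np.float64),
                                   mask=lesions.astype(np.uint8),
                                   id=f"phantom_{i:04d}"))
    return samples


def split(samples, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Seeded disjoint, exhaustive train/val/test partition."""
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"split fractions must sum to 1, got {fractions}")
    if len(fractions) != 3:
        raise ConfigurationError("exactly three split fractions (train, val, test) expected")
    n = len(samples)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    idx = {"train": order[:n_train],
           "val": order[n_train:n_train + n_val],
           "test": order[n_train + n_val:]}
    return tuple([samples[i] for i in idx[name]] for name in ("train", "val", "test"))


def write_dataset(samples, out_dir, splits=None) -> pd.DataFrame:
    """Write samples as 8-bit PNGs plus a manifest CSV.

    Layout: ``<out_dir>/images/<id>.png``, ``<out_dir>/masks/<id>.png``
    (mask values {0, 255}).  ``splits`` optionally maps sample id ->
    split name; unlisted ids get split "train".
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for s in samples:
        img8 = np.round(np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        img8 = img8[0] if img8.shape[0] == 1 else np.moveaxis(img8, 0, -1)
        image_path = out_dir / "images" / f"{s.id}.png"
        mask_path = out_dir / "masks" / f"{s.id}.png"
        iio.imwrite(image_path, img8)
        iio.imwrite(mask_path, (s.mask * 255).astype(np.uint8))
        records.append({"id": s.id,
                        "image_path": str(image_path),
                        "mask_path": str(mask_path),
                        "split": (splits or {}).get(s.id, "train")})
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
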