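"""Dataset I/O: manifest loading, image/mask reading, seeded batching.

Directory layout written by :mod:`mafnet.phantom` and read here:
``<root>/images/<id>.png``, ``<root>/masks/<id>.png``, ``<root>/manifest.csv``
with columns (id, image_path, mask_path, split).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from .errors import ContractError
from .phantom import ImageSample

SPLITS = ("train", "val", "test")


def load_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest CSV (existence of files, unique ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    required = {"id", "image_path", "mask_path", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"manifest missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ContractError(f"duplicate manifest ids: {dupes[:5]}")
    for col in ("image_path", "mask_path"):
        for p in df[col]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def load_image(image_path, size: int = 256) -> np.ndarray:
    """Load one image as (C, size, size) float in [0, 1] (bilinear resize)."""
    import imageio.v3 as iio

    if not Path(image_path).exists():
        raise FileNotFoundError(f"file not found: {image_path}")
    img = np.asarray(iio.imread(image_path))
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(np.float64) / 65535.0
    else:
        img = img.astype(np.float64)
    if img.ndim == 2:
        img = img[None]
    else:
        img = np.moveaxis(img[..., :3], -1, 0)
    chans = [sk_resize(c, (size, size), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True) for c in img]
    return np.clip(np.stack(chans), 0.0, 1.0)


def load_sample(image_path, mask_path, size: int = 256) -> ImageSample:
    """Load one image/mask pair, resize, normalize, binarize.

    Images are resized bilinearly and scaled to [0, 1]; masks are resized
    with nearest-neighbor interpolation (binarity preserved) and
    thresholded at 127/255.
    """
    import imageio.v3 as iio

    if not Path(mask_path).exists():
        raise FileNotFoundError(f"file not found: {mask_path}")
    img = load_image(image_path, size=size)
    mask = np.asarray(iio.imread(mask_path))
    if mask.ndim == 3:
        mask = mask[..., 0]
    mask = sk_resize(mask, (size, size), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    mask = (mask > 127).astype(np.uint8) if mask.max() > 1 else (mask > 0.5).astype(np.uint8)
    return ImageSample(image=img, mask=mask, id=Path(image_path).stem)


@dataclass
class SegmentationDataset:
    """In-memory arrays per split: images (N, C, H, W), masks (N, 1, H, W)."""

    arrays: dict  # split -> (images, masks, ids)

    @classmethod
    def from_manifest(cls, manifest, size: int = 256) -> "SegmentationDataset":
        if isinstance(manifest, (str, Path)):
            manifest = load_manifest(manifest)
        arrays = {}
        for split_name in SPLITS:
            rows = manifest[manifest["split"] == split_name]
            if rows.empty:
                continue
            samples = [load_sample(r.image_path, r.mask_path, size=size)
                       for r in rows.itertuples()]
            arrays[split_name] = cls._stack(samples)
        return cls(arrays=arrays)

    @classmethod
    def from_samples(cls, train, val=(), test=()) -> "SegmentationDataset":
        arrays = {}
        for name, group in (("train", train), ("val", val), ("test", test)):
            group = list(group)
            if group:
                arrays[name] = cls._stack(group)
        return cls(arrays=arrays)

    @staticmethod
    def _stack(samples):
        images = np.stack([s.image for s in samples]).astype(np.float32)
        masks = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
        ids = [s.id for s in samples]
        return images, masks, ids

    def images(self, split: str) -> np.ndarray:
        return self._get(split)[0]

    def masks(self, split: str) -> np.ndarray:
        return self._get(split)[1]

    def ids(self, split: str) -> list[str]:
        return self._get(split)[2]

    def n(self, split: str) -> int:
        return self._get(split)[0].shape[0] if split in self.arrays else 0

    def _get(self, split: str):
        if split not in self.arrays:
            raise ContractError(f"split {split!r} is empty or absent")
        return self.arrays[split]


def batches(dataset: SegmentationDataset, split: str, batch_size: int = 16,
            shuffle_seed: int | None = None):
    """Yield (image batch, mask batch) arrays; the final partial batch is kept.

    The train split is shuffled when ``shuffle_seed`` is given; val/test
    keep manifest order.
    """
    images, masks, _ = dataset._get(split)
    n = images.shape[0]
    if n == 0:
        raise ContractError(f"split {split!r} is empty")
    order = np.arange(n)
    if shuffle_seed is not None and split == "train":
        order = np.random.default_rng(shuffle_seed).permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        yield images[idx], masks[idx]
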