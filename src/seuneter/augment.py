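"""Cutout data augmentation.

Cutout zero-fills ``hole_n`` axis-aligned squares of edge ``mask_l`` at
uniformly random positions of the intensity image (labels are never
touched).  Masking local evidence forces the network to use global image
context instead of a few specific visual features, which curbs
over-fitting on small training sets.  Defaults (5 squares of edge 47)
match the study conditions at 512 x 512.

Squares are sampled independently (overlap allowed) and fully inside the
frame, so the number of newly zeroed pixels is bounded by
``hole_n * mask_l**2``.  Augmentation is applied offline: the training
split gains exactly one stored Cutout copy per original image, doubling
its size (350 -> 700 under the study split).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .schema_io import (
    DatasetManifest,
    ImageSample,
    LabelSchema,
    ManifestRecord,
    default_schema,
    load_sample,
    save_image,
    save_manifest,
)

__all__ = ["CutoutConfig", "apply_cutout", "cutout_mask", "augment_training_set"]


@dataclass
class CutoutConfig:
    hole_n: int = 5
    mask_l: int = 47
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hole_n < 0:
            raise ValueError("hole_n must be >= 0")
        if self.mask_l < 1:
            raise ValueError("mask_l must be >= 1")


def _sample_corners(
    shape: tuple[int, int], config: CutoutConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    h, w = shape
    if config.mask_l > min(h, w):
        raise ValueError(f"mask_l {config.mask_l} exceeds image edge {min(h, w)}")
    corners = []
    for _ in range(config.hole_n):
        rand_y = int(rng.integers(0, h - config.mask_l + 1))
        rand_x = int(rng.integers(0, w - config.mask_l + 1))
        corners.append((rand_y, rand_x))
    return corners


def cutout_mask(
    shape: tuple[int, int], config: CutoutConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Multiplicative 0/1 mask (zero inside every sampled square) plus the
    sampled (row, col) top-left corners, logged for reconstruction."""
    mask = np.ones(shape, dtype=np.float64)
    corners = _sample_corners(shape, config, rng)
    L = config.mask_l
    for ry, rx in corners:
        mask[ry : ry + L, rx : rx + L] = 0.0
    return mask, corners


def apply_cutout(
    image: ImageSample,
    config: CutoutConfig,
    rng: np.random.Generator | None = None,
    return_corners: bool = False,
):
    """Zero-fill the sampled squares of the [0, 1]-rescaled image.

    The label map paired with the image is shared untouched by the caller;
    only intensities change.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pix = image.as_float()
    mask, corners = cutout_mask(pix.shape, config, rng)
    out = ImageSample(pixels=pix * mask, intensity_range=(0.0, 1.0))
    if return_corners:
        return out, corners
    return out


def augment_training_set(
    manifest: DatasetManifest,
    config: CutoutConfig,
    out_dir: str | Path,
    schema: LabelSchema | None = None,
) -> DatasetManifest:
    """Write one Cutout copy per training image; val/test untouched.

    The augmented copy shares the original's label path.  Returns a new
    manifest whose train split is exactly doubled.
    """
    schema = schema or default_schema()
    train = manifest.split("train")
    if not train:
        raise ValueError("manifest has no train records")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4701]))
    records = list(manifest.records)
    for i, rec in enumerate(train):
        sample, _ = load_sample(rec.image_path, rec.label_path, schema)
        aug = apply_cutout(sample, config, rng)
        img16 = ImageSample(
            pixels=np.round(aug.as_float() * 0xFFFF).astype(np.uint16),
            intensity_range=(0.0, float(0xFFFF)),
        )
        path = out / f"cutout_{i:04d}.png"
        save_image(img16, path)
        records.append(ManifestRecord(str(path), rec.label_path, "train"))
    augmented = DatasetManifest(records=records, seed=manifest.seed)
    save_manifest(augmented, out / "manifest_augmented.csv")
    return augmented
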