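"""16-class cervical-spine label schema and PNG / manifest I/O.

The segmentation task uses a fixed schema of 16 classes on mid-sagittal
cervical-spine images: the background, seven vertebral bodies (C2..T1),
six intervertebral discs (C2/3..C7/T1), the spinal canal and the spinal
cord.  Label maps are single-channel 8-bit PNGs whose pixel value *is*
the class id; intensity images are 8- or 16-bit grayscale PNGs and are
preserved bit-exact on disk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LabelSchema",
    "ImageSample",
    "LabelMap",
    "ManifestRecord",
    "DatasetManifest",
    "default_schema",
    "load_sample",
    "load_labelmap",
    "save_labelmap",
    "save_image",
    "save_manifest",
    "load_manifest",
    "colorize_labelmap",
]

_VERTEBRA_NAMES = ("C2", "C3", "C4", "C5", "C6", "C7", "T1")
_DISC_NAMES = ("C2/3", "C3/4", "C4/5", "C5/6", "C6/7", "C7/T1")


@dataclass(frozen=True)
class LabelSchema:
    """The fixed id -> anatomical-name mapping and its rule subsets.

    ``vertebra_ids`` and ``disc_ids`` drive the adhesion-splitting rules;
    ``cord_id`` is excluded from the component-count reconciliation, so the
    number of counted structures is ``n_structures`` (= 14 by default).
    """

    entries: tuple[tuple[int, str], ...]
    background_id: int
    cord_id: int
    canal_id: int
    vertebra_ids: frozenset[int]
    disc_ids: frozenset[int]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.entries]
        if len(self.entries) != 16 or sorted(ids) != list(range(16)):
            raise ValueError("schema must contain exactly the ids 0..15")
        union = (
            self.vertebra_ids
            | self.disc_ids
            | {self.canal_id, self.cord_id, self.background_id}
        )
        n = len(self.vertebra_ids) + len(self.disc_ids) + 3
        if union != set(range(16)) or n != 16:
            raise ValueError("vertebra/disc/canal/cord/background ids must partition 0..15")

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(cid for cid, _ in self.entries)

    @property
    def n_structures(self) -> int:
        """Count of classes excluding background and cord (the '14' of the
        component-count reconciliation rule)."""
        return self.n_classes - 2

    @property
    def foreground_ids(self) -> tuple[int, ...]:
        return tuple(cid for cid in self.class_ids if cid != self.background_id)

    def name_of(self, class_id: int) -> str:
        for cid, name in self.entries:
            if cid == class_id:
                return name
        raise KeyError(f"class id {class_id} not in schema")

    def id_of(self, name: str) -> int:
        for cid, cname in self.entries:
            if cname == name:
                return cid
        raise KeyError(f"class name {name!r} not in schema")


def default_schema() -> LabelSchema:
    """Background=0, bodies C2..T1 = 1..7 (superior to inferior), discs
    C2/3..C7/T1 = 8..13, canal=14, cord=15.

    The numeric assignment is a repository convention; only the category
    list itself is fixed by the task.
    """
    entries = [(0, "background")]
    entries += [(i + 1, n) for i, n in enumerate(_VERTEBRA_NAMES)]
    entries += [(i + 8, n) for i, n in enumerate(_DISC_NAMES)]
    entries += [(14, "spinal canal"), (15, "spinal cord")]
    return LabelSchema(
        entries=tuple(entries),
        background_id=0,
        cord_id=15,
        canal_id=14,
        vertebra_ids=frozenset(range(1, 8)),
        disc_ids=frozenset(range(8, 14)),
    )


@dataclass
class ImageSample:
    """A 2-D grayscale intensity image.

    ``pixels`` keeps the native integer dtype when loaded from disk; use
    :meth:`as_float` to get the [0, 1] rescaling fed to the network.
    """

    pixels: np.ndarray
    intensity_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < 32 or w < 32:
            raise ValueError(f"image must be at least 32x32, got {h}x{w}")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_float(self) -> np.ndarray:
        """Rescale intensities to [0, 1] floats using ``intensity_range``."""
        lo, hi = self.intensity_range
        span = hi - lo if hi > lo else 1.0
        return np.clip((self.pixels.astype(np.float64) - lo) / span, 0.0, 1.0)


@dataclass
class LabelMap:
    """An integer class map aligned with an :class:`ImageSample`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"label map must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer valued")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def validate(self, schema: LabelSchema) -> "LabelMap":
        bad = ~np.isin(self.labels, schema.class_ids)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"label {int(self.labels[r, c])} not in schema (first at pixel ({r}, {c}))"
            )
        return self

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy())


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    label_path: str
    split: str


@dataclass
class DatasetManifest:
    """Paths of (image, label) pairs with their train/val/test assignment."""

    records: list[ManifestRecord]
    seed: int = 0

    def split(self, name: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == name]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.split] = out.get(r.split, 0) + 1
        return out


def _read_gray_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode == "I;16":
            arr = np.array(im, dtype=np.uint16)
        elif im.mode in ("L", "P"):
            arr = np.array(im.convert("L"), dtype=np.uint8)
        elif im.mode == "I":
            arr = np.array(im, dtype=np.int32)
            if arr.max(initial=0) <= 0xFFFF and arr.min(initial=0) >= 0:
                arr = arr.astype(np.uint16)
        else:
            arr = np.array(im.convert("L"), dtype=np.uint8)
    if arr.ndim != 2:
        raise ValueError(f"{path} did not decode to a 2-D raster (shape {arr.shape})")
    return arr


def load_labelmap(path: str | Path, schema: LabelSchema | None = None) -> LabelMap:
    arr = _read_gray_png(path)
    lm = LabelMap(arr.astype(np.uint8))
    if schema is not None:
        lm.validate(schema)
    return lm


def load_sample(
    image_path: str | Path, label_path: str | Path, schema: LabelSchema
) -> tuple[ImageSample, LabelMap]:
    """Load an (image, label) PNG pair, checking shape agreement and that
    every label value resolves through the schema."""
    img = _read_gray_png(image_path)
    lab = _read_gray_png(label_path)
    if img.shape != lab.shape:
        raise ValueError(
            f"shape mismatch: image {img.shape} vs label {lab.shape} "
            f"({image_path} / {label_path})"
        )
    max_native = float(np.iinfo(img.dtype).max) if np.issubdtype(img.dtype, np.integer) else 1.0
    sample = ImageSample(pixels=img, intensity_range=(0.0, max_native))
    labelmap = LabelMap(lab.astype(np.uint8)).validate(schema)
    return sample, labelmap


def save_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Write a label map as a lossless single-channel 8-bit PNG."""
    arr = labelmap.labels
    if arr.min(initial=0) < 0 or arr.max(initial=0) > 255:
        raise ValueError("label values must fit in 8 bits")
    Image.fromarray(arr.astype(np.uint8)).save(path, format="PNG")


def save_image(sample: ImageSample, path: str | Path) -> None:
    """Write an intensity image losslessly (8-bit for uint8, 16-bit otherwise)."""
    arr = sample.pixels
    if arr.dtype == np.uint8:
        Image.fromarray(arr).save(path, format="PNG")
    else:
        arr16 = np.clip(np.asarray(arr), 0, 0xFFFF).astype(np.uint16)
        Image.fromarray(arr16).save(path, format="PNG")


_PALETTE = np.array(
    [
        (0, 0, 0),
        (230, 90, 70), (240, 130, 60), (250, 170, 50), (250, 210, 60),
        (210, 230, 70), (160, 230, 80), (110, 220, 90),
        (70, 200, 150), (60, 180, 200), (60, 140, 230), (80, 100, 240),
        (130, 80, 240), (180, 70, 230),
        (220, 220, 220), (255, 255, 255),
    ],
    dtype=np.uint8,
)


def colorize_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Optional RGB export for visual inspection (not for round-tripping)."""
    rgb = _PALETTE[labelmap.labels]
    Image.fromarray(rgb).save(path, format="PNG")


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "label_path", "split"])
        for rec in manifest.records:
            writer.writerow([rec.image_path, rec.label_path, rec.split])


def load_manifest(path: str | Path, seed: int = 0) -> DatasetManifest:
    records: list[ManifestRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["split"] not in ("train", "val", "test"):
                raise ValueError(f"unknown split {row['split']!r}")
            records.append(ManifestRecord(row["image_path"], row["label_path"], row["split"]))
    return DatasetManifest(records=records, seed=seed)
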