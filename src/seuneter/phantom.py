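"""Synthetic sagittal-spine phantoms with exact 16-class ground truth.

The generator draws the structures the segmentation task assumes — a
column of 7 vertebral bodies stacked superior to inferior with 6
intervertebral discs between them, a spinal-canal band posterior to the
column, and the spinal cord strictly inside the canal — as axis-aligned
rectangles/bands on a noisy background.  Shapes are deliberately simple:
the post-processing and metric modules depend only on topology (component
counts, adjacency, interior holes), which rectangles expose exactly, so
every cleanup rule has a countable oracle.

Structures are separated by thin background gaps, mirroring the annotation
convention in which the 14 non-background, non-cord structures form 14
distinct connected domains.

:func:`make_degraded_prediction` corrupts a ground-truth map with the
anomaly kinds a trained network actually produces (stray blobs, small
islands, vertebra/disc adhesion, interior cavities) so the post-processing
stages can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .schema_io import (
    DatasetManifest,
    ImageSample,
    LabelMap,
    LabelSchema,
    ManifestRecord,
    default_schema,
    save_image,
    save_labelmap,
    save_manifest,
)

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "generate_dataset",
    "make_degraded_prediction",
    "AddLargeBlob",
    "AddSmallIsland",
    "MergeAdjacent",
    "PunchHole",
]


def _default_intensity_means() -> np.ndarray:
    # distinct and monotone in class id so a tiny network can separate the
    # classes in a handful of epochs
    return np.array([0.05] + [0.08 + 0.055 * c for c in range(1, 16)])


@dataclass
class PhantomConfig:
    """Geometry and appearance of one phantom.

    Extents left as ``None`` are derived from the frame size; explicit
    values override the derivation.  ``jitter_sd`` perturbs horizontal
    structure placement per sample (in pixels); ``noise_sd`` is the
    additive Gaussian intensity noise on the [0, 1] scale.
    """

    height: int = 512
    width: int = 512
    n_vertebrae: int = 7
    n_discs: int = 6
    vertebra_size: tuple[int, int] | None = None  # (rows, cols)
    disc_size: tuple[int, int] | None = None
    canal_width: int | None = None
    cord_width: int | None = None
    gap: int | None = None  # background rows between stacked structures
    intensity_means: np.ndarray = field(default_factory=_default_intensity_means)
    noise_sd: float = 0.03
    jitter_sd: float = 2.0
    corner_radius: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discs != self.n_vertebrae - 1:
            raise ValueError("n_discs must equal n_vertebrae - 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.intensity_means) != 16:
            raise ValueError("intensity_means must have 16 entries")

    # -- derived geometry -------------------------------------------------

    def resolved(self) -> "_Geometry":
        H, W = self.height, self.width
        y0, y1 = round(0.05 * H), round(0.95 * H)
        span = y1 - y0
        gap = self.gap if self.gap is not None else max(1, round(H / 170))
        nv, nd = self.n_vertebrae, self.n_discs
        n_gaps = nv + nd - 1
        if self.vertebra_size is None:
            # vertebra ~3x taller than a disc
            hv = (span - n_gaps * gap) * 3 // (3 * nv + nd)
            wv = round(0.36 * W)
            vert = (hv, wv)
        else:
            vert = self.vertebra_size
        if self.disc_size is None:
            disc = (max(1, vert[0] // 3), vert[1])
        else:
            disc = self.disc_size
        canal_w = self.canal_width if self.canal_width is not None else round(0.16 * W)
        cord_w = self.cord_width if self.cord_width is not None else max(2, round(0.07 * W))
        geom = _Geometry(
            y0=y0,
            gap=gap,
            vert=vert,
            disc=disc,
            col_x0=round(0.12 * W),
            canal_x0=round(0.58 * W),
            canal_w=canal_w,
            cord_w=cord_w,
        )
        # fit checks, naming the violated extent
        total = nv * vert[0] + nd * disc[0] + n_gaps * gap
        if vert[0] < 1 or disc[0] < 1:
            raise ValueError(f"frame too small: vertebra/disc heights {vert[0]}/{disc[0]} < 1")
        if total > span:
            raise ValueError(f"column height {total} exceeds vertical span {span}")
        if geom.col_x0 + vert[1] >= geom.canal_x0:
            raise ValueError("vertebral column width overlaps the canal band")
        if cord_w >= canal_w:
            raise ValueError(f"cord_width {cord_w} must be < canal_width {canal_w}")
        if cord_w + 2 > canal_w:
            raise ValueError("canal band too narrow to enclose the cord")
        if geom.canal_x0 + canal_w >= W:
            raise ValueError("canal band extends past the right frame edge")
        return geom


@dataclass
class _Geometry:
    y0: int
    gap: int
    vert: tuple[int, int]
    disc: tuple[int, int]
    col_x0: int
    canal_x0: int
    canal_w: int
    cord_w: int


def _paint_rect(labels: np.ndarray, r0: int, r1: int, c0: int, c1: int, value: int) -> None:
    labels[r0:r1, c0:c1] = value


def generate_phantom(
    config: PhantomConfig, schema: LabelSchema | None = None
) -> tuple[ImageSample, LabelMap]:
    """Draw one phantom; pure function of (config, seed)."""
    schema = schema or default_schema()
    geom = config.resolved()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2861]))
    H, W = config.height, config.width
    labels = np.zeros((H, W), dtype=np.uint8)

    vert_ids = sorted(schema.vertebra_ids)
    disc_ids = sorted(schema.disc_ids)
    hv, wv = geom.vert
    hd, wd = geom.disc

    def jitter() -> int:
        if config.jitter_sd <= 0:
            return 0
        return int(round(rng.normal(0.0, config.jitter_sd)))

    max_dx = max(0, geom.canal_x0 - geom.col_x0 - max(wv, wd) - 2)
    y = geom.y0 + max(0, jitter())
    for i in range(config.n_vertebrae):
        dx = int(np.clip(geom.col_x0 + jitter(), 1, geom.col_x0 + max_dx))
        _paint_rect(labels, y, y + hv, dx, dx + wv, vert_ids[i])
        y += hv + geom.gap
        if i < config.n_discs:
            ddx = int(np.clip(geom.col_x0 + jitter(), 1, geom.col_x0 + max_dx))
            _paint_rect(labels, y, y + hd, ddx, ddx + wd, disc_ids[i])
            y += hd + geom.gap

    # canal band with the cord strictly inside it
    cy0, cy1 = geom.y0, round(0.95 * H)
    cx0 = geom.canal_x0
    _paint_rect(labels, cy0, cy1, cx0, cx0 + geom.canal_w, schema.canal_id)
    inset_c = (geom.canal_w - geom.cord_w) // 2
    inset_r = max(2, geom.gap + 1)
    _paint_rect(
        labels,
        cy0 + inset_r,
        cy1 - inset_r,
        cx0 + inset_c,
        cx0 + inset_c + geom.cord_w,
        schema.cord_id,
    )

    means = np.asarray(config.intensity_means, dtype=np.float64)
    image = means[labels]
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    sample = ImageSample(pixels=image, intensity_range=(0.0, 1.0))
    return sample, LabelMap(labels).validate(schema)


def generate_dataset(
    config: PhantomConfig,
    n_train: int,
    n_val: int,
    n_test: int,
    out_dir: str | Path,
    schema: LabelSchema | None = None,
) -> DatasetManifest:
    """Write phantom pairs and a CSV manifest; per-sample seeds derive
    deterministically from ``config.seed`` so regeneration is bit-identical."""
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split counts must be >= 0")
    schema = schema or default_schema()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[ManifestRecord] = []
    idx = 0
    for split, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        for _ in range(count):
            child = int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0] % (2**31))
            cfg_i = PhantomConfig(**{**config.__dict__, "seed": child})
            sample, labelmap = generate_phantom(cfg_i, schema)
            # quantize intensities to 16-bit for lossless PNG storage
            img16 = ImageSample(
                pixels=np.round(sample.as_float() * 0xFFFF).astype(np.uint16),
                intensity_range=(0.0, float(0xFFFF)),
            )
            ipath = out / f"img_{idx:04d}.png"
            lpath = out / f"lab_{idx:04d}.png"
            save_image(img16, ipath)
            save_labelmap(labelmap, lpath)
            records.append(ManifestRecord(str(ipath), str(lpath), split))
            idx += 1
    manifest = DatasetManifest(records=records, seed=config.seed)
    save_manifest(manifest, out / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# defect fixtures


@dataclass(frozen=True)
class AddLargeBlob:
    class_id: int
    area: int


@dataclass(frozen=True)
class AddSmallIsland:
    class_id: int
    area: int


@dataclass(frozen=True)
class MergeAdjacent:
    class_a: int
    class_b: int


@dataclass(frozen=True)
class PunchHole:
    class_id: int
    area: int


Defect = AddLargeBlob | AddSmallIsland | MergeAdjacent | PunchHole


def _require_present(labels: np.ndarray, class_id: int) -> np.ndarray:
    mask = labels == class_id
    if not mask.any():
        raise ValueError(f"defect class {class_id} not present in truth")
    return mask


def _free_positions(free: np.ndarray, h: int, w: int) -> np.ndarray:
    """Top-left corners (r, c) of h x w windows lying fully inside ``free``."""
    ok = ndimage.minimum_filter(free.astype(np.uint8), size=(h, w), mode="constant")
    # minimum_filter is centered; shift to top-left corner convention
    rr, cc = np.nonzero(ok)
    r0 = rr - (h - 1) // 2
    c0 = cc - (w - 1) // 2
    keep = (r0 >= 0) & (c0 >= 0) & (r0 + h <= free.shape[0]) & (c0 + w <= free.shape[1])
    return np.stack([r0[keep], c0[keep]], axis=1)


def _paint_area(labels: np.ndarray, r0: int, c0: int, h: int, w: int, area: int, value: int) -> int:
    """Paint exactly ``area`` pixels row-major inside an h x w box; returns painted count."""
    painted = 0
    for r in range(r0, r0 + h):
        take = min(w, area - painted)
        if take <= 0:
            break
        labels[r, c0 : c0 + take] = value
        painted += take
    return painted


def _add_blob(labels: np.ndarray, class_id: int, area: int, rng: np.random.Generator, margin: int) -> None:
    side = max(1, int(round(np.sqrt(area))))
    h = side
    w = side if side * side >= area else side + 1
    while h * w < area:
        h += 1
    free = labels == 0
    # keep a background margin so the blob stays its own connected domain
    pos = _free_positions(free, h + 2 * margin, w + 2 * margin)
    if len(pos) == 0:
        raise ValueError(f"no background window of {h}x{w} available for a blob of area {area}")
    r0, c0 = pos[rng.integers(len(pos))]
    _paint_area(labels, int(r0) + margin, int(c0) + margin, h, w, area, class_id)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    comp, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n <= 1:
        return mask
    areas = np.bincount(comp.ravel())[1:]
    return comp == (int(np.argmax(areas)) + 1)


def _merge(labels: np.ndarray, a: int, b: int, bridge_width: int = 2) -> None:
    # bridge the principal (anatomical) component of each class, ignoring
    # any stray blobs other defects may have added
    ma = _largest_component(_require_present(labels, a))
    mb = _largest_component(_require_present(labels, b))
    ra = np.nonzero(ma.any(axis=1))[0]
    rb = np.nonzero(mb.any(axis=1))[0]
    if ra.max() < rb.min():
        upper, lower, top, bot = ma, mb, ra.max(), rb.min()
    elif rb.max() < ra.min():
        upper, lower, top, bot = mb, ma, rb.max(), ra.min()
    else:
        raise ValueError(f"classes {a} and {b} are not vertically separated; cannot bridge")
    ca = np.nonzero(upper.any(axis=0))[0]
    cb = np.nonzero(lower.any(axis=0))[0]
    lo, hi = max(ca.min(), cb.min()), min(ca.max(), cb.max())
    if hi < lo:
        raise ValueError(f"classes {a} and {b} share no columns; cannot bridge")
    mid = (lo + hi) // 2
    c0 = int(np.clip(mid - bridge_width // 2, lo, hi - bridge_width + 1))
    labels[top + 1 : bot, c0 : c0 + bridge_width] = a


def _punch(labels: np.ndarray, class_id: int, area: int, rng: np.random.Generator, background: int) -> None:
    mask = _require_present(labels, class_id)
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    cols = np.nonzero(interior.any(axis=0))[0]
    if len(cols) == 0:
        raise ValueError(f"class {class_id} has no interior to punch")
    iw = len(cols)
    w = max(1, min(iw, int(round(np.sqrt(area)))))
    h = -(-area // w)  # ceil
    pos = _free_positions(interior, h, w)
    while len(pos) == 0 and w > 1:
        w -= 1
        h = -(-area // w)
        pos = _free_positions(interior, h, w)
    if len(pos) == 0:
        raise ValueError(f"class {class_id} interior cannot host a hole of area {area}")
    r0, c0 = pos[rng.integers(len(pos))]
    _paint_area(labels, int(r0), int(c0), h, w, area, background)


def make_degraded_prediction(
    truth: LabelMap,
    defects: Sequence[Defect],
    seed: int = 0,
    schema: LabelSchema | None = None,
) -> LabelMap:
    """Return ``truth`` corrupted exactly as the defect list specifies.

    Blob and hole areas are hit exactly (well within the +-10% contract);
    an empty defect list returns an identical copy.
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40901]))
    labels = truth.labels.copy()
    for defect in defects:
        if isinstance(defect, AddLargeBlob):
            _require_present(labels, defect.class_id)
            _add_blob(labels, defect.class_id, defect.area, rng, margin=3)
        elif isinstance(defect, AddSmallIsland):
            _require_present(labels, defect.class_id)
            _add_blob(labels, defect.class_id, defect.area, rng, margin=2)
        elif isinstance(defect, MergeAdjacent):
            _merge(labels, defect.class_a, defect.class_b)
        elif isinstance(defect, PunchHole):
            _punch(labels, defect.class_id, defect.area, rng, schema.background_id)
        else:  # pragma: no cover - guarded by typing
            raise TypeError(f"unknown defect {defect!r}")
    return LabelMap(labels).validate(schema)
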