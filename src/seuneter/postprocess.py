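"""Prior-knowledge correction of predicted label maps, in four fixed stages.

A trained network's raw argmax maps show three recurring anomaly kinds:
stray blobs far from the spine, small mislabeled islands, and adhesions
where a vertebra and a disc (or the cord) fuse into one region.  Because
the anatomy is constant — 14 separate structures once the spinal cord is
set aside (7 vertebral bodies, 6 discs, the canal), with the cord inside
the canal — the predictions can be corrected by connected-component
reasoning alone:

1. ``remove_large_anomalies`` (external, coarse): connected components of
   the non-background mask are judged at block scale — a component counts
   as a block when any of it survives a morphological opening with a
   ``ker_l`` square; blocks with area below ``eta_l`` are erased to
   background.  Components the coarse opening suppresses entirely (thin
   true structures such as discs) keep their labels and are left to the
   fine pass.
2. ``remove_small_anomalies`` (external, fine): per-class connected
   components below ``eta_s`` are erased.
3. ``reconcile_component_count`` (internal): the union of all classes
   except background and cord is labeled and its component count K is
   compared to the expected 14.  K = 14: each component is relabeled
   uniformly to its majority class; K > 14: the surplus smallest
   components are erased; K < 14: adhesions are split
   (:func:`split_adhesions`), cutting thin bridges in mixed
   vertebra+disc components with a ``ker_s`` opening and dropping disc
   fragments below ``eta_d``.
4. ``fill_cavities`` (internal): interior background holes in the cord
   and canal are filled with the enclosing class.

All area comparisons are strict (area < threshold is removed; equality is
kept).  Components use 8-connectivity, holes 4-connectivity.  The full
chain is idempotent and each stage only moves pixels toward background or
toward a majority class, never inventing structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .schema_io import LabelMap, LabelSchema, default_schema

__all__ = [
    "PostprocessConfig",
    "StageRecord",
    "SegmentationResult",
    "remove_large_anomalies",
    "remove_small_anomalies",
    "reconcile_component_count",
    "split_adhesions",
    "fill_cavities",
    "postprocess_all",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class PostprocessConfig:
    ker_l: int = 7
    ker_s: int = 3
    eta_l: int = 2000
    eta_s: int = 100
    eta_d: int = 30
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.ker_l > self.ker_s >= 1:
            raise ValueError("need ker_l > ker_s >= 1")
        if not self.eta_l > self.eta_s > self.eta_d >= 1:
            raise ValueError("need eta_l > eta_s > eta_d >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        return _EIGHT if self.connectivity == 8 else _FOUR

    @classmethod
    def for_shape(cls, shape: tuple[int, int], **overrides) -> "PostprocessConfig":
        """Defaults are calibrated at 512 x 512; area thresholds scale with
        image area and kernels with linear size (floored at 3 and 1)."""
        h, w = shape
        area_scale = (h * w) / (512 * 512)
        lin_scale = min(h, w) / 512
        base = cls()
        values = dict(
            ker_l=max(3, round(base.ker_l * lin_scale)),
            ker_s=max(1, round(base.ker_s * lin_scale)),
            eta_l=max(3, round(base.eta_l * area_scale)),
            eta_s=max(2, round(base.eta_s * area_scale)),
            eta_d=max(1, round(base.eta_d * area_scale)),
            connectivity=base.connectivity,
        )
        values.update(overrides)
        if values["ker_l"] <= values["ker_s"]:
            values["ker_l"] = values["ker_s"] + 2
        return cls(**values)


@dataclass(frozen=True)
class StageRecord:
    stage: str
    pixels_changed: int
    components_removed: int
    notes: dict = field(default_factory=dict)


@dataclass
class SegmentationResult:
    prediction: LabelMap
    stage_log: list[StageRecord] = field(default_factory=list)

    @classmethod
    def from_labelmap(cls, prediction: LabelMap) -> "SegmentationResult":
        return cls(prediction=prediction.copy(), stage_log=[])

    def _log(self, stage: str, before: np.ndarray, removed: int, **notes) -> None:
        changed = int(np.count_nonzero(before != self.prediction.labels))
        self.stage_log.append(StageRecord(stage, changed, removed, dict(notes)))

    def has_stage(self, stage: str) -> bool:
        return any(rec.stage == stage for rec in self.stage_log)


def _square(k: int) -> np.ndarray:
    return np.ones((k, k), dtype=bool)


def _majority(labels: np.ndarray, mask: np.ndarray, candidates: set[int]) -> tuple[int, bool]:
    """Majority class of ``mask`` among ``candidates``; ties -> smaller id."""
    counts = np.bincount(labels[mask], minlength=16)
    allowed = sorted(candidates)
    sub = counts[allowed]
    best = int(np.argmax(sub))  # argmax returns the first (smallest id) on ties
    tie = int(np.count_nonzero(sub == sub[best])) > 1
    return allowed[best], tie


def remove_large_anomalies(
    result: SegmentationResult,
    config: PostprocessConfig,
    schema: LabelSchema | None = None,
) -> SegmentationResult:
    schema = schema or default_schema()
    labels = result.prediction.labels
    before = labels.copy()
    fg = labels != schema.background_id
    removed = 0
    if fg.any():
        opened = ndimage.binary_opening(fg, structure=_square(config.ker_l))
        comp, n = ndimage.label(fg, structure=config.structure)
        if n:
            areas = np.bincount(comp.ravel())[1:]
            # a component is a coarse-scale block iff the opening keeps any of it
            block_ids = np.unique(comp[opened])
            block_ids = block_ids[block_ids > 0]
            small = [i for i in block_ids if areas[i - 1] < config.eta_l]
            if small:
                labels[np.isin(comp, small)] = schema.background_id
                removed = len(small)
    result._log("remove_large", before, removed)
    return result


def remove_small_anomalies(
    result: SegmentationResult,
    config: PostprocessConfig,
    schema: LabelSchema | None = None,
) -> SegmentationResult:
    if not result.has_stage("remove_large"):
        raise ValueError("remove_small_anomalies requires remove_large_anomalies first")
    schema = schema or default_schema()
    labels = result.prediction.labels
    before = labels.copy()
    removed = 0
    for c in schema.foreground_ids:
        mask = labels == c
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=config.structure)
        areas = np.bincount(comp.ravel())[1:]
        small = np.nonzero(areas < config.eta_s)[0] + 1
        if len(small):
            labels[np.isin(comp, small)] = schema.background_id
            removed += len(small)
    result._log("remove_small", before, removed)
    return result


def _structural_union(labels: np.ndarray, schema: LabelSchema) -> np.ndarray:
    return (labels != schema.background_id) & (labels != schema.cord_id)


def _relabel_components(
    labels: np.ndarray,
    comp: np.ndarray,
    comp_ids: np.ndarray,
    candidates: set[int],
) -> tuple[int, int]:
    """Uniform majority relabeling of each listed component; returns
    (pixels changed, ties encountered)."""
    changed = 0
    ties = 0
    for cid in comp_ids:
        mask = comp == cid
        cls, tie = _majority(labels, mask, candidates)
        ties += tie
        changed += int(np.count_nonzero(labels[mask] != cls))
        labels[mask] = cls
    return changed, ties


def _split_adhesions_inplace(
    labels: np.ndarray, config: PostprocessConfig, schema: LabelSchema
) -> dict:
    """Shared worker for the K < expected branch; mutates ``labels``."""
    notes: dict = {"ties": 0}
    union = _structural_union(labels, schema)
    comp, n = ndimage.label(union, structure=config.structure)
    vert = set(schema.vertebra_ids)
    disc = set(schema.disc_ids)
    # cut thin bridges inside components mixing vertebra and disc classes
    cut = 0
    for cid in range(1, n + 1):
        mask = comp == cid
        present = set(np.unique(labels[mask]))
        if present & vert and present & disc:
            opened = ndimage.binary_opening(mask, structure=_square(config.ker_s))
            bridge = mask & ~opened
            labels[bridge] = schema.background_id
            cut += int(np.count_nonzero(bridge))
    notes["bridge_pixels_cut"] = cut
    # vertebra union: majority relabel per component
    vmask = np.isin(labels, sorted(vert))
    vcomp, vn = ndimage.label(vmask, structure=config.structure)
    _, t = _relabel_components(labels, vcomp, np.arange(1, vn + 1), vert)
    notes["ties"] += t
    # disc union: drop sub-eta_d fragments, then majority relabel
    dmask = np.isin(labels, sorted(disc))
    dcomp, dn = ndimage.label(dmask, structure=config.structure)
    if dn:
        areas = np.bincount(dcomp.ravel())[1:]
        small = np.nonzero(areas < config.eta_d)[0] + 1
        if len(small):
            labels[np.isin(dcomp, small)] = schema.background_id
            dcomp[np.isin(dcomp, small)] = 0
        notes["disc_fragments_removed"] = int(len(small))
        keep = [i for i in range(1, dn + 1) if (dcomp == i).any()]
        _, t = _relabel_components(labels, dcomp, np.array(keep, dtype=int), disc)
        notes["ties"] += t
    return notes


def reconcile_component_count(
    result: SegmentationResult,
    schema: LabelSchema | None = None,
    config: PostprocessConfig | None = None,
) -> SegmentationResult:
    schema = schema or default_schema()
    config = config or PostprocessConfig()
    labels = result.prediction.labels
    before = labels.copy()
    expected = schema.n_structures
    union = _structural_union(labels, schema)
    comp, K = ndimage.label(union, structure=config.structure)
    removed = 0
    candidates = set(schema.foreground_ids) - {schema.cord_id}
    if K == expected:
        _, ties = _relabel_components(labels, comp, np.arange(1, K + 1), candidates)
        result._log("reconcile", before, removed, K=int(K), action="relabel", ties=ties)
    elif K > expected:
        areas = np.bincount(comp.ravel())[1:]
        order = np.argsort(areas, kind="stable") + 1
        surplus = order[: K - expected]
        labels[np.isin(comp, surplus)] = schema.background_id
        comp[np.isin(comp, surplus)] = 0
        removed = int(len(surplus))
        keep = np.array([i for i in range(1, K + 1) if i not in set(surplus.tolist())])
        _, ties = _relabel_components(labels, comp, keep, candidates)
        result._log("reconcile", before, removed, K=int(K), action="remove_extra", ties=ties)
    else:
        notes = _split_adhesions_inplace(labels, config, schema)
        result._log("reconcile", before, notes.pop("disc_fragments_removed", 0),
                    K=int(K), action="split_adhesions", **notes)
    return result


def split_adhesions(
    result: SegmentationResult,
    schema: LabelSchema | None = None,
    config: PostprocessConfig | None = None,
) -> SegmentationResult:
    """Standalone entry to the adhesion-splitting branch."""
    schema = schema or default_schema()
    config = config or PostprocessConfig()
    before = result.prediction.labels.copy()
    notes = _split_adhesions_inplace(result.prediction.labels, config, schema)
    result._log("split_adhesions", before, notes.pop("disc_fragments_removed", 0), **notes)
    return result


def fill_cavities(
    result: SegmentationResult, schema: LabelSchema | None = None
) -> SegmentationResult:
    """Fill interior background holes of the cord and canal with the
    enclosing class; no non-background pixel is ever altered."""
    schema = schema or default_schema()
    labels = result.prediction.labels
    before = labels.copy()
    for c in (schema.cord_id, schema.canal_id):
        mask = labels == c
        if not mask.any():
            continue
        filled = ndimage.binary_fill_holes(mask, structure=_FOUR)
        add = filled & ~mask & (labels == schema.background_id)
        labels[add] = c
    result._log("fill_cavities", before, 0)
    return result


def postprocess_all(
    prediction: LabelMap,
    schema: LabelSchema | None = None,
    config: PostprocessConfig | None = None,
) -> SegmentationResult:
    """Apply the four stages in their fixed order; idempotent."""
    schema = schema or default_schema()
    config = config or PostprocessConfig.for_shape(prediction.shape)
    result = SegmentationResult.from_labelmap(prediction)
    remove_large_anomalies(result, config, schema)
    remove_small_anomalies(result, config, schema)
    reconcile_component_count(result, schema, config)
    fill_cavities(result, schema)
    return result
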