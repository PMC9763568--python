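"""Combined cross-entropy + soft-Dice objective and IOU/DSC evaluation.

The training objective is ``Loss = lambda * CeLoss + (1 - lambda) * DeLoss``
with ``lambda = 0.5`` by default: cross-entropy judges every pixel's class
posterior individually (a microscopic, well-conditioned signal), while the
Dice term measures region overlap globally and so counteracts the extreme
foreground/background imbalance of spine images.

Soft Dice for class c is ``(2 * sum(p_c * g_c) + eps) / (sum(p_c) +
sum(g_c) + eps)``; a class absent from both prediction and truth scores 1
through ``eps`` (absence correctly predicted), and the Dice loss is one
minus the mean over the included classes (foreground only by default, so
the dominant background cannot swamp the term).

Evaluation reports per-class IOU = TP/(TP+FP+FN) and DSC =
2TP/(2TP+FP+FN), pooled (micro-averaged) over all images of a split, and
their unweighted class means.  Means are reported both over all 16
classes (background included) and over the 15 foreground classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema_io import LabelMap, LabelSchema, default_schema

__all__ = [
    "LossConfig",
    "softmax",
    "one_hot",
    "ce_loss",
    "dice_loss",
    "combined_loss",
    "combined_loss_and_grad",
    "MetricsReport",
    "evaluate",
]

_LOG_CLAMP = 1e-12


@dataclass
class LossConfig:
    lambda_weight: float = 0.5
    dice_smooth: float = 1e-6
    include_background_in_dice: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be > 0")


def softmax(logits: np.ndarray, axis: int = -3) -> np.ndarray:
    """Stable softmax over the class axis of (..., C, H, W) score maps."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(..., H, W) int labels -> (..., C, H, W) one-hot indicators."""
    eye = np.eye(n_classes, dtype=np.float64)
    g = eye[labels]  # (..., H, W, C)
    return np.moveaxis(g, -1, -3)


def _as_probs(probs: np.ndarray) -> np.ndarray:
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim == 3:
        p = p[None]
    if p.ndim != 4:
        raise ValueError(f"expected (C, H, W) or (N, C, H, W) probabilities, got {p.shape}")
    return p


def _as_truth(truth: np.ndarray | LabelMap, n_classes: int, batch: int) -> np.ndarray:
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    if t.ndim == 2:
        t = t[None]
    if t.shape[0] != batch:
        raise ValueError(f"truth batch {t.shape[0]} != probability batch {batch}")
    return one_hot(t, n_classes)


def ce_loss(probs: np.ndarray, truth: np.ndarray | LabelMap) -> float:
    """Mean pixelwise cross-entropy, -(1/N) sum_i sum_c g_ic log s_ic.

    Zero probabilities on the true class are clamped so the loss stays
    finite under hard-zero predictions.
    """
    p = _as_probs(probs)
    g = _as_truth(truth, p.shape[1], p.shape[0])
    logp = np.log(np.clip(p, _LOG_CLAMP, None))
    n_pixels = p.shape[0] * p.shape[2] * p.shape[3]
    return float(-(g * logp).sum() / n_pixels)


def _soft_dice_per_class(
    p: np.ndarray, g: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (dice_c, numerator_c, denominator_c) pooled over batch+pixels."""
    axes = (0, 2, 3)
    inter = (p * g).sum(axis=axes)
    denom = p.sum(axis=axes) + g.sum(axis=axes)
    num = 2.0 * inter + eps
    den = denom + eps
    return num / den, num, den


def _included_classes(n_classes: int, config: LossConfig, background_id: int = 0) -> np.ndarray:
    if config.include_background_in_dice:
        return np.arange(n_classes)
    return np.array([c for c in range(n_classes) if c != background_id])


def dice_loss(
    probs: np.ndarray, truth: np.ndarray | LabelMap, config: LossConfig | None = None
) -> float:
    """1 - mean soft Dice over the included classes; always in [0, 1]."""
    config = config or LossConfig()
    p = _as_probs(probs)
    g = _as_truth(truth, p.shape[1], p.shape[0])
    dice, _, _ = _soft_dice_per_class(p, g, config.dice_smooth)
    keep = _included_classes(p.shape[1], config)
    return float(1.0 - dice[keep].mean())


def combined_loss(
    probs: np.ndarray, truth: np.ndarray | LabelMap, config: LossConfig | None = None
) -> float:
    config = config or LossConfig()
    lam = config.lambda_weight
    return lam * ce_loss(probs, truth) + (1.0 - lam) * dice_loss(probs, truth, config)


def combined_loss_and_grad(
    logits: np.ndarray, truth: np.ndarray | LabelMap, config: LossConfig | None = None
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the raw score maps.

    Both loss terms are differentiated through the softmax analytically;
    used by the training loop (the forward-only functions above serve the
    probability-space API and the tests' closed forms).
    """
    config = config or LossConfig()
    z = np.asarray(logits, dtype=np.float64)
    squeeze = z.ndim == 3
    if squeeze:
        z = z[None]
    p = softmax(z)
    g = _as_truth(truth, p.shape[1], p.shape[0])
    n_pixels = p.shape[0] * p.shape[2] * p.shape[3]
    lam = config.lambda_weight

    logp = np.log(np.clip(p, _LOG_CLAMP, None))
    ce = float(-(g * logp).sum() / n_pixels)
    # d(CE)/dz has the classic softmax-cross-entropy form
    dz = lam * (p - g) / n_pixels

    dice, num, den = _soft_dice_per_class(p, g, config.dice_smooth)
    keep = _included_classes(p.shape[1], config)
    de = float(1.0 - dice[keep].mean())
    # d(De)/dp_c = -(1/|K|) * (2 g - dice_c * 1) / den_c   for c in K
    dp = np.zeros_like(p)
    for c in keep:
        dp[:, c] = -(2.0 * g[:, c] - dice[c]) / (den[c] * len(keep))
    # chain through softmax: dz = p * (dp - sum_c dp_c p_c)
    dz += (1.0 - lam) * p * (dp - (dp * p).sum(axis=1, keepdims=True))

    loss = lam * ce + (1.0 - lam) * de
    return loss, (dz[0] if squeeze else dz)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class MetricsReport:
    per_class_iou: dict[int, float]
    per_class_dsc: dict[int, float]
    miou: float
    mdsc: float
    miou_foreground: float
    mdsc_foreground: float
    n_images: int
    class_names: dict[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class_id": cid,
                "class_name": self.class_names.get(cid, str(cid)),
                "iou": self.per_class_iou[cid],
                "dsc": self.per_class_dsc[cid],
            }
            for cid in sorted(self.per_class_iou)
        ]
        rows.append({"class_id": -1, "class_name": "mean (all classes)",
                     "iou": self.miou, "dsc": self.mdsc})
        rows.append({"class_id": -1, "class_name": "mean (foreground)",
                     "iou": self.miou_foreground, "dsc": self.mdsc_foreground})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate(
    predictions: Sequence[LabelMap],
    truths: Sequence[LabelMap],
    schema: LabelSchema | None = None,
    average: str = "micro",
) -> MetricsReport:
    """Per-class IOU/DSC over paired label-map lists.

    ``micro`` (default) pools TP/FP/FN per class across all images before
    dividing; ``macro`` computes per-image scores (a class absent from
    both maps of an image scores 1) and averages them.  The DSC = 2*IOU /
    (1 + IOU) identity holds exactly per class under micro averaging.
    """
    schema = schema or default_schema()
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("need equal-length, non-empty prediction/truth lists")
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")
    ids = schema.class_ids
    n = len(ids)
    tp = np.zeros(n)
    fp = np.zeros(n)
    fn = np.zeros(n)
    macro_iou = np.zeros(n)
    macro_dsc = np.zeros(n)
    for pred, truth in zip(predictions, truths):
        p, t = pred.labels, truth.labels
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch: prediction {p.shape} vs truth {t.shape}")
        for c in ids:
            pm, tm = p == c, t == c
            tpi = float(np.count_nonzero(pm & tm))
            fpi = float(np.count_nonzero(pm & ~tm))
            fni = float(np.count_nonzero(~pm & tm))
            tp[c] += tpi
            fp[c] += fpi
            fn[c] += fni
            if tpi + fpi + fni == 0:
                macro_iou[c] += 1.0
                macro_dsc[c] += 1.0
            else:
                macro_iou[c] += tpi / (tpi + fpi + fni)
                macro_dsc[c] += 2 * tpi / (2 * tpi + fpi + fni)
    if average == "micro":
        denom = tp + fp + fn
        iou = np.where(denom > 0, tp / np.maximum(denom, 1), 1.0)
        dsc = np.where(denom > 0, 2 * tp / np.maximum(2 * tp + fp + fn, 1), 1.0)
    else:
        iou = macro_iou / len(predictions)
        dsc = macro_dsc / len(predictions)
    fg = [c for c in ids if c != schema.background_id]
    return MetricsReport(
        per_class_iou={c: float(iou[c]) for c in ids},
        per_class_dsc={c: float(dsc[c]) for c in ids},
        miou=float(iou.mean()),
        mdsc=float(dsc.mean()),
        miou_foreground=float(iou[fg].mean()),
        mdsc_foreground=float(dsc[fg].mean()),
        n_images=len(predictions),
        class_names={c: schema.name_of(c) for c in ids},
    )
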