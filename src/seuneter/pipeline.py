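"""Training, prediction, evaluation and ablation orchestration.

Default settings follow the study conditions (RMSprop, learning rate
1e-5, batch size 6, 200 epochs); :meth:`TrainConfig.desk_profile` shrinks
every dimension of the problem (64 x 64 phantoms, depth-3 network, ~25
epochs, learning rate 1e-3) so a full train/predict/evaluate cycle runs
on one CPU core in minutes.  Every random draw (weight init, batch
shuffling, Cutout squares) derives from the config seed, so runs are
reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import CutoutConfig, augment_training_set
from .loss_metrics import LossConfig, MetricsReport, combined_loss_and_grad, evaluate
from .model import (
    ModelConfig,
    SeDeepUnet,
    _batchnorms,
    build_model,
    load_checkpoint,
    save_checkpoint,
)
from .nn import RMSprop
from .postprocess import PostprocessConfig, postprocess_all
from .schema_io import (
    DatasetManifest,
    LabelMap,
    LabelSchema,
    default_schema,
    load_sample,
)

__all__ = ["TrainConfig", "TrainResult", "train", "predict", "predict_from_checkpoint",
           "evaluate_split", "run_ablation", "repeat_runs"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 6
    epochs: int = 200
    optimizer: str = "rmsprop"
    seed: int = 0
    checkpoint_dir: str | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    cutout: CutoutConfig | None = None
    desk: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    @classmethod
    def desk_profile(cls, seed: int = 0, epochs: int = 30, **overrides) -> "TrainConfig":
        """Scaled-down study conditions for CPU-only smoke runs: a depth-3
        network on 64 x 64 phantoms with a learning rate matched to the
        short schedule."""
        model = overrides.pop(
            "model",
            ModelConfig(depth=3, base_channels=8, max_channels=64, se_reduction=4, seed=seed),
        )
        return cls(
            learning_rate=1e-2,
            batch_size=4,
            epochs=epochs,
            seed=seed,
            model=model,
            desk=True,
            **overrides,
        )


@dataclass
class TrainResult:
    history: pd.DataFrame  # epoch, train_loss, val_mdsc
    checkpoint_path: str | None
    best_epoch: int
    best_val_mdsc: float
    network: SeDeepUnet


def _load_split(
    manifest: DatasetManifest, split: str, schema: LabelSchema
) -> tuple[np.ndarray, np.ndarray]:
    records = manifest.split(split)
    images, labels = [], []
    for rec in records:
        sample, labelmap = load_sample(rec.image_path, rec.label_path, schema)
        images.append(sample.as_float()[None])
        labels.append(labelmap.labels)
    if not images:
        return np.zeros((0, 1, 0, 0)), np.zeros((0, 0, 0), dtype=int)
    return np.stack(images), np.stack(labels)


def train(
    manifest: DatasetManifest,
    config: TrainConfig,
    schema: LabelSchema | None = None,
) -> TrainResult:
    """Optimize the combined loss over the train split with RMSprop.

    Records train loss and validation mDSC per epoch; the checkpoint with
    the best validation mDSC is kept (falling back to the final epoch when
    there is no validation split).  Aborts with the offending epoch if the
    loss goes non-finite.
    """
    schema = schema or default_schema()
    X, Y = _load_split(manifest, "train", schema)
    if len(X) == 0:
        raise ValueError("manifest has no train records")
    Xv, Yv = _load_split(manifest, "val", schema)

    net = SeDeepUnet(config.model)
    opt = RMSprop(list(net.params()), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))

    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    best_mdsc, best_epoch = -np.inf, -1
    best_params: list[np.ndarray] | None = None
    best_bn_stats: list[tuple[np.ndarray, np.ndarray]] | None = None
    rows = []
    for epoch in range(1, config.epochs + 1):
        net.train(True)
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            out = net.forward(X[idx])
            loss, dz = combined_loss_and_grad(out, Y[idx], config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(dz)
            opt.step()
            losses.append(loss)
        val_mdsc = np.nan
        if len(Xv):
            preds = predict(net, Xv)
            report = evaluate(preds, [LabelMap(y) for y in Yv], schema)
            val_mdsc = report.mdsc
        rows.append(dict(epoch=epoch, train_loss=float(np.mean(losses)), val_mdsc=val_mdsc))
        score = val_mdsc if len(Xv) else -float(np.mean(losses))
        if score > best_mdsc or best_params is None:
            best_mdsc, best_epoch = score, epoch
            best_params = [p.data.copy() for p in net.params()]
            best_bn_stats = [
                (bn.running_mean.copy(), bn.running_var.copy()) for bn in _batchnorms(net)
            ]
    for p, saved in zip(net.params(), best_params):
        p.data[...] = saved
    for bn, (mean, var) in zip(_batchnorms(net), best_bn_stats):
        bn.running_mean, bn.running_var = mean, var
    ckpt_path = None
    if ckpt_dir:
        ckpt_path = str(ckpt_dir / "best.npz")
        save_checkpoint(net, ckpt_path, extra={"best_epoch": best_epoch})
    return TrainResult(
        history=pd.DataFrame(rows),
        checkpoint_path=ckpt_path,
        best_epoch=best_epoch,
        best_val_mdsc=float(best_mdsc if len(Xv) else np.nan),
        network=net,
    )


def predict(
    net: SeDeepUnet,
    images: np.ndarray,
    apply_postprocess: bool = False,
    schema: LabelSchema | None = None,
    pp_config: PostprocessConfig | None = None,
    batch_size: int = 4,
) -> list[LabelMap]:
    """Per-pixel argmax of the evaluation-mode score maps, optionally
    followed by the full post-processing chain."""
    schema = schema or default_schema()
    maps: list[LabelMap] = []
    for start in range(0, len(images), batch_size):
        logits = net.predict_logits(images[start : start + batch_size])
        for arr in logits.argmax(axis=1).astype(np.uint8):
            lm = LabelMap(arr)
            if apply_postprocess:
                cfg = pp_config or PostprocessConfig.for_shape(lm.shape)
                lm = postprocess_all(lm, schema, cfg).prediction
            maps.append(lm)
    return maps


def predict_from_checkpoint(
    checkpoint_path: str | Path,
    images: np.ndarray,
    apply_postprocess: bool = False,
    schema: LabelSchema | None = None,
    pp_config: PostprocessConfig | None = None,
) -> list[LabelMap]:
    net, _ = load_checkpoint(checkpoint_path)
    return predict(net, images, apply_postprocess, schema, pp_config)


def evaluate_split(
    net: SeDeepUnet,
    manifest: DatasetManifest,
    split: str = "test",
    apply_postprocess: bool = False,
    schema: LabelSchema | None = None,
    pp_config: PostprocessConfig | None = None,
) -> MetricsReport:
    schema = schema or default_schema()
    X, Y = _load_split(manifest, split, schema)
    if len(X) == 0:
        raise ValueError(f"manifest has no {split!r} records")
    preds = predict(net, X, apply_postprocess, schema, pp_config)
    return evaluate(preds, [LabelMap(y) for y in Y], schema)


_ABLATION_ORDER = ("A1", "A2", "A3", "A4")


def run_ablation(
    manifest: DatasetManifest,
    base: TrainConfig,
    switches: Sequence[str] = _ABLATION_ORDER,
    work_dir: str | Path | None = None,
    schema: LabelSchema | None = None,
    pp_config: PostprocessConfig | None = None,
) -> pd.DataFrame:
    """Cumulative module ablation on a fixed split and seed.

    Starts from a plain U-Net baseline (no channel attention, one fewer
    down-sampling stage, no Cutout, no post-processing) and stacks, in
    order: A1 channel attention, A2 extra depth, A3 Cutout augmentation,
    A4 post-processing.  One row of test mDSC/mIOU per configuration.
    """
    schema = schema or default_schema()
    for s in switches:
        if s not in _ABLATION_ORDER:
            raise ValueError(f"unknown ablation switch {s!r}")
    active = [s for s in _ABLATION_ORDER if s in switches]
    rows = []
    stacked: list[str] = []
    for step in [None, *active]:
        if step is not None:
            stacked.append(step)
        use_se = "A1" in stacked
        extra_depth = 1 if "A2" in stacked else 0
        use_cutout = "A3" in stacked
        use_pp = "A4" in stacked
        model = replace(
            base.model,
            use_se=use_se,
            depth=base.model.depth - 1 + extra_depth,
        )
        cfg = replace(base, model=model, checkpoint_dir=None)
        run_manifest = manifest
        if use_cutout:
            if base.cutout is None:
                raise ValueError("A3 requested but base.cutout is not configured")
            aug_dir = Path(work_dir or ".") / f"cutout_{'_'.join(stacked)}"
            run_manifest = augment_training_set(manifest, base.cutout, aug_dir, schema)
        result = train(run_manifest, cfg, schema)
        report = evaluate_split(result.network, manifest, "test", use_pp, schema, pp_config)
        rows.append(
            dict(
                configuration="U-Net" if not stacked else "U-Net + " + " + ".join(stacked),
                mdsc=report.mdsc,
                miou=report.miou,
            )
        )
    return pd.DataFrame(rows)


def repeat_runs(
    manifest: DatasetManifest,
    config: TrainConfig,
    n_repeats: int = 10,
    schema: LabelSchema | None = None,
) -> pd.DataFrame:
    """Repeated-runs validation: n independent trainings with derived seeds."""
    rows = []
    for i in range(n_repeats):
        seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        cfg = replace(config, seed=seed, model=replace(config.model, seed=seed))
        result = train(manifest, cfg, schema)
        report = evaluate_split(result.network, manifest, "test", schema=schema)
        rows.append(dict(run=i, seed=seed, test_mdsc=report.mdsc, test_miou=report.miou))
    return pd.DataFrame(rows)
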