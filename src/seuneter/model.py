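"""SeDeepUnet: a deepened U-Net with channel attention in every double conv.

The encoder applies a stem double convolution and ``depth`` down-sampling
stages (2x2 max pool + double conv), doubling the channel count per stage
up to ``max_channels``; with defaults (depth 5, base 32) a 512 x 512 input
reaches a 1024-channel 16 x 16 bottleneck.  The decoder mirrors the
encoder with five up-sampling stages, concatenating the same-resolution
encoder output (skip connection) before each double conv, and a 1 x 1
head produces per-class score maps at input resolution.

Every double convolution is [conv3x3 -> (BN) -> ReLU] x2 followed by a
squeeze-and-excitation block, so each stage reweights its channels by
learned global context.  Setting ``use_se=False`` recovers a plain
deepened U-Net for ablation.

Score maps are raw (no softmax); normalization belongs to the loss module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "ModelConfig",
    "NetworkDescription",
    "SeDeepUnet",
    "build_model",
    "se_block",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    in_channels: int = 1
    n_classes: int = 16
    depth: int = 5
    base_channels: int = 32
    max_channels: int = 1024
    se_reduction: int = 16
    use_se: bool = True
    use_batchnorm: bool = True
    upsample_mode: str = "transposed_conv"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.upsample_mode not in ("transposed_conv", "bilinear"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    def channels_at(self, stage: int) -> int:
        """Encoder channel count after the stem (stage 0) or down stage i."""
        return min(self.base_channels * 2**stage, self.max_channels)

    def check_input(self, height: int, width: int) -> None:
        div = 2**self.depth
        if height % div or width % div:
            raise ValueError(
                f"input {height}x{width} must be divisible by 2^depth = {div}"
            )


@dataclass
class NetworkDescription:
    """Realized layer graph: one row per stage plus the parameter total."""

    stages: list[dict]
    total_parameters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    @property
    def bottleneck(self) -> dict:
        return next(s for s in self.stages if s["kind"] == "bottleneck")


class _DoubleConv(nn.Sequential):
    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig, rng: np.random.Generator) -> None:
        layers: list[nn.Layer] = []
        for cin in (in_ch, out_ch):
            layers.append(nn.Conv2d(cin, out_ch, 3, rng))
            if cfg.use_batchnorm:
                layers.append(nn.BatchNorm2d(out_ch))
            layers.append(nn.ReLU())
        if cfg.use_se:
            layers.append(nn.SEBlock(out_ch, cfg.se_reduction, rng))
        super().__init__(*layers)


class SeDeepUnet(nn.Layer):
    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7129]))
        cfg = config
        self.stem = _DoubleConv(cfg.in_channels, cfg.channels_at(0), cfg, rng)
        self.pools: list[nn.MaxPool2d] = []
        self.encs: list[_DoubleConv] = []
        for i in range(1, cfg.depth + 1):
            self.pools.append(nn.MaxPool2d())
            self.encs.append(_DoubleConv(cfg.channels_at(i - 1), cfg.channels_at(i), cfg, rng))
        self.ups: list[nn.Layer] = []
        self.decs: list[_DoubleConv] = []
        for i in range(cfg.depth):
            deep = cfg.channels_at(cfg.depth - i)
            skip = cfg.channels_at(cfg.depth - 1 - i)
            if cfg.upsample_mode == "transposed_conv":
                self.ups.append(nn.ConvTranspose2x2(deep, skip, rng))
                self.decs.append(_DoubleConv(2 * skip, skip, cfg, rng))
            else:
                self.ups.append(nn.BilinearUp2())
                self.decs.append(_DoubleConv(deep + skip, skip, cfg, rng))
        self.head = nn.Conv2d(cfg.channels_at(0), cfg.n_classes, 1, rng)

    # -- plumbing ---------------------------------------------------------

    def _modules(self) -> list[nn.Layer]:
        return [self.stem, *self.pools, *self.encs, *self.ups, *self.decs, self.head]

    def params(self):
        for m in self._modules():
            yield from m.params()

    def train(self, mode: bool = True) -> "SeDeepUnet":
        self.training = mode
        for m in self._modules():
            m.train(mode)
        return self

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, {self.config.in_channels}, H, W), got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in network input")
        self.config.check_input(x.shape[2], x.shape[3])
        feats = [self.stem(x)]
        h = feats[0]
        for pool, enc in zip(self.pools, self.encs):
            h = enc(pool(h))
            feats.append(h)
        self._skip_channels = []
        for i, (up, dec) in enumerate(zip(self.ups, self.decs)):
            skip = feats[self.config.depth - 1 - i]
            u = up(h)
            if u.shape[2:] != skip.shape[2:]:  # pragma: no cover - guarded by check_input
                raise ValueError(f"skip shape {skip.shape} vs upsampled {u.shape}")
            self._skip_channels.append(skip.shape[1])
            h = dec(np.concatenate([skip, u], axis=1))
        return self.head(h)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.head.backward(grad_out)
        depth = self.config.depth
        pending: list[np.ndarray | None] = [None] * depth
        for i in reversed(range(depth)):
            g = self.decs[i].backward(g)
            c_skip = self._skip_channels[i]
            g_skip, g_up = g[:, :c_skip], g[:, c_skip:]
            pending[depth - 1 - i] = g_skip
            g = self.ups[i].backward(g_up)
        for k in reversed(range(1, depth + 1)):
            g = self.encs[k - 1].backward(g)
            g = self.pools[k - 1].backward(g)
            g = g + pending[k - 1]
        return self.stem.backward(g)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode forward pass."""
        was_training = self.training
        self.train(False)
        out = self.forward(x)
        self.train(was_training)
        return out


def describe_network(net: SeDeepUnet, input_hw: tuple[int, int]) -> NetworkDescription:
    cfg = net.config
    H, W = input_hw
    cfg.check_input(H, W)
    stages: list[dict] = []

    def row(kind: str, name: str, in_shape, out_shape, n_params: int) -> None:
        stages.append(
            dict(kind=kind, name=name, in_shape=tuple(in_shape), out_shape=tuple(out_shape),
                 channels=out_shape[0], parameters=n_params)
        )

    row("stem", "stem", (cfg.in_channels, H, W), (cfg.channels_at(0), H, W), net.stem.n_parameters())
    h, w = H, W
    for i, enc in enumerate(net.encs, start=1):
        h, w = h // 2, w // 2
        kind = "bottleneck" if i == cfg.depth else "down"
        row(kind, f"down{i}", (cfg.channels_at(i - 1), 2 * h, 2 * w), (cfg.channels_at(i), h, w),
            enc.n_parameters())
    for i, (up, dec) in enumerate(zip(net.ups, net.decs)):
        deep = cfg.channels_at(cfg.depth - i)
        skip = cfg.channels_at(cfg.depth - 1 - i)
        h, w = h * 2, w * 2
        # skip-shape agreement with the matching encoder output
        enc_out = stages[cfg.depth - 1 - i]["out_shape"]
        assert enc_out[1:] == (h, w) and enc_out[0] == skip
        row("up", f"up{i + 1}", (deep, h // 2, w // 2), (skip, h, w),
            up.n_parameters() + dec.n_parameters())
    row("head", "head", (cfg.channels_at(0), H, W), (cfg.n_classes, H, W), net.head.n_parameters())
    return NetworkDescription(stages=stages, total_parameters=net.n_parameters())


def build_model(
    config: ModelConfig, input_hw: tuple[int, int] = (512, 512)
) -> tuple[NetworkDescription, SeDeepUnet]:
    """Instantiate the network and its realized layer-graph description.

    Raises at build time if ``input_hw`` is not divisible by ``2**depth``.
    """
    config.check_input(*input_hw)
    net = SeDeepUnet(config)
    return describe_network(net, input_hw), net


def se_block(
    features: np.ndarray,
    weights: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    """Functional squeeze-and-excitation with explicit excitation weights.

    ``weights`` is (w1, b1, w2, b2): w1 maps C -> C/r, w2 maps back.
    Returns features rescaled per channel by sigmoid-activated excitation.
    """
    w1, b1, w2, b2 = (np.asarray(a, dtype=np.float64) for a in weights)
    C = features.shape[-3]
    if w1.shape[1] != C or w2.shape[0] != C:
        raise ValueError(f"excitation weights do not match {C} channels: {w1.shape}, {w2.shape}")
    squeezed = features.mean(axis=(-2, -1))  # (..., C)
    hidden = np.maximum(squeezed @ w1.T + b1, 0.0)
    scale = 1.0 / (1.0 + np.exp(-(hidden @ w2.T + b2)))
    return features * scale[..., :, None, None]


def _iter_layers(layer: nn.Layer):
    yield layer
    for child in getattr(layer, "layers", []):
        yield from _iter_layers(child)


def _batchnorms(net: SeDeepUnet) -> list[nn.BatchNorm2d]:
    out = []
    for module in net._modules():
        for layer in _iter_layers(module):
            if isinstance(layer, nn.BatchNorm2d):
                out.append(layer)
    return out


def save_checkpoint(net: SeDeepUnet, path: str | Path, extra: dict | None = None) -> None:
    """Weights, BatchNorm running statistics and the ModelConfig header
    (+ optional metadata) in one npz file."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(net.params())}
    for i, bn in enumerate(_batchnorms(net)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    header = {"model": asdict(net.config), "extra": extra or {}}
    arrays["header_json"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[SeDeepUnet, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["header_json"].tobytes()).decode())
        net = SeDeepUnet(ModelConfig(**header["model"]))
        for i, p in enumerate(net.params()):
            arr = data[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint param {i} shape {arr.shape} != {p.data.shape}")
            p.data[...] = arr
        for i, bn in enumerate(_batchnorms(net)):
            bn.running_mean = data[f"bn_mean_{i}"].copy()
            bn.running_var = data[f"bn_var_{i}"].copy()
    return net, header.get("extra", {})
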