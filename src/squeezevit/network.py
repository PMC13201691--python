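"""SqueezeViT assembly: stem → Fire Block → Translution Block → head.

Default spatial ledger for a 224×224 single-channel radiograph:

    224 → stem 3×3 conv (stride 2, pad 1, 3 ch) → 112
        → stem 3×3 max pool (stride 2, pad 1)   → 56
        → Stage 1 Fire Block (plan 3→32→64→64→128, pool) → 28
        → Stage 2 Translution Block (C=128 preserved)    → 28
        → Stage 3 Fire 128→256 + pool → 14 → 1×1 conv → GAP → (C,1,1)
        → flatten → fully connected → L logits

The head's 1×1 conv width (198) and the encoder defaults are chosen so
the total trainable parameter count lands on the model's 0.54×10⁶
budget.  Ablation switches reproduce the block-removal study: Stage 2
replaced by an identity pass-through, or Stage 1 rebuilt with
N ∈ {1, 4, 8, 16} modules over a geometric channel plan.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .errors import ConfigurationError, ShapeError
from .fire import (
    STAGE1_PLAN,
    ConvSpec,
    FireBlock,
    FireBlockConfig,
    FireModule,
    derive_fire_channels,
    interpolated_plan,
)
from .translution import AttentionSpec, TranslutionBlock, TranslutionConfig

__all__ = [
    "NetworkConfig",
    "SqueezeViT",
    "build_squeezevit",
    "apply_ablation",
    "ABLATION_TAGS",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1

ABLATION_TAGS = ("no_translution", "fire_n1", "fire_n4", "fire_n8", "fire_n16")


@dataclass(frozen=True)
class NetworkConfig:
    """Single source of truth for constructing a SqueezeViT model."""

    input_channels: int = 1
    input_size: tuple[int, int] = (224, 224)
    num_labels: int = 14
    stem_out: int = 3
    stem_conv: ConvSpec = ConvSpec(3, 2, 1, 1, 3)
    stem_pool: ConvSpec = ConvSpec(3, 2, 1)
    stage1_plan: tuple[int, ...] = STAGE1_PLAN
    stage1_enabled: bool = True
    stage2: TranslutionConfig | None = field(default_factory=TranslutionConfig)
    stage3_fire_out: int = 256
    stage3_pool: ConvSpec = ConvSpec(3, 2, 1)
    head_width: int = 198
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "stage1_plan", tuple(self.stage1_plan))
        object.__setattr__(self, "input_size", tuple(self.input_size))
        if self.num_labels < 1:
            raise ConfigurationError("num_labels must be positive")
        if self.stage1_plan[0] != self.stem_out:
            raise ConfigurationError(
                f"stem outputs {self.stem_out} channels but Stage-1 plan "
                f"starts at {self.stage1_plan[0]}"
            )
        c1 = self.stage1_plan[-1]
        if self.stage2 is not None and self.stage2.c != c1:
            raise ConfigurationError(
                f"Stage-1 ends at {c1} channels but the Translution Block "
                f"expects {self.stage2.c}"
            )

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage2"] = None if self.stage2 is None else dataclasses.asdict(self.stage2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("stem_conv", "stem_pool", "stage3_pool"):
            if key in d and isinstance(d[key], dict):
                d[key] = ConvSpec(**d[key])
        s2 = d.get("stage2")
        if isinstance(s2, dict):
            att = s2.get("attention")
            if isinstance(att, dict):
                s2["attention"] = AttentionSpec(**att)
            d["stage2"] = TranslutionConfig(**s2)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def binary_config(base: NetworkConfig | None = None, **kw) -> NetworkConfig:
    """The single-logit (normal vs abnormal) variant of a config."""
    base = base or NetworkConfig(**kw)
    return dataclasses.replace(base, num_labels=1)


class SqueezeViT(nn.Module):
    """The assembled classifier; emits logits (sigmoid applied downstream)."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        sc = cfg.stem_conv
        self.stem_w = nn.kaiming_conv(rng, sc.out_channels, cfg.input_channels,
                                      sc.kernel_size, nonneg_sum=True)
        self.stem_b = nn.const_param(nn.RELU_BIAS_INIT, sc.out_channels)
        self.stage1 = FireBlock(FireBlockConfig(cfg.stage1_plan), rng)
        self.stage2 = (TranslutionBlock(cfg.stage2, rng)
                       if cfg.stage2 is not None else None)
        c_in3 = cfg.stage1_plan[-1]
        self.stage3_fire = FireModule(
            derive_fire_channels(c_in3, cfg.stage3_fire_out), rng)
        self.head_conv_w = nn.kaiming_conv(rng, cfg.head_width,
                                           cfg.stage3_fire_out, 1)
        self.head_conv_b = nn.zeros_param(cfg.head_width)
        # zero-initialised classifier: training starts from the
        # maximum-entropy predictor (all logits 0) instead of a randomly
        # saturated one
        self.fc_w = nn.zeros_param(cfg.head_width, cfg.num_labels)
        self.fc_b = nn.zeros_param(cfg.num_labels)

    # -- forward -------------------------------------------------------------
    def __call__(self, images: nn.Tensor | np.ndarray) -> nn.Tensor:
        return self.forward_intermediates(images)["logits"]

    def forward_intermediates(
            self, images: nn.Tensor | np.ndarray) -> dict[str, nn.Tensor]:
        """Forward pass that also exposes every stage boundary."""
        x = images if isinstance(images, nn.Tensor) else nn.Tensor(
            np.asarray(images, dtype=np.float32))
        cfg = self.cfg
        if x.ndim != 4 or x.shape[1] != cfg.input_channels:
            raise ShapeError(
                f"expected (batch, {cfg.input_channels}, H, W), got {x.shape}"
            )
        if tuple(x.shape[2:]) != cfg.input_size:
            raise ShapeError(
                f"model built for {cfg.input_size} inputs, got {x.shape[2:]}; "
                "resize upstream (the model never resizes silently)"
            )
        out: dict[str, nn.Tensor] = {}
        sc, sp = cfg.stem_conv, cfg.stem_pool
        x = nn.relu(nn.conv2d(x, self.stem_w, self.stem_b,
                              stride=sc.stride, padding=sc.padding))
        out["stem_conv"] = x
        x = nn.maxpool2d(x, sp.kernel_size, sp.stride, sp.padding)
        out["stem_pool"] = x
        x = out["stage1"] = self.stage1(x)
        if self.stage2 is not None:
            x = self.stage2(x)
        out["stage2"] = x
        x = out["stage3_fire"] = self.stage3_fire(x)
        p3 = cfg.stage3_pool
        x = nn.maxpool2d(x, p3.kernel_size, p3.stride, p3.padding)
        x = out["stage3_pool"] = nn.conv2d(x, self.head_conv_w, self.head_conv_b)
        x = nn.mean(x, axes=(2, 3))                 # GAP
        out["pooled"] = nn.reshape(x, (x.shape[0], cfg.head_width, 1, 1))
        out["logits"] = nn.add(nn.matmul(x, self.fc_w), self.fc_b)
        return out

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-class sigmoid probabilities, computed without a tape."""
        images = np.asarray(images, dtype=np.float32)
        outs = []
        with nn.no_grad():
            for lo in range(0, len(images), batch_size):
                logits = self(images[lo:lo + batch_size])
                outs.append(nn.sigmoid(logits.data))
        return np.concatenate(outs, axis=0)

    # -- reporting -----------------------------------------------------------
    def named_blocks(self) -> list[tuple[str, nn.Module | nn.Parameter]]:
        blocks: list[tuple[str, nn.Module | nn.Parameter]] = [
            ("stem.conv.w", self.stem_w), ("stem.conv.b", self.stem_b),
            ("stage1", self.stage1),
        ]
        if self.stage2 is not None:
            blocks.append(("stage2", self.stage2))
        blocks += [
            ("stage3.fire", self.stage3_fire),
            ("head.conv.w", self.head_conv_w), ("head.conv.b", self.head_conv_b),
            ("head.fc.w", self.fc_w), ("head.fc.b", self.fc_b),
        ]
        return blocks


def build_squeezevit(cfg: NetworkConfig | None = None) -> SqueezeViT:
    """Construct a model with a deterministic parameter layout for cfg.seed."""
    return SqueezeViT(cfg or NetworkConfig())


def forward(model: SqueezeViT, images: np.ndarray) -> np.ndarray:
    """Functional forward: batch of images → (batch, L) logit matrix."""
    with nn.no_grad():
        return model(images).data


def apply_ablation(cfg: NetworkConfig, ablation: str) -> NetworkConfig:
    """Return the block-removal variant of a config.

    ``no_translution`` replaces Stage 2 with an identity pass-through;
    ``fire_nK`` (K ∈ {1,4,8,16}) rebuilds Stage 1 with K modules over a
    geometric channel plan ending at 128.
    """
    if ablation == "no_translution":
        return dataclasses.replace(cfg, stage2=None)
    if ablation.startswith("fire_n"):
        try:
            n = int(ablation[len("fire_n"):])
        except ValueError:
            n = -1
        if ablation in ABLATION_TAGS:
            plan = interpolated_plan(n, cfg.stage1_plan[0], cfg.stage1_plan[-1])
            return dataclasses.replace(cfg, stage1_plan=plan)
    raise ConfigurationError(
        f"unknown ablation {ablation!r}; valid tags: {', '.join(ABLATION_TAGS)}"
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SqueezeViT, path: str | Path) -> None:
    """Write weights + config + seed as a versioned .npz archive."""
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    meta = json.dumps({
        "format_version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> SqueezeViT:
    """Rebuild the model recorded in a checkpoint archive."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint version {meta.get('format_version')}"
            )
        cfg = NetworkConfig.from_dict(meta["config"])
        model = SqueezeViT(cfg)
        n = len(model.parameters())
        model.load_state_arrays([z[f"p{i}"] for i in range(n)])
    return model
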