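"""Fire modules and Fire Blocks.

A Fire module squeezes its input through a 1×1 bottleneck conv and
re-expands it through parallel 1×1 and 3×3 "excitation" convs whose
outputs are concatenated channel-wise:

    X' = ReLU(W_s * X + b_s)                         (squeeze, C_in → C_s)
    e_1x1 = ReLU(W_1x1 * X' + b_1x1)                 (excitation, C_s → n_e1)
    e_3x3 = ReLU(W_3x3 * X' + b_3x3)                 (excitation, C_s → n_e3)
    F_out = Concat(e_1x1, e_3x3)                     (C_out = n_e1 + n_e3)

The squeeze width is half the module's input width (floored, clamped to
at least 1) and each excitation branch produces half of the requested
output width, so a module C_in → C_out is fully determined by the two
widths.  A Fire Block stacks N modules along a channel plan and ends with
a 3×3 max pool (stride 2, padding 1) that halves the spatial dims;
modules themselves never change H or W (the 3×3 branch uses padding 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError

__all__ = [
    "ConvSpec",
    "FireModuleConfig",
    "FireBlockConfig",
    "derive_fire_channels",
    "FireModule",
    "FireBlock",
    "conv_output_dim",
    "fire_forward",
    "fire_block_forward",
    "fire_param_count",
]


@dataclass(frozen=True)
class ConvSpec:
    """Kernel/stride/padding/channel description of one conv or pool layer."""

    kernel_size: int
    stride: int
    padding: int
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.kernel_size < 1 or self.stride < 1:
            raise ConfigurationError("kernel size and stride must be positive")
        if self.padding < 0:
            raise ConfigurationError("padding must be non-negative")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")

    def output_dims(self, H: int, W: int) -> tuple[int, int]:
        """H' = floor((H + 2p − k)/s) + 1 and likewise for W'."""
        Ho = (H + 2 * self.padding - self.kernel_size) // self.stride + 1
        Wo = (W + 2 * self.padding - self.kernel_size) // self.stride + 1
        if Ho < 1 or Wo < 1:
            raise ConfigurationError(
                f"conv k={self.kernel_size} s={self.stride} p={self.padding} "
                f"collapses a {H}x{W} input to {Ho}x{Wo}"
            )
        return Ho, Wo


# default terminal pool of every Fire Block
POOL_SPEC = ConvSpec(kernel_size=3, stride=2, padding=1)


@dataclass(frozen=True)
class FireModuleConfig:
    """Channel widths of one Fire module (C_in → C_s → n_e1 + n_e3)."""

    c_in: int
    c_s: int
    n_e1: int
    n_e3: int

    def __post_init__(self):
        if min(self.c_in, self.c_s, self.n_e1, self.n_e3) < 1:
            raise ConfigurationError("all Fire widths must be positive")
        if self.c_in >= 2 and self.c_s >= self.c_in:
            raise ConfigurationError(
                f"squeeze width {self.c_s} is not a bottleneck for C_in={self.c_in}"
            )

    @property
    def c_out(self) -> int:
        return self.n_e1 + self.n_e3


def derive_fire_channels(c_in: int, c_out: int) -> FireModuleConfig:
    """Widths of a C_in → C_out Fire module under the halving rules.

    The squeeze conv outputs half the input channels (floored, at least 1)
    and each excitation branch produces half of the output channels.
    """
    if c_in < 1:
        raise ConfigurationError(f"C_in must be positive, got {c_in}")
    if c_out < 2 or c_out % 2 != 0:
        raise ConfigurationError(
            f"Fire output width must be even and >= 2 so the excitation "
            f"branches split evenly, got C_out={c_out}"
        )
    return FireModuleConfig(
        c_in=c_in, c_s=max(1, c_in // 2), n_e1=c_out // 2, n_e3=c_out // 2
    )


def fire_param_count(cfg: FireModuleConfig) -> int:
    """Closed-form learnable-scalar count of one Fire module (with biases)."""
    squeeze = cfg.c_in * cfg.c_s + cfg.c_s
    e1 = cfg.c_s * cfg.n_e1 + cfg.n_e1
    e3 = 9 * cfg.c_s * cfg.n_e3 + cfg.n_e3
    return squeeze + e1 + e3


def fire_macs(cfg: FireModuleConfig, H: int, W: int) -> int:
    """Multiply-accumulates of one Fire module on an H×W map."""
    per_pixel = cfg.c_in * cfg.c_s + cfg.c_s * cfg.n_e1 + 9 * cfg.c_s * cfg.n_e3
    return H * W * per_pixel


@dataclass(frozen=True)
class FireBlockConfig:
    """N stacked Fire modules over a channel plan, plus the terminal pool."""

    channel_plan: tuple[int, ...]
    pool: ConvSpec = POOL_SPEC

    def __post_init__(self):
        plan = tuple(self.channel_plan)
        object.__setattr__(self, "channel_plan", plan)
        if len(plan) < 2:
            raise ConfigurationError(
                "channel plan needs at least an input and an output width"
            )
        for width in plan[1:]:
            if width % 2 != 0:
                raise ConfigurationError(
                    f"Fire output width {width} in plan {plan} is odd; excitation "
                    "branches cannot split evenly"
                )

    @property
    def n_modules(self) -> int:
        return len(self.channel_plan) - 1

    def module_configs(self) -> list[FireModuleConfig]:
        plan = self.channel_plan
        return [derive_fire_channels(a, b) for a, b in zip(plan[:-1], plan[1:])]


# Stage-1 default: N = 4 modules, plan 3 → 32 → 64 → 64 → 128.
STAGE1_PLAN = (3, 32, 64, 64, 128)


def interpolated_plan(n_modules: int, c_in: int = 3, c_out: int = 128) -> tuple[int, ...]:
    """Geometric channel interpolation c_in → c_out, interior widths even.

    Used for Fire-Block ablations with module counts the default plan does
    not cover (N ∈ {1, 8, 16}).
    """
    if n_modules < 1:
        raise ConfigurationError("a Fire Block needs at least one module")
    widths = [c_in]
    for i in range(1, n_modules):
        w = c_in * (c_out / c_in) ** (i / n_modules)
        widths.append(max(2, 2 * round(w / 2)))
    widths.append(c_out)
    return tuple(widths)


class FireModule(nn.Module):
    """Learnable squeeze → parallel excitation → concat unit."""

    def __init__(self, cfg: FireModuleConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.w_s = nn.kaiming_conv(rng, cfg.c_s, cfg.c_in, 1,
                                   nonneg_sum=cfg.c_s <= 2)
        self.b_s = nn.const_param(nn.RELU_BIAS_INIT, cfg.c_s)
        self.w_e1 = nn.kaiming_conv(rng, cfg.n_e1, cfg.c_s, 1)
        self.b_e1 = nn.const_param(nn.RELU_BIAS_INIT, cfg.n_e1)
        self.w_e3 = nn.kaiming_conv(rng, cfg.n_e3, cfg.c_s, 3)
        self.b_e3 = nn.const_param(nn.RELU_BIAS_INIT, cfg.n_e3)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.cfg.c_in:
            raise ShapeError(
                f"Fire module expected {self.cfg.c_in} input channels, "
                f"got {x.shape[1]}"
            )
        xs = nn.relu(nn.conv2d(x, self.w_s, self.b_s))
        e1 = nn.relu(nn.conv2d(xs, self.w_e1, self.b_e1))
        e3 = nn.relu(nn.conv2d(xs, self.w_e3, self.b_e3, stride=1, padding=1))
        return nn.concat([e1, e3], axis=1)


class FireBlock(nn.Module):
    """A chain of Fire modules terminated by the 3×3 down-sampling max pool."""

    def __init__(self, cfg: FireBlockConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.modules = [FireModule(mc, rng) for mc in cfg.module_configs()]

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for m in self.modules:
            x = m(x)
        p = self.cfg.pool
        return nn.maxpool2d(x, kernel=p.kernel_size, stride=p.stride,
                            padding=p.padding)


def fire_forward(x: nn.Tensor | np.ndarray, module: FireModule) -> nn.Tensor:
    """Functional forward through one Fire module."""
    if not isinstance(x, nn.Tensor):
        x = nn.Tensor(np.asarray(x, dtype=np.float32))
    return module(x)


def fire_block_forward(x: nn.Tensor | np.ndarray, block: FireBlock) -> nn.Tensor:
    """Functional forward through a Fire Block."""
    if not isinstance(x, nn.Tensor):
        x = nn.Tensor(np.asarray(x, dtype=np.float32))
    if x.shape[1] != block.cfg.channel_plan[0]:
        raise ShapeError(
            f"Fire Block expected {block.cfg.channel_plan[0]} input channels, "
            f"got {x.shape[1]}"
        )
    return block(x)


def conv_output_dim(size: int, kernel: int, stride: int, padding: int) -> int:
    """Scalar form of the conv dimension formula."""
    return (size + 2 * padding - kernel) // stride + 1
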