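"""Analytic parameter and multiply-accumulate (MAC) accounting.

Conventions: 1 MAC = one multiply + one accumulate.  Convolutions cost
H′·W′·C_out·k²·C_in, linear layers cost (tokens)·d_in·d_out, and the
attention stage additionally pays for its two matrix products,
P·heads·N²·d_k for the scores QKᵀ and P·heads·N²·d_v for softmax·V per
encoder layer.  Bias adds, ReLU, pooling, softmax and normalisation are
excluded (the standard convention behind "MACs (10⁹)" reporting).

Parameter counts are exact integers obtained by enumerating every
learnable scalar of the built model; MACs depend on the input size,
parameters do not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .errors import ConfigurationError
from .fire import FireModule
from .network import NetworkConfig, SqueezeViT
from .translution import AttentionSpec, PatchGrid, TranslutionBlock

__all__ = [
    "LayerCost",
    "ComplexityReport",
    "count_parameters",
    "count_macs",
    "analyze",
    "reduction_percent",
    "attention_score_flops",
    "patch_tradeoff",
    "reference_budgets",
]


@dataclass(frozen=True)
class LayerCost:
    name: str
    params: int
    macs: int


@dataclass(frozen=True)
class ComplexityReport:
    input_size: tuple[int, int]
    per_layer: tuple[LayerCost, ...]

    @property
    def params(self) -> int:
        return sum(l.params for l in self.per_layer)

    @property
    def macs(self) -> int:
        return sum(l.macs for l in self.per_layer)

    @property
    def params_millions(self) -> float:
        return round(self.params / 1e6, 2)

    def macs_scaled(self) -> dict[str, float]:
        """The raw count under both published scalings (10⁹ and 10¹⁰)."""
        return {"raw": self.macs, "x1e9": round(self.macs / 1e9, 2),
                "x1e10": round(self.macs / 1e10, 2)}

    def reductions(self) -> dict[str, float]:
        """Reduction percentages vs the published baseline budgets."""
        refs = reference_budgets()["params_millions"]
        p = self.params / 1e6
        return {name: reduction_percent(p, ref) for name, ref in refs.items()}

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "params": self.params,
            "params_millions": self.params_millions,
            "macs": self.macs_scaled(),
            "reductions_percent": self.reductions(),
            "per_layer": [
                {"name": l.name, "params": l.params, "macs": l.macs}
                for l in self.per_layer
            ],
        }

    def table(self) -> str:
        lines = [f"{'layer':<28}{'params':>12}{'MACs':>16}"]
        for l in self.per_layer:
            lines.append(f"{l.name:<28}{l.params:>12,}{l.macs:>16,}")
        lines.append(f"{'total':<28}{self.params:>12,}{self.macs:>16,}")
        return "\n".join(lines)


def reference_budgets() -> dict:
    with resources.files(__package__).joinpath("reference_budgets.json").open() as fh:
        return json.load(fh)


def count_parameters(model: SqueezeViT) -> int:
    """Exact count of every learnable scalar in the model."""
    return model.num_parameters()


def count_macs(model: SqueezeViT,
               input_size: tuple[int, int] | None = None) -> int:
    """MACs of one forward pass at the given (H, W) input size."""
    return analyze(model, input_size).macs


def reduction_percent(p_model: float, p_reference: float) -> float:
    """100·(reference − model)/reference, one decimal."""
    if p_reference <= 0:
        raise ConfigurationError("reference count must be positive")
    return round(100.0 * (p_reference - p_model) / p_reference, 1)


def attention_score_flops(grid: PatchGrid, spec: AttentionSpec) -> int:
    """QKᵀ score multiply-accumulates over all heads, layers and sequences."""
    return spec.depth * grid.pixels_per_patch * spec.heads * grid.n_patches ** 2 * spec.d_k


def patch_tradeoff(grid_a: PatchGrid, grid_b: PatchGrid,
                   spec: AttentionSpec) -> tuple[float, float]:
    """(token-count ratio, attention-score-FLOPs ratio) of grid a over b.

    On the same map, halving the patch side from 4 to 2 quadruples both
    the token count N and the total attention-score cost.
    """
    if (grid_a.H, grid_a.W) != (grid_b.H, grid_b.W):
        raise ConfigurationError("grids must tile the same feature map")
    token_ratio = grid_a.n_patches / grid_b.n_patches
    flops_ratio = attention_score_flops(grid_a, spec) / attention_score_flops(grid_b, spec)
    return token_ratio, flops_ratio


# ---------------------------------------------------------------------------
# model walk
# ---------------------------------------------------------------------------

def _fire_entries(name: str, mod: FireModule, H: int, W: int) -> LayerCost:
    cfg = mod.cfg
    macs = H * W * (cfg.c_in * cfg.c_s + cfg.c_s * cfg.n_e1 + 9 * cfg.c_s * cfg.n_e3)
    return LayerCost(name, mod.num_parameters(), macs)


def _encoder_entries(block: TranslutionBlock, grid: PatchGrid) -> list[LayerCost]:
    spec = block.cfg.attention
    d = spec.token_dim
    N, P = grid.n_patches, grid.pixels_per_patch
    tokens = P * N
    entries = []
    for i, layer in enumerate(block.encoder.layers):
        proj = 4 * tokens * d * d                      # Q, K, V, output
        scores = P * spec.heads * N * N * spec.d_k     # QKᵀ
        attn_v = P * spec.heads * N * N * spec.d_v     # softmax(·)·V
        ffn = tokens * (d * spec.ffn_width + spec.ffn_width * d)
        entries.append(LayerCost(
            f"stage2.encoder.{i}", layer.num_parameters(),
            proj + scores + attn_v + ffn,
        ))
    return entries


def analyze(model: SqueezeViT,
            input_size: tuple[int, int] | None = None) -> ComplexityReport:
    """Layer-by-layer parameter and MAC breakdown of a built model."""
    cfg: NetworkConfig = model.cfg
    H, W = input_size or cfg.input_size
    entries: list[LayerCost] = []

    sc = cfg.stem_conv
    Ho, Wo = sc.output_dims(H, W)
    stem_params = model.stem_w.size + model.stem_b.size
    stem_macs = Ho * Wo * sc.out_channels * sc.kernel_size ** 2 * cfg.input_channels
    entries.append(LayerCost("stem.conv", stem_params, stem_macs))
    Ho, Wo = cfg.stem_pool.output_dims(Ho, Wo)

    for i, mod in enumerate(model.stage1.modules):
        entries.append(_fire_entries(f"stage1.fire{i}", mod, Ho, Wo))
    Ho, Wo = model.stage1.cfg.pool.output_dims(Ho, Wo)

    if model.stage2 is not None:
        blk = model.stage2
        entries.append(_fire_entries("stage2.fire_expand", blk.fire_expand, Ho, Wo))
        entries.append(_fire_entries("stage2.fire_reduce", blk.fire_reduce, Ho, Wo))
        grid = PatchGrid(Ho, Wo, blk.cfg.patch_h, blk.cfg.patch_w)
        entries.extend(_encoder_entries(blk, grid))
        proj_params = blk.w_proj.size + blk.b_proj.size
        entries.append(LayerCost(
            "stage2.project", proj_params,
            Ho * Wo * blk.cfg.c * blk.cfg.inner_dim))
        entries.append(_fire_entries("stage2.fire_fuse", blk.fire_fuse, Ho, Wo))

    entries.append(_fire_entries("stage3.fire", model.stage3_fire, Ho, Wo))
    Ho, Wo = cfg.stage3_pool.output_dims(Ho, Wo)
    head_params = model.head_conv_w.size + model.head_conv_b.size
    entries.append(LayerCost(
        "head.conv1x1", head_params,
        Ho * Wo * cfg.head_width * cfg.stage3_fire_out))
    fc_params = model.fc_w.size + model.fc_b.size
    entries.append(LayerCost("head.fc", fc_params, cfg.head_width * cfg.num_labels))

    return ComplexityReport(input_size=(H, W), per_layer=tuple(entries))
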