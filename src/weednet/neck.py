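"""Multi-scale fusion necks.

Two fusion units consume the backbone pyramid:

* :class:`PFA` (progressive feature aggregator) fuses P2–P5 at the P3
  grid: per-level 1×1 projection, average-pool down / bilinear up,
  ``F_init = Conv1x1(Concat((F2'⊗F3')⊕F4', F5'))``, then two factorized
  convolution branches (kernel 3 and 5) whose concatenation is added
  back to ``F_init``.
* :class:`DFS` (deep feature synthesizer) fuses P3–P5 at the P4 grid:
  ``F_init' = (F3''⊗F4'')⊕F5''``, factorized branches, per-pixel
  tokenization, one transformer encoder layer for global context, and
  an output-channel residual ``F_trans' ⊕ Conv1x1(F_init')``.

⊗ and ⊕ denote element-wise multiplication and addition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .blocks import AsymmetricBranch, AttentionConfig, ConvBNAct, TransformerEncoderLayer, detokenize, tokenize
from .nn import Conv2d, Module
from .nn import functional as F
from .nn.autograd import Tensor


@dataclass
class PyramidFeatures:
    """Backbone taps F2…F5 at strides 4/8/16/32 of the input image."""

    f2: Tensor
    f3: Tensor
    f4: Tensor
    f5: Tensor

    def __post_init__(self):
        maps = [self.f2, self.f3, self.f4, self.f5]
        for hi, lo in zip(maps, maps[1:]):
            if hi.shape[2] != 2 * lo.shape[2] or hi.shape[3] != 2 * lo.shape[3]:
                raise ValueError(
                    "pyramid levels must halve spatially: "
                    f"{hi.shape} vs {lo.shape}"
                )

    def __getitem__(self, level: str) -> Tensor:
        try:
            return {"F2": self.f2, "F3": self.f3, "F4": self.f4, "F5": self.f5}[level]
        except KeyError:
            raise KeyError(f"missing pyramid level {level!r}") from None


_STRIDES = {"F2": 4, "F3": 8, "F4": 16, "F5": 32}


class FeatureAligner(Module):
    """Project each requested level to a common width, then resample it
    to the target level's grid (channel projection happens first;
    average pooling down, bilinear interpolation up)."""

    def __init__(self, in_channels: Dict[str, int], target_level: str, target_channels: int):
        super().__init__()
        if target_level not in ("P3", "P4"):
            raise ValueError("target_level must be 'P3' or 'P4'")
        if target_channels < 1:
            raise ValueError("target_channels must be >= 1")
        self.levels = list(in_channels)
        self.target_stride = {"P3": 8, "P4": 16}[target_level]
        for lv, c in in_channels.items():
            setattr(self, f"proj_{lv}", ConvBNAct(c, target_channels, 1))

    def forward(self, levels: PyramidFeatures) -> Dict[str, Tensor]:
        out = {}
        for lv in self.levels:
            x = getattr(self, f"proj_{lv}")(levels[lv])
            ratio = self.target_stride / _STRIDES[lv]
            if ratio > 1:
                x = F.avg_pool2d(x, int(ratio))
            elif ratio < 1:
                _, _, h, w = x.shape
                scale = int(1 / ratio)
                x = F.interpolate_bilinear(x, (h * scale, w * scale))
            out[lv] = x
        return out


def pfa_initial_fusion(aligned: Dict[str, Tensor], conv: Conv2d) -> Tensor:
    """Conv1x1(Concat((F2'⊗F3')⊕F4', F5'))."""
    f2, f3, f4, f5 = (aligned[k] for k in ("F2", "F3", "F4", "F5"))
    if not (f2.shape == f3.shape == f4.shape == f5.shape):
        raise ValueError("aligned features must share one shape")
    mixed = f2 * f3 + f4
    return conv(F.concat([mixed, f5], axis=1))


def dfs_initial_fusion(aligned: Dict[str, Tensor]) -> Tensor:
    """(F3''⊗F4'')⊕F5'' — purely element-wise, no convolution."""
    f3, f4, f5 = (aligned[k] for k in ("F3", "F4", "F5"))
    if not (f3.shape == f4.shape == f5.shape):
        raise ValueError("aligned features must share one shape")
    return f3 * f4 + f5


class PFA(Module):
    def __init__(self, in_channels: Tuple[int, int, int, int], channels: int):
        super().__init__()
        c2, c3, c4, c5 = in_channels
        if channels % 2:
            raise ValueError("PFA channel width must be even (two half-width branches)")
        self.channels = channels
        self.align = FeatureAligner(
            {"F2": c2, "F3": c3, "F4": c4, "F5": c5}, "P3", channels
        )
        self.fuse = Conv2d(2 * channels, channels, 1)
        self.ac3 = AsymmetricBranch(channels, channels // 2, 3)
        self.ac5 = AsymmetricBranch(channels, channels // 2, 5)

    def initial_fusion(self, levels: PyramidFeatures) -> Tensor:
        return pfa_initial_fusion(self.align(levels), self.fuse)

    def forward(self, levels: PyramidFeatures) -> Tensor:
        f_init = self.initial_fusion(levels)
        branches = F.concat([self.ac3(f_init), self.ac5(f_init)], axis=1)
        return branches + f_init


class DFS(Module):
    def __init__(self, in_channels: Tuple[int, int, int], channels: int, n_heads: int = 4):
        super().__init__()
        c3, c4, c5 = in_channels
        self.channels = channels
        self.out_channels = 2 * channels
        self.align = FeatureAligner({"F3": c3, "F4": c4, "F5": c5}, "P4", channels)
        self.ac3 = AsymmetricBranch(channels, channels, 3)
        self.ac5 = AsymmetricBranch(channels, channels, 5)
        self.encoder = TransformerEncoderLayer(
            AttentionConfig(embed_dim=2 * channels, n_heads=n_heads)
        )
        self.residual_proj = Conv2d(channels, 2 * channels, 1)

    def initial_fusion(self, levels: PyramidFeatures) -> Tensor:
        return dfs_initial_fusion(self.align(levels))

    def forward(self, levels: PyramidFeatures) -> Tensor:
        f_init = self.initial_fusion(levels)
        combined = F.concat([self.ac3(f_init), self.ac5(f_init)], axis=1)
        _, _, h, w = combined.shape
        t_attn = self.encoder(tokenize(combined))
        f_transformer = detokenize(t_attn, h, w)
        return f_transformer + self.residual_proj(f_init)
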