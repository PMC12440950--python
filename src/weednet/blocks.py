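"""Computational building blocks of the segmentation network.

The vocabulary follows the lightweight-detector literature:

* ``ConvBNAct`` — convolution + batch norm + SiLU, the base unit.
* ``UIB`` / ``ResUIB`` — (residual) unified inverted bottlenecks with a
  narrow→expand→narrow channel pattern and depthwise 3×3 convolutions.
* ``CSPMUIB`` — a cross-stage-partial block whose transform branch is a
  ResUIB stack and whose second branch is a stride-1 3×3 max pool,
  densely aggregated before a 1×1 fusion.
* ``AsymmetricBranch`` — a factorized 1×k → k×1 convolution pair.
* ``TransformerEncoderLayer`` — one pre-norm multi-head self-attention
  + feed-forward layer operating on token sequences.
* ``SPPF`` and ``C2PSA`` — the serial pyramid-pooling and partial
  pointwise-spatial-attention blocks retained from the base detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .nn import BatchNorm2d, Conv2d, LayerNorm, Linear, Module, ModuleList, Sequential
from .nn import functional as F
from .nn.autograd import Tensor


@dataclass
class BlockConfig:
    """Configuration of a CSP-MUIB block.

    Parameters
    ----------
    split_ratio:
        Fraction ``e`` of the output width given to each of the two
        cross-stage paths after the expanding 1×1 convolution.
    expansion:
        Factor ``E`` by which the inverted bottlenecks widen their
        hidden representation.
    n_resuib:
        Number of residual unified inverted blocks stacked on the
        transform path.
    """

    in_channels: int
    out_channels: int
    split_ratio: float = 0.5
    expansion: float = 2.0
    n_resuib: int = 1
    norm_eps: float = 1e-3

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio e must lie in (0, 1)")
        if self.expansion <= 0:
            raise ValueError("expansion E must be positive")
        if self.n_resuib < 0:
            raise ValueError("n_resuib must be non-negative")
        if self.hidden_channels < 1:
            raise ValueError("e * out_channels rounds below one channel")
        if int(round(self.expansion * self.hidden_channels)) < 1:
            raise ValueError("E * hidden width rounds below one channel")

    @property
    def hidden_channels(self) -> int:
        return int(round(self.out_channels * self.split_ratio))


@dataclass
class AttentionConfig:
    embed_dim: int
    n_heads: int = 4
    ffn_ratio: float = 2.0
    norm_eps: float = 1e-5

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def ffn_hidden(self) -> int:
        return int(self.embed_dim * self.ffn_ratio)


class ConvBNAct(Module):
    """Conv → BatchNorm → SiLU with 'same' padding at stride 1."""

    def __init__(self, cin: int, cout: int, kernel=1, stride=1, groups: int = 1,
                 act: bool = True):
        super().__init__()
        kh, kw = F._pair(kernel)
        self.conv = Conv2d(cin, cout, (kh, kw), stride=stride,
                           padding=(kh // 2, kw // 2), groups=groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(self.conv(x))
        return F.silu(x) if self.act else x


class UIB(Module):
    """Unified inverted bottleneck, extra-depthwise variant.

    depthwise 3×3 → 1×1 expand (×E) → depthwise 3×3 → 1×1 linear project.
    """

    def __init__(self, cin: int, cout: int, expansion: float = 2.0):
        super().__init__()
        hidden = int(round(cin * expansion))
        if hidden < 1:
            raise ValueError("expansion collapses the hidden width to zero")
        self.dw1 = ConvBNAct(cin, cin, 3, groups=cin)
        self.expand = ConvBNAct(cin, hidden, 1)
        self.dw2 = ConvBNAct(hidden, hidden, 3, groups=hidden)
        self.project = ConvBNAct(hidden, cout, 1, act=False)
        self.hidden_channels = hidden

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.dw2(self.expand(self.dw1(x))))


class ResUIB(Module):
    """Two UIBs, each wrapped in an identity skip (channel-preserving)."""

    def __init__(self, channels: int, expansion: float = 2.0):
        super().__init__()
        self.uib1 = UIB(channels, channels, expansion)
        self.uib2 = UIB(channels, channels, expansion)

    def forward(self, x: Tensor) -> Tensor:
        y = x + self.uib1(x)
        return y + self.uib2(y)


class CSPMUIB(Module):
    """Cross-stage pooling + unified-inverted-bottleneck block.

    A 1×1 convolution expands the input to two `hidden`-wide halves
    (a, b). Half `a` feeds a stride-1 3×3 max pool and is also carried
    through untouched as the cross-stage connection; half `b` runs
    through ``n`` ResUIBs whose intermediate outputs (including `b`
    itself) are all retained. Everything is concatenated —
    ``hidden * (n + 3)`` channels — and fused by a final 1×1.
    """

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        self.cfg = cfg
        h = cfg.hidden_channels
        self.expand = ConvBNAct(cfg.in_channels, 2 * h, 1)
        self.stack = ModuleList(
            ResUIB(h, cfg.expansion) for _ in range(cfg.n_resuib)
        )
        self.fuse = ConvBNAct(h * (cfg.n_resuib + 3), cfg.out_channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        h = self.cfg.hidden_channels
        z = self.expand(x)
        a = z[:, :h]
        b = z[:, h:]
        feats = [F.max_pool2d(a, 3, 1, 1), b]
        for block in self.stack:
            b = block(b)
            feats.append(b)
        feats.append(a)
        return self.fuse(F.concat(feats, axis=1))


class AsymmetricBranch(Module):
    """Factorized convolution: 1×k → BN → SiLU → k×1 → BN → SiLU."""

    def __init__(self, cin: int, cout: int, k: int):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("asymmetric branch requires an odd kernel length")
        self.conv_1xk = ConvBNAct(cin, cout, (1, k))
        self.conv_kx1 = ConvBNAct(cout, cout, (k, 1))

    def forward(self, x: Tensor) -> Tensor:
        return self.conv_kx1(self.conv_1xk(x))


def tokenize(x: Tensor) -> Tensor:
    """(B, C, H, W) → (B, H·W, C): one token per pixel, channel as depth."""
    b, c, h, w = x.shape
    return F.transpose(x, (0, 2, 3, 1)).reshape(b, h * w, c)


def detokenize(t: Tensor, height: int, width: int) -> Tensor:
    """Inverse of :func:`tokenize`; bit-exact round trip."""
    b, n, d = t.shape
    if n != height * width:
        raise ValueError(f"sequence length {n} != {height}x{width}")
    return F.transpose(t.reshape(b, height, width, d), (0, 3, 1, 2))


class MultiHeadSelfAttention(Module):
    def __init__(self, cfg: AttentionConfig):
        super().__init__()
        self.cfg = cfg
        d = cfg.embed_dim
        self.wq = Linear(d, d)
        self.wk = Linear(d, d)
        self.wv = Linear(d, d)
        self.wo = Linear(d, d)

    def forward(self, t: Tensor) -> Tensor:
        b, n, d = t.shape
        h, dk = self.cfg.n_heads, self.cfg.head_dim
        def split(x):  # (B,N,D) -> (B,h,N,dk)
            return F.transpose(x.reshape(b, n, h, dk), (0, 2, 1, 3))
        q, k, v = split(self.wq(t)), split(self.wk(t)), split(self.wv(t))
        logits = F.matmul(q, F.transpose(k, (0, 1, 3, 2))) * (1.0 / math.sqrt(dk))
        attn = F.softmax(logits, axis=-1)
        out = F.matmul(attn, v)  # (B,h,N,dk)
        out = F.transpose(out, (0, 2, 1, 3)).reshape(b, n, d)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer: T′ = T + MHSA(LN(T)); out = T′ + FFN(LN(T′))."""

    def __init__(self, cfg: AttentionConfig):
        super().__init__()
        self.cfg = cfg
        self.ln1 = LayerNorm(cfg.embed_dim, cfg.norm_eps)
        self.attn = MultiHeadSelfAttention(cfg)
        self.ln2 = LayerNorm(cfg.embed_dim, cfg.norm_eps)
        self.ffn1 = Linear(cfg.embed_dim, cfg.ffn_hidden)
        self.ffn2 = Linear(cfg.ffn_hidden, cfg.embed_dim)

    def forward(self, t: Tensor) -> Tensor:
        t1 = t + self.attn(self.ln1(t))
        return t1 + self.ffn2(F.silu(self.ffn1(self.ln2(t1))))


class SPPF(Module):
    """Serial spatial pyramid pooling (three chained 5×5 stride-1 pools)."""

    def __init__(self, cin: int, cout: int, pool_kernel: int = 5):
        super().__init__()
        h = cin // 2
        self.cv1 = ConvBNAct(cin, h, 1)
        self.cv2 = ConvBNAct(4 * h, cout, 1)
        self.k = pool_kernel

    def forward(self, x: Tensor) -> Tensor:
        x = self.cv1(x)
        p = self.k // 2
        y1 = F.max_pool2d(x, self.k, 1, p)
        y2 = F.max_pool2d(y1, self.k, 1, p)
        y3 = F.max_pool2d(y2, self.k, 1, p)
        return self.cv2(F.concat([x, y1, y2, y3], axis=1))


class _PSABlock(Module):
    """Pointwise spatial attention over pixel tokens + conv feed-forward."""

    def __init__(self, channels: int, n_heads: int = 4):
        super().__init__()
        self.q = Conv2d(channels, channels // 2, 1, bias=False)
        self.k = Conv2d(channels, channels // 2, 1, bias=False)
        self.v = Conv2d(channels, channels, 1, bias=False)
        self.pe = Conv2d(channels, channels, 3, padding=1, groups=channels, bias=False)
        self.proj = ConvBNAct(channels, channels, 1, act=False)
        self.ffn = Sequential(
            ConvBNAct(channels, channels * 2, 1), ConvBNAct(channels * 2, channels, 1, act=False)
        )
        self.heads = n_heads
        self.qk_dim = channels // 2

    def forward(self, x: Tensor) -> Tensor:
        b, c, hh, ww = x.shape
        n = hh * ww
        h = self.heads
        dqk = self.qk_dim // h
        dv = c // h
        q = F.transpose(self.q(x).reshape(b, h, dqk, n), (0, 1, 3, 2))
        k = self.k(x).reshape(b, h, dqk, n)
        v = self.v(x).reshape(b, h, dv, n)
        attn = F.softmax(F.matmul(q, k) * (1.0 / math.sqrt(dqk)), axis=-1)  # (b,h,n,n)
        out = F.matmul(v, F.transpose(attn, (0, 1, 3, 2))).reshape(b, c, hh, ww)
        out = out + self.pe(self.v(x))
        x = x + self.proj(out)
        return x + self.ffn(x)


class C2PSA(Module):
    """Cross-stage partial wrapper around pointwise spatial attention."""

    def __init__(self, cin: int, cout: int, n: int = 1):
        super().__init__()
        self.h = cin // 2
        self.cv1 = ConvBNAct(cin, 2 * self.h, 1)
        self.blocks = ModuleList(_PSABlock(self.h) for _ in range(n))
        self.cv2 = ConvBNAct(2 * self.h, cout, 1)

    def forward(self, x: Tensor) -> Tensor:
        z = self.cv1(x)
        a, b = z[:, : self.h], z[:, self.h :]
        for blk in self.blocks:
            b = blk(b)
        return self.cv2(F.concat([a, b], axis=1))
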