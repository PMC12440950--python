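"""Unit tests of the computational building blocks."""

import math

import numpy as np
import pytest

from weednet.blocks import (
    AsymmetricBranch,
    AttentionConfig,
    BlockConfig,
    CSPMUIB,
    ConvBNAct,
    MultiHeadSelfAttention,
    ResUIB,
    TransformerEncoderLayer,
    UIB,
    detokenize,
    tokenize,
)
from weednet.nn import functional as F
from weednet.nn.autograd import Tensor, no_grad

rng = np.random.default_rng(42)


def rand(*shape):
    return Tensor(rng.standard_normal(shape).astype(np.float32))


def eval_bn_stats(x, gamma, beta, eps=1e-3):
    return (x / math.sqrt(1.0 + eps)) * gamma + beta


# ---------------------------------------------------------------------------
# ConvBNAct
# ---------------------------------------------------------------------------

class TestConvBNAct:
    def test_zero_input_zero_shift_gives_zero_output(self):
        m = ConvBNAct(4, 8, 3)
        m.eval()
        out = m(Tensor(np.zeros((1, 4, 6, 6), np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_stride_one_preserves_spatial_size(self):
        m = ConvBNAct(64, 64, 3)
        out = m(rand(1, 64, 80, 80))
        assert out.shape == (1, 64, 80, 80)

    def test_trainable_tensor_count_matches_enumeration(self):
        # conv 3->16 with 3x3 kernel, no conv bias, affine norm:
        # 3*16*9 weights + 16 gammas + 16 betas = 464
        m = ConvBNAct(3, 16, 3)
        assert m.n_parameters() == 3 * 16 * 9 + 16 + 16 == 464

    def test_invalid_kernel_or_stride_rejected(self):
        with pytest.raises(ValueError):
            ConvBNAct(3, 8, 0)
        with pytest.raises(ValueError):
            ConvBNAct(3, 8, 3, stride=0)


# ---------------------------------------------------------------------------
# UIB / ResUIB
# ---------------------------------------------------------------------------

class TestUIB:
    def test_narrow_expand_narrow_channel_pattern(self):
        m = UIB(32, 32, expansion=2.0)
        assert m.hidden_channels == 64
        out = m(rand(1, 32, 8, 8))
        assert out.shape == (1, 32, 8, 8)

    def test_zero_input_gives_zero_output(self):
        m = UIB(8, 8)
        m.eval()
        out = m(Tensor(np.zeros((1, 8, 5, 5), np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_parameter_count_matches_tensor_enumeration(self):
        cin, e = 16, 2.0
        m = UIB(cin, cin, e)
        hidden = int(cin * e)
        expected = (
            (cin * 9 + 2 * cin)                 # depthwise 3x3 + norm
            + (cin * hidden + 2 * hidden)       # 1x1 expand + norm
            + (hidden * 9 + 2 * hidden)         # depthwise 3x3 + norm
            + (hidden * cin + 2 * cin)          # 1x1 project + norm
        )
        assert m.n_parameters() == expected

    def test_vanishing_expansion_rejected(self):
        with pytest.raises(ValueError):
            UIB(2, 2, expansion=0.1)


class TestResUIB:
    def test_zeroed_projections_reduce_to_identity(self):
        m = ResUIB(16)
        m.eval()
        for uib in (m.uib1, m.uib2):
            uib.project.conv.weight.data[:] = 0.0
        x = rand(2, 16, 6, 6)
        out = m(x)
        assert np.allclose(out.data, x.data, atol=1e-6)

    def test_shape_preserved(self):
        m = ResUIB(64)
        assert m(rand(1, 64, 40, 40)).shape == (1, 64, 40, 40)

    def test_forward_equals_unrolled_composition(self):
        m = ResUIB(8)
        m.eval()
        x = rand(1, 8, 5, 5)
        with no_grad():
            y = Tensor(x.data + m.uib1(x).data)
            expected = y.data + m.uib2(y).data
            out = m(x)
        assert np.allclose(out.data, expected, atol=1e-6)


# ---------------------------------------------------------------------------
# CSP-MUIB
# ---------------------------------------------------------------------------

class TestCSPMUIB:
    def test_declared_shape_contract(self):
        m = CSPMUIB(BlockConfig(64, 64, n_resuib=1))
        assert m(rand(1, 64, 80, 80)).shape == (1, 64, 80, 80)

    def test_degenerate_stack_n0_still_well_formed(self):
        m = CSPMUIB(BlockConfig(32, 48, n_resuib=0))
        out = m(rand(2, 32, 10, 10))
        assert out.shape == (2, 48, 10, 10)
        assert np.isfinite(out.data).all()

    def test_concat_width_is_hidden_times_n_plus_3(self):
        cfg = BlockConfig(64, 64, n_resuib=2)
        m = CSPMUIB(cfg)
        assert m.fuse.conv.weight.shape[1] == cfg.hidden_channels * (2 + 3)

    def test_maxpool_path_equals_sliding_window_oracle(self, rng):
        for _ in range(100):
            x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
            out = F.max_pool2d(Tensor(x), 3, 1, 1).data
            padded = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
            expected = np.empty_like(x)
            for i in range(6):
                for j in range(6):
                    expected[..., i, j] = padded[..., i : i + 3, j : j + 3].max(axis=(-1, -2))
            assert np.array_equal(out, expected)

    def test_impulse_maxpool_matches_brute_force(self):
        x = np.zeros((1, 1, 7, 7), np.float32)
        x[0, 0, 3, 4] = 1.0
        out = F.max_pool2d(Tensor(x), 3, 1, 1).data
        assert out.sum() == 9.0  # the impulse wins in its 3x3 neighbourhood
        assert out[0, 0, 3, 4] == 1.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BlockConfig(8, 8, split_ratio=0.0)
        with pytest.raises(ValueError):
            BlockConfig(8, 8, split_ratio=1.2)
        with pytest.raises(ValueError):
            BlockConfig(8, 1, split_ratio=0.1)  # e*out rounds below 1
        with pytest.raises(ValueError):
            BlockConfig(8, 8, n_resuib=-1)


# ---------------------------------------------------------------------------
# Asymmetric (factorized) convolution branch
# ---------------------------------------------------------------------------

class TestAsymmetricBranch:
    def test_zero_input_zero_shift_gives_zero(self):
        m = AsymmetricBranch(4, 4, 3)
        m.eval()
        out = m(Tensor(np.zeros((1, 4, 5, 5), np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_spatial_size_preserved(self):
        for k in (3, 5):
            m = AsymmetricBranch(6, 3, k)
            assert m(rand(1, 6, 9, 11)).shape == (1, 3, 9, 11)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            AsymmetricBranch(4, 4, 4)

    @pytest.mark.parametrize("k", [3, 5])
    def test_matches_sequential_direct_convolution_oracle(self, k):
        m = AsymmetricBranch(2, 3, k)
        m.eval()
        x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
        out = m(Tensor(x)).data

        def direct(x_in, w, pad_hw):
            cout, cin, kh, kw = w.shape
            b, _, h, wdt = x_in.shape
            xp = np.pad(x_in, ((0, 0), (0, 0), (pad_hw[0], pad_hw[0]), (pad_hw[1], pad_hw[1])))
            res = np.zeros((b, cout, h, wdt), np.float64)
            for co in range(cout):
                for ci in range(cin):
                    for dy in range(kh):
                        for dx in range(kw):
                            res[:, co] += w[co, ci, dy, dx] * xp[:, ci, dy : dy + h, dx : dx + wdt]
            return res

        def silu(v):
            return v / (1.0 + np.exp(-v))

        w1 = m.conv_1xk.conv.weight.data
        y = direct(x, w1, (0, k // 2))
        y = silu(eval_bn_stats(y, m.conv_1xk.bn.weight.data.reshape(1, -1, 1, 1),
                               m.conv_1xk.bn.bias.data.reshape(1, -1, 1, 1)))
        w2 = m.conv_kx1.conv.weight.data
        y = direct(y.astype(np.float32), w2, (k // 2, 0))
        y = silu(eval_bn_stats(y, m.conv_kx1.bn.weight.data.reshape(1, -1, 1, 1),
                               m.conv_kx1.bn.bias.data.reshape(1, -1, 1, 1)))
        assert np.abs(out - y).max() < 1e-5


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def mhsa_oracle(layer: TransformerEncoderLayer, t: np.ndarray) -> np.ndarray:
    """Loop-based re-computation of the encoder layer from its weights."""
    cfg = layer.cfg

    def ln(v, g, b, eps):
        mu = v.mean(-1, keepdims=True)
        var = v.var(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + eps) * g + b

    def lin(v, w, b):
        return v @ w.T + b

    tn = ln(t, layer.ln1.weight.data, layer.ln1.bias.data, cfg.norm_eps)
    q = lin(tn, layer.attn.wq.weight.data, layer.attn.wq.bias.data)
    k = lin(tn, layer.attn.wk.weight.data, layer.attn.wk.bias.data)
    v = lin(tn, layer.attn.wv.weight.data, layer.attn.wv.bias.data)
    b, n, d = t.shape
    h, dk = cfg.n_heads, cfg.head_dim
    heads = []
    for bi in range(b):
        rows = []
        for hi in range(h):
            qs = q[bi, :, hi * dk : (hi + 1) * dk]
            ks = k[bi, :, hi * dk : (hi + 1) * dk]
            vs = v[bi, :, hi * dk : (hi + 1) * dk]
            logits = qs @ ks.T / math.sqrt(dk)
            e = np.exp(logits - logits.max(-1, keepdims=True))
            attn = e / e.sum(-1, keepdims=True)
            rows.append(attn @ vs)
        heads.append(np.concatenate(rows, axis=-1))
    concat = np.stack(heads)
    t1 = t + lin(concat, layer.attn.wo.weight.data, layer.attn.wo.bias.data)
    tn2 = ln(t1, layer.ln2.weight.data, layer.ln2.bias.data, cfg.norm_eps)
    hdn = lin(tn2, layer.ffn1.weight.data, layer.ffn1.bias.data)
    hdn = hdn / (1.0 + np.exp(-hdn))
    return t1 + lin(hdn, layer.ffn2.weight.data, layer.ffn2.bias.data)


class TestAttention:
    def test_zero_input_gives_zero_output(self):
        layer = TransformerEncoderLayer(AttentionConfig(8, 2))
        out = layer(Tensor(np.zeros((1, 4, 8), np.float32)))
        assert np.allclose(out.data, 0.0, atol=1e-7)

    def test_single_token_attention_returns_value_row(self):
        attn = MultiHeadSelfAttention(AttentionConfig(8, 2))
        t = rand(1, 1, 8)
        # with one key, softmax weight is exactly 1, so MHSA = Wo(V(t))
        with no_grad():
            v = F.linear(t, attn.wv.weight, attn.wv.bias)
            expected = F.linear(v, attn.wo.weight, attn.wo.bias)
            out = attn(t)
        assert np.allclose(out.data, expected.data, atol=1e-6)

    def test_random_case_matches_loop_oracle(self):
        layer = TransformerEncoderLayer(AttentionConfig(4, 2))
        t = rng.standard_normal((2, 3, 4)).astype(np.float32)
        with no_grad():
            out = layer(Tensor(t)).data
        assert np.abs(out - mhsa_oracle(layer, t)).max() < 1e-5

    def test_attention_rows_sum_to_one(self):
        attn = MultiHeadSelfAttention(AttentionConfig(8, 4))
        t = rand(1, 5, 8)
        with no_grad():
            q = F.linear(t, attn.wq.weight, attn.wq.bias)
            k = F.linear(t, attn.wk.weight, attn.wk.bias)
        b, n, d = t.shape
        h, dk = 4, 2
        qh = q.data.reshape(b, n, h, dk).transpose(0, 2, 1, 3)
        kh = k.data.reshape(b, n, h, dk).transpose(0, 2, 1, 3)
        logits = qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(dk)
        e = np.exp(logits - logits.max(-1, keepdims=True))
        weights = e / e.sum(-1, keepdims=True)
        assert np.allclose(weights.sum(-1), 1.0, atol=1e-6)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(10, 4)

    def test_zeroed_output_projections_reduce_to_identity(self):
        layer = TransformerEncoderLayer(AttentionConfig(8, 2))
        layer.attn.wo.weight.data[:] = 0.0
        layer.ffn2.weight.data[:] = 0.0
        t = rand(2, 3, 8)
        with no_grad():
            out = layer(t)
        assert np.allclose(out.data, t.data, atol=1e-6)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("h,w", [(8, 8), (10, 14), (7, 9), (16, 5)])
def test_stride_one_blocks_preserve_spatial_size(h, w):
    x = rand(1, 16, h, w)
    for block in (
        ConvBNAct(16, 8, 3),
        UIB(16, 16),
        ResUIB(16),
        CSPMUIB(BlockConfig(16, 16, n_resuib=1)),
        AsymmetricBranch(16, 8, 5),
    ):
        out = block(x)
        assert out.shape[2:] == (h, w), type(block).__name__


def test_tokenize_detokenize_roundtrip_is_bit_exact():
    x = rand(1, 8, 4, 4)
    t = tokenize(x)
    assert t.shape == (1, 16, 8)
    back = detokenize(t, 4, 4)
    assert np.array_equal(back.data, x.data)


def test_token_index_arithmetic_is_row_major_per_pixel():
    b, c, h, w = 1, 3, 2, 4
    x = np.arange(b * c * h * w, dtype=np.float32).reshape(b, c, h, w)
    t = tokenize(Tensor(x)).data
    for n in range(h * w):
        for d in range(c):
            assert t[0, n, d] == x[0, d, n // w, n % w]
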