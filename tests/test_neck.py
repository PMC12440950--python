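"""Tests of the PFA/DFS fusion necks and feature alignment."""

import numpy as np
import pytest

from weednet.neck import (
    DFS,
    FeatureAligner,
    PFA,
    PyramidFeatures,
    dfs_initial_fusion,
    pfa_initial_fusion,
)
from weednet.nn import functional as F
from weednet.nn.autograd import Tensor, no_grad

rng = np.random.default_rng(7)


def pyramid(b=1, c=(8, 16, 16, 32), base=16):
    return PyramidFeatures(
        f2=Tensor(rng.standard_normal((b, c[0], base * 2, base * 2)).astype(np.float32)),
        f3=Tensor(rng.standard_normal((b, c[1], base, base)).astype(np.float32)),
        f4=Tensor(rng.standard_normal((b, c[2], base // 2, base // 2)).astype(np.float32)),
        f5=Tensor(rng.standard_normal((b, c[3], base // 4, base // 4)).astype(np.float32)),
    )


class TestAlignment:
    def test_constant_map_survives_average_pooling(self):
        aligner = FeatureAligner({"F2": 4}, "P3", 6)
        aligner.eval()
        levels = pyramid(c=(4, 16, 16, 32))
        levels.f2.data[:] = 1.0
        out = aligner(levels)["F2"]
        assert out.shape[2:] == (16, 16)
        # projection of a constant is constant; 2x2 mean preserves it
        assert np.allclose(out.data, out.data[..., :1, :1], atol=1e-5)

    def test_constant_map_survives_bilinear_upsampling(self):
        aligner = FeatureAligner({"F5": 32}, "P4", 6)
        aligner.eval()
        levels = pyramid()
        levels.f5.data[:] = 2.0
        out = aligner(levels)["F5"]
        assert out.shape[2:] == (8, 8)
        assert np.allclose(out.data, out.data[..., :1, :1], atol=1e-5)

    def test_average_pooling_equals_block_mean_oracle(self):
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        out = F.avg_pool2d(Tensor(x), 2).data
        expected = x.reshape(1, 3, 2, 2, 2, 2).mean(axis=(3, 5))
        assert np.allclose(out, expected, atol=1e-7)

    def test_missing_level_raises(self):
        levels = pyramid()
        with pytest.raises(KeyError):
            levels["F9"]

    def test_invalid_pyramid_rejected(self):
        with pytest.raises(ValueError):
            PyramidFeatures(
                f2=Tensor(np.zeros((1, 4, 10, 10), np.float32)),
                f3=Tensor(np.zeros((1, 4, 6, 6), np.float32)),
                f4=Tensor(np.zeros((1, 4, 3, 3), np.float32)),
                f5=Tensor(np.zeros((1, 4, 2, 2), np.float32)),
            )


class TestPFAInitialFusion:
    def test_ones_f2_reduces_multiplicative_term(self):
        pfa = PFA((8, 16, 16, 32), 8)
        pfa.eval()
        levels = pyramid()
        aligned = pfa.align(levels)
        aligned["F2"] = Tensor(np.ones_like(aligned["F2"].data))
        out = pfa_initial_fusion(aligned, pfa.fuse)
        mixed = aligned["F3"].data + aligned["F4"].data
        expected = pfa.fuse(
            F.concat([Tensor(mixed), aligned["F5"]], axis=1)
        ).data
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_zero_inputs_zero_shifts_give_zero(self):
        pfa = PFA((8, 16, 16, 32), 8)
        pfa.eval()
        zeros = {
            k: Tensor(np.zeros((1, 8, 16, 16), np.float32))
            for k in ("F2", "F3", "F4", "F5")
        }
        pfa.fuse.bias.data[:] = 0.0
        out = pfa_initial_fusion(zeros, pfa.fuse)
        assert np.allclose(out.data, 0.0)

    def test_matches_elementwise_oracle(self):
        pfa = PFA((8, 16, 16, 32), 8)
        aligned = {
            k: Tensor(rng.standard_normal((1, 2, 4, 4)).astype(np.float32))
            for k in ("F2", "F3", "F4", "F5")
        }
        conv = pfa.fuse
        conv.weight.data = rng.standard_normal((2, 4, 1, 1)).astype(np.float32)
        conv.bias.data = rng.standard_normal(2).astype(np.float32)
        with no_grad():
            out = pfa_initial_fusion(aligned, conv).data
        mixed = aligned["F2"].data * aligned["F3"].data + aligned["F4"].data
        stacked = np.concatenate([mixed, aligned["F5"].data], axis=1)
        w = conv.weight.data[:, :, 0, 0]
        expected = np.einsum("oc,bchw->bohw", w, stacked) + conv.bias.data.reshape(1, -1, 1, 1)
        assert np.abs(out - expected).max() < 1e-5

    def test_shape_mismatch_rejected(self):
        pfa = PFA((8, 16, 16, 32), 8)
        aligned = {
            "F2": Tensor(np.zeros((1, 8, 4, 4), np.float32)),
            "F3": Tensor(np.zeros((1, 8, 4, 4), np.float32)),
            "F4": Tensor(np.zeros((1, 8, 8, 8), np.float32)),
            "F5": Tensor(np.zeros((1, 8, 4, 4), np.float32)),
        }
        with pytest.raises(ValueError):
            pfa_initial_fusion(aligned, pfa.fuse)


class TestDFSInitialFusion:
    def test_ones_f3_reduces_to_sum(self):
        a = {
            "F3": Tensor(np.ones((1, 3, 4, 4), np.float32)),
            "F4": Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32)),
            "F5": Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32)),
        }
        out = dfs_initial_fusion(a)
        assert np.allclose(out.data, a["F4"].data + a["F5"].data, atol=1e-6)

    def test_zero_f3_f4_reduces_to_f5(self):
        a = {
            "F3": Tensor(np.zeros((1, 3, 4, 4), np.float32)),
            "F4": Tensor(np.zeros((1, 3, 4, 4), np.float32)),
            "F5": Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32)),
        }
        assert np.allclose(dfs_initial_fusion(a).data, a["F5"].data)

    def test_matches_elementwise_oracle(self):
        a = {
            k: Tensor(rng.standard_normal((2, 3, 5, 5)).astype(np.float32))
            for k in ("F3", "F4", "F5")
        }
        out = dfs_initial_fusion(a).data
        expected = a["F3"].data * a["F4"].data + a["F5"].data
        assert np.abs(out - expected).max() < 1e-6


class TestNeckForward:
    def test_pfa_output_lives_on_p3_grid(self):
        pfa = PFA((8, 16, 16, 32), 8)
        for base in (8, 16):
            out = pfa(pyramid(base=base))
            assert out.shape == (1, 8, base, base)

    def test_pfa_zero_pyramid_gives_zero(self):
        pfa = PFA((8, 16, 16, 32), 8)
        pfa.eval()
        pfa.fuse.bias.data[:] = 0.0
        levels = pyramid()
        for f in (levels.f2, levels.f3, levels.f4, levels.f5):
            f.data[:] = 0.0
        assert np.allclose(pfa(levels).data, 0.0)

    def test_pfa_zeroed_branches_reduce_to_initial_fusion(self):
        pfa = PFA((8, 16, 16, 32), 8)
        pfa.eval()
        for branch in (pfa.ac3, pfa.ac5):
            branch.conv_kx1.conv.weight.data[:] = 0.0
        levels = pyramid()
        with no_grad():
            out = pfa(levels)
            f_init = pfa.initial_fusion(levels)
        assert np.allclose(out.data, f_init.data, atol=1e-6)

    def test_dfs_output_lives_on_p4_grid_with_doubled_channels(self):
        dfs = DFS((16, 16, 32), 8)
        for base in (8, 16):
            out = dfs(pyramid(base=base))
            assert out.shape == (1, 16, base // 2, base // 2)

    def test_dfs_zero_pyramid_gives_zero(self):
        dfs = DFS((16, 16, 32), 8)
        dfs.eval()
        dfs.residual_proj.bias.data[:] = 0.0
        levels = pyramid()
        for f in (levels.f2, levels.f3, levels.f4, levels.f5):
            f.data[:] = 0.0
        assert np.allclose(dfs(levels).data, 0.0, atol=1e-7)

    def test_dfs_zeroed_attention_and_branches_reduce_to_projection(self):
        dfs = DFS((16, 16, 32), 8)
        dfs.eval()
        for branch in (dfs.ac3, dfs.ac5):
            branch.conv_kx1.conv.weight.data[:] = 0.0
        levels = pyramid()
        with no_grad():
            out = dfs(levels)
            expected = dfs.residual_proj(dfs.initial_fusion(levels))
        assert np.allclose(out.data, expected.data, atol=1e-6)

    def test_every_input_level_influences_the_output(self):
        pfa = PFA((8, 16, 16, 32), 8)
        pfa.eval()
        levels = pyramid()
        with no_grad():
            base = float(pfa(levels).data.sum())
        for f in ("f2", "f3", "f4", "f5"):
            getattr(levels, f).data[0, 0, 0, 0] += 1.0
            with no_grad():
                bumped = float(pfa(levels).data.sum())
            getattr(levels, f).data[0, 0, 0, 0] -= 1.0
            assert bumped != pytest.approx(base, abs=1e-9), f

    def test_dfs_inputs_connected(self):
        dfs = DFS((16, 16, 32), 8)
        dfs.eval()
        levels = pyramid()
        with no_grad():
            base = float(dfs(levels).data.sum())
        for f in ("f3", "f4", "f5"):
            getattr(levels, f).data[0, 0, 0, 0] += 1.0
            with no_grad():
                bumped = float(dfs(levels).data.sum())
            getattr(levels, f).data[0, 0, 0, 0] -= 1.0
            assert bumped != pytest.approx(base, abs=1e-9), f
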