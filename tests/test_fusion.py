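"""MFF blocks and the assembled edge-guided network."""

import numpy as np
import pytest
from autograd import grad
from scipy.special import expit

from lemunet import build_backbone, build_lemunet
from lemunet.fusion import MFF2, highfreq_residual, mff1
from lemunet.losses import combined_loss, default_loss_weights
from lemunet.nn import count_parameters, tree_leaves
from lemunet.pyramid import Volume, build_laplacian_pyramid


def highfreq_oracle(fd):
    """Channel-looped one-level pyramid residual via the Volume API."""
    out = np.empty_like(fd)
    for n in range(fd.shape[0]):
        for c in range(fd.shape[1]):
            pyr = build_laplacian_pyramid(Volume(np.asarray(fd[n, c], dtype=np.float64)), K=1)
            out[n, c] = pyr.levels[0].values
    return out


class TestHighfreqResidual:
    def test_constant_channels_give_zero(self):
        fd = np.full((1, 2, 8, 8, 8), 1.7, dtype=np.float32)
        np.testing.assert_allclose(highfreq_residual(fd), 0.0, atol=1e-6)

    def test_matches_channel_looped_pyramid_oracle(self, rng):
        fd = rng.standard_normal((1, 2, 8, 8, 8)).astype(np.float32)
        got = np.asarray(highfreq_residual(fd))
        assert got.shape == fd.shape
        np.testing.assert_allclose(got, highfreq_oracle(fd), atol=1e-5)

    def test_tiny_grid_raises(self):
        with pytest.raises(ValueError):
            highfreq_residual(np.zeros((1, 1, 1, 4, 4), dtype=np.float32))


class TestMFF1:
    def test_zero_edge_feature_gives_zero(self, rng):
        fd = rng.standard_normal((1, 3, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(mff1(fd, np.zeros_like(fd)), np.zeros_like(fd))

    def test_constant_decoder_feature_halves_edge(self, rng):
        fd = np.full((1, 3, 8, 8, 8), 2.0, dtype=np.float32)
        fe = rng.standard_normal(fd.shape).astype(np.float32)
        np.testing.assert_allclose(mff1(fd, fe), 0.5 * fe, atol=1e-6)

    def test_matches_explicit_composition(self, rng):
        fd = rng.standard_normal((1, 2, 8, 8, 8)).astype(np.float32)
        fe = rng.standard_normal(fd.shape).astype(np.float32)
        exp = expit(highfreq_oracle(fd)) * fe
        np.testing.assert_allclose(np.asarray(mff1(fd, fe)), exp, rtol=1e-4, atol=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mff1(np.zeros((1, 2, 8, 8, 8), np.float32), np.zeros((1, 3, 8, 8, 8), np.float32))


class TestMFF2:
    @pytest.fixture
    def block(self, rng):
        mod = MFF2(channels=3)
        return mod, mod.init(rng)

    def test_zero_edges_give_zero(self, block, rng):
        mod, p = block
        fd2 = rng.standard_normal((1, 6, 4, 4, 4)).astype(np.float32)
        out = np.asarray(mod(p, fd2, np.zeros((1, 3, 8, 8, 8), np.float32),
                             np.zeros((1, 6, 4, 4, 4), np.float32)))
        np.testing.assert_allclose(out, 0.0, atol=1e-7)

    def test_output_width_and_resolution(self, block, rng):
        mod, p = block
        fd2 = rng.standard_normal((1, 6, 4, 4, 4)).astype(np.float32)
        fe1 = rng.standard_normal((1, 3, 8, 8, 8)).astype(np.float32)
        fe2 = rng.standard_normal((1, 6, 4, 4, 4)).astype(np.float32)
        assert np.asarray(mod(p, fd2, fe1, fe2)).shape == (1, 6, 4, 4, 4)

    def test_matches_step_by_step_oracle(self, block, rng):
        mod, p = block
        fd2 = rng.standard_normal((1, 6, 4, 4, 4)).astype(np.float32)
        fe1 = rng.standard_normal((1, 3, 8, 8, 8)).astype(np.float32)
        fe2 = rng.standard_normal((1, 6, 4, 4, 4)).astype(np.float32)
        # literal sequential evaluation with plain numpy
        gate_i = expit(np.einsum("oc,ncdhw->nodhw", p["conv_i"]["w"], fe2)
                       + p["conv_i"]["b"][None, :, None, None, None])
        down1 = fe1[:, :, ::2, ::2, ::2]
        bridge = (np.einsum("oc,ncdhw->nodhw", p["bridge"]["w"], down1)
                  + p["bridge"]["b"][None, :, None, None, None])
        exp = expit(highfreq_oracle(fd2)) * (fe2 + bridge * gate_i)
        np.testing.assert_allclose(np.asarray(mod(p, fd2, fe1, fe2)), exp,
                                   rtol=1e-4, atol=1e-5)

    def test_resolution_inconsistency_raises(self, block):
        mod, p = block
        with pytest.raises(ValueError):
            mod(p, np.zeros((1, 6, 4, 4, 4), np.float32),
                np.zeros((1, 3, 4, 4, 4), np.float32),
                np.zeros((1, 6, 4, 4, 4), np.float32))


class TestLEMUNet:
    def test_output_contract(self, tiny_lemunet, rng):
        model, params = tiny_lemunet
        x = rng.standard_normal((1, 3, 32, 32, 32)).astype(np.float32)
        out = model(params, x)
        assert len(out) == 5
        for i, o in enumerate(out.ds_outputs):
            n = 32 // 2**i
            assert o.shape == (1, 2, n, n, n)
            np.testing.assert_allclose(o.sum(axis=1), 1.0, atol=1e-5)

    def test_repeated_forward_bit_identical(self, tiny_lemunet, rng):
        model, params = tiny_lemunet
        x = rng.standard_normal((1, 3, 16, 16, 16)).astype(np.float32)
        a = model(params, x)
        b = model(params, x)
        for oa, ob in zip(a.ds_outputs, b.ds_outputs):
            np.testing.assert_array_equal(oa, ob)

    def test_fusion_off_equals_plain_backbone_bitwise(self, tiny_cfg, rng):
        bb_model, bb_params = build_backbone(tiny_cfg, seed=3)
        model, params = build_lemunet(tiny_cfg, seed=4)
        params["backbone"] = bb_params
        x = rng.standard_normal((1, 3, 16, 16, 16)).astype(np.float32)
        plain = bb_model(bb_params, x)
        fused_off = model(params, x, zero_fusion=True)
        for a, b in zip(plain.ds_outputs, fused_off.ds_outputs):
            np.testing.assert_array_equal(a, b)

    def test_fusion_changes_the_shallow_outputs(self, tiny_lemunet, rng):
        model, params = tiny_lemunet
        x = rng.standard_normal((1, 3, 16, 16, 16)).astype(np.float32)
        on = model(params, x)
        off = model(params, x, zero_fusion=True)
        assert not np.array_equal(on.ds_outputs[0], off.ds_outputs[0])
        # fusion happens at the last two decode layers only; deeper heads agree
        for a, b in zip(on.ds_outputs[2:], off.ds_outputs[2:]):
            np.testing.assert_array_equal(a, b)

    def test_logits_respond_continuously_to_fusion_scale(self, tiny_lemunet, rng):
        model, params = tiny_lemunet
        x = rng.standard_normal((1, 3, 16, 16, 16)).astype(np.float32)
        outs = []
        for zero in (False, True):
            outs.append(model(params, x, zero_fusion=zero).full)
        delta = np.abs(outs[0] - outs[1]).max()
        assert 0 < delta < 1.0  # a bounded, non-degenerate response

    def test_gradient_reaches_every_parameter_group(self, tiny_lemunet, rng):
        model, params = tiny_lemunet
        x = rng.standard_normal((1, 3, 16, 16, 16)).astype(np.float32)
        gt = (rng.random((1, 16, 16, 16)) < 0.05).astype(np.int64)
        w = default_loss_weights(5)
        g = grad(lambda p: combined_loss(model(p, x), gt, w))(params)
        for group in ("lea1", "lea2", "mff2", "t1_branch", "backbone"):
            total = sum(float(np.abs(leaf).sum()) for _, leaf in tree_leaves(g[group]))
            assert total > 0, f"no gradient reaches {group}"
        assert abs(float(g["lea1"]["lam"])) > 0
        assert abs(float(g["lea2"]["lam"])) > 0

    def test_missing_t1_channel_rejected(self, tiny_lemunet):
        model, params = tiny_lemunet
        with pytest.raises(ValueError):
            model(params, np.zeros((1, 3, 16, 16), dtype=np.float32))

    def test_laplacian_inputs_have_expected_grids(self, rng):
        from lemunet.fusion import LEMUNet

        t1 = rng.standard_normal((2, 1, 16, 16, 16)).astype(np.float32)
        fl1, fl2 = LEMUNet.laplacian_inputs(t1)
        assert fl1.shape == (2, 1, 16, 16, 16)
        assert fl2.shape == (2, 1, 8, 8, 8)
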