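"""Neural block semantics against nested-loop oracles and finite differences."""

import numpy as np
import pytest

from leafcount import blocks
from leafcount.nn import Tensor


def rng64(seed=0):
    return np.random.default_rng(seed)


def make_crw(c, seed=1):
    return blocks.CRW(c, rng=np.random.default_rng(seed), dtype=np.float64)


class TestCRW:
    def test_zero_weights_gate_at_half(self):
        crw = make_crw(8)
        crw.fc1.weight.data[:] = 0
        crw.fc2.weight.data[:] = 0
        x = Tensor(rng64(2).normal(size=(2, 8, 4, 4)))
        np.testing.assert_allclose(crw(x).data, 0.5 * x.data, atol=1e-12)

    def test_zero_input_stays_zero(self):
        crw = make_crw(8)
        out = crw(Tensor(np.zeros((1, 8, 5, 5))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_scalar_loop_oracle(self):
        crw = make_crw(8, seed=11)
        x = Tensor(rng64(3).normal(size=(1, 8, 4, 4)))
        got = crw(x).data[0]
        W1, W2 = crw.fc1.weight.data, crw.fc2.weight.data
        xd = x.data[0]
        z = np.concatenate([xd.max(axis=(1, 2)), xd.mean(axis=(1, 2))])
        gate = 1.0 / (1.0 + np.exp(-(W2 @ np.maximum(W1 @ z, 0.0))))
        ref = np.empty_like(xd)
        for c in range(8):
            for i in range(4):
                for j in range(4):
                    ref[c, i, j] = xd[c, i, j] * gate[c]
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_gate_strictly_inside_unit_interval(self):
        crw = make_crw(16, seed=4)
        g = crw.gate(Tensor(rng64(5).normal(size=(3, 16, 6, 6)))).data
        assert (g > 0).all() and (g < 1).all()

    def test_rejects_channel_mismatch(self):
        with pytest.raises(ValueError):
            make_crw(8)(Tensor(np.zeros((1, 4, 4, 4))))


def build_scrf(seed=21):
    return blocks.SCRF(4, 8, 16, out_channels=8, rng=np.random.default_rng(seed),
                       dtype=np.float64)


class TestSCRF:
    def test_zero_inputs_give_zero_output(self):
        s = build_scrf()
        out = s(Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 8, 4, 4))),
                Tensor(np.zeros((1, 16, 2, 2))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_shape_contract(self):
        s = blocks.SCRF(32, 64, 128, out_channels=64,
                        rng=np.random.default_rng(1), dtype=np.float32)
        out = s(Tensor(np.zeros((1, 32, 80, 80), np.float32)),
                Tensor(np.zeros((1, 64, 40, 40), np.float32)),
                Tensor(np.zeros((1, 128, 20, 20), np.float32)))
        assert out.shape == (1, 64, 40, 40)

    def test_equals_hand_composed_primitive_chain(self):
        from leafcount.nn import concat

        s = build_scrf(23)
        r = rng64(6)
        p_prev = Tensor(r.normal(size=(1, 4, 8, 8)))
        p_same = Tensor(r.normal(size=(1, 8, 4, 4)))
        p_deep = Tensor(r.normal(size=(1, 16, 2, 2)))
        got = s(p_prev, p_same, p_deep).data
        chain = s.proj(
            s.crw(
                concat(
                    [s.down(p_prev), s.same(p_same), s.deep(p_deep).upsample_nearest2()],
                    axis=1,
                )
            )
        ).data
        np.testing.assert_allclose(got, chain, atol=1e-6)

    def test_rejects_incompatible_ratios(self):
        s = build_scrf()
        with pytest.raises(ValueError):
            s(Tensor(np.zeros((1, 4, 6, 6))), Tensor(np.zeros((1, 8, 4, 4))),
              Tensor(np.zeros((1, 16, 2, 2))))


class TestACRF:
    def build(self, seed=31, with_deep=True):
        return blocks.ACRF(4, 8, 16 if with_deep else None, 4, out_channels=8,
                           rng=np.random.default_rng(seed), dtype=np.float64)

    def test_zero_inputs_give_zero_output(self):
        a = self.build()
        out = a(Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 8, 4, 4))),
                Tensor(np.zeros((1, 16, 2, 2))), Tensor(np.zeros((1, 4, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_output_matches_same_level_spatial_size(self):
        a = self.build()
        r = rng64(7)
        out = a(Tensor(r.normal(size=(1, 4, 8, 8))), Tensor(r.normal(size=(1, 8, 4, 4))),
                Tensor(r.normal(size=(1, 16, 2, 2))), Tensor(r.normal(size=(1, 4, 8, 8))))
        assert out.shape == (1, 8, 4, 4)

    def test_equals_hand_composed_primitive_chain(self):
        from leafcount.nn import concat

        a = self.build(33)
        r = rng64(8)
        pp = Tensor(r.normal(size=(1, 4, 8, 8)))
        ps = Tensor(r.normal(size=(1, 8, 4, 4)))
        pd = Tensor(r.normal(size=(1, 16, 2, 2)))
        p2 = Tensor(r.normal(size=(1, 4, 8, 8)))
        got = a(pp, ps, pd, p2).data
        chain = a.proj(
            a.crw(
                concat(
                    [a.down1(pp), a.same(ps), a.deep(pd).upsample_nearest2(), a.down2(p2)],
                    axis=1,
                )
            )
        ).data
        np.testing.assert_allclose(got, chain, atol=1e-6)


class TestMCRFPN:
    def build(self, seed=41):
        return blocks.MCRFPN((8, 16, 32), rng=np.random.default_rng(seed),
                             dtype=np.float64)

    def feats(self, r, n=1):
        return [
            Tensor(r.normal(size=(n, 8, 16, 16)), requires_grad=True),
            Tensor(r.normal(size=(n, 16, 8, 8)), requires_grad=True),
            Tensor(r.normal(size=(n, 32, 4, 4)), requires_grad=True),
        ]

    def test_zero_inputs_give_zero_outputs(self):
        neck = self.build()
        outs = neck([Tensor(np.zeros((1, 8, 16, 16))), Tensor(np.zeros((1, 16, 8, 8))),
                     Tensor(np.zeros((1, 32, 4, 4)))])
        for o in outs:
            np.testing.assert_array_equal(o.data, 0.0)

    def test_levels_keep_spatial_sizes_and_widths(self):
        neck = self.build()
        outs = neck(self.feats(rng64(9)))
        assert [o.shape for o in outs] == [(1, 8, 16, 16), (1, 16, 8, 8), (1, 32, 4, 4)]
        assert all(np.isfinite(o.data).all() for o in outs)

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError):
            self.build()([Tensor(np.zeros((1, 8, 16, 16)))])

    def test_loss_gradient_reaches_every_level(self):
        """Finite-difference probe: each backbone level influences the output."""
        neck = self.build(43)
        r = rng64(10)
        feats = self.feats(r)
        loss = sum((o * o).sum() for o in neck(feats))
        loss.backward()
        for lvl, f in enumerate(feats):
            assert np.abs(f.grad).max() > 0
            idx = (0, 0, 1, 1)
            eps = 1e-6
            for sgn_data in [None]:
                xp = [Tensor(g.data.copy()) for g in feats]
                xm = [Tensor(g.data.copy()) for g in feats]
                xp[lvl].data[idx] += eps
                xm[lvl].data[idx] -= eps
                fp = float(sum((o * o).sum() for o in neck(xp)).data)
                fm = float(sum((o * o).sum() for o in neck(xm)).data)
                fd = (fp - fm) / (2 * eps)
            assert f.grad[idx] == pytest.approx(fd, rel=1e-3, abs=1e-8)


def make_dycm(c=4, groups=2, s_r=2, k_large=3, k_small=1, qk=4, seed=51):
    cfg = blocks.DyCMConfig(groups=groups, region_grid=s_r, k_large=k_large,
                            k_small=k_small, qk_channels=qk)
    return blocks.DyCMConv(c, cfg, rng=np.random.default_rng(seed), dtype=np.float64)


class TestDyCMRelevance:
    def test_constant_field_gives_identical_rows(self):
        dy = make_dycm()
        x = Tensor(np.full((1, 4, 6, 6), 1.7))
        rel = dy.relevance(x).data
        for g in range(2):
            rows = rel[0, g]
            np.testing.assert_allclose(rows, np.broadcast_to(rows[0], rows.shape), atol=1e-10)

    def test_zero_input_gives_zero_relevance(self):
        dy = make_dycm()
        rel = dy.relevance(Tensor(np.zeros((1, 4, 6, 6))))
        np.testing.assert_array_equal(rel.data, 0.0)

    def test_matches_nested_loop_inner_products(self):
        dy = make_dycm(seed=53)
        x = Tensor(rng64(11).normal(size=(1, 4, 6, 6)))
        rel = dy.relevance(x).data
        # loop oracle from the module's own Q/K projections
        q = dy.q_proj(x).data[0]  # [qk, 6, 6]
        pooled = x.adaptive_avg_pool((2, 2))
        k = dy.k_proj(pooled).data[0]  # [qk, 2, 2]
        gd = 2  # qk 4 / groups 2
        for g in range(2):
            for i in range(36):
                for j in range(4):
                    qvec = q[g * gd : (g + 1) * gd].reshape(gd, 36)[:, i]
                    kvec = k[g * gd : (g + 1) * gd].reshape(gd, 4)[:, j]
                    assert rel[0, g, i, j] == pytest.approx(float(qvec @ kvec), abs=1e-6)

    def test_rejects_channel_mismatch(self):
        with pytest.raises(ValueError):
            make_dycm().relevance(Tensor(np.zeros((1, 6, 4, 4))))


class TestDyCMKernels:
    def test_kernels_are_simplex_valued(self):
        dy = make_dycm(k_large=5, k_small=3)
        rel = dy.relevance(Tensor(rng64(12).normal(size=(2, 4, 6, 6))))
        kl, ks = dy.kernels(rel)
        for ker, k2 in ((kl, 25), (ks, 9)):
            assert ker.shape[-1] == k2
            assert (ker.data > 0).all()
            np.testing.assert_allclose(ker.data.sum(axis=-1), 1.0, atol=1e-10)

    def test_unit_small_kernel_is_scalar_one(self):
        dy = make_dycm(k_small=1)
        rel = dy.relevance(Tensor(rng64(13).normal(size=(1, 4, 6, 6))))
        _, ks = dy.kernels(rel)
        np.testing.assert_allclose(ks.data, 1.0, atol=1e-12)

    def test_zero_linear_weights_give_uniform_kernels(self):
        dy = make_dycm(k_large=3, k_small=1)
        dy.kernel_gen.weight.data[:] = 0
        dy.kernel_gen.bias.data[:] = 0
        rel = dy.relevance(Tensor(rng64(14).normal(size=(1, 4, 6, 6))))
        kl, _ = dy.kernels(rel)
        np.testing.assert_allclose(kl.data, 1.0 / 9.0, atol=1e-12)


class TestDyCMForward:
    def test_zero_input_gives_zero_output(self):
        dy = make_dycm()
        out = dy(Tensor(np.zeros((1, 4, 6, 6))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_shape_preserving(self):
        dy = make_dycm(k_large=5, k_small=3)
        out = dy(Tensor(rng64(15).normal(size=(2, 4, 6, 6))))
        assert out.shape == (2, 4, 6, 6)
        assert np.isfinite(out.data).all()

    def test_matches_per_position_loop_oracle(self):
        dy = make_dycm(c=2, groups=1, s_r=2, k_large=3, k_small=1, qk=2, seed=55)
        x = Tensor(rng64(16).normal(size=(1, 2, 6, 6)))
        got = dy(x).data[0]
        rel = dy.relevance(x)
        kl, ks = dy.kernels(rel)
        kl = kl.data[0, 0]  # [36, 9]
        ks = ks.data[0, 0]  # [36, 1]
        xd = x.data[0]
        pad = np.pad(xd, ((0, 0), (1, 1), (1, 1)))
        ref = np.zeros_like(xd)
        for c in range(2):
            for i in range(6):
                for j in range(6):
                    pos = i * 6 + j
                    acc = 0.0
                    for di in range(3):
                        for dj in range(3):
                            acc += kl[pos, di * 3 + dj] * pad[c, i + di, j + dj]
                    acc += ks[pos, 0] * xd[c, i, j]  # 1x1 dynamic branch
                    ref[c, i, j] = acc
        # static depthwise branch via explicit loop
        wd = dy.dw.weight.data
        bd = dy.dw.bias.data
        for c in range(2):
            for i in range(6):
                for j in range(6):
                    acc = bd[c]
                    for di in range(3):
                        for dj in range(3):
                            acc += wd[c, 0, di, dj] * pad[c, i + di, j + dj]
                    ref[c, i, j] += acc
        np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_gradient_matches_finite_difference(self):
        dy = make_dycm(seed=57)
        x = Tensor(rng64(17).normal(size=(1, 4, 6, 6)), requires_grad=True)
        (dy(x) * dy(x)).sum().backward()
        idx = (0, 2, 3, 1)
        eps = 1e-6
        def f(a):
            t = Tensor(a)
            return float((dy(t) * dy(t)).sum().data)

        fd = (f(_bump(x.data, idx, eps)) - f(_bump(x.data, idx, -eps))) / (2 * eps)
        assert x.grad[idx] == pytest.approx(fd, rel=1e-3)

    def test_rejects_even_kernel(self):
        with pytest.raises(ValueError):
            blocks.DyCMConfig(k_large=4, k_small=1)


def _bump(x, idx, eps):
    y = x.copy()
    y[idx] += eps
    return y


class TestC3K2:
    def build(self, use_dycm=True, seed=61):
        cfg = blocks.DyCMConfig(groups=2, region_grid=2, k_large=3, k_small=1, qk_channels=4)
        return blocks.C3K2(8, 8, use_dycm=use_dycm, dycm_cfg=cfg,
                           rng=np.random.default_rng(seed), dtype=np.float64)

    def test_zero_input_bias_free_gives_zero(self):
        blk = self.build()
        out = blk(Tensor(np.zeros((1, 8, 6, 6))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_shape_contract_equal_channels(self):
        blk = self.build(use_dycm=False)
        out = blk(Tensor(rng64(18).normal(size=(1, 8, 12, 12))))
        assert out.shape == (1, 8, 12, 12)

    def test_zeroed_bottleneck_leaves_residual_path(self):
        from leafcount.nn import concat

        blk = self.build(seed=63)
        for _, p in blk.bottlenecks[0].named_parameters():
            p.data[:] = 0
        x = Tensor(rng64(19).normal(size=(1, 8, 6, 6)))
        got = blk(x).data
        y = blk.pre(x)
        a, b = y[:, : blk.half], y[:, blk.half :]
        ref = blk.fuse(concat([a, b], axis=1)).data
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_registry_names_resolve(self):
        assert "c3k2" in blocks.BLOCK_REGISTRY and "dycm_c3k2" in blocks.BLOCK_REGISTRY
        assert "fpn" in blocks.NECK_REGISTRY and "mcrfpn" in blocks.NECK_REGISTRY
        with pytest.raises(ValueError):
            blocks.build_block("nope", 4, 4, np.random.default_rng(0))
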