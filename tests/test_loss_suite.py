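"""BerHu, log-gradient, multi-level and adversarial objectives against
hand-evaluated cases and independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cystodepth import loss_suite as ls
from cystodepth import nn
from cystodepth.depth_net import MultiScalePrediction


# ---------------------------------------------------------------------------
# Independent per-pixel oracles (plain numpy, no Tensor machinery)
# ---------------------------------------------------------------------------

def berhu_oracle(D, D_star, mask):
    d = np.abs(D - D_star)[mask]
    c = d.max() / 5.0
    if c == 0:
        return 0.0, 0.0
    terms = np.where(d <= c, d, (d ** 2 + c ** 2) / (2 * c))
    return float(terms.mean()), float(c)


def gradient_oracle(D, D_star, mask):
    y = np.log(D) - np.log(D_star)
    total, n = 0.0, 0
    H, W = D.shape[-2], D.shape[-1]
    flat_y = y.reshape(-1, H, W)
    flat_m = mask.reshape(-1, H, W)
    for yy, mm in zip(flat_y, flat_m):
        for i in range(H):
            for j in range(W):
                if j + 1 < W and mm[i, j] and mm[i, j + 1]:
                    total += (yy[i, j + 1] - yy[i, j]) ** 2
                    n += 1
                if i + 1 < H and mm[i, j] and mm[i + 1, j]:
                    total += (yy[i + 1, j] - yy[i, j]) ** 2
                    n += 1
    return total / n if n else 0.0


class TestBerHu:
    def test_perfect_prediction_zero(self):
        D = np.full((4, 4), 20.0)
        loss, c = ls.berhu_loss(D, D.copy(), np.ones_like(D, bool))
        assert float(loss.data) == 0.0 and c == 0.0

    def test_hand_case_diffs_zero_and_five(self):
        D = np.array([[10.0, 10.0]])
        D_star = np.array([[10.0, 15.0]])
        loss, c = ls.berhu_loss(D, D_star, np.ones_like(D, bool))
        # c = 5/5 = 1; terms {0, (25+1)/2} = {0, 13}; mean = 6.5
        assert c == pytest.approx(1.0)
        assert float(loss.data) == pytest.approx(6.5)

    @pytest.mark.parametrize("d", [0.5, 1.0, 3.7])
    def test_constant_difference_closed_form(self, d):
        D = np.full((8, 8), 25.0)
        loss, c = ls.berhu_loss(D, D - d, np.ones_like(D, bool))
        assert float(loss.data) == pytest.approx(2.6 * d)
        assert c == pytest.approx(d / 5)

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            D = rng.uniform(5, 40, (6, 6))
            D_star = D + rng.normal(0, 3, (6, 6))
            mask = rng.uniform(size=(6, 6)) > 0.2
            if not mask.any():
                mask[0, 0] = True
            loss, c = ls.berhu_loss(D, D_star, mask)
            ref, c_ref = berhu_oracle(D, D_star, mask)
            assert float(loss.data) == pytest.approx(ref, rel=1e-9)
            assert c == pytest.approx(c_ref, rel=1e-9)

    def test_continuity_at_threshold_and_l1_bound(self):
        # per-pixel term at |d| = c equals c: (c^2+c^2)/(2c) = c
        rng = np.random.default_rng(1)
        D = rng.uniform(10, 30, (5, 5))
        D_star = D + rng.normal(0, 2, (5, 5))
        mask = np.ones_like(D, bool)
        d = np.abs(D - D_star)
        c = d.max() / 5
        terms = np.where(d <= c, d, (d ** 2 + c ** 2) / (2 * c))
        assert np.all(terms >= d / 2 - 1e-12)       # BerHu >= L1/2
        assert np.all(terms[d <= c] == d[d <= c])   # equals L1 below c

    def test_empty_mask_rejected(self):
        D = np.ones((3, 3))
        with pytest.raises(ValueError):
            ls.berhu_loss(D, D, np.zeros_like(D, bool))

    def test_gradient_flows_to_prediction(self):
        D = np.full((4, 4), 20.0)
        pred = nn.Tensor(np.full((4, 4), 23.0), requires_grad=True)
        loss, _ = ls.berhu_loss(D, pred, np.ones_like(D, bool))
        loss.backward()
        assert pred.grad is not None and np.any(pred.grad != 0)


class TestGradientLoss:
    def test_equal_maps_zero(self):
        D = np.random.default_rng(0).uniform(5, 30, (6, 6))
        assert float(ls.gradient_loss(D, D.copy(),
                                      np.ones_like(D, bool)).data) == 0.0

    @pytest.mark.parametrize("k", [0.5, 2.0, 7.3])
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(2)
        D = rng.uniform(5, 30, (6, 6))
        mask = np.ones_like(D, bool)
        base = float(ls.gradient_loss(D, D * 1.3, mask).data)
        scaled = float(ls.gradient_loss(D, (D * 1.3) * k, mask).data)
        assert scaled == pytest.approx(base, rel=1e-9)
        # D* = k*D exactly -> constant y -> 0
        assert float(ls.gradient_loss(D, k * D, mask).data) \
            == pytest.approx(0.0, abs=1e-18)

    def test_hand_case_single_stencil(self):
        e = math.e
        D = np.array([[e, e]])
        D_star = np.array([[e, e ** 2]])
        loss = ls.gradient_loss(D, D_star, np.ones_like(D, bool))
        # y = (0, -1): one x-gradient of -1 -> mean of squares = 1
        assert float(loss.data) == pytest.approx(1.0)

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            D = rng.uniform(5, 40, (5, 5))
            D_star = D * rng.uniform(0.7, 1.4, (5, 5))
            mask = rng.uniform(size=(5, 5)) > 0.25
            mask[0, :2] = True
            loss = ls.gradient_loss(D, D_star, mask)
            assert float(loss.data) == pytest.approx(
                gradient_oracle(D, D_star, mask), rel=1e-9)

    def test_nonpositive_depth_rejected(self):
        D = np.ones((3, 3))
        bad = D.copy()
        bad[1, 1] = 0.0
        with pytest.raises(ValueError):
            ls.gradient_loss(D, bad, np.ones_like(D, bool))


class TestUpsampleBilinear:
    def test_constant_preserved(self):
        out = ls.upsample_bilinear(np.full((3, 3), 7.0), (6, 6))
        assert np.allclose(out.data, 7.0)

    def test_monotone_on_ramp(self):
        out = ls.upsample_bilinear(np.array([[0.0, 1.0]]), (1, 4)).data[0]
        assert np.all(np.diff(out) >= 0)

    def test_downscale_rejected(self):
        with pytest.raises(ValueError):
            ls.upsample_bilinear(np.zeros((4, 4)), (2, 2))

    def test_against_direct_interpolation_oracle(self):
        rng = np.random.default_rng(4)
        src = rng.normal(size=(5, 5))
        out = ls.upsample_bilinear(src, (10, 10)).data
        # direct align_corners=False evaluation per output pixel
        ref = np.empty((10, 10))
        for o in range(10):
            for p in range(10):
                sy = min(max((o + 0.5) * 0.5 - 0.5, 0), 4)
                sx = min(max((p + 0.5) * 0.5 - 0.5, 0), 4)
                y0, x0 = int(sy), int(sx)
                y1, x1 = min(y0 + 1, 4), min(x0 + 1, 4)
                wy, wx = sy - y0, sx - x0
                ref[o, p] = (src[y0, x0] * (1 - wy) * (1 - wx)
                             + src[y0, x1] * (1 - wy) * wx
                             + src[y1, x0] * wy * (1 - wx)
                             + src[y1, x1] * wy * wx)
        assert np.allclose(out, ref, atol=1e-12)


class TestMultiscale:
    def _preds(self, maps):
        return MultiScalePrediction(levels=[(l, nn.Tensor(m[None, None]))
                                            for l, m in maps])

    def test_constant_truth_all_levels_zero(self):
        D = np.full((16, 16), 12.0)
        preds = self._preds([(l, np.full((16 >> (l - 1), 16 >> (l - 1)), 12.0))
                             for l in range(1, 5)])
        bd = ls.multiscale_loss(D[None], preds, np.ones((1, 16, 16), bool))
        assert float(bd.total.data) == pytest.approx(0.0, abs=1e-12)

    def test_weight_decomposition(self):
        rng = np.random.default_rng(5)
        D = rng.uniform(10, 30, (16, 16))
        maps = [(l, rng.uniform(10, 30, (16 >> (l - 1), 16 >> (l - 1))))
                for l in range(1, 5)]
        mask = np.ones((1, 16, 16), bool)
        both = ls.multiscale_loss(D[None], self._preds(maps), mask,
                                  ls.LossWeights(c0=1.0, c1=0.5))
        berhu_only = ls.multiscale_loss(D[None], self._preds(maps), mask,
                                        ls.LossWeights(c0=1.0, c1=0.0))
        grad_only = ls.multiscale_loss(D[None], self._preds(maps), mask,
                                       ls.LossWeights(c0=0.0, c1=1.0))
        assert float(both.total.data) == pytest.approx(
            float(berhu_only.total.data) + 0.5 * float(grad_only.total.data),
            rel=1e-9)
        assert sum(v["berhu"] for v in berhu_only.per_level.values()) \
            == pytest.approx(float(berhu_only.total.data), rel=1e-9)

    def test_single_level_matches_component(self):
        rng = np.random.default_rng(6)
        D = rng.uniform(10, 30, (8, 8))
        small = rng.uniform(10, 30, (4, 4))
        preds = self._preds([(2, small)])
        mask = np.ones((1, 8, 8), bool)
        bd = ls.multiscale_loss(D[None], preds, mask,
                                ls.LossWeights(c0=1.0, c1=0.0))
        up = ls.upsample_bilinear(small, (8, 8)).data
        ref, _ = ls.berhu_loss(D, up, np.ones((8, 8), bool))
        assert float(bd.total.data) == pytest.approx(float(ref.data), rel=1e-9)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            ls.LossWeights(c0=-1.0)


class TestAdversarialObjective:
    def test_constant_half_closed_form(self):
        maps = {l: nn.Tensor(np.full((2, 1, 4, 4), 0.5)) for l in (3, 4, 5)}
        la = ls.adversarial_objective(maps, {l: nn.Tensor(np.full(
            (2, 1, 4, 4), 0.5)) for l in (3, 4, 5)})
        assert float(la.data) == pytest.approx(-6 * math.log(2), rel=1e-12)

    def test_perfect_discrimination_approaches_zero(self):
        ones = {l: nn.Tensor(np.ones((2, 1, 4, 4))) for l in (3, 4, 5)}
        zeros = {l: nn.Tensor(np.zeros((2, 1, 4, 4))) for l in (3, 4, 5)}
        la = float(ls.adversarial_objective(ones, zeros).data)
        assert la <= 0
        assert la == pytest.approx(0.0, abs=1e-5)  # eps-clamp keeps it finite

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_random_tensors_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        synth = {l: rng.uniform(1e-4, 1 - 1e-4, (3, 1, 2, 2)) for l in (3, 4, 5)}
        real = {l: rng.uniform(1e-4, 1 - 1e-4, (3, 1, 2, 2)) for l in (3, 4, 5)}
        la = ls.adversarial_objective({l: nn.Tensor(v) for l, v in synth.items()},
                                      {l: nn.Tensor(v) for l, v in real.items()})
        ref = sum(np.log(synth[l]).mean() + np.log1p(-real[l]).mean()
                  for l in (3, 4, 5))
        assert float(la.data) == pytest.approx(ref, rel=1e-6)
        assert float(la.data) <= 0

    def test_mismatched_levels_rejected(self):
        a = {3: nn.Tensor(np.full((1, 1, 2, 2), 0.5))}
        b = {4: nn.Tensor(np.full((1, 1, 2, 2), 0.5))}
        with pytest.raises(ValueError):
            ls.adversarial_objective(a, b)

    def test_generator_forms(self):
        real = {l: nn.Tensor(np.full((2, 1, 2, 2), 0.3)) for l in (3, 4, 5)}
        nonsat = float(ls.generator_loss(real).data)
        sat = float(ls.generator_loss(real, saturating=True).data)
        assert nonsat == pytest.approx(-3 * math.log(0.3), rel=1e-9)
        assert sat == pytest.approx(3 * math.log(0.7), rel=1e-9)
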