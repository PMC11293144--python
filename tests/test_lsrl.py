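"""Label-context / label-trigger representations, projections, combination.

Vectorized implementations are compared against naive per-entry loop oracles
written independently of the library code, and analytic gradients against
central finite differences.
"""

import numpy as np
import pytest

from biotrig.autodiff import Tensor
from biotrig.lsrl import (
    CombinationConfig,
    LcarParams,
    LsrlError,
    LtarParams,
    ProjectionHeads,
    combine,
    compute_lcar,
    compute_ltar,
    lcar_attention_weights,
    project,
)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def loop_lcar(h_s, h_l, wq, wk, wv, include_1_over_n):
    """Per-row oracle: softmax of scaled dots, then weighted value sum."""
    n, d = h_s.shape
    m = h_l.shape[0]
    out = np.zeros((n, d))
    for i in range(n):
        q = h_s[i] @ wq
        scores = np.array([q @ (h_l[j] @ wk) for j in range(m)]) / np.sqrt(d)
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        c = sum(a[j] * (h_l[j] @ wv) for j in range(m))
        out[i] = c / m if include_1_over_n else c
    return out


class TestLcar:
    def test_hand_computed_two_label_example(self):
        """d=2, N=2: attention (0.6698, 0.3302), C = (0.3349, 0.1651)."""
        params = LcarParams.identity(2)
        h_s = np.array([[1.0, 0.0]])
        h_l = np.array([[1.0, 0.0], [0.0, 1.0]])
        attn = lcar_attention_weights(h_s, h_l, params)
        np.testing.assert_allclose(attn, [[0.669762, 0.330238]], atol=1e-5)
        c = compute_lcar(h_s, h_l, params).data
        np.testing.assert_allclose(c, [[0.334881, 0.165119]], atol=1e-5)

    def test_single_label_degenerate(self):
        params = LcarParams.identity(3)
        h_s = np.random.default_rng(0).normal(size=(4, 3))
        h_l = np.array([[1.0, -2.0, 0.5]])
        c = compute_lcar(h_s, h_l, params).data
        np.testing.assert_allclose(c, np.tile(h_l, (4, 1)))

    def test_identical_label_rows_average_to_v_over_n(self):
        params = LcarParams.identity(2)
        v = np.array([0.7, -1.3])
        h_l = np.tile(v, (5, 1))
        h_s = np.random.default_rng(1).normal(size=(3, 2))
        c = compute_lcar(h_s, h_l, params).data
        np.testing.assert_allclose(c, np.tile(v / 5, (3, 1)))

    def test_matches_loop_oracle(self, rng):
        d, n, m = 4, 5, 3
        params = LcarParams.init(d, rng)
        h_s, h_l = rng.normal(size=(n, d)), rng.normal(size=(m, d))
        for flag in (True, False):
            params.include_1_over_n = flag
            got = compute_lcar(h_s, h_l, params).data
            want = loop_lcar(h_s, h_l, params.wq.data, params.wk.data, params.wv.data, flag)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        params = LcarParams.init(6, rng)
        attn = lcar_attention_weights(
            rng.normal(size=(7, 6)) * 10, rng.normal(size=(4, 6)) * 10, params
        )
        np.testing.assert_allclose(attn.sum(axis=-1), np.ones(7), atol=1e-12)

    def test_zero_labels_rejected(self, rng):
        params = LcarParams.init(3, rng)
        with pytest.raises(LsrlError):
            compute_lcar(rng.normal(size=(2, 3)), np.zeros((0, 3)), params)


class TestLtar:
    def test_zero_parameters_give_half(self):
        params = LtarParams(Tensor(np.zeros((2, 2))), Tensor(0.0))
        a = compute_ltar(np.ones((3, 2)), np.ones((4, 2)), params).data
        np.testing.assert_allclose(a, 0.5)

    def test_closed_form_sigmoid(self):
        params = LtarParams(Tensor(np.array([[0.0, 2.0], [0.0, 0.0]])), Tensor(0.0))
        a = compute_ltar(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]), params).data
        assert a[0, 0] == pytest.approx(sigmoid(2.0), abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        d, n, m = 3, 4, 3
        params = LtarParams.init(d, rng)
        h_s, h_l = rng.normal(size=(n, d)), rng.normal(size=(m, d))
        got = compute_ltar(h_s, h_l, params).data
        want = np.array(
            [
                [
                    sigmoid(h_s[i] @ params.w.data @ h_l[j] + params.b.data)
                    for j in range(m)
                ]
                for i in range(n)
            ]
        )
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert np.all((got > 0) & (got < 1))

    def test_monotone_in_bias(self, rng):
        d = 3
        w = rng.normal(size=(d, d))
        h_s, h_l = rng.normal(size=(4, d)), rng.normal(size=(2, d))
        lo = compute_ltar(h_s, h_l, LtarParams(Tensor(w), Tensor(-0.5))).data
        hi = compute_ltar(h_s, h_l, LtarParams(Tensor(w), Tensor(0.5))).data
        assert np.all(hi > lo)

    def test_non_finite_parameters_rejected(self):
        params = LtarParams(Tensor(np.full((2, 2), np.nan)), Tensor(0.0))
        with pytest.raises(LsrlError):
            compute_ltar(np.ones((1, 2)), np.ones((1, 2)), params)


class TestProjectAndCombine:
    def test_zero_inputs_give_bias_rows(self, rng):
        heads = ProjectionHeads.init(d=3, m=2, k_bio=5, rng=rng)
        xs, xc, xt = project(np.zeros((4, 3)), np.zeros((4, 3)), np.zeros((4, 2)), heads)
        np.testing.assert_allclose(xs.data, np.tile(heads.b1.data, (4, 1)))
        np.testing.assert_allclose(xc.data, np.tile(heads.b2.data, (4, 1)))
        np.testing.assert_allclose(xt.data, np.tile(heads.b3.data, (4, 1)))

    def test_linearity_about_bias(self, rng):
        heads = ProjectionHeads.init(d=3, m=2, k_bio=4, rng=rng)
        h = rng.normal(size=(1, 3))
        one = project(h, np.zeros((1, 3)), np.zeros((1, 2)), heads)[0].data
        two = project(2 * h, np.zeros((1, 3)), np.zeros((1, 2)), heads)[0].data
        np.testing.assert_allclose(two - heads.b1.data, 2 * (one - heads.b1.data), atol=1e-12)

    def test_matches_affine_oracle(self, rng):
        heads = ProjectionHeads.init(d=4, m=3, k_bio=5, rng=rng)
        h_s, c, a = rng.normal(size=(6, 4)), rng.normal(size=(6, 4)), rng.normal(size=(6, 3))
        xs, xc, xt = project(h_s, c, a, heads)
        np.testing.assert_allclose(xs.data, h_s @ heads.w1.data + heads.b1.data, atol=1e-10)
        np.testing.assert_allclose(xc.data, c @ heads.w2.data + heads.b2.data, atol=1e-10)
        np.testing.assert_allclose(xt.data, a @ heads.w3.data + heads.b3.data, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        heads = ProjectionHeads.init(d=4, m=3, k_bio=5, rng=rng)
        with pytest.raises(LsrlError):
            project(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 3)), heads)

    def test_combine_residual_base(self):
        xp = np.arange(6.0).reshape(2, 3)
        zero = np.zeros_like(xp)
        out = combine(xp, zero, zero, CombinationConfig(0.4)).data
        np.testing.assert_allclose(out, xp)

    def test_combine_alpha_half_sums_shared_term(self):
        xp, z = np.ones((2, 2)), np.full((2, 2), 3.0)
        out = combine(xp, z, z, CombinationConfig(0.5)).data
        np.testing.assert_allclose(out, xp + z)

    def test_combine_hand_arithmetic(self):
        out = combine(
            np.array([[1.0, 1.0]]),
            np.array([[2.0, 0.0]]),
            np.array([[0.0, 2.0]]),
            CombinationConfig(0.3),
        ).data
        np.testing.assert_allclose(out, [[1.6, 2.4]])

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_alpha_outside_open_interval_rejected(self, alpha):
        with pytest.raises(LsrlError):
            CombinationConfig(alpha)

    def test_alpha_derivative_is_ctx_minus_trig(self, rng):
        xp, xc, xt = (rng.normal(size=(3, 4)) for _ in range(3))
        eps = 1e-6
        hi = combine(xp, xc, xt, CombinationConfig(0.5 + eps)).data
        lo = combine(xp, xc, xt, CombinationConfig(0.5 - eps)).data
        np.testing.assert_allclose((hi - lo) / (2 * eps), xc - xt, atol=1e-5)


class TestEndToEndGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """n=2, m=2, d=3 pipeline: d(loss)/d(params) vs central differences."""
        rng = np.random.default_rng(42)
        n, m, d, k_bio = 2, 2, 3, 5
        h_s0 = rng.normal(size=(n, d))
        h_l0 = rng.normal(size=(m, d))
        lcar = LcarParams.init(d, rng)
        ltar = LtarParams.init(d, rng)
        heads = ProjectionHeads.init(d, m, k_bio, rng)
        weights = rng.normal(size=(n, k_bio))  # fixed linear readout -> scalar

        def forward(h_s_arr):
            h_s = Tensor(h_s_arr, requires_grad=True)
            c = compute_lcar(h_s, Tensor(h_l0), lcar)
            a = compute_ltar(h_s, Tensor(h_l0), ltar)
            xs, xc, xt = project(h_s, c, a, heads)
            x = combine(xs, xc, xt, CombinationConfig(0.5))
            return h_s, (x * Tensor(weights)).sum()

        h_s_t, loss = forward(h_s0.copy())
        loss.backward()
        eps = 1e-6

        # input gradient: perturb the h_s array itself
        num_hs = np.zeros_like(h_s0)
        for idx in np.ndindex(h_s0.shape):
            pert = h_s0.copy()
            pert[idx] += eps
            hi = forward(pert)[1].item()
            pert[idx] -= 2 * eps
            lo = forward(pert)[1].item()
            num_hs[idx] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(h_s_t.grad, num_hs, rtol=1e-4, atol=1e-7)

        # parameter gradients: perturb shared parameter tensors in place
        params = {"W": ltar.w, "wq": lcar.wq, "w2": heads.w2, "b3": heads.b3}
        for name, tensor in params.items():
            num = np.zeros_like(tensor.data)
            for idx in np.ndindex(tensor.data.shape):
                orig = tensor.data[idx]
                tensor.data[idx] = orig + eps
                hi = forward(h_s0.copy())[1].item()
                tensor.data[idx] = orig - eps
                lo = forward(h_s0.copy())[1].item()
                tensor.data[idx] = orig
                num[idx] = (hi - lo) / (2 * eps)
            np.testing.assert_allclose(
                tensor.grad, num, rtol=1e-4, atol=1e-7, err_msg=f"gradient of {name}"
            )
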