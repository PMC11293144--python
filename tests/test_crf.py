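"""CRF scoring, normalization, decoding and training-gradient correctness.

Small instances are checked against brute-force enumeration over all K**n
tag sequences — an oracle independent of the forward/Viterbi recursions.
"""

import numpy as np
import pytest
from scipy.special import logsumexp as sp_logsumexp

from biotrig.autodiff import Tensor
from biotrig.crf import (
    CrfError,
    CrfParams,
    all_sequence_scores,
    crf_nll,
    log_partition,
    log_prob,
    nll_loss,
    score_sequence,
    viterbi_decode,
)
from biotrig.schema import BioTagset, EventTypeSchema, is_valid_transition, transition_mask


def loop_score(F, y, t_eff, start, stop):
    """Naive three-term summation oracle."""
    s = t_eff[start, y[0]]
    for i, tag in enumerate(y):
        s += F[i, tag]
    for a, b in zip(y[:-1], y[1:]):
        s += t_eff[a, b]
    return s + t_eff[y[-1], stop]


class TestScore:
    def test_single_token_zero_transitions(self):
        params = CrfParams.zeros(3)
        F = np.array([[1.0, 2.0, -1.0]])
        for y in range(3):
            assert score_sequence(F, [y], params) == pytest.approx(F[0, y])

    def test_two_tokens_additive(self):
        params = CrfParams.zeros(2)
        F = np.array([[1.0, 4.0], [2.0, -3.0]])
        assert score_sequence(F, [1, 0], params) == pytest.approx(4.0 + 2.0)

    def test_matches_loop_oracle(self, rng):
        params = CrfParams.random(3, rng)
        F = rng.normal(size=(3, 3))
        t = params.effective()
        for y, s in all_sequence_scores(F, params):
            assert s == pytest.approx(
                loop_score(F, y, t, params.start, params.stop), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(CrfError):
            score_sequence(np.zeros((2, 3)), [0], CrfParams.zeros(3))


class TestPartition:
    def test_single_token_is_logsumexp_of_emissions(self):
        params = CrfParams.zeros(4)
        F = np.array([[0.3, -1.2, 2.0, 0.0]])
        assert log_partition(F, params) == pytest.approx(sp_logsumexp(F[0]))

    def test_matches_enumeration(self, rng):
        params = CrfParams.random(3, rng)
        F = rng.normal(size=(3, 3))
        scores = [s for _, s in all_sequence_scores(F, params)]
        assert log_partition(F, params) == pytest.approx(sp_logsumexp(scores), abs=1e-8)

    def test_large_emissions_stay_finite(self, rng):
        params = CrfParams.random(3, rng)
        F = rng.normal(size=(4, 3)) * 100.0
        assert np.isfinite(log_partition(F, params))

    def test_upper_bounds_every_sequence_score(self, rng):
        for _ in range(20):
            params = CrfParams.random(4, rng)
            F = rng.normal(size=(3, 4)) * 2.0
            lz = log_partition(F, params)
            assert all(s <= lz + 1e-9 for _, s in all_sequence_scores(F, params))


class TestProbability:
    @pytest.mark.parametrize("n,k", [(2, 4), (3, 3), (4, 2)])
    def test_probabilities_sum_to_one(self, n, k, rng):
        params = CrfParams.random(k, rng)
        F = rng.normal(size=(n, k))
        total = sum(np.exp(log_prob(F, y, params)) for y, _ in all_sequence_scores(F, params))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_masked_unique_path_has_probability_one(self):
        # forbid every transition except the chain START->0->1->STOP
        k = 2
        mask = np.ones((k + 2, k + 2), dtype=bool)
        params = CrfParams.zeros(k, invalid_mask=None)
        mask[k, 0] = mask[0, 1] = mask[1, k + 1] = False
        params.invalid_mask = mask
        F = np.zeros((2, k))
        assert log_prob(F, [0, 1], params) == pytest.approx(0.0, abs=1e-6)

    def test_emission_row_shift_invariance(self, rng):
        params = CrfParams.random(3, rng)
        F = rng.normal(size=(3, 3))
        y = [0, 2, 1]
        shifted = F.copy()
        shifted[1] += 7.5
        assert log_prob(F, y, params) == pytest.approx(
            log_prob(shifted, y, params), abs=1e-9
        )

    def test_nll_is_negative_log_prob(self, rng):
        params = CrfParams.random(2, rng)
        F = rng.normal(size=(2, 2))
        assert nll_loss(F, [0, 1], params) == pytest.approx(-log_prob(F, [0, 1], params))
        assert nll_loss(F, [0, 1], params) >= 0.0


class TestViterbi:
    def test_single_token_argmax(self):
        params = CrfParams.zeros(3)
        assert viterbi_decode(np.array([[0.1, 5.0, -2.0]]), params) == [1]

    def test_attains_enumerated_maximum(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(1, 6))
            params = CrfParams.random(k, rng)
            F = rng.normal(size=(n, k))
            best = max(s for _, s in all_sequence_scores(F, params))
            decoded = viterbi_decode(F, params)
            assert score_sequence(F, decoded, params) == pytest.approx(best, abs=1e-9)

    def test_masked_decoding_is_bio_valid(self, small_schema, small_tagset):
        rng = np.random.default_rng(3)
        mask = transition_mask(small_tagset)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            params = CrfParams.random(small_tagset.size, rng, invalid_mask=mask)
            F = rng.normal(size=(n, small_tagset.size)) * 3.0
            tags = small_tagset.decode(viterbi_decode(F, params))
            for a, b in zip(tags[:-1], tags[1:]):
                assert is_valid_transition(a, b, small_tagset)
            assert not tags[0].startswith("I-")


class TestTrainingOp:
    def test_nll_matches_functional_value(self, rng):
        k, n = 3, 4
        params = CrfParams.random(k, rng)
        F = rng.normal(size=(n, k))
        y = rng.integers(0, k, size=n)
        expected = nll_loss(F, y, params)
        got = crf_nll(
            Tensor(F[None]), y[None], np.array([n]), Tensor(params.transitions)
        )
        assert got.item() == pytest.approx(expected, abs=1e-10)

    def test_gradients_match_central_differences(self, rng):
        k, n = 3, 3
        trans = rng.normal(size=(k + 2, k + 2)) * 0.3
        F = rng.normal(size=(1, n, k))
        y = np.array([[0, 2, 1]])
        lengths = np.array([n])

        e_t = Tensor(F.copy(), requires_grad=True)
        t_t = Tensor(trans.copy(), requires_grad=True)
        crf_nll(e_t, y, lengths, t_t).backward()

        eps = 1e-6

        def value(Farr, Tarr):
            return crf_nll(Tensor(Farr), y, lengths, Tensor(Tarr)).item()

        num_f = np.zeros_like(F)
        for idx in np.ndindex(F.shape):
            Fp, Fm = F.copy(), F.copy()
            Fp[idx] += eps
            Fm[idx] -= eps
            num_f[idx] = (value(Fp, trans) - value(Fm, trans)) / (2 * eps)
        np.testing.assert_allclose(e_t.grad, num_f, rtol=1e-5, atol=1e-7)

        num_t = np.zeros_like(trans)
        for idx in np.ndindex(trans.shape):
            Tp, Tm = trans.copy(), trans.copy()
            Tp[idx] += eps
            Tm[idx] -= eps
            num_t[idx] = (value(F, Tp) - value(F, Tm)) / (2 * eps)
        np.testing.assert_allclose(t_t.grad, num_t, rtol=1e-5, atol=1e-7)

    def test_one_gradient_step_reduces_nll(self, rng):
        k, n = 4, 5
        F = rng.normal(size=(1, n, k))
        y = rng.integers(0, k, size=(1, n))
        lengths = np.array([n])
        e_t = Tensor(F, requires_grad=True)
        t_t = Tensor(np.zeros((k + 2, k + 2)), requires_grad=True)
        loss0 = crf_nll(e_t, y, lengths, t_t)
        loss0.backward()
        e_t.data -= 0.1 * e_t.grad
        t_t.data -= 0.1 * t_t.grad
        loss1 = crf_nll(Tensor(e_t.data), y, lengths, Tensor(t_t.data))
        assert loss1.item() < loss0.item()

    def test_batch_mean_over_variable_lengths(self, rng):
        k = 3
        params = CrfParams.random(k, rng)
        F1, F2 = rng.normal(size=(2, k)), rng.normal(size=(4, k))
        y1, y2 = np.array([1, 0]), np.array([2, 2, 0, 1])
        padded = np.zeros((2, 4, k))
        padded[0, :2], padded[1] = F1, F2
        tags = np.zeros((2, 4), dtype=int)
        tags[0, :2], tags[1] = y1, y2
        got = crf_nll(
            Tensor(padded), tags, np.array([2, 4]), Tensor(params.transitions)
        )
        expected = 0.5 * (nll_loss(F1, y1, params) + nll_loss(F2, y2, params))
        assert got.item() == pytest.approx(expected, abs=1e-10)


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    arrays(np.float64, (3, 3), elements=st.floats(-5, 5)),
    st.lists(st.integers(0, 2), min_size=3, max_size=3),
)
def test_property_log_partition_dominates_any_score(F, y):
    """log Z >= score(y) for every sequence (containment of one term)."""
    params = CrfParams.random(3, np.random.default_rng(0))
    assert log_partition(F, params) >= score_sequence(F, y, params) - 1e-9
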