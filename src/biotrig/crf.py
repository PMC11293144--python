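"""Linear-chain CRF over BIO tags.

A tag sequence ``y`` for emissions ``F`` (one row of tag scores per token) is
scored as the sum of its emission scores plus transition scores, including
boundary transitions from a virtual START state and into a virtual STOP
state::

    score(F, y) = T[START, y_1] + sum_i F[i, y_i]
                + sum_i T[y_i, y_{i+1}] + T[y_n, STOP]

The sequence probability is the globally normalized softmax over all
``K**n`` sequences; the normalizer is computed by the forward recursion in
log space.  Decoding is Viterbi.  Training uses the negative log-likelihood,
whose gradient with respect to emissions and transitions is expected minus
observed feature counts, obtained from forward-backward marginals — exposed
as an autodiff-compatible custom op (:func:`crf_nll`).

An optional hard mask forbids BIO-invalid transitions (``O -> I-t`` etc.) by
adding a large negative penalty; it is off by default, leaving the CRF to
*learn* the constraint from data.

Brute-force enumeration helpers (:func:`all_sequence_scores`) are included as
independent oracles for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp as sp_logsumexp

from .autodiff import Tensor

MASK_PENALTY = 1e4  # finite stand-in for -inf: keeps training gradients finite


class CrfError(ValueError):
    pass


@dataclass
class CrfParams:
    """Transition matrix over ``K`` tags plus virtual START/STOP states.

    ``transitions`` has shape ``(K+2, K+2)`` with row/col ``K`` = START and
    ``K+1`` = STOP.  ``invalid_mask`` (optional, same shape, boolean) marks
    transitions to be suppressed with a ``-MASK_PENALTY`` additive penalty.
    """

    transitions: np.ndarray
    invalid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        if self.transitions.ndim != 2 or (
            self.transitions.shape[0] != self.transitions.shape[1]
        ):
            raise CrfError("transition matrix must be square")
        if not np.all(np.isfinite(self.transitions)):
            raise CrfError("transition matrix must be finite (mask via invalid_mask)")

    @property
    def n_tags(self) -> int:
        return self.transitions.shape[0] - 2

    @property
    def start(self) -> int:
        return self.n_tags

    @property
    def stop(self) -> int:
        return self.n_tags + 1

    def effective(self) -> np.ndarray:
        """Transitions with the structural + BIO penalties applied."""
        t = self.transitions.copy()
        if self.invalid_mask is not None:
            t = t - MASK_PENALTY * self.invalid_mask
        # START never entered, STOP never left, regardless of user mask
        t[:, self.start] -= MASK_PENALTY
        t[self.stop, :] -= MASK_PENALTY
        return t

    @classmethod
    def zeros(cls, n_tags: int, invalid_mask: np.ndarray | None = None) -> "CrfParams":
        return cls(np.zeros((n_tags + 2, n_tags + 2)), invalid_mask)

    @classmethod
    def random(
        cls,
        n_tags: int,
        rng: np.random.Generator,
        scale: float = 0.1,
        invalid_mask: np.ndarray | None = None,
    ) -> "CrfParams":
        t = rng.uniform(-scale, scale, size=(n_tags + 2, n_tags + 2))
        return cls(t, invalid_mask)


def _check(F: np.ndarray, params: CrfParams) -> np.ndarray:
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 1:
        raise CrfError("emission matrix must be (n >= 1, K)")
    if F.shape[1] != params.n_tags:
        raise CrfError(
            f"emissions have {F.shape[1]} tags but transitions expect {params.n_tags}"
        )
    return F


def score_sequence(F, y, params: CrfParams) -> float:
    """Score of one tag sequence: emissions + transitions + boundary terms."""
    F = _check(F, params)
    y = np.asarray(y, dtype=int)
    if y.shape != (F.shape[0],):
        raise CrfError(f"tag sequence length {y.shape} mismatches emissions {F.shape}")
    t = params.effective()
    s = t[params.start, y[0]] + F[np.arange(len(y)), y].sum()
    s += t[y[:-1], y[1:]].sum()
    s += t[y[-1], params.stop]
    return float(s)


def log_partition(F, params: CrfParams) -> float:
    """log sum over all tag sequences of exp(score), forward recursion."""
    F = _check(F, params)
    t = params.effective()
    K = params.n_tags
    alpha = t[params.start, :K] + F[0]
    for i in range(1, F.shape[0]):
        alpha = sp_logsumexp(alpha[:, None] + t[:K, :K], axis=0) + F[i]
    return float(sp_logsumexp(alpha + t[:K, params.stop]))


def log_prob(F, y, params: CrfParams) -> float:
    return score_sequence(F, y, params) - log_partition(F, params)


def nll_loss(F, y, params: CrfParams) -> float:
    return -log_prob(F, y, params)


def viterbi_decode(F, params: CrfParams) -> list[int]:
    """Highest-scoring tag sequence; argmax ties go to the lowest tag index."""
    F = _check(F, params)
    t = params.effective()
    K, n = params.n_tags, F.shape[0]
    delta = t[params.start, :K] + F[0]
    back = np.zeros((n, K), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + t[:K, :K]
        back[i] = cand.argmax(axis=0)  # np.argmax: first (lowest) index on ties
        delta = cand.max(axis=0) + F[i]
    last = int((delta + t[:K, params.stop]).argmax())
    path = [last]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return path[::-1]


def all_sequence_scores(F, params: CrfParams):
    """Enumerate every tag sequence with its score (oracle; small n only)."""
    F = _check(F, params)
    K, n = params.n_tags, F.shape[0]
    for y in itertools.product(range(K), repeat=n):
        yield list(y), score_sequence(F, np.array(y), params)


# -- training op -------------------------------------------------------------


def _forward_backward(F: np.ndarray, t: np.ndarray, start: int, stop: int):
    """Return (logZ, unary marginals, expected transition counts)."""
    n, K = F.shape
    alpha = np.empty((n, K))
    alpha[0] = t[start, :K] + F[0]
    for i in range(1, n):
        alpha[i] = sp_logsumexp(alpha[i - 1][:, None] + t[:K, :K], axis=0) + F[i]
    log_z = sp_logsumexp(alpha[n - 1] + t[:K, stop])
    beta = np.empty((n, K))
    beta[n - 1] = t[:K, stop]
    for i in range(n - 2, -1, -1):
        beta[i] = sp_logsumexp(t[:K, :K] + (F[i + 1] + beta[i + 1])[None, :], axis=1)
    unary = np.exp(alpha + beta - log_z)
    expected_t = np.zeros_like(t)
    for i in range(n - 1):
        pair = np.exp(
            alpha[i][:, None] + t[:K, :K] + (F[i + 1] + beta[i + 1])[None, :] - log_z
        )
        expected_t[:K, :K] += pair
    expected_t[start, :K] += unary[0]
    expected_t[:K, stop] += unary[n - 1]
    return log_z, unary, expected_t


def crf_nll(
    emissions: Tensor,
    tags: np.ndarray,
    lengths: np.ndarray,
    transitions: Tensor,
    invalid_mask: np.ndarray | None = None,
) -> Tensor:
    """Mean negative log-likelihood over a padded batch (autodiff op).

    ``emissions``: Tensor of shape (B, n_max, K); ``tags``: int array
    (B, n_max); ``lengths``: int array (B,).  ``transitions`` is the raw
    (K+2, K+2) Tensor; the structural START/STOP penalties and the optional
    BIO mask are applied internally as constants, so their gradient is the
    same as the raw matrix's.

    The backward pass uses the analytic gradient of the CRF likelihood:
    expected feature counts (forward-backward marginals) minus observed
    counts, scaled by ``1/B``.
    """
    B = emissions.data.shape[0]
    params = CrfParams(transitions.data, invalid_mask)
    t_eff = params.effective()
    start, stop = params.start, params.stop

    total = 0.0
    grad_f = np.zeros_like(emissions.data)
    grad_t = np.zeros_like(transitions.data)
    for b in range(B):
        n = int(lengths[b])
        F = emissions.data[b, :n]
        y = np.asarray(tags[b, :n], dtype=int)
        log_z, unary, expected_t = _forward_backward(F, t_eff, start, stop)
        gold = (
            t_eff[start, y[0]]
            + F[np.arange(n), y].sum()
            + t_eff[y[:-1], y[1:]].sum()
            + t_eff[y[-1], stop]
        )
        total += log_z - gold
        obs_f = np.zeros_like(F)
        obs_f[np.arange(n), y] = 1.0
        grad_f[b, :n] = unary - obs_f
        obs_t = np.zeros_like(grad_t)
        obs_t[start, y[0]] += 1.0
        np.add.at(obs_t, (y[:-1], y[1:]), 1.0)
        obs_t[y[-1], stop] += 1.0
        grad_t += expected_t - obs_t

    out_data = np.asarray(total / B)

    def backward(g):
        scale = float(g) / B
        if emissions.requires_grad:
            emissions._accumulate(scale * grad_f)
        if transitions.requires_grad:
            transitions._accumulate(scale * grad_t)

    return Tensor(out_data, parents=(emissions, transitions), backward=backward)
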