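"""Label-based synergistic representation learning.

Given word-level sentence encodings ``H_S`` (n x d) and label encodings
``H_L`` (m x d) produced by the joint encoder, this module computes:

* LCAR, the label-context aware representation ``C`` (n x d): single-head
  scaled dot-product attention with the sentence as query and the labels as
  key and value, averaged with a ``1/N`` factor over the ``N = m`` labels
  (the factor is a literal part of the formulation and can be switched off,
  since it interacts with the softmax normalization of the attention
  weights);

* LTAR, the label-trigger aware representation ``A`` (n x m): a sigmoid
  bilinear interaction ``A[i, j] = sigmoid(h_S_i^T W h_L_j + b)`` with a
  learnable interaction matrix ``W``, scoring each token's affinity to each
  event-type label;

* three independent affine projection heads mapping ``H_S``, ``C`` and ``A``
  to per-token tag-score rows of width ``k_bio = 2k + 1`` (the BIO tag count);

* the alpha-weighted combination ``x = X' + alpha * X_hat + (1 - alpha) *
  X_tilde`` that serves as the CRF emission matrix.  The sentence term
  enters unweighted, as a residual base.

All operations accept numpy arrays or autodiff Tensors (batched or not) and
return Tensors, so gradients flow end to end during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor


class LsrlError(ValueError):
    pass


def _init_linear(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class LcarParams:
    """Learned projections for label-context attention (single head)."""

    wq: Tensor  # d x d, applied to H_S rows (query)
    wk: Tensor  # d x d, applied to H_L rows (key)
    wv: Tensor  # d x d, applied to H_L rows (value)
    include_1_over_n: bool = True

    @classmethod
    def init(cls, d: int, rng: np.random.Generator, include_1_over_n: bool = True):
        return cls(
            wq=Tensor(_init_linear(rng, d, (d, d)), requires_grad=True),
            wk=Tensor(_init_linear(rng, d, (d, d)), requires_grad=True),
            wv=Tensor(_init_linear(rng, d, (d, d)), requires_grad=True),
            include_1_over_n=include_1_over_n,
        )

    @classmethod
    def identity(cls, d: int, include_1_over_n: bool = True):
        """Identity projections — used by tests and worked examples."""
        eye = np.eye(d)
        return cls(Tensor(eye), Tensor(eye), Tensor(eye), include_1_over_n)

    def parameters(self) -> list[Tensor]:
        return [self.wq, self.wk, self.wv]


@dataclass
class LtarParams:
    """Bilinear interaction matrix and bias for label-trigger scoring."""

    w: Tensor  # d x d
    b: Tensor  # scalar

    @classmethod
    def init(cls, d: int, rng: np.random.Generator):
        return cls(
            w=Tensor(_init_linear(rng, d, (d, d)), requires_grad=True),
            b=Tensor(0.0, requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


@dataclass
class ProjectionHeads:
    """Three separate single-layer affine heads onto the BIO tag space.

    head1: d -> k_bio on H_S rows; head2: d -> k_bio on C rows;
    head3: m -> k_bio on A rows.  No shared weights, no hidden nonlinearity:
    the outputs are CRF emission scores.
    """

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor
    w3: Tensor
    b3: Tensor

    @classmethod
    def init(cls, d: int, m: int, k_bio: int, rng: np.random.Generator):
        return cls(
            w1=Tensor(_init_linear(rng, d, (d, k_bio)), requires_grad=True),
            b1=Tensor(np.zeros(k_bio), requires_grad=True),
            w2=Tensor(_init_linear(rng, d, (d, k_bio)), requires_grad=True),
            b2=Tensor(np.zeros(k_bio), requires_grad=True),
            w3=Tensor(_init_linear(rng, m, (m, k_bio)), requires_grad=True),
            b3=Tensor(np.zeros(k_bio), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]


@dataclass(frozen=True)
class CombinationConfig:
    """The weight balancing context vs trigger affinity contributions."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise LsrlError(f"alpha must lie in the open interval (0, 1), got {self.alpha}")


@dataclass
class LsrlOutputs:
    c: Tensor  # n x d   (or B x n x d)
    a: Tensor  # n x m
    x_sent: Tensor  # X': n x k_bio
    x_ctx: Tensor  # X-hat: n x k_bio
    x_trig: Tensor  # X-tilde: n x k_bio
    x: Tensor  # combined emissions: n x k_bio


def compute_lcar(h_s, h_l, params: LcarParams) -> Tensor:
    """Label-context aware representation via attention over the labels.

    Attention weights are a softmax over labels of scaled dot products of the
    projected query (sentence row) and keys (label rows), scale
    ``1/sqrt(d)``; the output is the weight-averaged projected label values,
    times ``1/N`` when ``include_1_over_n`` is set.
    """
    h_s, h_l = astensor(h_s), astensor(h_l)
    n_labels = h_l.shape[-2]
    if n_labels < 1:
        raise LsrlError("need at least one label encoding")
    d = h_s.shape[-1]
    if h_l.shape[-1] != d:
        raise LsrlError("sentence and label encoding dimensions differ")
    q = h_s @ params.wq
    k = h_l @ params.wk
    v = h_l @ params.wv
    scores = (q @ k.T) * (1.0 / np.sqrt(d))
    attn = ad.softmax(scores, axis=-1)
    c = attn @ v
    if params.include_1_over_n:
        c = c * (1.0 / n_labels)
    return c


def lcar_attention_weights(h_s, h_l, params: LcarParams) -> np.ndarray:
    """The row-normalized attention matrix (each row sums to 1)."""
    h_s, h_l = astensor(h_s), astensor(h_l)
    d = h_s.shape[-1]
    q = h_s @ params.wq
    k = h_l @ params.wk
    return ad.softmax((q @ k.T) * (1.0 / np.sqrt(d)), axis=-1).data


def compute_ltar(h_s, h_l, params: LtarParams) -> Tensor:
    """Sigmoid bilinear label-trigger affinity matrix, entries in (0, 1)."""
    h_s, h_l = astensor(h_s), astensor(h_l)
    if not (np.all(np.isfinite(params.w.data)) and np.all(np.isfinite(params.b.data))):
        raise LsrlError("non-finite interaction parameters")
    if h_s.shape[-1] != params.w.shape[0] or h_l.shape[-1] != params.w.shape[1]:
        raise LsrlError("encoding dimension mismatches interaction matrix")
    return ad.sigmoid((h_s @ params.w) @ h_l.T + params.b)


def project(h_s, c, a, heads: ProjectionHeads) -> tuple[Tensor, Tensor, Tensor]:
    """Map each representation through its own affine head (no sharing)."""
    h_s, c, a = astensor(h_s), astensor(c), astensor(a)
    for x, w, which in ((h_s, heads.w1, "H_S"), (c, heads.w2, "C"), (a, heads.w3, "A")):
        if x.shape[-1] != w.shape[0]:
            raise LsrlError(
                f"{which} width {x.shape[-1]} mismatches its head input {w.shape[0]}"
            )
    x_sent = h_s @ heads.w1 + heads.b1
    x_ctx = c @ heads.w2 + heads.b2
    x_trig = a @ heads.w3 + heads.b3
    return x_sent, x_ctx, x_trig


def combine(x_sent, x_ctx, x_trig, cfg: CombinationConfig) -> Tensor:
    """``x = X' + alpha * X_hat + (1 - alpha) * X_tilde``, rowwise."""
    x_sent, x_ctx, x_trig = astensor(x_sent), astensor(x_ctx), astensor(x_trig)
    if not (x_sent.shape == x_ctx.shape == x_trig.shape):
        raise LsrlError("combination inputs must share a shape")
    return x_sent + cfg.alpha * x_ctx + (1.0 - cfg.alpha) * x_trig
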