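"""Joint label-prompt + sentence encoding.

The encoder input is the concatenation ``<[CLS], L, [SEP], S, [SEP]>`` where
``L`` is a label prompt — one dedicated special token per event type, in a
randomly permuted but per-run-fixed order — and ``S`` is the sub-tokenized
sentence.  Running a self-attention encoder over the whole concatenation
lets every sentence token interact directly with every type label.  The
output is split into ``H_L`` (one row per label, prompt order) and ``H_S``
(one row per sentence *word*, taken from the word's first sub-token).

Multi-word label names ("Positive Regulation") are represented by a single
added special token with its own trainable embedding.  The encoder contract
is satisfied by any conforming transformer; the shipped
:class:`TinyTransformer` (2 layers by default) makes the full pipeline
trainable at desk scale, and :class:`IdentityEncoder` (raw embedding
lookup) exposes the splitting logic to exact tests.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .schema import EventTypeSchema

logger = logging.getLogger(__name__)

PAD, CLS, SEP, UNK = "[PAD]", "[CLS]", "[SEP]", "[UNK]"


class EncodingError(ValueError):
    pass


class Vocab:
    """Word-level vocabulary with label special tokens and char fallback.

    Known words map to a single sub-token; out-of-vocabulary words fall back
    to per-character sub-tokens (``#c``), so every word gets at least one
    sub-token and rare words span several.  Each event type contributes one
    added special token ``[L-<type>]`` carrying the label's trainable
    embedding.
    """

    _CHARS = string.ascii_lowercase + string.digits + string.punctuation

    def __init__(self, words, schema: EventTypeSchema, lowercase: bool = True):
        self.lowercase = lowercase
        self.schema = schema
        self._tokens: list[str] = [PAD, CLS, SEP, UNK]
        self._tokens += [self.label_token(t) for t in schema.types]
        self._tokens += [f"#{c}" for c in self._CHARS]
        seen = set(self._tokens)
        for w in words:
            w = w.lower() if lowercase else w
            if w not in seen:
                seen.add(w)
                self._tokens.append(w)
        self._index = {t: i for i, t in enumerate(self._tokens)}

    @staticmethod
    def label_token(type_id: str) -> str:
        return f"[L-{type_id}]"

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def id(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise EncodingError(f"token {token!r} not in vocabulary") from None

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    def encode_word(self, word: str) -> list[int]:
        """Sub-token ids for one word (len 1 if known, else char fallback)."""
        w = word.lower() if self.lowercase else word
        if w in self._index:
            return [self._index[w]]
        ids = [self._index.get(f"#{c}", self._index[UNK]) for c in w]
        return ids or [self._index[UNK]]

    @classmethod
    def build(cls, sentences, schema: EventTypeSchema, lowercase: bool = True):
        """Build from an iterable of token lists."""
        words: list[str] = []
        for sent in sentences:
            words.extend(sent)
        return cls(words, schema, lowercase)

    def to_dict(self) -> dict:
        return {
            "tokens": self._tokens,
            "lowercase": self.lowercase,
        }

    @classmethod
    def from_dict(cls, payload: dict, schema: EventTypeSchema) -> "Vocab":
        vocab = cls.__new__(cls)
        vocab.lowercase = payload["lowercase"]
        vocab.schema = schema
        vocab._tokens = list(payload["tokens"])
        vocab._index = {t: i for i, t in enumerate(vocab._tokens)}
        return vocab


@dataclass(frozen=True)
class LabelPrompt:
    """Per-run-fixed random ordering of the label special tokens."""

    types_in_order: tuple[str, ...]
    token_ids: tuple[int, ...]
    seed: int

    @property
    def m(self) -> int:
        return len(self.types_in_order)


def build_label_prompt(schema: EventTypeSchema, vocab: Vocab, seed: int) -> LabelPrompt:
    """Permute the schema types with a recorded seed; one token per type."""
    rng = np.random.default_rng(seed)
    order = tuple(schema.types[i] for i in rng.permutation(schema.k))
    ids = tuple(vocab.id(Vocab.label_token(t)) for t in order)
    return LabelPrompt(order, ids, seed)


@dataclass
class JointInput:
    """The packed ``<[CLS], L, [SEP], S, [SEP]>`` id sequence.

    ``label_positions`` indexes the prompt tokens (prompt order);
    ``word_spans`` maps each retained sentence word to its half-open
    sub-token run; the first position of each run is the word's
    representative.  ``segment_ids`` are 0 for the prompt block, 1 for the
    sentence block.
    """

    ids: np.ndarray
    segment_ids: np.ndarray
    label_positions: np.ndarray
    word_spans: list[tuple[int, int]]
    n_words: int
    truncated: bool = False

    @property
    def word_positions(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.word_spans], dtype=int)

    def __len__(self) -> int:
        return len(self.ids)


def build_joint_input(
    prompt: LabelPrompt,
    words: list[str],
    vocab: Vocab,
    max_len: int = 256,
) -> JointInput:
    """Pack prompt and sentence into one encoder input.

    When the packed sequence would exceed ``max_len``, sentence sub-tokens
    are dropped from the tail at whole-word granularity — the prompt is
    never truncated.  A prompt that does not fit on its own is an error.
    """
    m = prompt.m
    prompt_len = 1 + m + 1  # [CLS] L [SEP]
    if prompt_len + 1 > max_len:
        raise EncodingError(
            f"label prompt ({prompt_len} tokens + final [SEP]) exceeds max_len={max_len}"
        )
    budget = max_len - prompt_len - 1  # room for sentence sub-tokens
    ids: list[int] = [vocab.id(CLS), *prompt.token_ids, vocab.id(SEP)]
    label_positions = np.arange(1, 1 + m)
    word_spans: list[tuple[int, int]] = []
    used = 0
    truncated = False
    for w in words:
        sub = vocab.encode_word(w)
        if used + len(sub) > budget:
            truncated = True
            break
        lo = prompt_len + used
        word_spans.append((lo, lo + len(sub)))
        ids.extend(sub)
        used += len(sub)
    if truncated:
        logger.warning(
            "sentence truncated to %d of %d words (max_len=%d)",
            len(word_spans), len(words), max_len,
        )
    ids.append(vocab.id(SEP))
    segment_ids = np.zeros(len(ids), dtype=int)
    segment_ids[prompt_len:] = 1
    return JointInput(
        ids=np.asarray(ids, dtype=int),
        segment_ids=segment_ids,
        label_positions=label_positions,
        word_spans=word_spans,
        n_words=len(word_spans),
        truncated=truncated,
    )


@dataclass
class EncodedPair:
    """Split encoder output: label rows ``H_L`` and word rows ``H_S``."""

    h_l: Tensor  # m x d
    h_s: Tensor  # n x d


@dataclass(frozen=True)
class EncoderConfig:
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    max_len: int = 256
    dropout: float = 0.1


class TinyTransformer:
    """Small trainable multi-head self-attention encoder (pre-norm)."""

    def __init__(self, cfg: EncoderConfig, vocab_size: int, rng: np.random.Generator):
        if cfg.d_model % cfg.n_heads:
            raise EncodingError("d_model must be divisible by n_heads")
        self.cfg = cfg
        d, ff = cfg.d_model, cfg.d_ff
        scale = 0.02

        def p(*shape):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        self.tok_emb = p(vocab_size, d)
        self.pos_emb = p(cfg.max_len, d)
        self.seg_emb = p(2, d)
        self.layers = []
        for _ in range(cfg.n_layers):
            layer = {
                "wq": p(d, d), "wk": p(d, d), "wv": p(d, d), "wo": p(d, d),
                "ln1_g": Tensor(np.ones(d), requires_grad=True),
                "ln1_b": Tensor(np.zeros(d), requires_grad=True),
                "w1": p(d, ff), "b1": Tensor(np.zeros(ff), requires_grad=True),
                "w2": p(ff, d), "b2": Tensor(np.zeros(d), requires_grad=True),
                "ln2_g": Tensor(np.ones(d), requires_grad=True),
                "ln2_b": Tensor(np.zeros(d), requires_grad=True),
            }
            self.layers.append(layer)

    @property
    def d_model(self) -> int:
        return self.cfg.d_model

    def parameters(self) -> list[Tensor]:
        params = [self.tok_emb, self.pos_emb, self.seg_emb]
        for layer in self.layers:
            params.extend(layer.values())
        return params

    def __call__(
        self,
        ids: np.ndarray,
        attn_mask: np.ndarray,
        segment_ids: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Encode a padded batch: (B, S) ids -> (B, S, d) vectors."""
        cfg = self.cfg
        B, S = ids.shape
        if S > cfg.max_len:
            raise EncodingError(f"sequence length {S} exceeds max_len {cfg.max_len}")
        x = self.tok_emb[ids] + self.pos_emb[np.arange(S)] + self.seg_emb[segment_ids]
        # additive mask: large negative on padding keys
        neg = np.where(attn_mask[:, None, None, :] > 0, 0.0, -1e9)
        dh = cfg.d_model // cfg.n_heads
        drop = cfg.dropout if train else 0.0
        for layer in self.layers:
            h = ad.layer_norm(x, layer["ln1_g"], layer["ln1_b"])

            def split_heads(t):
                return t.reshape((B, S, cfg.n_heads, dh)).swapaxes(1, 2)

            q = split_heads(h @ layer["wq"])
            k = split_heads(h @ layer["wk"])
            v = split_heads(h @ layer["wv"])
            scores = (q @ k.T) * (1.0 / np.sqrt(dh)) + Tensor(neg)
            attn = ad.softmax(scores, axis=-1)
            ctx = (attn @ v).swapaxes(1, 2).reshape((B, S, cfg.d_model))
            x = x + ad.dropout(ctx @ layer["wo"], drop, rng, train)
            h = ad.layer_norm(x, layer["ln2_g"], layer["ln2_b"])
            ffn = ad.relu(h @ layer["w1"] + layer["b1"]) @ layer["w2"] + layer["b2"]
            x = x + ad.dropout(ffn, drop, rng, train)
        return x


class IdentityEncoder:
    """Stub encoder returning raw token embeddings (for exact-gather tests)."""

    def __init__(self, vocab_size: int, d_model: int, rng=None, embeddings=None):
        if embeddings is None:
            rng = rng or np.random.default_rng(0)
            embeddings = rng.normal(size=(vocab_size, d_model))
        self.tok_emb = Tensor(np.asarray(embeddings, float), requires_grad=True)
        self.cfg = EncoderConfig(d_model=self.tok_emb.shape[1])

    @property
    def d_model(self) -> int:
        return self.tok_emb.shape[1]

    def parameters(self) -> list[Tensor]:
        return [self.tok_emb]

    def __call__(self, ids, attn_mask, segment_ids, train=False, rng=None) -> Tensor:
        return self.tok_emb[ids]


def encode_and_split(encoder, ji: JointInput) -> EncodedPair:
    """Run one joint input through the encoder and split into (H_L, H_S).

    ``H_L`` gathers the label positions in prompt order; ``H_S`` gathers one
    row per sentence word via the first-sub-token rule.
    """
    ids = ji.ids[None, :]
    mask = np.ones_like(ids)
    seg = ji.segment_ids[None, :]
    out = encoder(ids, mask, seg)  # (1, S, d)
    h = out[0]
    h_l = h[ji.label_positions]
    h_s = h[ji.word_positions]
    return EncodedPair(h_l=h_l, h_s=h_s)


def encode_batch(
    encoder,
    joint_inputs: list[JointInput],
    pad_id: int,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor, np.ndarray]:
    """Encode a batch of joint inputs; returns (H_L, padded H_S, lengths).

    ``H_L`` is (B, m, d); ``H_S`` is (B, n_max, d) with zero rows past each
    sentence's length.
    """
    B = len(joint_inputs)
    S = max(len(ji) for ji in joint_inputs)
    m = joint_inputs[0].label_positions.size
    ids = np.full((B, S), pad_id, dtype=int)
    mask = np.zeros((B, S), dtype=int)
    seg = np.zeros((B, S), dtype=int)
    for b, ji in enumerate(joint_inputs):
        ids[b, : len(ji)] = ji.ids
        mask[b, : len(ji)] = 1
        seg[b, : len(ji)] = ji.segment_ids
    out = encoder(ids, mask, seg, train=train, rng=rng)  # (B, S, d)

    b_idx = np.repeat(np.arange(B), m)
    l_idx = np.concatenate([ji.label_positions for ji in joint_inputs])
    h_l = out[(b_idx, l_idx)].reshape((B, m, encoder.d_model))

    lengths = np.array([ji.n_words for ji in joint_inputs], dtype=int)
    n_max = int(lengths.max())
    # gather word-initial rows into a padded (B, n_max, d) block by scattering
    # through a flat index: padded slot -> flat position in (B*S)
    flat_index = np.zeros((B, n_max), dtype=int)
    valid = np.zeros((B, n_max, 1))
    for b, ji in enumerate(joint_inputs):
        wp = ji.word_positions
        flat_index[b, : wp.size] = b * S + wp
        valid[b, : wp.size] = 1.0
    flat_out = out.reshape((B * S, encoder.d_model))
    h_s = flat_out[flat_index.ravel()].reshape((B, n_max, encoder.d_model))
    h_s = h_s * Tensor(valid)  # zero padded rows (index 0 points at a real row)
    return h_l, h_s, lengths
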