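"""The assembled trigger-detection model.

Pipeline per sentence batch:

1. pack ``<[CLS], L, [SEP], S, [SEP]>`` joint inputs (label prompt + sentence)
   and run the self-attention encoder; split into label encodings ``H_L`` and
   word-level sentence encodings ``H_S``;
2. compute the label-context representation ``C`` (attention over labels) and
   the label-trigger affinity matrix ``A`` (sigmoid bilinear form);
3. project ``H_S``, ``C`` and ``A`` through three independent affine heads
   onto the BIO tag space and combine them as
   ``x = X' + alpha * X_hat + (1 - alpha) * X_tilde``;
4. use ``x`` as CRF emissions: negative log-likelihood for training, Viterbi
   for decoding, spans recovered from the decoded BIO tags.

Ablation flags remove individual terms: ``disable_lcar`` drops the
``alpha * X_hat`` term, ``disable_ltar`` drops the ``(1-alpha) * X_tilde``
term, ``disable_lsrl`` leaves the sentence projection alone, and
``disable_joint_encoding`` encodes the sentence without the label prompt
(labels are then encoded in a separate pass so ``C``/``A`` remain defined).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import crf as crf_mod
from .autodiff import Tensor
from .encoder import (
    EncoderConfig,
    JointInput,
    LabelPrompt,
    TinyTransformer,
    Vocab,
    build_joint_input,
    build_label_prompt,
    encode_batch,
)
from .lsrl import (
    CombinationConfig,
    LcarParams,
    LtarParams,
    ProjectionHeads,
    combine,
    compute_lcar,
    compute_ltar,
    project,
)
from .schema import BioTagset, EventTypeSchema, TriggerSpan, spans_to_tags, tags_to_spans, transition_mask
from .standoff import SentenceRecord


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    alpha: float = 0.5
    include_1_over_n: bool = True
    max_len: int = 256
    crf_mask: bool = False
    disable_lcar: bool = False
    disable_ltar: bool = False
    disable_lsrl: bool = False
    disable_joint_encoding: bool = False
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def combination(self) -> CombinationConfig:
        return CombinationConfig(alpha=self.alpha)


def ablate(config: ModelConfig, **flags: bool) -> ModelConfig:
    """Return a config variant with the given ablation flags set."""
    allowed = {"disable_lcar", "disable_ltar", "disable_lsrl", "disable_joint_encoding"}
    unknown = set(flags) - allowed
    if unknown:
        raise ModelError(f"unknown ablation flags: {sorted(unknown)}")
    return dataclasses.replace(config, **flags)


class TriggerModel:
    """Trainable label-aware trigger detector over an event-type schema."""

    def __init__(
        self,
        schema: EventTypeSchema,
        vocab: Vocab,
        config: ModelConfig = ModelConfig(),
        seed: int = 0,
    ):
        self.schema = schema
        self.vocab = vocab
        self.config = config
        self.seed = seed
        self.tagset = BioTagset.from_schema(schema)
        rng = np.random.default_rng(seed)
        self.encoder = TinyTransformer(config.encoder, len(vocab), rng)
        self.prompt: LabelPrompt = build_label_prompt(schema, vocab, seed)
        d = config.encoder.d_model
        self.lcar = LcarParams.init(d, rng, include_1_over_n=config.include_1_over_n)
        self.ltar = LtarParams.init(d, rng)
        self.heads = ProjectionHeads.init(d, self.prompt.m, self.tagset.size, rng)
        self.transitions = Tensor(
            np.zeros((self.tagset.size + 2, self.tagset.size + 2)), requires_grad=True
        )
        self.invalid_mask = transition_mask(self.tagset) if config.crf_mask else None

    # -- parameters --------------------------------------------------------

    def named_parameters(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {
            "enc.tok_emb": self.encoder.tok_emb,
            "enc.pos_emb": self.encoder.pos_emb,
            "enc.seg_emb": self.encoder.seg_emb,
        }
        for i, layer in enumerate(self.encoder.layers):
            for key, tensor in layer.items():
                named[f"enc.layer{i}.{key}"] = tensor
        for key, tensor in zip(("wq", "wk", "wv"), self.lcar.parameters()):
            named[f"lcar.{key}"] = tensor
        named["ltar.w"], named["ltar.b"] = self.ltar.w, self.ltar.b
        for key in ("w1", "b1", "w2", "b2", "w3", "b3"):
            named[f"heads.{key}"] = getattr(self.heads, key)
        named["crf.transitions"] = self.transitions
        return named

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    # -- input packing -----------------------------------------------------

    def joint_input(self, record: SentenceRecord) -> JointInput:
        if self.config.disable_joint_encoding:
            empty = LabelPrompt((), (), self.prompt.seed)
            return build_joint_input(
                empty, record.surfaces, self.vocab, self.config.max_len
            )
        return build_joint_input(
            self.prompt, record.surfaces, self.vocab, self.config.max_len
        )

    def _label_only_input(self) -> JointInput:
        return build_joint_input(self.prompt, [], self.vocab, self.config.max_len)

    # -- forward -----------------------------------------------------------

    def emissions(
        self,
        records: list[SentenceRecord],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        """Combined emission matrix for a batch: ((B, n_max, k_bio), lengths)."""
        if not records:
            raise ModelError("empty batch")
        jis = [self.joint_input(r) for r in records]
        h_l, h_s, lengths = encode_batch(
            self.encoder, jis, self.vocab.pad_id, train=train, rng=rng
        )
        if self.config.disable_joint_encoding:
            # labels encoded separately, once per forward pass
            l_ji = self._label_only_input()
            h_l, _, _ = encode_batch(
                self.encoder, [l_ji], self.vocab.pad_id, train=train, rng=rng
            )  # (1, m, d); broadcasts against (B, n, d)
        cfg = self.config
        if cfg.disable_lsrl:
            x_sent = h_s @ self.heads.w1 + self.heads.b1
            return x_sent, lengths
        c = compute_lcar(h_s, h_l, self.lcar)
        a = compute_ltar(h_s, h_l, self.ltar)
        x_sent, x_ctx, x_trig = project(h_s, c, a, self.heads)
        if cfg.disable_lcar and cfg.disable_ltar:
            x = x_sent
        elif cfg.disable_lcar:
            x = x_sent + x_trig
        elif cfg.disable_ltar:
            x = x_sent + cfg.alpha * x_ctx
        else:
            x = combine(x_sent, x_ctx, x_trig, cfg.combination())
        return x, lengths

    def gold_tag_matrix(
        self, records: list[SentenceRecord], lengths: np.ndarray
    ) -> np.ndarray:
        """Padded int matrix of gold BIO tag indices, truncation-aware."""
        B, n_max = len(records), int(lengths.max())
        tags = np.zeros((B, n_max), dtype=int)
        for b, rec in enumerate(records):
            n = int(lengths[b])
            spans = [s for s in rec.gold_spans if s.token_end <= n]
            row = self.tagset.encode(spans_to_tags(spans, n, self.tagset))
            tags[b, :n] = row
        return tags

    def loss(
        self,
        records: list[SentenceRecord],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Mean CRF negative log-likelihood over the batch."""
        emissions, lengths = self.emissions(records, train=train, rng=rng)
        tags = self.gold_tag_matrix(records, lengths)
        return crf_mod.crf_nll(
            emissions, tags, lengths, self.transitions, self.invalid_mask
        )

    def predict(self, records: list[SentenceRecord]) -> list[list[TriggerSpan]]:
        """Viterbi-decode each sentence and convert BIO tags to spans."""
        emissions, lengths = self.emissions(records, train=False)
        params = crf_mod.CrfParams(self.transitions.data, self.invalid_mask)
        out: list[list[TriggerSpan]] = []
        for b in range(len(records)):
            n = int(lengths[b])
            idx = crf_mod.viterbi_decode(emissions.data[b, :n], params)
            out.append(tags_to_spans(self.tagset.decode(idx)))
        return out

    def predict_tags(self, records: list[SentenceRecord]) -> list[list[str]]:
        emissions, lengths = self.emissions(records, train=False)
        params = crf_mod.CrfParams(self.transitions.data, self.invalid_mask)
        return [
            self.tagset.decode(
                crf_mod.viterbi_decode(emissions.data[b, : int(lengths[b])], params)
            )
            for b in range(len(records))
        ]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write parameters (.npz) plus schema/vocab/config metadata (.json)."""
        path = Path(path)
        arrays = {k: v.data for k, v in self.named_parameters().items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "schema": {
                "name": self.schema.name,
                "types": [
                    {"id": t, "label": self.schema.label_words[t]}
                    for t in self.schema.types
                ],
            },
            "vocab": self.vocab.to_dict(),
            "seed": self.seed,
            "prompt_order": list(self.prompt.types_in_order),
            "config": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(self.config).items()
                    if k != "encoder"
                },
                "encoder": dataclasses.asdict(self.config.encoder),
            },
        }
        path.with_suffix(".json").write_text(
            json.dumps(meta, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, path) -> "TriggerModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        schema = EventTypeSchema(
            types=tuple(e["id"] for e in meta["schema"]["types"]),
            label_words={e["id"]: e["label"] for e in meta["schema"]["types"]},
            name=meta["schema"]["name"],
        )
        vocab = Vocab.from_dict(meta["vocab"], schema)
        enc_cfg = EncoderConfig(**meta["config"].pop("encoder"))
        config = ModelConfig(encoder=enc_cfg, **meta["config"])
        model = cls(schema, vocab, config, seed=meta["seed"])
        if list(model.prompt.types_in_order) != meta["prompt_order"]:
            raise ModelError("prompt order mismatch on reload")
        arrays = np.load(path.with_suffix(".npz"))
        for name, tensor in model.named_parameters().items():
            tensor.data = np.asarray(arrays[name], dtype=np.float64)
        return model
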