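"""Seeded synthetic corpora with planted trigger lexicons and ambiguity.

The generator emulates the statistical structure a label-aware trigger
detector exploits, without any external data:

* each event type owns a small lexicon of unambiguous trigger words (one
  multi-token surface per type exercises B/I tagging);
* a pool of *ambiguous* trigger words is shared between two or more types —
  mirroring genuinely polysemous biomedical triggers such as
  "proliferation", which can signal either a growth or a cell-proliferation
  event — and each (ambiguous word, type) pair has a dedicated context-cue
  word: when the cue appears in the sentence, the trigger's gold type is
  that type, deterministically.  The Bayes-optimal classifier on this
  process therefore attains F1 = 1, while any context-blind lexicon lookup
  is capped strictly below 1;
* remaining positions are filled from a disjoint background vocabulary.

Sentences are generated slot-wise (trigger slots plus background slots), so
gold spans are non-overlapping by construction.  Everything is
deterministic given (spec, n_sentences, seed).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .schema import BioTagset, EventTypeSchema, TriggerSpan, spans_to_tags
from .standoff import EAnnotation, SentenceRecord, StandoffDocument, TAnnotation


class SynthError(ValueError):
    pass


DEFAULT_TYPES = ("Growth", "Cell_Proliferation", "Localization", "Binding", "Regulation")


@dataclass
class SyntheticSpec:
    """Generative process parameters.

    Defaults define the reference study conditions used throughout the test
    suite: 5 event types, background vocabulary of 200 words, 4 unambiguous
    trigger words per type (one of them two tokens long), 5 ambiguous words
    shared between type pairs, sentence lengths uniform on [6, 12], one
    trigger slot per sentence filled with probability ``trigger_density`` =
    0.6, and an ambiguous word chosen for a filled slot with probability
    ``ambiguity_rate`` = 0.3.  ``cue_noise`` = 0 keeps the context cues
    deterministic so recovery thresholds are sharp.
    """

    schema: EventTypeSchema = field(
        default_factory=lambda: EventTypeSchema(types=DEFAULT_TYPES, name="synthetic")
    )
    n_unambiguous_per_type: int = 4
    n_ambiguous: int = 5
    background_vocab_size: int = 200
    min_sentence_len: int = 6
    max_sentence_len: int = 12
    trigger_density: float = 0.6
    ambiguity_rate: float = 0.3
    cue_noise: float = 0.0
    slots_per_sentence: int = 1
    sentences_per_doc: int = 10
    seed: int = 0

    # derived lexicons, built in __post_init__
    unambiguous: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    ambiguous: dict[str, tuple[str, ...]] = field(default_factory=dict)
    cues: dict[tuple[str, str], str] = field(default_factory=dict)
    background: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate, name in (
            (self.trigger_density, "trigger_density"),
            (self.ambiguity_rate, "ambiguity_rate"),
            (self.cue_noise, "cue_noise"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise SynthError(f"{name} must lie in [0, 1], got {rate}")
        if not self.unambiguous:
            self._build_lexicons()
        self.validate()

    def _build_lexicons(self) -> None:
        types = self.schema.types
        for t in types:
            low = t.lower()
            words: list[tuple[str, ...]] = [
                (f"trg_{low}_{i}",) for i in range(self.n_unambiguous_per_type - 1)
            ]
            # one two-token surface per type exercises B-/I- tagging
            words.append((f"trg_{low}_a", f"trg_{low}_b"))
            self.unambiguous[t] = words
        for i in range(self.n_ambiguous):
            pair = (types[i % len(types)], types[(i + 1) % len(types)])
            word = f"amb_{i}"
            self.ambiguous[word] = pair
            for t in pair:
                self.cues[(word, t)] = f"cue_{i}_{t.lower()}"
        self.background = [f"w{i:04d}" for i in range(self.background_vocab_size)]

    def validate(self) -> None:
        trigger_tokens = {
            tok for words in self.unambiguous.values() for w in words for tok in w
        }
        trigger_tokens |= set(self.ambiguous)
        cue_tokens = set(self.cues.values())
        bg = set(self.background)
        if trigger_tokens & bg or cue_tokens & bg:
            raise SynthError("lexicon words collide with the background vocabulary")
        if len(set(self.cues.values())) != len(self.cues):
            raise SynthError("context cues must be distinct")
        for word, types in self.ambiguous.items():
            if len(types) < 2:
                raise SynthError(f"ambiguous word {word!r} needs >= 2 candidate types")
            if len(set(types)) != len(types):
                raise SynthError(f"ambiguous word {word!r} repeats a type")


@dataclass
class GenerationEntry:
    """Ground-truth log record for one planted trigger instance."""

    sent_global_index: int
    token_start: int
    token_end: int
    type: str
    surface: tuple[str, ...]
    ambiguous: bool
    cue: str | None


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    documents: list[StandoffDocument]
    sentences: list[SentenceRecord]
    log: list[GenerationEntry]

    @property
    def true_trigger_count(self) -> int:
        return len(self.log)

    def per_type_counts(self) -> dict[str, int]:
        return dict(Counter(e.type for e in self.log))


def _make_sentence(spec: SyntheticSpec, rng: np.random.Generator):
    """One sentence: (tokens, spans, log entries without global index)."""
    n = int(rng.integers(spec.min_sentence_len, spec.max_sentence_len + 1))
    tokens = [str(rng.choice(spec.background)) for _ in range(n)]
    entries = []
    spans = []
    occupied: set[int] = set()
    # place trigger slots left-to-right; occupied positions are never reused,
    # so gold spans are non-overlapping by construction
    cursor = 0
    for _ in range(spec.slots_per_sentence):
        if rng.random() >= spec.trigger_density:
            cursor += 2
            continue
        if rng.random() < spec.ambiguity_rate and spec.ambiguous:
            word = str(rng.choice(sorted(spec.ambiguous)))
            gold = str(rng.choice(spec.ambiguous[word]))
            surface: tuple[str, ...] = (word,)
            cue = spec.cues[(word, gold)]
            if spec.cue_noise > 0 and rng.random() < spec.cue_noise:
                cue = None
            ambiguous = True
        else:
            gold = str(rng.choice(spec.schema.types))
            lex = spec.unambiguous[gold]
            surface = lex[int(rng.integers(len(lex)))]
            cue, ambiguous = None, False
        candidates = [
            s
            for s in range(cursor, n - len(surface) + 1)
            if all(p not in occupied for p in range(s, s + len(surface)))
        ][:3]
        if not candidates:
            break
        start = int(rng.choice(candidates))
        for off, tok in enumerate(surface):
            tokens[start + off] = tok
        occupied.update(range(start, start + len(surface)))
        if cue is not None:
            free = [i for i in range(n) if i not in occupied]
            cue_pos = int(rng.choice(free))
            tokens[cue_pos] = cue
            occupied.add(cue_pos)
        spans.append(TriggerSpan(start, start + len(surface), gold))
        entries.append((start, start + len(surface), gold, surface, ambiguous, cue))
        cursor = start + len(surface) + 1
    return tokens, spans, entries


def generate_corpus(
    spec: SyntheticSpec, n_sentences: int, seed: int | None = None
) -> SyntheticCorpus:
    """Generate a corpus of ``n_sentences``, deterministic under the seed."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tagset = BioTagset.from_schema(spec.schema)

    documents: list[StandoffDocument] = []
    records: list[SentenceRecord] = []
    log: list[GenerationEntry] = []

    sent_global = 0
    n_docs = (n_sentences + spec.sentences_per_doc - 1) // spec.sentences_per_doc
    for d in range(n_docs):
        doc_id = f"synth{seed}_{d:04d}"
        doc_sents = min(spec.sentences_per_doc, n_sentences - d * spec.sentences_per_doc)
        text_parts: list[str] = []
        t_anns: list[TAnnotation] = []
        e_anns: list[EAnnotation] = []
        offset = 0
        ann_counter = 0
        for s in range(doc_sents):
            tokens, spans, entries = _make_sentence(spec, rng)
            sent_text = " ".join(tokens)
            tok_offsets = []
            pos = offset
            for tok in tokens:
                tok_offsets.append((tok, pos, pos + len(tok)))
                pos += len(tok) + 1
            for (t0, t1, gold, surface, ambiguous, cue), sp in zip(entries, spans):
                ann_counter += 1
                lo = tok_offsets[t0][1]
                hi = tok_offsets[t1 - 1][2]
                tid = f"T{ann_counter}"
                t_anns.append(
                    TAnnotation(tid, gold, lo, hi, " ".join(surface))
                )
                log.append(
                    GenerationEntry(sent_global, t0, t1, gold, surface, ambiguous, cue)
                )
            records.append(
                SentenceRecord(doc_id, s, tok_offsets, sorted(
                    spans, key=lambda sp: sp.token_start))
            )
            # sanity: gold spans must encode to valid BIO
            spans_to_tags(spans, len(tokens), tagset)
            text_parts.append(sent_text)
            offset += len(sent_text) + 1
            sent_global += 1
        text = "\n".join(text_parts) + "\n"
        for i, t in enumerate(t_anns, 1):
            e_anns.append(EAnnotation(f"E{i}", t.type, t.id))
        documents.append(StandoffDocument(doc_id, text, t_anns, e_anns))
    return SyntheticCorpus(spec, documents, records, log)


def _majority_lookup(corpus: SyntheticCorpus) -> dict[tuple[str, ...], str]:
    """Most-frequent gold type per trigger surface; ties break lexically."""
    counts: dict[tuple[str, ...], Counter] = {}
    for e in corpus.log:
        counts.setdefault(e.surface, Counter())[e.type] += 1
    lookup = {}
    for surface, ctr in counts.items():
        top = max(ctr.values())
        lookup[surface] = sorted(t for t, c in ctr.items() if c == top)[0]
    return lookup


def lexicon_baseline_predictions(
    corpus: SyntheticCorpus, lookup_corpus: SyntheticCorpus | None = None
) -> list[list[TriggerSpan]]:
    """Context-blind predictions from a most-frequent-type surface lookup.

    The lookup table is built from ``lookup_corpus`` (default: the corpus
    itself).  Multi-token surfaces are matched greedily, longest first.
    """
    lookup = _majority_lookup(lookup_corpus or corpus)
    surfaces = sorted(lookup, key=len, reverse=True)
    preds: list[list[TriggerSpan]] = []
    for rec in corpus.sentences:
        toks = rec.surfaces
        spans: list[TriggerSpan] = []
        i = 0
        while i < len(toks):
            matched = False
            for surf in surfaces:
                L = len(surf)
                if tuple(toks[i : i + L]) == surf:
                    spans.append(TriggerSpan(i, i + L, lookup[surf]))
                    i += L
                    matched = True
                    break
            if not matched:
                i += 1
        preds.append(spans)
    return preds


def lexicon_baseline_score(
    corpus: SyntheticCorpus, lookup_corpus: SyntheticCorpus | None = None
) -> float:
    """Micro-F1 of the context-blind lexicon baseline on ``corpus``."""
    from .metrics import evaluate

    preds = lexicon_baseline_predictions(corpus, lookup_corpus)
    gold = [rec.gold_spans for rec in corpus.sentences]
    return evaluate(gold, preds, averaging="micro").f1 / 100.0
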