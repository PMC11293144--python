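"""BioNLP standoff corpus I/O: ``.txt`` / ``.a1`` / ``.a2`` triples.

A document is raw text plus standoff annotations referencing character
offsets: ``T`` lines carry typed text-bound annotations (entities in ``.a1``,
event triggers in ``.a2``) and ``E`` lines carry event structures whose first
argument names the trigger ``T`` id.  This module parses and writes that
format, splits documents into tokenized sentence records carrying gold
trigger spans, and computes corpus statistics.

Only the trigger reference of an ``E`` line is interpreted; the argument
structure is retained as an opaque string (argument extraction is out of
scope).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .schema import EventTypeSchema, TriggerSpan

logger = logging.getLogger(__name__)


class StandoffError(ValueError):
    """Malformed standoff input or inconsistent documents."""


@dataclass(frozen=True)
class TAnnotation:
    """A text-bound annotation (``T`` line): typed character span."""

    id: str
    type: str
    char_start: int
    char_end: int
    surface: str


@dataclass(frozen=True)
class EAnnotation:
    """An event annotation (``E`` line): event type + trigger reference."""

    id: str
    event_type: str
    trigger_t_id: str
    raw_args: str = ""


@dataclass
class StandoffDocument:
    doc_id: str
    text: str
    t_annotations: list[TAnnotation] = field(default_factory=list)
    e_annotations: list[EAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ann in self.t_annotations:
            if ann.id in seen:
                raise StandoffError(f"{self.doc_id}: duplicate annotation id {ann.id}")
            seen.add(ann.id)
            if self.text[ann.char_start : ann.char_end] != ann.surface:
                raise StandoffError(
                    f"{self.doc_id}:{ann.id}: surface {ann.surface!r} does not "
                    f"match text[{ann.char_start}:{ann.char_end}]"
                )
        for ev in self.e_annotations:
            if ev.id in seen:
                raise StandoffError(f"{self.doc_id}: duplicate annotation id {ev.id}")
            seen.add(ev.id)

    def trigger_annotations(self, schema: EventTypeSchema) -> list[TAnnotation]:
        """T annotations that are event triggers under the schema.

        A ``T`` is a trigger iff its type is in the schema AND, when ``E``
        lines exist, some ``E`` line references it; without ``E`` lines,
        type-membership alone decides (corpora exported without event
        structures).
        """
        in_schema = [t for t in self.t_annotations if t.type in schema]
        if not self.e_annotations:
            return in_schema
        referenced = {e.trigger_t_id for e in self.e_annotations}
        return [t for t in in_schema if t.id in referenced]


@dataclass
class SentenceRecord:
    """Tokenized sentence with character offsets and typed trigger spans."""

    doc_id: str
    sent_index: int
    tokens: list[tuple[str, int, int]]
    gold_spans: list[TriggerSpan] = field(default_factory=list)

    @property
    def surfaces(self) -> list[str]:
        return [t[0] for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)

    def span_surface(self, span: TriggerSpan) -> str:
        return " ".join(self.surfaces[span.token_start : span.token_end])


@dataclass
class CorpusStats:
    n_documents: int
    n_sentences: int
    n_trigger_mentions: int
    n_event_instances: int
    per_type: dict[str, int]

    @property
    def n_events(self) -> int:
        """Trigger-mention count (equals the sum of per-type counts)."""
        return self.n_trigger_mentions


_E_LINE = re.compile(r"^(E\d+)\t(\S+):(T\d+)\s*(.*)$")


def _parse_ann_file(path: Path, text: str, doc_id: str):
    """Parse one .a1/.a2 file into (T list, E list, n_discontinuous_skipped)."""
    t_anns: list[TAnnotation] = []
    e_anns: list[EAnnotation] = []
    skipped = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            try:
                ann_id, rest = line.split("\t", 1)
                type_and_offsets, surface = (rest.split("\t", 1) + [""])[:2]
                parts = type_and_offsets.split(" ", 1)
                ann_type, offsets = parts[0], parts[1]
            except (ValueError, IndexError):
                raise StandoffError(f"{path.name}:{lineno}: malformed T line") from None
            if ";" in offsets:
                skipped += 1
                logger.warning(
                    "%s:%d: discontinuous annotation %s skipped (BIO cannot "
                    "represent it)", path.name, lineno, ann_id,
                )
                continue
            start_s, end_s = offsets.split()
            start, end = int(start_s), int(end_s)
            if text[start:end] != surface:
                raise StandoffError(
                    f"{path.name}:{lineno}: surface {surface!r} does not match "
                    f"text[{start}:{end}]={text[start:end]!r}"
                )
            t_anns.append(TAnnotation(ann_id, ann_type, start, end, surface))
        elif line.startswith("E"):
            m = _E_LINE.match(line)
            if not m:
                raise StandoffError(f"{path.name}:{lineno}: malformed E line")
            e_anns.append(EAnnotation(m.group(1), m.group(2), m.group(3), m.group(4)))
        # other line kinds (A, M, R, *) are ignored: not trigger-relevant
    return t_anns, e_anns, skipped


def read_standoff_dir(path, schema: EventTypeSchema) -> list[StandoffDocument]:
    """Read all ``.txt``(+``.a1``/``.a2``) triples under ``path``.

    ``.a2`` may be absent (unannotated test splits).  Surface/offset
    mismatches are hard errors naming file and line; discontinuous
    (semicolon-offset) annotations are skipped with a logged warning.
    """
    root = Path(path)
    docs: list[StandoffDocument] = []
    for txt in sorted(root.glob("*.txt")):
        doc_id = txt.stem
        text = txt.read_text(encoding="utf-8")
        t_anns: list[TAnnotation] = []
        e_anns: list[EAnnotation] = []
        for suffix in (".a1", ".a2"):
            ann_path = txt.with_suffix(suffix)
            if ann_path.exists():
                ts, es, _ = _parse_ann_file(ann_path, text, doc_id)
                t_anns.extend(ts)
                e_anns.extend(es)
        t_anns.sort(key=lambda a: int(a.id[1:]))
        e_anns.sort(key=lambda a: int(a.id[1:]))
        docs.append(StandoffDocument(doc_id, text, t_anns, e_anns))
    return docs


def write_standoff(docs: Iterable[StandoffDocument], path, schema: EventTypeSchema) -> None:
    """Write documents as ``.txt``/``.a1``/``.a2`` triples under ``path``.

    ``T`` annotations whose type is in the schema go to ``.a2`` together with
    the ``E`` lines; other ``T`` annotations (entities) go to ``.a1``.  A
    subsequent :func:`read_standoff_dir` reproduces the documents
    field-for-field.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise StandoffError(f"colliding doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        (root / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        a1_lines, a2_lines = [], []
        for t in sorted(doc.t_annotations, key=lambda a: int(a.id[1:])):
            line = f"{t.id}\t{t.type} {t.char_start} {t.char_end}\t{t.surface}"
            (a2_lines if t.type in schema else a1_lines).append(line)
        for e in sorted(doc.e_annotations, key=lambda a: int(a.id[1:])):
            line = f"{e.id}\t{e.event_type}:{e.trigger_t_id}"
            if e.raw_args:
                line += f" {e.raw_args}"
            a2_lines.append(line)
        (root / f"{doc.doc_id}.a1").write_text(
            "".join(l + "\n" for l in a1_lines), encoding="utf-8"
        )
        (root / f"{doc.doc_id}.a2").write_text(
            "".join(l + "\n" for l in a2_lines), encoding="utf-8"
        )


_PUNCT = ".,;:()[]{}!?\"'"


def _tokenize_span(text: str, offset: int, split_punct: bool):
    """Offset-preserving tokenization of one sentence string."""
    tokens: list[tuple[str, int, int]] = []
    for m in re.finditer(r"\S+", text):
        word, lo = m.group(), offset + m.start()
        if not split_punct:
            tokens.append((word, lo, lo + len(word)))
            continue
        # strip leading/trailing punctuation into their own tokens
        core_lo, core_hi = 0, len(word)
        lead, trail = [], []
        while core_lo < core_hi and word[core_lo] in _PUNCT:
            lead.append((word[core_lo], lo + core_lo, lo + core_lo + 1))
            core_lo += 1
        while core_hi > core_lo and word[core_hi - 1] in _PUNCT:
            trail.append((word[core_hi - 1], lo + core_hi - 1, lo + core_hi))
            core_hi -= 1
        tokens.extend(lead)
        if core_hi > core_lo:
            tokens.append((word[core_lo:core_hi], lo + core_lo, lo + core_hi))
        tokens.extend(reversed(trail))
    return tokens


def _split_sentences(text: str) -> list[tuple[int, int]]:
    """Offset-preserving sentence boundaries; newline always splits.

    Within a line, a period followed by whitespace and an uppercase letter
    also splits.
    """
    bounds: list[tuple[int, int]] = []
    line_start = 0
    for line in text.split("\n"):
        lo, hi = line_start, line_start + len(line)
        seg_start = lo
        for m in re.finditer(r"\.(\s+)(?=[A-Z])", line):
            end = lo + m.start() + 1
            bounds.append((seg_start, end))
            seg_start = lo + m.end()
        if hi > seg_start or (hi == seg_start and line.strip()):
            bounds.append((seg_start, hi))
        line_start = hi + 1
    return [(a, b) for a, b in bounds if text[a:b].strip()]


def sentence_split_and_tokenize(
    doc: StandoffDocument,
    schema: EventTypeSchema | None = None,
    split_punct: bool = False,
) -> list[SentenceRecord]:
    """Split a document into tokenized sentence records with gold spans.

    The default tokenizer splits on whitespace only, so a sentence-final
    period stays attached to its word.  Triggers whose character extent does
    not align with token boundaries are force-aligned to the smallest
    covering token run (logged).
    """
    triggers = doc.trigger_annotations(schema) if schema is not None else []
    records: list[SentenceRecord] = []
    for sent_index, (lo, hi) in enumerate(_split_sentences(doc.text)):
        tokens = _tokenize_span(doc.text[lo:hi], lo, split_punct)
        if not tokens:
            continue
        spans: list[TriggerSpan] = []
        for t in triggers:
            if not (lo <= t.char_start and t.char_end <= hi):
                continue
            covering = [
                i
                for i, (_, s, e) in enumerate(tokens)
                if s < t.char_end and t.char_start < e
            ]
            if not covering:
                continue
            i0, i1 = covering[0], covering[-1] + 1
            aligned = (
                tokens[i0][1] == t.char_start and tokens[i1 - 1][2] == t.char_end
            )
            if not aligned:
                logger.warning(
                    "%s sent %d: trigger %s (%r) force-aligned to covering "
                    "tokens [%d,%d)", doc.doc_id, sent_index, t.id, t.surface,
                    i0, i1,
                )
            spans.append(TriggerSpan(i0, i1, t.type))
        spans.sort(key=lambda s: (s.token_start, s.token_end))
        records.append(
            SentenceRecord(doc.doc_id, sent_index, tokens, spans)
        )
    return records


def corpus_statistics(
    docs: Sequence[StandoffDocument], schema: EventTypeSchema
) -> CorpusStats:
    per_type: Counter[str] = Counter()
    n_sentences = 0
    n_event_instances = 0
    for doc in docs:
        n_sentences += len(sentence_split_and_tokenize(doc, schema))
        for t in doc.trigger_annotations(schema):
            per_type[t.type] += 1
        n_event_instances += sum(
            1 for e in doc.e_annotations if e.event_type in schema
        )
    return CorpusStats(
        n_documents=len(docs),
        n_sentences=n_sentences,
        n_trigger_mentions=sum(per_type.values()),
        n_event_instances=n_event_instances,
        per_type=dict(per_type),
    )


def write_conll(
    records: Sequence[SentenceRecord],
    tag_sequences: Sequence[Sequence[str]],
    path,
) -> None:
    """Write sentences as two-column token/tag CoNLL, blank-line separated."""
    if len(records) != len(tag_sequences):
        raise StandoffError("records and tag sequences are misaligned")
    with open(path, "w", encoding="utf-8") as fh:
        for rec, tags in zip(records, tag_sequences):
            if len(rec) != len(tags):
                raise StandoffError(
                    f"{rec.doc_id} sent {rec.sent_index}: {len(tags)} tags "
                    f"for {len(rec)} tokens"
                )
            for (surface, _, _), tag in zip(rec.tokens, tags):
                fh.write(f"{surface}\t{tag}\n")
            fh.write("\n")


def write_a2_predictions(
    records: Sequence[SentenceRecord],
    predictions: Sequence[Sequence[TriggerSpan]],
    path,
) -> None:
    """Export predicted spans as ``.a2``-style ``T`` lines, one file per doc."""
    if len(records) != len(predictions):
        raise StandoffError("records and predictions are misaligned")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    by_doc: dict[str, list[str]] = {}
    counters: Counter[str] = Counter()
    for rec, spans in zip(records, predictions):
        for sp in spans:
            counters[rec.doc_id] += 1
            tid = f"T{counters[rec.doc_id]}"
            lo = rec.tokens[sp.token_start][1]
            hi = rec.tokens[sp.token_end - 1][2]
            surface = rec.span_surface(sp)
            by_doc.setdefault(rec.doc_id, []).append(
                f"{tid}\t{sp.type} {lo} {hi}\t{surface}"
            )
    for doc_id, lines in by_doc.items():
        (root / f"{doc_id}.a2").write_text(
            "".join(l + "\n" for l in lines), encoding="utf-8"
        )
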