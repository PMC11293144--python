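"""Event-type schemas, the BIO tag vocabulary, and span <-> tag conversion.

An event-type schema is the ordered set of pre-defined event types of a
trigger-detection corpus (e.g. the 19 MLEE types or the 9 GENIA types).  The
derived BIO tag set has size ``2k + 1``: the outside tag ``O`` plus a
``B-type`` / ``I-type`` pair per event type, so multi-token triggers and
boundaries between adjacent triggers are representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

O_TAG = "O"
START = "<START>"
STOP = "<STOP>"


class SchemaError(ValueError):
    """Invalid schema, tag or span input."""


@dataclass(frozen=True)
class TriggerSpan:
    """A typed trigger span over sentence tokens, 0-based half-open."""

    token_start: int
    token_end: int
    type: str

    def __post_init__(self) -> None:
        if not (0 <= self.token_start < self.token_end):
            raise SchemaError(
                f"invalid span boundaries [{self.token_start}, {self.token_end})"
            )

    @property
    def length(self) -> int:
        return self.token_end - self.token_start

    def overlaps(self, other: "TriggerSpan") -> bool:
        return self.token_start < other.token_end and other.token_start < self.token_end


@dataclass(frozen=True)
class EventTypeSchema:
    """Ordered set of event-type identifiers with display label words.

    Type identifiers use underscores (``Positive_Regulation``); ``label_words``
    holds the human-readable prompt form (``"Positive Regulation"``).
    """

    types: tuple[str, ...]
    label_words: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.types) < 1:
            raise SchemaError("schema needs at least one event type")
        if len(set(self.types)) != len(self.types):
            raise SchemaError("duplicate event type identifiers")
        words = dict(self.label_words)
        for t in self.types:
            words.setdefault(t, t.replace("_", " "))
        extra = set(words) - set(self.types)
        if extra:
            raise SchemaError(f"label words for unknown types: {sorted(extra)}")
        object.__setattr__(self, "types", tuple(self.types))
        object.__setattr__(self, "label_words", words)

    @property
    def k(self) -> int:
        return len(self.types)

    def __contains__(self, type_id: str) -> bool:
        return type_id in set(self.types)

    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "types": [
                {"id": t, "label": self.label_words[t]} for t in self.types
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EventTypeSchema":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "EventTypeSchema":
        entries = payload["types"]
        types = tuple(e["id"] for e in entries)
        words = {e["id"]: e.get("label", e["id"].replace("_", " ")) for e in entries}
        return cls(types=types, label_words=words, name=payload.get("name", ""))

    @classmethod
    def builtin(cls, name: str) -> "EventTypeSchema":
        """Load a shipped schema: ``"mlee"`` (19 types) or ``"genia"`` (9)."""
        ref = resources.files("biotrig").joinpath("schemas", f"{name.lower()}.yaml")
        try:
            text = ref.read_text(encoding="utf-8")
        except FileNotFoundError:
            raise SchemaError(f"no builtin schema named {name!r}") from None
        return cls._from_payload(yaml.safe_load(text))


@dataclass(frozen=True)
class BioTagset:
    """BIO tag vocabulary derived from a schema: ``O`` first, then B/I pairs.

    ``size`` is ``2k + 1`` where ``k`` is the number of event types.
    """

    schema: EventTypeSchema
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tags = [O_TAG]
        for t in self.schema.types:
            tags.extend((f"B-{t}", f"I-{t}"))
        object.__setattr__(self, "tags", tuple(tags))
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(tags)})

    @classmethod
    def from_schema(cls, schema: EventTypeSchema) -> "BioTagset":
        return cls(schema=schema)

    @property
    def size(self) -> int:
        return len(self.tags)

    def index(self, tag: str) -> int:
        try:
            return self._index[tag]
        except KeyError:
            raise SchemaError(f"unknown tag {tag!r}") from None

    def tag(self, index: int) -> str:
        return self.tags[index]

    def b(self, type_id: str) -> str:
        if type_id not in self.schema:
            raise SchemaError(f"unknown event type {type_id!r}")
        return f"B-{type_id}"

    def i(self, type_id: str) -> str:
        if type_id not in self.schema:
            raise SchemaError(f"unknown event type {type_id!r}")
        return f"I-{type_id}"

    def encode(self, tags: Sequence[str]) -> list[int]:
        return [self.index(t) for t in tags]

    def decode(self, indices: Sequence[int]) -> list[str]:
        return [self.tags[i] for i in indices]


def _tag_parts(tag: str) -> tuple[str, str | None]:
    if tag == O_TAG or tag in (START, STOP):
        return tag, None
    prefix, _, type_id = tag.partition("-")
    return prefix, type_id


def spans_to_tags(
    spans: Iterable[TriggerSpan], n: int, tagset: BioTagset
) -> list[str]:
    """Encode non-overlapping typed spans over ``n`` tokens as BIO tags.

    Raises :class:`SchemaError` on overlapping spans (BIO cannot represent
    overlap), out-of-range spans, or types missing from the schema.
    """
    spans = sorted(spans, key=lambda s: (s.token_start, s.token_end))
    tags = [O_TAG] * n
    prev: TriggerSpan | None = None
    for sp in spans:
        if sp.type not in tagset.schema:
            raise SchemaError(f"span type {sp.type!r} not in schema")
        if sp.token_end > n:
            raise SchemaError(f"span {sp} out of range for sentence length {n}")
        if prev is not None and prev.overlaps(sp):
            raise SchemaError(f"overlapping spans {prev} and {sp}")
        tags[sp.token_start] = tagset.b(sp.type)
        for i in range(sp.token_start + 1, sp.token_end):
            tags[i] = tagset.i(sp.type)
        prev = sp
    return tags


def tags_to_spans(tags: Sequence[str]) -> list[TriggerSpan]:
    """Decode a BIO tag sequence into typed spans.

    Ill-formed sequences are repaired, never rejected: a stray ``I-t``
    (sentence-initial, after ``O``, or after a different type) is treated as
    ``B-t`` ("begin-on-stray").  Output spans are always non-overlapping.
    """
    spans: list[TriggerSpan] = []
    start: int | None = None
    cur_type: str | None = None

    def flush(end: int) -> None:
        nonlocal start, cur_type
        if start is not None:
            spans.append(TriggerSpan(start, end, cur_type))
        start, cur_type = None, None

    for i, tag in enumerate(tags):
        prefix, type_id = _tag_parts(tag)
        if prefix == O_TAG:
            flush(i)
        elif prefix == "B":
            flush(i)
            start, cur_type = i, type_id
        elif prefix == "I":
            if cur_type != type_id:  # stray I: begin a new span here
                flush(i)
                start, cur_type = i, type_id
        else:
            raise SchemaError(f"unknown tag {tag!r}")
    flush(len(tags))
    return spans


def is_valid_transition(a: str, b: str, tagset: BioTagset) -> bool:
    """BIO transition validity: ``I-t`` may only follow ``B-t`` or ``I-t``.

    ``a`` may be the virtual ``START`` state and ``b`` the virtual ``STOP``
    state; all transitions into ``STOP`` are valid, and ``START -> I-t`` is
    not.
    """
    for tag, role in ((a, "from"), (b, "to")):
        if tag in (START, STOP):
            if (tag == START and role == "to") or (tag == STOP and role == "from"):
                raise SchemaError(f"virtual state {tag} cannot appear as {role!r}")
            continue
        tagset.index(tag)  # raises on unknown
    if b == STOP:
        return True
    b_prefix, b_type = _tag_parts(b)
    if b_prefix != "I":
        return True
    if a == START:
        return False
    a_prefix, a_type = _tag_parts(a)
    return a_prefix in ("B", "I") and a_type == b_type


def transition_mask(tagset: BioTagset):
    """Boolean matrix of *invalid* transitions over tags + START/STOP.

    Shape ``(size+2, size+2)`` with row/col ``size`` = START, ``size+1`` =
    STOP.  Entries into START, out of STOP, and the BIO-invalid pairs are
    marked True.
    """
    import numpy as np

    k = tagset.size
    invalid = np.zeros((k + 2, k + 2), dtype=bool)
    start, stop = k, k + 1
    labels = list(tagset.tags)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            invalid[i, j] = not is_valid_transition(a, b, tagset)
    for j, b in enumerate(labels):
        invalid[start, j] = not is_valid_transition(START, b, tagset)
    invalid[:, start] = True
    invalid[stop, :] = True
    return invalid
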