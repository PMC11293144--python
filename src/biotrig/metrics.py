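"""Span-level trigger evaluation: exact span + type match, micro or macro.

A predicted trigger counts as correct only when both its token span and its
event type match a gold trigger exactly — the strictest standard matching
rule.  Micro averaging pools TP/FP/FN globally; macro averaging takes the
unweighted mean of per-type F1 over the types present in gold (types never
seen in gold are excluded to avoid 0/0 artifacts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .schema import TriggerSpan


class EvalError(ValueError):
    pass


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return 100.0 * p, 100.0 * r, 100.0 * f1


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    averaging: str
    per_type: dict[str, dict[str, float]] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.averaging}: P={self.precision:.2f}% R={self.recall:.2f}% "
            f"F1={self.f1:.2f}% (TP={self.tp} FP={self.fp} FN={self.fn})"
        )


def evaluate(
    gold: Sequence[Sequence[TriggerSpan]],
    pred: Sequence[Sequence[TriggerSpan]],
    averaging: str = "micro",
) -> EvalReport:
    """Score sentence-aligned predictions against gold trigger spans."""
    if averaging not in ("micro", "macro"):
        raise EvalError(f"unknown averaging {averaging!r}")
    if len(gold) != len(pred):
        raise EvalError(
            f"gold has {len(gold)} sentences but predictions have {len(pred)}"
        )
    tp_t: Counter[str] = Counter()
    fp_t: Counter[str] = Counter()
    fn_t: Counter[str] = Counter()
    gold_types: set[str] = set()
    for g_spans, p_spans in zip(gold, pred):
        g = Counter((s.token_start, s.token_end, s.type) for s in g_spans)
        p = Counter((s.token_start, s.token_end, s.type) for s in p_spans)
        gold_types.update(t for _, _, t in g)
        for key in g | p:
            t = key[2]
            hit = min(g[key], p[key])
            tp_t[t] += hit
            fp_t[t] += p[key] - hit
            fn_t[t] += g[key] - hit
    tp, fp, fn = sum(tp_t.values()), sum(fp_t.values()), sum(fn_t.values())
    per_type = {}
    for t in sorted(set(tp_t) | set(fp_t) | set(fn_t) | gold_types):
        p_, r_, f_ = _prf(tp_t[t], fp_t[t], fn_t[t])
        per_type[t] = {
            "precision": p_, "recall": r_, "f1": f_,
            "tp": tp_t[t], "fp": fp_t[t], "fn": fn_t[t],
        }
    if averaging == "micro":
        precision, recall, f1 = _prf(tp, fp, fn)
    else:
        present = [t for t in per_type if t in gold_types]
        if present:
            precision = sum(per_type[t]["precision"] for t in present) / len(present)
            recall = sum(per_type[t]["recall"] for t in present) / len(present)
            f1 = sum(per_type[t]["f1"] for t in present) / len(present)
        else:
            precision = recall = f1 = 0.0
    return EvalReport(precision, recall, f1, tp, fp, fn, averaging, per_type)
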