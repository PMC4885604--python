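"""Scoring of predicted relations against gold annotations.

The protocol matches on span identity — concept boundaries are assumed
to be given — so a prediction is a true positive iff a gold relation has
the same (doc_id, subject span, object span, relation_type). Trigger
identity is not part of the match key. ``relaxed`` mode collapses the
three regulation polarities into one class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import Document
from .errors import EvaluationError
from .lexicon import (
    REGULATION_TYPES,
    Lexicon,
    PatternRule,
    RelationType,
    TriggerLexicon,
)
from .concept_recognition import ConceptMention
from .relation_extraction import RelationInstance, extract_relations


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    #: Names of ratios whose denominator was zero (reported as 0 by convention).
    zero_denominators: tuple[str, ...] = field(default=())

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalReport":
        zeros = []
        if tp + fp == 0:
            precision = 0.0
            zeros.append("precision")
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall = 0.0
            zeros.append("recall")
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f1 = 0.0
            zeros.append("f1")
        else:
            f1 = 2 * precision * recall / (precision + recall)
        return cls(tp, fp, fn, precision, recall, f1, tuple(zeros))

    def to_json_obj(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "zero_denominators": list(self.zero_denominators),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_obj(), indent=2) + "\n"

    def to_text(self) -> str:
        lines = [
            f"TP {self.tp}  FP {self.fp}  FN {self.fn}",
            f"precision {self.precision:.4f}  recall {self.recall:.4f}  "
            f"F1 {self.f1:.4f}",
        ]
        if self.zero_denominators:
            lines.append("zero denominators: " + ", ".join(self.zero_denominators))
        return "\n".join(lines) + "\n"


def _relation_key(r: RelationInstance, mode: str) -> tuple:
    rel = r.relation_type
    if mode == "relaxed" and rel in REGULATION_TYPES:
        rel_name = "regulation"
    else:
        rel_name = rel.value
    return (r.doc_id, r.subject.span, r.object.span, rel_name)


def evaluate_relations(
    gold: Sequence[RelationInstance],
    predicted: Sequence[RelationInstance],
    mode: str = "strict",
) -> EvalReport:
    """Score ``predicted`` against ``gold``.

    Each gold relation matches at most one prediction (greedy in document
    order). Duplicate gold keys raise :class:`EvaluationError`.
    """
    if mode not in {"strict", "relaxed"}:
        raise EvaluationError(f"unknown mode {mode!r}")
    gold_keys: dict[tuple, int] = {}
    for g in gold:
        key = _relation_key(g, "strict")
        if key in gold_keys:
            raise EvaluationError(f"duplicate gold relation {key}")
        gold_keys[key] = 1
    unmatched = {_relation_key(g, mode) for g in gold}
    if len(unmatched) != len(gold):
        # distinct under strict keys but colliding after relaxation
        raise EvaluationError("duplicate gold relation under relaxed matching")

    tp = 0
    fp = 0
    for p in predicted:
        key = _relation_key(p, mode)
        if key in unmatched:
            unmatched.remove(key)
            tp += 1
        else:
            fp += 1
    fn = len(unmatched)
    return EvalReport.from_counts(tp, fp, fn)


def evaluate_with_gold_boundaries(
    document: Document,
    gold_mentions: Sequence[ConceptMention],
    gold_relations: Sequence[RelationInstance],
    triggers: TriggerLexicon,
    rules: Sequence[PatternRule],
    mode: str = "strict",
    lexicon: Lexicon | None = None,
) -> EvalReport:
    """Run extraction with gold concept boundaries and score the output.

    Concept recognition is skipped entirely; the gold mentions are
    substituted for NER output before tagging and pattern matching.
    """
    doc_mentions = [m for m in gold_mentions if m.doc_id == document.doc_id]
    predicted = extract_relations(
        document,
        lexicon if lexicon is not None else Lexicon(),
        triggers,
        rules,
        mentions=doc_mentions,
    )
    doc_gold = [r for r in gold_relations if r.doc_id == document.doc_id]
    return evaluate_relations(doc_gold, predicted, mode=mode)
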