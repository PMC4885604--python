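"""Slot tagging and pattern-rule matching over tagged sentences.

A sentence is tokenized, concept mentions are collapsed to single tagged
tokens, remaining tokens are matched against the trigger lexicon by
lemma, and pattern rules are applied: a rule matches when its slot tags
occur in order with at most ``max_gap`` PLAIN tokens between consecutive
slots (tagged tokens may never be skipped).

Known limitation: negation scope is not handled — a PLAIN "not" inside a
gap does not block a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .concept_recognition import ConceptMention, recognize_sentence
from .corpus_io import Document, Sentence
from .errors import ExtractionError
from .lexicon import (
    CONCEPT_TAGS,
    PLAIN_TAG,
    TRIGGER_TAGS,
    ConceptType,
    Lexicon,
    PatternRule,
    RelationType,
    TriggerEntry,
    TriggerLexicon,
    tokenize,
)


@dataclass(frozen=True)
class TaggedToken:
    """A token (or collapsed mention span) with its slot tag.

    ``tag`` is a concept-type name (``"Gene"`` …), a trigger-class name
    (``"POSITIVE_REG"`` …) or ``"PLAIN"``.
    """

    token_index: int
    char_start: int
    char_end: int
    surface: str
    tag: str
    mention: ConceptMention | None = None
    trigger: TriggerEntry | None = None


@dataclass(frozen=True)
class RelationInstance:
    """A binary relation with sentence-level provenance."""

    doc_id: str
    sentence_index: int
    subject: ConceptMention
    object: ConceptMention
    trigger: TaggedToken
    relation_type: RelationType
    rule_id: str
    supporting_sentence_text: str

    def __post_init__(self) -> None:
        if self.subject.span == self.object.span:
            raise ExtractionError("relation subject and object coincide")
        if not (self.subject.sentence_index == self.object.sentence_index == self.sentence_index):
            raise ExtractionError("relation participants span multiple sentences")
        if self.relation_type is RelationType.METASTASIS:
            if self.subject.concept_type is not ConceptType.NEOPLASMS:
                raise ExtractionError(
                    "metastasis relation requires a Neoplasms subject, got "
                    f"{self.subject.concept_type.value}"
                )
            if self.object.concept_type not in (ConceptType.TISSUES, ConceptType.ORGAN):
                raise ExtractionError(
                    "metastasis relation requires a Tissues/Organ object, got "
                    f"{self.object.concept_type.value}"
                )

    def match_key(self) -> tuple:
        """Identity for duplicate collapsing and strict evaluation."""
        return (
            self.doc_id,
            self.subject.span,
            self.object.span,
            self.trigger.char_start,
            self.trigger.char_end,
            self.relation_type,
        )


def tag_sentence(
    sentence: Sentence,
    mentions: Sequence[ConceptMention],
    triggers: TriggerLexicon,
) -> list[TaggedToken]:
    """Tokenize a sentence and assign slot tags.

    Mentions must be non-overlapping and lie within the sentence; each
    collapses to one tagged token covering its full span.
    """
    for m in mentions:
        if m.char_start < sentence.char_start or m.char_end > sentence.char_end:
            raise ExtractionError(
                f"mention {m.surface!r} [{m.char_start},{m.char_end}) outside "
                f"sentence {sentence.index} [{sentence.char_start},{sentence.char_end})"
            )
    ordered = sorted(mentions, key=lambda m: m.char_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.char_end > b.char_start:
            raise ExtractionError(f"overlapping mentions {a.surface!r} / {b.surface!r}")

    tokens = tokenize(sentence.text)
    tagged: list[TaggedToken] = []
    i = 0
    m_idx = 0
    while i < len(tokens):
        start, end, surface = tokens[i]
        doc_start = sentence.char_start + start
        # advance mention pointer past mentions that ended before this token
        while m_idx < len(ordered) and ordered[m_idx].char_end <= doc_start:
            m_idx += 1
        if m_idx < len(ordered) and ordered[m_idx].char_start < sentence.char_start + end:
            mention = ordered[m_idx]
            # consume every token the mention covers
            j = i
            while j < len(tokens) and sentence.char_start + tokens[j][0] < mention.char_end:
                j += 1
            tagged.append(
                TaggedToken(
                    token_index=len(tagged),
                    char_start=mention.char_start,
                    char_end=mention.char_end,
                    surface=mention.surface,
                    tag=mention.concept_type.value,
                    mention=mention,
                )
            )
            i = j
            m_idx += 1
            continue
        entry = triggers.match(surface)
        if entry is not None:
            tagged.append(
                TaggedToken(
                    token_index=len(tagged),
                    char_start=doc_start,
                    char_end=sentence.char_start + end,
                    surface=surface,
                    tag=entry.trigger_class.value,
                    trigger=entry,
                )
            )
        else:
            tagged.append(
                TaggedToken(
                    token_index=len(tagged),
                    char_start=doc_start,
                    char_end=sentence.char_start + end,
                    surface=surface,
                    tag=PLAIN_TAG,
                )
            )
        i += 1
    return tagged


def tag_matches(slot_tag: str, token_tag: str) -> bool:
    """Whether a rule slot tag accepts a token tag."""
    if slot_tag in TRIGGER_TAGS:
        return slot_tag == token_tag
    accepted = CONCEPT_TAGS[slot_tag]
    try:
        return ConceptType(token_tag) in accepted
    except ValueError:
        return False


def find_matches(tags: Sequence[str], rule: PatternRule) -> list[tuple[int, ...]]:
    """All slot-to-position assignments of ``rule`` over a tag sequence.

    Positions are strictly increasing; between consecutive slot positions
    every intermediate token must be PLAIN and there may be at most
    ``rule.max_gap`` of them.
    """
    n = len(tags)
    results: list[tuple[int, ...]] = []

    def extend(slot: int, prev_pos: int, chosen: tuple[int, ...]) -> None:
        if slot == len(rule.slots):
            results.append(chosen)
            return
        lo = 0 if prev_pos < 0 else prev_pos + 1
        for pos in range(lo, n):
            if prev_pos >= 0:
                gap = pos - prev_pos - 1
                if gap > rule.max_gap:
                    break
                if any(tags[k] != PLAIN_TAG for k in range(prev_pos + 1, pos)):
                    break
            if tag_matches(rule.slots[slot], tags[pos]):
                extend(slot + 1, pos, chosen + (pos,))
            # a non-PLAIN token at `pos` that does not match the slot blocks
            # any later position for this slot — handled by the loop guard
            # above on the next iteration.
        return

    extend(0, -1, ())
    return results


def match_patterns(
    tagged: Sequence[TaggedToken],
    rules: Sequence[PatternRule],
    *,
    doc_id: str = "",
    sentence_index: int = 0,
    sentence_text: str = "",
) -> list[RelationInstance]:
    """Apply pattern rules to a tagged sentence.

    Duplicates (same subject/object/trigger spans and relation type) are
    collapsed keeping the first rule in file order; output is ordered by
    (rule order, leftmost slot position).
    """
    tags = [t.tag for t in tagged]
    out: list[RelationInstance] = []
    seen: set[tuple] = set()
    for rule in rules:
        for positions in sorted(find_matches(tags, rule), key=lambda p: (min(p), p)):
            subj_tok = tagged[positions[rule.subject_slot]]
            obj_tok = tagged[positions[rule.object_slot]]
            trig_tok = tagged[positions[rule.trigger_slot]]
            if subj_tok.mention is None or obj_tok.mention is None:
                raise ExtractionError(
                    f"rule {rule.rule_id}: matched concept slot without a mention"
                )
            relation = RelationInstance(
                doc_id=doc_id,
                sentence_index=sentence_index,
                subject=subj_tok.mention,
                object=obj_tok.mention,
                trigger=trig_tok,
                relation_type=rule.relation_type,
                rule_id=rule.rule_id,
                supporting_sentence_text=sentence_text,
            )
            key = relation.match_key()
            if key in seen:
                continue
            seen.add(key)
            out.append(relation)
    return out


def extract_relations(
    document: Document,
    lexicon: Lexicon,
    triggers: TriggerLexicon,
    rules: Sequence[PatternRule],
    mentions: Iterable[ConceptMention] | None = None,
) -> list[RelationInstance]:
    """Full per-document pipeline: recognize → tag → match, per sentence.

    When ``mentions`` is given (e.g. gold boundaries), recognition is
    skipped and those mentions are used instead.
    """
    given: dict[int, list[ConceptMention]] | None = None
    if mentions is not None:
        given = {}
        for m in mentions:
            given.setdefault(m.sentence_index, []).append(m)

    relations: list[RelationInstance] = []
    for sentence in document.sentences:
        if given is None:
            sent_mentions = recognize_sentence(document.doc_id, sentence, lexicon)
        else:
            sent_mentions = given.get(sentence.index, [])
        tagged = tag_sentence(sentence, sent_mentions, triggers)
        relations.extend(
            match_patterns(
                tagged,
                rules,
                doc_id=document.doc_id,
                sentence_index=sentence.index,
                sentence_text=sentence.text,
            )
        )
    return relations
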