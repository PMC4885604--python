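"""Sentence segmentation and concept mention recognition.

Recognition combines a dictionary longest-match scan (token-boundary
anchored, left to right, longer match wins) with a rule-based microRNA
name recognizer. Overlaps between the two are resolved in favour of the
more specific microRNA rule. Mentions never cross sentence boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus_io import Document, Sentence
from .errors import ExtractionError
from .lexicon import (
    UNNORMALIZED,
    ConceptType,
    Lexicon,
    fold_text,
    tokenize,
)

#: Trailing abbreviations that must not terminate a sentence.
ABBREVIATIONS = (
    "et al.", "Fig.", "Figs.", "vs.", "e.g.", "i.e.", "Dr.", "etc.",
    "cf.", "No.", "ca.", "approx.", "resp.", "ref.", "Refs.",
)

_SPLIT_RE = re.compile(r"[.!?](?=\s+[A-Z0-9])")


def split_sentences(text: str) -> list[Sentence]:
    """Split at terminal punctuation followed by whitespace and an
    uppercase letter or digit, guarding a fixed abbreviation list."""
    boundaries: list[int] = []
    for m in _SPLIT_RE.finditer(text):
        end = m.end()  # position just past the punctuation mark
        prefix = text[:end]
        if any(prefix.endswith(abbr) for abbr in ABBREVIATIONS):
            continue
        boundaries.append(end)
    boundaries.append(len(text))

    sentences: list[Sentence] = []
    cursor = 0
    for boundary in boundaries:
        chunk = text[cursor:boundary]
        stripped = chunk.strip()
        if stripped:
            start = cursor + chunk.index(stripped[0])
            # locate the stripped span precisely
            lead = len(chunk) - len(chunk.lstrip())
            trail = len(chunk) - len(chunk.rstrip())
            start = cursor + lead
            end = boundary - trail
            sentences.append(
                Sentence(index=len(sentences), char_start=start, char_end=end,
                         text=text[start:end])
            )
        cursor = boundary
    return sentences


@dataclass(frozen=True)
class ConceptMention:
    """A typed, normalized text span in document coordinates."""

    doc_id: str
    sentence_index: int
    char_start: int
    char_end: int
    surface: str
    concept_type: ConceptType
    normalized_id: str = UNNORMALIZED
    provenance: str = "dictionary"
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ExtractionError(
                f"mention {self.surface!r}: empty span [{self.char_start}, {self.char_end})"
            )
        if self.provenance not in {"dictionary", "mirna_rule", "gold"}:
            raise ExtractionError(f"invalid provenance {self.provenance!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.char_start, self.char_end)

    def overlaps(self, other: "ConceptMention") -> bool:
        return self.char_start < other.char_end and other.char_start < self.char_end


def _only_whitespace_between(text: str, a_end: int, b_start: int) -> bool:
    return text[a_end:b_start].strip() == ""


def recognize_dictionary(
    doc_id: str, sentence: Sentence, lexicon: Lexicon
) -> list[ConceptMention]:
    """Dictionary longest-match scan over one sentence.

    Matches are anchored at token boundaries; multi-token entries require
    only whitespace between their tokens. On overlap the longer (and then
    earlier-in-lexicon) match wins, implemented by the greedy left-to-right
    longest-first scan.
    """
    tokens = tokenize(sentence.text)
    mentions: list[ConceptMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        max_n = min(lexicon.max_tokens, len(tokens) - i)
        for n in range(max_n, 0, -1):
            window = tokens[i:i + n]
            if any(
                not _only_whitespace_between(sentence.text, window[k][1], window[k + 1][0])
                for k in range(n - 1)
            ):
                continue
            start, end = window[0][0], window[-1][1]
            surface = sentence.text[start:end]
            entry, ambiguous = lexicon.lookup(surface)
            if entry is None:
                continue
            flags = ("ambiguous",) if ambiguous else ()
            mentions.append(
                ConceptMention(
                    doc_id=doc_id,
                    sentence_index=sentence.index,
                    char_start=sentence.char_start + start,
                    char_end=sentence.char_start + end,
                    surface=surface,
                    concept_type=entry.concept_type,
                    normalized_id=entry.normalized_id,
                    provenance="dictionary",
                    flags=flags,
                )
            )
            i += n
            matched = True
            break
        if not matched:
            i += 1
    return mentions


#: microRNA name shapes: miR-181a, miR-200b/200c, let-7a, microRNA-21,
#: miR-34 star / miR-34*. Token-anchored to block substring hits.
MIRNA_RE = re.compile(
    r"(?<![^\W_])"                 # no word character immediately before
    r"(?:miR|microRNA|miRNA|mir|let)"
    r"[-‐ ]?\d+[a-z]?"
    r"(?:[-/]\d+[a-z]?)*"
    r"(?:\*| star)?"
    r"(?!\w)",
    re.IGNORECASE,
)


def recognize_mirna(
    doc_id: str, sentence: Sentence, lexicon: Lexicon | None = None
) -> list[ConceptMention]:
    """Rule-based microRNA recognizer.

    The normalized ID is looked up in the lexicon when the surface is
    present there; otherwise the mention stays UNNORMALIZED.
    """
    mentions: list[ConceptMention] = []
    for m in MIRNA_RE.finditer(sentence.text):
        # reject matches whose preceding char is a hyphen joined to a word
        # (e.g. "pre-miR-21" keeps the full token out of scope here)
        if m.start() > 0 and sentence.text[m.start() - 1] in "-‐":
            continue
        surface = m.group()
        normalized_id = UNNORMALIZED
        flags: tuple[str, ...] = ()
        if lexicon is not None:
            entry, ambiguous = lexicon.lookup(surface)
            if entry is not None and entry.concept_type is ConceptType.MICRO_RNA:
                normalized_id = entry.normalized_id
                if ambiguous:
                    flags = ("ambiguous",)
        mentions.append(
            ConceptMention(
                doc_id=doc_id,
                sentence_index=sentence.index,
                char_start=sentence.char_start + m.start(),
                char_end=sentence.char_start + m.end(),
                surface=surface,
                concept_type=ConceptType.MICRO_RNA,
                normalized_id=normalized_id,
                provenance="mirna_rule",
            )
        )
    return mentions


def resolve_conflicts(
    dictionary_mentions: list[ConceptMention],
    mirna_mentions: list[ConceptMention],
) -> list[ConceptMention]:
    """Union both recognizers' output with overlap resolution.

    The microRNA rule beats the dictionary on overlap (it is the more
    specific recognizer); among microRNA candidates the longer, then
    leftmost, match wins. Output is sorted by start offset.
    """
    kept_mirna: list[ConceptMention] = []
    for cand in sorted(mirna_mentions, key=lambda m: (-(m.char_end - m.char_start), m.char_start)):
        if not any(cand.overlaps(k) for k in kept_mirna):
            kept_mirna.append(cand)
    kept = list(kept_mirna)
    for cand in dictionary_mentions:
        if not any(cand.overlaps(k) for k in kept_mirna):
            kept.append(cand)
    kept.sort(key=lambda m: (m.char_start, m.char_end))
    return kept


def recognize_sentence(
    doc_id: str, sentence: Sentence, lexicon: Lexicon
) -> list[ConceptMention]:
    return resolve_conflicts(
        recognize_dictionary(doc_id, sentence, lexicon),
        recognize_mirna(doc_id, sentence, lexicon),
    )


def recognize_document(document: Document, lexicon: Lexicon) -> list[ConceptMention]:
    mentions: list[ConceptMention] = []
    for sentence in document.sentences:
        mentions.extend(recognize_sentence(document.doc_id, sentence, lexicon))
    return mentions
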