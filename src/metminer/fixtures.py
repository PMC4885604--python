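"""Synthetic abstracts with planted gold mentions and relations.

Templates carry typed placeholders (``{Gene:1}``, ``{POS}``, …) whose
fillers are drawn uniformly (seeded) from the bundled lexicons, so the
generated corpora exercise both recognition and extraction with exact
gold character offsets. Covered templates instantiate bundled pattern
rules; uncovered (distractor) templates contain concepts but no trigger
and therefore plant no relations.

Regeneration with the same seed and parameters is byte-identical.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import yaml

from .concept_recognition import ConceptMention, split_sentences
from .corpus_io import Document
from .errors import FixtureError
from .lexicon import (
    ConceptType,
    Lexicon,
    PatternRule,
    TriggerClass,
    TriggerLexicon,
    default_templates_path,
)
from .relation_extraction import RelationInstance, tag_sentence

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z]+)(?::(\d+))?\}")

_TRIGGER_PLACEHOLDERS = {
    "POS": TriggerClass.POSITIVE_REG,
    "NEG": TriggerClass.NEGATIVE_REG,
    "NEU": TriggerClass.NEUTRAL_REG,
    "MET": TriggerClass.METASTASIS_TRIGGER,
}


@dataclass(frozen=True)
class SentenceTemplate:
    template_id: str
    text: str
    covered: bool
    n_sentences: int
    #: [subject, trigger, object] occurrence indices (text order) per relation.
    relations: tuple[tuple[int, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        occurrences = _PLACEHOLDER_RE.findall(self.text)
        if not occurrences and self.relations:
            raise FixtureError(f"template {self.template_id}: relations without placeholders")
        for name, _ in occurrences:
            if name not in _TRIGGER_PLACEHOLDERS and name not in ConceptType._value2member_map_:
                raise FixtureError(
                    f"template {self.template_id}: unknown placeholder {{{name}}}"
                )
        for rel in self.relations:
            if len(rel) != 3:
                raise FixtureError(f"template {self.template_id}: malformed relation spec")
            for idx in rel:
                if not 0 <= idx < len(occurrences):
                    raise FixtureError(
                        f"template {self.template_id}: occurrence index {idx} out of range"
                    )
            if occurrences[rel[1]][0] not in _TRIGGER_PLACEHOLDERS:
                raise FixtureError(
                    f"template {self.template_id}: relation trigger occurrence "
                    f"{rel[1]} is not a trigger placeholder"
                )


def load_templates(source: str | Path | IO[str] | None = None) -> list[SentenceTemplate]:
    if source is None:
        source = default_templates_path()
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    if isinstance(data, dict):
        data = data.get("templates", [])
    templates = []
    for item in data:
        templates.append(
            SentenceTemplate(
                template_id=str(item["template_id"]),
                text=str(item["text"]),
                covered=bool(item["covered"]),
                n_sentences=int(item.get("n_sentences", 1)),
                relations=tuple(tuple(int(i) for i in rel) for rel in item.get("relations", [])),
            )
        )
    return templates


def _inflect(verb: str) -> str:
    """Third-person singular inflection for trigger lemmas."""
    if re.search(r"(s|x|z|ch|sh)$", verb):
        return verb + "es"
    return verb + "s"


def _fill_template(
    template: SentenceTemplate,
    rng: random.Random,
    lexicon: Lexicon,
    triggers: TriggerLexicon,
) -> tuple[str, list[dict]]:
    """Instantiate one template; returns (text, occurrence records)."""
    fillers: dict[tuple[str, str], object] = {}
    used_surfaces: dict[str, set[str]] = {}

    def filler_for(name: str, variant: str):
        key = (name, variant)
        if key in fillers:
            return fillers[key]
        if name in _TRIGGER_PLACEHOLDERS:
            pool = triggers.entries_of_class(_TRIGGER_PLACEHOLDERS[name])
            if not pool:
                raise FixtureError(f"no triggers of class {name}")
            fillers[key] = rng.choice(pool)
            return fillers[key]
        concept_type = ConceptType(name)
        pool = lexicon.entries_of_type(concept_type)
        if not pool:
            raise FixtureError(f"no lexicon entries of type {name}")
        taken = used_surfaces.setdefault(name, set())
        fresh = [e for e in pool if e.surface not in taken]
        entry = rng.choice(fresh if fresh else pool)
        taken.add(entry.surface)
        fillers[key] = entry
        return entry

    parts: list[str] = []
    occurrences: list[dict] = []
    cursor = 0
    pos = 0
    for m in _PLACEHOLDER_RE.finditer(template.text):
        parts.append(template.text[cursor:m.start()])
        pos += m.start() - cursor
        name, variant = m.group(1), m.group(2) or ""
        filler = filler_for(name, variant)
        if name in _TRIGGER_PLACEHOLDERS:
            surface = _inflect(filler.surface_form)
            occurrences.append(
                {"kind": "trigger", "entry": filler, "start": pos, "end": pos + len(surface)}
            )
        else:
            surface = filler.surface
            occurrences.append(
                {"kind": "concept", "entry": filler, "start": pos, "end": pos + len(surface)}
            )
        parts.append(surface)
        pos += len(surface)
        cursor = m.end()
    parts.append(template.text[cursor:])
    return "".join(parts), occurrences


def generate_abstract(
    seed: int,
    templates: Sequence[SentenceTemplate],
    lexicon: Lexicon,
    triggers: TriggerLexicon,
    n_sentences: int,
    distractor_fraction: float = 0.0,
    doc_id: str | None = None,
) -> tuple[Document, list[ConceptMention], list[RelationInstance]]:
    """Generate one abstract with exact gold offsets.

    Template units are sampled until ``n_sentences`` sentences are
    produced; each unit is a distractor (uncovered template) with
    probability ``distractor_fraction``.
    """
    rng = random.Random(seed)
    if doc_id is None:
        doc_id = f"SYN-{seed}"
    covered = [t for t in templates if t.covered]
    uncovered = [t for t in templates if not t.covered]
    if not covered and distractor_fraction < 1.0:
        raise FixtureError("no covered templates available")
    if not uncovered and distractor_fraction > 0.0:
        raise FixtureError("distractor_fraction > 0 but no uncovered templates")

    pieces: list[tuple[str, SentenceTemplate, list[dict]]] = []
    budget = n_sentences
    while budget > 0:
        use_distractor = uncovered and rng.random() < distractor_fraction
        pool = uncovered if use_distractor else covered
        pool = [t for t in pool if t.n_sentences <= budget]
        if not pool:
            pool = [t for t in (uncovered if use_distractor else covered) if t.n_sentences == 1]
            if not pool:
                raise FixtureError("no template fits the remaining sentence budget")
        template = rng.choice(pool)
        text, occurrences = _fill_template(template, rng, lexicon, triggers)
        pieces.append((text, template, occurrences))
        budget -= template.n_sentences

    abstract_parts: list[str] = []
    offset = 0
    all_records: list[tuple[SentenceTemplate, list[dict]]] = []
    for text, template, occurrences in pieces:
        if abstract_parts:
            abstract_parts.append(" ")
            offset += 1
        for occ in occurrences:
            occ["start"] += offset
            occ["end"] += offset
        abstract_parts.append(text)
        offset += len(text)
        all_records.append((template, occurrences))
    abstract_text = "".join(abstract_parts)

    sentences = tuple(split_sentences(abstract_text))
    document = Document(
        doc_id=doc_id,
        title=f"Synthetic abstract {doc_id}",
        abstract_text=abstract_text,
        sentences=sentences,
    )

    def sentence_for(start: int) -> int:
        for s in sentences:
            if s.char_start <= start < s.char_end:
                return s.index
        raise FixtureError(f"offset {start} outside all sentences")

    gold_mentions: list[ConceptMention] = []
    mention_by_occ: dict[int, ConceptMention] = {}
    occ_counter = 0
    for template, occurrences in all_records:
        for occ in occurrences:
            if occ["kind"] == "concept":
                entry = occ["entry"]
                surface = abstract_text[occ["start"]:occ["end"]]
                if surface != entry.surface:
                    raise FixtureError(
                        f"{doc_id}: gold offset drift for {entry.surface!r}"
                    )
                mention = ConceptMention(
                    doc_id=doc_id,
                    sentence_index=sentence_for(occ["start"]),
                    char_start=occ["start"],
                    char_end=occ["end"],
                    surface=surface,
                    concept_type=entry.concept_type,
                    normalized_id=entry.normalized_id,
                    provenance="gold",
                )
                gold_mentions.append(mention)
                mention_by_occ[occ_counter] = mention
            occ_counter += 1

    gold_relations: list[RelationInstance] = []
    occ_base = 0
    for template, occurrences in all_records:
        for subj_i, trig_i, obj_i in template.relations:
            subject = mention_by_occ[occ_base + subj_i]
            obj = mention_by_occ[occ_base + obj_i]
            trig_occ = occurrences[trig_i]
            trigger_entry = trig_occ["entry"]
            sent_idx = sentence_for(trig_occ["start"])
            sentence = sentences[sent_idx]
            sent_mentions = [m for m in gold_mentions if m.sentence_index == sent_idx]
            tagged = tag_sentence(sentence, sent_mentions, triggers)
            trigger_token = next(
                t for t in tagged
                if t.char_start == trig_occ["start"] and t.char_end == trig_occ["end"]
            )
            gold_relations.append(
                RelationInstance(
                    doc_id=doc_id,
                    sentence_index=sent_idx,
                    subject=subject,
                    object=obj,
                    trigger=trigger_token,
                    relation_type=trigger_entry.relation_type,
                    rule_id=f"gold:{template.template_id}",
                    supporting_sentence_text=sentence.text,
                )
            )
        occ_base += len(occurrences)

    return document, gold_mentions, gold_relations


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    gold_mentions: list[ConceptMention]
    gold_relations: list[RelationInstance]
    params: dict


def generate_corpus(
    n_docs: int,
    seed: int,
    templates: Sequence[SentenceTemplate] | None = None,
    lexicon: Lexicon | None = None,
    triggers: TriggerLexicon | None = None,
    sentences_per_doc: int = 5,
    distractor_fraction: float = 0.0,
) -> SyntheticCorpus:
    """Generate a corpus of independent abstracts (per-doc seed = seed + index)."""
    from .lexicon import load_default_lexicon, load_default_triggers

    if templates is None:
        templates = load_templates()
    if lexicon is None:
        lexicon = load_default_lexicon()
    if triggers is None:
        triggers = load_default_triggers()

    corpus = SyntheticCorpus(
        documents=[],
        gold_mentions=[],
        gold_relations=[],
        params={
            "n_docs": n_docs,
            "seed": seed,
            "sentences_per_doc": sentences_per_doc,
            "distractor_fraction": distractor_fraction,
        },
    )
    for i in range(n_docs):
        doc, mentions, relations = generate_abstract(
            seed=seed + i,
            templates=templates,
            lexicon=lexicon,
            triggers=triggers,
            n_sentences=sentences_per_doc,
            distractor_fraction=distractor_fraction,
            doc_id=f"SYN-{seed}-{i:04d}",
        )
        corpus.documents.append(doc)
        corpus.gold_mentions.extend(mentions)
        corpus.gold_relations.extend(relations)
    return corpus
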