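"""Corpus input/output: plain-text abstracts, BioC XML, curation tables.

Internal coordinates are 0-based, half-open, character offsets into the
abstract text. BioC's ``offset``/``length`` locations are converted at
the boundary. The title is stored on the document but is not part of the
mined abstract text; in BioC it is written as its own passage.

BioC infon keys used by this package (documented format reference):

* annotation: ``type`` (concept type name), ``identifier`` (normalized
  ID or ``UNNORMALIZED``), ``provenance``, ``sentence_index``, ``flags``
  (comma-joined, optional)
* relation: ``relation_type``, ``rule_id``, ``sentence_index``,
  ``trigger_surface``, ``trigger_start``, ``trigger_end``,
  ``trigger_tag``, ``trigger_lemma``, ``trigger_token_index``
* abstract passage: ``type=abstract``, ``sentence_offsets`` (space-joined
  ``start:end`` document-relative sentence spans)
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, TYPE_CHECKING, Iterable, Sequence

from .errors import BioCError, DocumentError
from .lexicon import ConceptType, RelationType, TriggerClass, TriggerEntry, UNNORMALIZED

if TYPE_CHECKING:  # pragma: no cover - type-only imports avoid a cycle
    from .concept_recognition import ConceptMention
    from .relation_extraction import RelationInstance


@dataclass(frozen=True)
class Sentence:
    """A sentence span within an abstract."""

    index: int
    char_start: int
    char_end: int
    text: str

    def __post_init__(self) -> None:
        if self.index < 0:
            raise DocumentError(f"negative sentence index {self.index}")
        if not self.char_start < self.char_end:
            raise DocumentError(
                f"sentence {self.index}: empty or inverted span "
                f"[{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class Document:
    """One abstract with identifier, title and sentence geometry."""

    doc_id: str
    title: str
    abstract_text: str
    sentences: tuple[Sentence, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for i, sent in enumerate(self.sentences):
            if sent.index != i:
                raise DocumentError(f"{self.doc_id}: sentence indices not consecutive")
            if sent.char_start < prev_end:
                raise DocumentError(f"{self.doc_id}: overlapping sentences at {i}")
            if sent.char_end > len(self.abstract_text):
                raise DocumentError(f"{self.doc_id}: sentence {i} beyond text end")
            if self.abstract_text[sent.char_start:sent.char_end] != sent.text:
                raise DocumentError(f"{self.doc_id}: sentence {i} text/span mismatch")
            prev_end = sent.char_end

    def sentence_at(self, index: int) -> Sentence:
        return self.sentences[index]


def read_plain(text: str, doc_id: str, title: str = "") -> Document:
    """Build a :class:`Document` from raw abstract text.

    Sentences are segmented with :func:`metminer.concept_recognition.split_sentences`.
    """
    from .concept_recognition import split_sentences

    if not text.strip():
        raise DocumentError(f"{doc_id}: no content")
    sentences = tuple(split_sentences(text))
    return Document(doc_id=doc_id, title=title, abstract_text=text, sentences=sentences)


def read_plain_file(path: str | Path) -> Document:
    """Read a plain-text abstract file: line 1 doc_id, line 2 title, rest body."""
    raw = Path(path).read_text(encoding="utf-8")
    lines = raw.split("\n")
    if len(lines) < 3 or not lines[0].strip():
        raise DocumentError(f"{path}: expected doc_id, title and abstract lines")
    doc_id = lines[0].strip()
    title = lines[1].strip()
    body = "\n".join(lines[2:]).strip()
    return read_plain(body, doc_id, title=title)


def write_plain(document: Document) -> str:
    return f"{document.doc_id}\n{document.title}\n{document.abstract_text}\n"


# ---------------------------------------------------------------------------
# BioC XML


@dataclass
class BioCCollection:
    """Result of :func:`read_bioc`; iterable as (documents, mentions, relations)."""

    documents: list["Document"] = field(default_factory=list)
    mentions: list["ConceptMention"] = field(default_factory=list)
    relations: list["RelationInstance"] = field(default_factory=list)
    #: Annotations whose concept-type infon is not one of the nine types;
    #: preserved as raw dicts and flagged rather than silently dropped.
    unknown_annotations: list[dict] = field(default_factory=list)

    def __iter__(self):
        return iter((self.documents, self.mentions, self.relations))


def _infon(parent: ET.Element, key: str, value: str) -> None:
    el = ET.SubElement(parent, "infon", key=key)
    el.text = value


def _infons(el: ET.Element) -> dict[str, str]:
    return {i.get("key", ""): (i.text or "") for i in el.findall("infon")}


def _mention_key(m: "ConceptMention") -> tuple:
    return (m.doc_id, m.char_start, m.char_end, m.concept_type, m.normalized_id, m.provenance)


def write_bioc(
    documents: Sequence[Document],
    mentions: Sequence["ConceptMention"] = (),
    relations: Sequence["RelationInstance"] = (),
    stream: IO[str] | None = None,
) -> str | None:
    """Serialize a corpus to BioC XML.

    Output ordering is deterministic: documents by doc_id, annotations by
    offset. Raises :class:`BioCError` on dangling references.
    """
    doc_by_id = {}
    for doc in documents:
        if doc.doc_id in doc_by_id:
            raise BioCError(f"duplicate doc_id {doc.doc_id!r}")
        doc_by_id[doc.doc_id] = doc

    mentions_by_doc: dict[str, list] = {d: [] for d in doc_by_id}
    for m in mentions:
        if m.doc_id not in doc_by_id:
            raise BioCError(f"mention {m.surface!r} references unknown document {m.doc_id!r}")
        mentions_by_doc[m.doc_id].append(m)

    relations_by_doc: dict[str, list] = {d: [] for d in doc_by_id}
    for r in relations:
        if r.doc_id not in doc_by_id:
            raise BioCError(f"relation {r.rule_id!r} references unknown document {r.doc_id!r}")
        relations_by_doc[r.doc_id].append(r)

    root = ET.Element("collection")
    ET.SubElement(root, "source").text = "metminer"
    ET.SubElement(root, "date").text = ""
    ET.SubElement(root, "key").text = "metminer.key"

    for doc_id in sorted(doc_by_id):
        doc = doc_by_id[doc_id]
        doc_el = ET.SubElement(root, "document")
        ET.SubElement(doc_el, "id").text = doc_id

        abstract_offset = 0
        if doc.title:
            title_el = ET.SubElement(doc_el, "passage")
            _infon(title_el, "type", "title")
            ET.SubElement(title_el, "offset").text = "0"
            ET.SubElement(title_el, "text").text = doc.title
            abstract_offset = len(doc.title) + 1

        passage_el = ET.SubElement(doc_el, "passage")
        _infon(passage_el, "type", "abstract")
        _infon(
            passage_el,
            "sentence_offsets",
            " ".join(f"{s.char_start}:{s.char_end}" for s in doc.sentences),
        )
        ET.SubElement(passage_el, "offset").text = str(abstract_offset)
        ET.SubElement(passage_el, "text").text = doc.abstract_text

        doc_mentions = sorted(
            mentions_by_doc[doc_id],
            key=lambda m: (m.char_start, m.char_end, m.concept_type.value, m.normalized_id),
        )
        ann_ids: dict[tuple, str] = {}
        for i, m in enumerate(doc_mentions):
            ann_id = f"{doc_id}.M{i}"
            ann_ids.setdefault(_mention_key(m), ann_id)
            ann_el = ET.SubElement(passage_el, "annotation", id=ann_id)
            _infon(ann_el, "type", m.concept_type.value)
            _infon(ann_el, "identifier", m.normalized_id)
            _infon(ann_el, "provenance", m.provenance)
            _infon(ann_el, "sentence_index", str(m.sentence_index))
            if m.flags:
                _infon(ann_el, "flags", ",".join(m.flags))
            ET.SubElement(
                ann_el,
                "location",
                offset=str(m.char_start + abstract_offset),
                length=str(m.char_end - m.char_start),
            )
            ET.SubElement(ann_el, "text").text = m.surface

        doc_relations = sorted(
            relations_by_doc[doc_id],
            key=lambda r: (
                r.sentence_index,
                r.subject.char_start,
                r.object.char_start,
                r.relation_type.value,
            ),
        )
        for j, r in enumerate(doc_relations):
            rel_id = f"{doc_id}.R{j}"
            subj_id = ann_ids.get(_mention_key(r.subject))
            obj_id = ann_ids.get(_mention_key(r.object))
            if subj_id is None or obj_id is None:
                raise BioCError(
                    f"relation {rel_id} ({r.rule_id}): participant mention "
                    "not among serialized annotations"
                )
            rel_el = ET.SubElement(passage_el, "relation", id=rel_id)
            _infon(rel_el, "relation_type", r.relation_type.value)
            _infon(rel_el, "rule_id", r.rule_id)
            _infon(rel_el, "sentence_index", str(r.sentence_index))
            _infon(rel_el, "trigger_surface", r.trigger.surface)
            _infon(rel_el, "trigger_start", str(r.trigger.char_start))
            _infon(rel_el, "trigger_end", str(r.trigger.char_end))
            _infon(rel_el, "trigger_tag", r.trigger.tag)
            if r.trigger.trigger is not None:
                _infon(rel_el, "trigger_lemma", r.trigger.trigger.surface_form)
            _infon(rel_el, "trigger_token_index", str(r.trigger.token_index))
            ET.SubElement(rel_el, "node", refid=subj_id, role="subject")
            ET.SubElement(rel_el, "node", refid=obj_id, role="object")

    ET.indent(root)
    xml = ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"
    if stream is not None:
        stream.write(xml)
        return None
    return xml


def read_bioc(source: str | Path | IO[str]) -> BioCCollection:
    """Parse a BioC XML collection into documents, mentions and relations."""
    from .concept_recognition import ConceptMention, split_sentences
    from .relation_extraction import RelationInstance, TaggedToken

    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".xml")):
        data = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        data = source
    else:
        data = source.read()

    try:
        root = ET.fromstring(data)
    except ET.ParseError as exc:
        line, col = exc.position
        raise BioCError(f"malformed BioC XML at line {line}, column {col}: {exc}") from None

    result = BioCCollection()
    for doc_el in root.findall("document"):
        doc_id = (doc_el.findtext("id") or "").strip()
        if not doc_id:
            raise BioCError("document without id")

        title = ""
        abstract_el = None
        abstract_offset = 0
        for passage_el in doc_el.findall("passage"):
            infons = _infons(passage_el)
            ptype = infons.get("type", "abstract")
            if ptype == "title":
                title = passage_el.findtext("text") or ""
            else:
                abstract_el = passage_el
                abstract_offset = int(passage_el.findtext("offset") or "0")
                abstract_infons = infons
        if abstract_el is None:
            raise BioCError(f"{doc_id}: no abstract passage")
        text = abstract_el.findtext("text") or ""

        sent_spec = abstract_infons.get("sentence_offsets", "")
        if sent_spec:
            sentences = tuple(
                Sentence(i, int(a), int(b), text[int(a):int(b)])
                for i, (a, b) in enumerate(p.split(":") for p in sent_spec.split())
            )
        else:
            sentences = tuple(split_sentences(text))
        document = Document(doc_id=doc_id, title=title, abstract_text=text, sentences=sentences)
        result.documents.append(document)

        def sentence_index_for(start: int) -> int:
            idx = 0
            for i, s in enumerate(sentences):
                if s.char_start <= start < s.char_end:
                    idx = i
                    break
            return idx

        ann_map: dict[str, ConceptMention] = {}
        for ann_el in abstract_el.findall("annotation"):
            ann_id = ann_el.get("id", "?")
            infons = _infons(ann_el)
            loc = ann_el.find("location")
            if loc is None:
                raise BioCError(f"annotation {ann_id}: missing location")
            start = int(loc.get("offset", "0")) - abstract_offset
            length = int(loc.get("length", "0"))
            end = start + length
            if start < 0 or end > len(text):
                raise BioCError(f"annotation {ann_id}: span outside document text")
            surface = ann_el.findtext("text") or text[start:end]
            if text[start:end] != surface:
                raise BioCError(f"annotation {ann_id}: text does not match span")
            type_name = infons.get("type", "")
            try:
                concept_type = ConceptType(type_name)
            except ValueError:
                result.unknown_annotations.append(
                    {"id": ann_id, "doc_id": doc_id, "type": type_name,
                     "offset": start, "length": length, "text": surface,
                     "flags": ["unknown_concept_type"]}
                )
                continue
            sentence_index = int(infons.get("sentence_index", sentence_index_for(start)))
            flags = tuple(f for f in infons.get("flags", "").split(",") if f)
            mention = ConceptMention(
                doc_id=doc_id,
                sentence_index=sentence_index,
                char_start=start,
                char_end=end,
                surface=surface,
                concept_type=concept_type,
                normalized_id=infons.get("identifier", UNNORMALIZED) or UNNORMALIZED,
                provenance=infons.get("provenance", "gold"),
                flags=flags,
            )
            ann_map[ann_id] = mention
            result.mentions.append(mention)

        for rel_el in abstract_el.findall("relation"):
            rel_id = rel_el.get("id", "?")
            infons = _infons(rel_el)
            refs = {n.get("role"): n.get("refid") for n in rel_el.findall("node")}
            try:
                subject = ann_map[refs["subject"]]
                obj = ann_map[refs["object"]]
            except KeyError as exc:
                raise BioCError(f"relation {rel_id}: dangling reference {exc}") from None
            sentence_index = int(infons.get("sentence_index", str(subject.sentence_index)))
            trigger_tag = infons.get("trigger_tag", "PLAIN")
            trigger_entry = None
            if "trigger_lemma" in infons and trigger_tag in TriggerClass._value2member_map_:
                trigger_entry = TriggerEntry(infons["trigger_lemma"], TriggerClass(trigger_tag))
            trigger = TaggedToken(
                token_index=int(infons.get("trigger_token_index", "-1")),
                char_start=int(infons.get("trigger_start", "0")),
                char_end=int(infons.get("trigger_end", "0")),
                surface=infons.get("trigger_surface", ""),
                tag=trigger_tag,
                trigger=trigger_entry,
            )
            result.relations.append(
                RelationInstance(
                    doc_id=doc_id,
                    sentence_index=sentence_index,
                    subject=subject,
                    object=obj,
                    trigger=trigger,
                    relation_type=RelationType.from_name(infons.get("relation_type", "")),
                    rule_id=infons.get("rule_id", ""),
                    supporting_sentence_text=document.sentence_at(sentence_index).text,
                )
            )

    return result


# ---------------------------------------------------------------------------
# Curation table

CURATION_HEADER = (
    "doc_id",
    "sentence_text",
    "subject_surface",
    "subject_type",
    "subject_id",
    "relation_type",
    "object_surface",
    "object_type",
    "object_id",
)


@dataclass(frozen=True)
class CurationRow:
    doc_id: str
    sentence_text: str
    subject_surface: str
    subject_type: str
    subject_id: str
    relation_type: str
    object_surface: str
    object_type: str
    object_id: str

    def __post_init__(self) -> None:
        if self.relation_type not in {rt.value for rt in RelationType}:
            raise DocumentError(f"invalid relation_type {self.relation_type!r}")

    def as_tuple(self) -> tuple[str, ...]:
        return (
            self.doc_id, self.sentence_text,
            self.subject_surface, self.subject_type, self.subject_id,
            self.relation_type,
            self.object_surface, self.object_type, self.object_id,
        )


def export_curation_table(relations: Iterable["RelationInstance"]) -> list[CurationRow]:
    """One row per extracted binary relation, in extraction order."""
    rows = []
    for r in relations:
        rows.append(
            CurationRow(
                doc_id=r.doc_id,
                sentence_text=r.supporting_sentence_text,
                subject_surface=r.subject.surface,
                subject_type=r.subject.concept_type.value,
                subject_id=r.subject.normalized_id,
                relation_type=r.relation_type.value,
                object_surface=r.object.surface,
                object_type=r.object.concept_type.value,
                object_id=r.object.normalized_id,
            )
        )
    return rows


_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}


def _escape_field(value: str) -> str:
    out = []
    for ch in value:
        out.append(_ESCAPES.get(ch, ch))
    return "".join(out)


def _unescape_field(value: str) -> str:
    out = []
    it = iter(value)
    for ch in it:
        if ch == "\\":
            nxt = next(it, "")
            out.append({"t": "\t", "n": "\n", "r": "\r", "\\": "\\"}.get(nxt, nxt))
        else:
            out.append(ch)
    return "".join(out)


def curation_table_to_tsv(rows: Sequence[CurationRow]) -> str:
    lines = ["\t".join(CURATION_HEADER)]
    for row in rows:
        lines.append("\t".join(_escape_field(v) for v in row.as_tuple()))
    return "\n".join(lines) + "\n"


def curation_table_from_tsv(text: str) -> list[CurationRow]:
    lines = [ln for ln in text.split("\n") if ln]
    if not lines or lines[0] != "\t".join(CURATION_HEADER):
        raise DocumentError("curation table: missing or invalid header")
    rows = []
    for ln in lines[1:]:
        fields = [_unescape_field(f) for f in ln.split("\t")]
        if len(fields) != len(CURATION_HEADER):
            raise DocumentError(f"curation table: expected {len(CURATION_HEADER)} columns")
        rows.append(CurationRow(*fields))
    return rows
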