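"""Concept dictionaries, trigger lexicon and pattern rules.

The closed inventory of nine concept types, the four trigger classes and
their induced relation types live here, together with the loaders for the
three resource files that drive recognition and extraction:

* concept lexicon  — TSV: ``surface<TAB>concept_type<TAB>normalized_id``
* trigger lexicon  — TSV: ``surface<TAB>trigger_class``
* pattern rules    — YAML: list of rules over concept/trigger slot tags

All loaders accept a filesystem path, an open text stream, or an iterable
of lines, and each has a matching ``dump_*`` serializer such that
load → dump → load is the identity.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import yaml

from .errors import LexiconError

logger = logging.getLogger(__name__)

UNNORMALIZED = "UNNORMALIZED"


class ConceptType(str, Enum):
    """The closed set of nine curatable concept types."""

    GENE = "Gene"
    MICRO_RNA = "MicroRNA"
    NEOPLASM_METASTASIS = "NeoplasmMetastasis"
    CYTOSKELETON = "Cytoskeleton"
    CELL_MOVEMENT = "CellMovement"
    CELL_ADHESION = "CellAdhesion"
    NEOPLASMS = "Neoplasms"
    ORGAN = "Organ"
    TISSUES = "Tissues"

    @classmethod
    def from_name(cls, name: str) -> "ConceptType":
        try:
            return cls(name)
        except ValueError:
            raise LexiconError(f"unknown concept type: {name!r}") from None


#: Types that take an Entrez Gene namespace; all others use MeSH.
ENTREZ_TYPES = frozenset({ConceptType.GENE, ConceptType.MICRO_RNA})

#: Concept types treated as instances of metastasis by the <METASTASIS>
#: umbrella pattern tag.
METASTASIS_UMBRELLA = frozenset(
    {
        ConceptType.NEOPLASM_METASTASIS,
        ConceptType.CYTOSKELETON,
        ConceptType.CELL_MOVEMENT,
        ConceptType.CELL_ADHESION,
    }
)


class TriggerClass(str, Enum):
    POSITIVE_REG = "POSITIVE_REG"
    NEGATIVE_REG = "NEGATIVE_REG"
    NEUTRAL_REG = "NEUTRAL_REG"
    METASTASIS_TRIGGER = "METASTASIS_TRIGGER"

    @classmethod
    def from_name(cls, name: str) -> "TriggerClass":
        try:
            return cls(name)
        except ValueError:
            raise LexiconError(f"unknown trigger class: {name!r}") from None


class RelationType(str, Enum):
    POSITIVE_REGULATION = "positive_regulation"
    NEGATIVE_REGULATION = "negative_regulation"
    NEUTRAL_REGULATION = "neutral_regulation"
    METASTASIS = "metastasis"

    @classmethod
    def from_name(cls, name: str) -> "RelationType":
        try:
            return cls(name)
        except ValueError:
            raise LexiconError(f"unknown relation type: {name!r}") from None


REGULATION_TYPES = frozenset(
    {
        RelationType.POSITIVE_REGULATION,
        RelationType.NEGATIVE_REGULATION,
        RelationType.NEUTRAL_REGULATION,
    }
)

TRIGGER_TO_RELATION = {
    TriggerClass.POSITIVE_REG: RelationType.POSITIVE_REGULATION,
    TriggerClass.NEGATIVE_REG: RelationType.NEGATIVE_REGULATION,
    TriggerClass.NEUTRAL_REG: RelationType.NEUTRAL_REGULATION,
    TriggerClass.METASTASIS_TRIGGER: RelationType.METASTASIS,
}

#: Slot tags usable in pattern rules, mapped to the concept types they match.
CONCEPT_TAGS: dict[str, frozenset[ConceptType]] = {
    "GENE": frozenset({ConceptType.GENE, ConceptType.MICRO_RNA}),
    "MIRNA": frozenset({ConceptType.MICRO_RNA}),
    "METASTASIS": METASTASIS_UMBRELLA,
    "NEOPLASM_METASTASIS": frozenset({ConceptType.NEOPLASM_METASTASIS}),
    "CYTOSKELETON": frozenset({ConceptType.CYTOSKELETON}),
    "CELL_MOVEMENT": frozenset({ConceptType.CELL_MOVEMENT}),
    "CELL_ADHESION": frozenset({ConceptType.CELL_ADHESION}),
    "NEOPLASMS": frozenset({ConceptType.NEOPLASMS}),
    "ORGAN": frozenset({ConceptType.ORGAN}),
    "TISSUES": frozenset({ConceptType.TISSUES}),
}

TRIGGER_TAGS = frozenset(tc.value for tc in TriggerClass)
PLAIN_TAG = "PLAIN"

#: Adverbs that must never be loaded as trigger words (triggers are verbs or
#: nominal verbs; adverbs such as "more" do not cause direct relations).
STOP_ADVERBS = frozenset(
    {
        "more",
        "most",
        "less",
        "least",
        "frequently",
        "significantly",
        "highly",
        "often",
        "markedly",
        "strongly",
        "greatly",
    }
)

# ---------------------------------------------------------------------------
# Text folding: Greek letters map to their spelled-out names so that
# "TGF-β" and "TGF-beta" hit the same dictionary key; the unicode hyphen
# U+2010 folds to ASCII "-".

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "υ": "upsilon", "φ": "phi", "χ": "chi",
    "ψ": "psi", "ω": "omega",
    "Α": "alpha", "Β": "beta", "Γ": "gamma", "Δ": "delta", "Ε": "epsilon",
    "Ζ": "zeta", "Η": "eta", "Θ": "theta", "Ι": "iota", "Κ": "kappa",
    "Λ": "lambda", "Μ": "mu", "Ν": "nu", "Ξ": "xi", "Π": "pi", "Ρ": "rho",
    "Σ": "sigma", "Τ": "tau", "Υ": "upsilon", "Φ": "phi", "Χ": "chi",
    "Ψ": "psi", "Ω": "omega",
    "‐": "-",
}


def fold_text(text: str) -> str:
    """Normalize Greek letters and unicode hyphens for matching."""
    return "".join(_GREEK.get(ch, ch) for ch in text)


#: Word tokens: runs of unicode letters/digits with internal hyphens.
TOKEN_RE = re.compile(r"[^\W_]+(?:[-‐][^\W_]+)*")


def tokenize(text: str) -> list[tuple[int, int, str]]:
    """Return ``(start, end, surface)`` word tokens; hyphen is word-internal."""
    return [(m.start(), m.end(), m.group()) for m in TOKEN_RE.finditer(text)]


def _case_sensitive_surface(surface: str) -> bool:
    # Short or digit-bearing surfaces behave like gene symbols ("MET", "p53"):
    # matching them case-insensitively would be far too promiscuous.
    return len(surface) <= 4 or any(ch.isdigit() for ch in surface)


def _surface_key(surface: str) -> str:
    parts = [t[2] for t in tokenize(fold_text(surface))]
    return " ".join(parts)


# ---------------------------------------------------------------------------
# Concept lexicon


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    concept_type: ConceptType
    normalized_id: str = UNNORMALIZED

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise LexiconError("empty surface form")
        nid = self.normalized_id
        if nid != UNNORMALIZED:
            if self.concept_type in ENTREZ_TYPES:
                if not nid.startswith("EntrezGene:"):
                    raise LexiconError(
                        f"{self.surface!r} ({self.concept_type.value}): expected "
                        f"EntrezGene namespace or {UNNORMALIZED}, got {nid!r}"
                    )
            elif not nid.startswith("MeSH:"):
                raise LexiconError(
                    f"{self.surface!r} ({self.concept_type.value}): expected "
                    f"MeSH namespace or {UNNORMALIZED}, got {nid!r}"
                )


class Lexicon:
    """Concept dictionary indexed for longest-match lookup.

    Two indexes are kept: a case-sensitive one for gene-symbol-like
    surfaces (≤4 characters or containing digits) and a case-folded one
    for everything else. Keys are Greek-folded, whitespace-normalized
    token sequences. Lexicon (file) order is the documented tie-break.
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self.entries: list[LexiconEntry] = []
        self._cs: dict[str, list[LexiconEntry]] = {}
        self._ci: dict[str, list[LexiconEntry]] = {}
        self.max_tokens = 0
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexiconEntry) -> None:
        key = _surface_key(entry.surface)
        if _case_sensitive_surface(entry.surface):
            index = self._cs
        else:
            index = self._ci
            key = key.casefold()
        bucket = index.setdefault(key, [])
        if any(e.concept_type is entry.concept_type for e in bucket):
            logger.warning(
                "duplicate lexicon entry collapsed: %r / %s",
                entry.surface, entry.concept_type.value,
            )
            return
        bucket.append(entry)
        self.entries.append(entry)
        self.max_tokens = max(self.max_tokens, len(key.split(" ")))

    def lookup(self, surface: str) -> tuple[LexiconEntry | None, bool]:
        """Return ``(entry, ambiguous)`` for a candidate surface.

        ``ambiguous`` is True when more than one entry (different type or
        ID) shares the key; the first entry in lexicon order is returned.
        """
        key = _surface_key(surface)
        candidates = list(self._cs.get(key, ()))
        candidates += self._ci.get(key.casefold(), ())
        if not candidates:
            return None, False
        candidates.sort(key=self.entries.index)
        distinct = {(e.concept_type, e.normalized_id) for e in candidates}
        return candidates[0], len(distinct) > 1

    def entries_of_type(self, concept_type: ConceptType) -> list[LexiconEntry]:
        return [e for e in self.entries if e.concept_type is concept_type]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)


def _iter_lines(source: str | Path | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        yield from source  # type: ignore[misc]
    else:
        yield from source


def load_lexicon(source: str | Path | IO[str] | Iterable[str]) -> Lexicon:
    """Load a concept lexicon from TSV (surface, type, normalized_id)."""
    lexicon = Lexicon()
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise LexiconError(f"line {lineno}: expected at least 2 columns")
        surface = parts[0].strip()
        if not surface:
            raise LexiconError(f"line {lineno}: empty surface form")
        try:
            concept_type = ConceptType.from_name(parts[1].strip())
        except LexiconError as exc:
            raise LexiconError(f"line {lineno}: {exc}") from None
        normalized_id = parts[2].strip() if len(parts) > 2 and parts[2].strip() else UNNORMALIZED
        try:
            lexicon.add(LexiconEntry(surface, concept_type, normalized_id))
        except LexiconError as exc:
            raise LexiconError(f"line {lineno}: {exc}") from None
    return lexicon


def dump_lexicon(lexicon: Lexicon) -> str:
    lines = [
        f"{e.surface}\t{e.concept_type.value}\t{e.normalized_id}"
        for e in lexicon.entries
    ]
    return "\n".join(lines) + "\n" if lines else ""


# ---------------------------------------------------------------------------
# Trigger lexicon


@dataclass(frozen=True)
class TriggerEntry:
    surface_form: str
    trigger_class: TriggerClass

    def __post_init__(self) -> None:
        surface = self.surface_form.strip()
        if not surface:
            raise LexiconError("empty trigger surface form")
        if surface.casefold() in STOP_ADVERBS:
            raise LexiconError(
                f"{surface!r} is an adverb, not a verb/nominal verb; refusing "
                "to load it as a trigger"
            )

    @property
    def relation_type(self) -> RelationType:
        return TRIGGER_TO_RELATION[self.trigger_class]


def lemma_candidates(token: str) -> list[str]:
    """Candidate lemmas for a token under the light inflection rules.

    Handles plural -s/-es, past -ed, progressive -ing and the
    nominalization -tion↔-te / -ion↔∅ ("inhibition" → "inhibit",
    "regulation" → "regulate").
    """
    t = token.casefold()
    cands = [t]
    if t.endswith("s") and len(t) > 3:
        cands.append(t[:-1])
    if t.endswith("es") and len(t) > 4:
        cands.append(t[:-2])
    if t.endswith("ed") and len(t) > 4:
        cands.append(t[:-2])
        cands.append(t[:-2] + "e")
    if t.endswith("ing") and len(t) > 5:
        cands.append(t[:-3])
        cands.append(t[:-3] + "e")
    if t.endswith("tion") and len(t) > 5:
        cands.append(t[:-4] + "te")
    if t.endswith("ion") and len(t) > 4:
        cands.append(t[:-3])
    return cands


class TriggerLexicon:
    """Trigger vocabulary indexed by lemma; first entry wins on duplicates."""

    def __init__(self, entries: Iterable[TriggerEntry] = ()) -> None:
        self.entries: list[TriggerEntry] = []
        self._by_lemma: dict[str, TriggerEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: TriggerEntry) -> None:
        lemma = entry.surface_form.strip().casefold()
        if lemma in self._by_lemma:
            logger.warning("duplicate trigger collapsed: %r", entry.surface_form)
            return
        self._by_lemma[lemma] = entry
        self.entries.append(entry)

    def match(self, token_surface: str) -> TriggerEntry | None:
        for cand in lemma_candidates(token_surface):
            entry = self._by_lemma.get(cand)
            if entry is not None:
                return entry
        return None

    def entries_of_class(self, trigger_class: TriggerClass) -> list[TriggerEntry]:
        return [e for e in self.entries if e.trigger_class is trigger_class]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TriggerEntry]:
        return iter(self.entries)


def load_triggers(source: str | Path | IO[str] | Iterable[str]) -> TriggerLexicon:
    """Load a trigger lexicon from TSV (surface, trigger_class)."""
    triggers = TriggerLexicon()
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"line {lineno}: expected 2 columns")
        try:
            entry = TriggerEntry(parts[0].strip(), TriggerClass.from_name(parts[1].strip()))
        except LexiconError as exc:
            raise LexiconError(f"line {lineno}: {exc}") from None
        triggers.add(entry)
    return triggers


def dump_triggers(triggers: TriggerLexicon) -> str:
    lines = [f"{e.surface_form}\t{e.trigger_class.value}" for e in triggers.entries]
    return "\n".join(lines) + "\n" if lines else ""


# ---------------------------------------------------------------------------
# Pattern rules

DEFAULT_MAX_GAP = 3


@dataclass(frozen=True)
class PatternRule:
    """An ordered slot pattern over concept-type and trigger-class tags.

    Subject/object roles are carried by slot index, not surface order, so
    passive-voice rules (object before subject) are expressible.
    """

    rule_id: str
    slots: tuple[str, ...]
    subject_slot: int
    trigger_slot: int
    object_slot: int
    relation_type: RelationType
    max_gap: int = DEFAULT_MAX_GAP

    def __post_init__(self) -> None:
        rid = self.rule_id
        if not rid:
            raise LexiconError("pattern rule without rule_id")
        for tag in self.slots:
            if tag not in CONCEPT_TAGS and tag not in TRIGGER_TAGS:
                raise LexiconError(f"rule {rid}: unknown slot tag {tag!r}")
        n = len(self.slots)
        for name, idx in (
            ("subject_slot", self.subject_slot),
            ("trigger_slot", self.trigger_slot),
            ("object_slot", self.object_slot),
        ):
            if not 0 <= idx < n:
                raise LexiconError(f"rule {rid}: {name} {idx} out of range")
        if self.subject_slot == self.object_slot:
            raise LexiconError(f"rule {rid}: subject_slot == object_slot")
        if self.slots[self.subject_slot] not in CONCEPT_TAGS:
            raise LexiconError(f"rule {rid}: subject slot is not a concept tag")
        if self.slots[self.object_slot] not in CONCEPT_TAGS:
            raise LexiconError(f"rule {rid}: object slot is not a concept tag")
        trigger_tag = self.slots[self.trigger_slot]
        if trigger_tag not in TRIGGER_TAGS:
            raise LexiconError(f"rule {rid}: trigger slot is not a trigger tag")
        expected = TRIGGER_TO_RELATION[TriggerClass(trigger_tag)]
        if expected is not self.relation_type:
            raise LexiconError(
                f"rule {rid}: trigger tag {trigger_tag} implies relation "
                f"{expected.value}, not {self.relation_type.value}"
            )
        if self.max_gap < 0:
            raise LexiconError(f"rule {rid}: negative max_gap")


def load_patterns(source: str | Path | IO[str]) -> list[PatternRule]:
    """Load pattern rules from a YAML document (``rules:`` list or bare list)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    if isinstance(data, dict):
        data = data.get("rules", [])
    if not isinstance(data, list):
        raise LexiconError("pattern file must contain a list of rules")
    rules: list[PatternRule] = []
    seen: set[str] = set()
    for item in data:
        if not isinstance(item, dict):
            raise LexiconError("each pattern rule must be a mapping")
        try:
            rule = PatternRule(
                rule_id=str(item["rule_id"]),
                slots=tuple(str(s) for s in item["slots"]),
                subject_slot=int(item["subject_slot"]),
                trigger_slot=int(item["trigger_slot"]),
                object_slot=int(item["object_slot"]),
                relation_type=RelationType.from_name(str(item["relation_type"])),
                max_gap=int(item.get("max_gap", DEFAULT_MAX_GAP)),
            )
        except KeyError as exc:
            raise LexiconError(f"pattern rule missing field {exc}") from None
        if rule.rule_id in seen:
            raise LexiconError(f"duplicate rule_id {rule.rule_id!r}")
        seen.add(rule.rule_id)
        rules.append(rule)
    return rules


def dump_patterns(rules: Sequence[PatternRule]) -> str:
    data = {
        "rules": [
            {
                "rule_id": r.rule_id,
                "slots": list(r.slots),
                "subject_slot": r.subject_slot,
                "trigger_slot": r.trigger_slot,
                "object_slot": r.object_slot,
                "relation_type": r.relation_type.value,
                "max_gap": r.max_gap,
            }
            for r in rules
        ]
    }
    return yaml.safe_dump(data, sort_keys=False)


# ---------------------------------------------------------------------------
# Bundled defaults

_DATA_DIR = Path(__file__).parent / "data"


def default_lexicon_path() -> Path:
    return _DATA_DIR / "lexicon.tsv"


def default_triggers_path() -> Path:
    return _DATA_DIR / "triggers.tsv"


def default_patterns_path() -> Path:
    return _DATA_DIR / "patterns.yaml"


def default_templates_path() -> Path:
    return _DATA_DIR / "templates.yaml"


def load_default_lexicon() -> Lexicon:
    return load_lexicon(default_lexicon_path())


def load_default_triggers() -> TriggerLexicon:
    return load_triggers(default_triggers_path())


def load_default_patterns() -> list[PatternRule]:
    return load_patterns(default_patterns_path())
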