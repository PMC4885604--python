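import pytest

from metminer.concept_recognition import ConceptMention
from metminer.corpus_io import read_plain
from metminer.lexicon import (
    ConceptType,
    load_default_lexicon,
    load_default_patterns,
    load_default_triggers,
)
from metminer.fixtures import load_templates


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def triggers():
    return load_default_triggers()


@pytest.fixture(scope="session")
def rules():
    return load_default_patterns()


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture()
def make_doc():
    def _make(text, doc_id="DOC", title=""):
        return read_plain(text, doc_id, title=title)

    return _make


@pytest.fixture()
def make_mention():
    """Build a gold mention by locating a surface inside a document."""

    def _make(document, surface, concept_type, normalized_id="UNNORMALIZED",
              occurrence=0):
        start = -1
        for _ in range(occurrence + 1):
            start = document.abstract_text.index(surface, start + 1)
        end = start + len(surface)
        sent_idx = next(
            s.index for s in document.sentences
            if s.char_start <= start < s.char_end
        )
        return ConceptMention(
            doc_id=document.doc_id,
            sentence_index=sent_idx,
            char_start=start,
            char_end=end,
            surface=surface,
            concept_type=ConceptType(concept_type),
            normalized_id=normalized_id,
            provenance="gold",
        )

    return _make
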