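import pytest

from metminer.concept_recognition import (
    ConceptMention,
    recognize_dictionary,
    recognize_document,
    recognize_mirna,
    resolve_conflicts,
    split_sentences,
)
from metminer.corpus_io import Sentence, read_plain
from metminer.lexicon import ConceptType, load_lexicon


def sentence_of(text):
    return Sentence(index=0, char_start=0, char_end=len(text), text=text)


class TestSplitSentences:
    def test_basic_split(self):
        assert len(split_sentences("A binds B. C binds D.")) == 2

    def test_abbreviation_guard(self):
        assert len(split_sentences("Smith et al. showed X.")) == 1

    def test_figure_guard_and_real_boundary(self):
        sents = split_sentences("miR-21 is induced (Fig. 2). EMT follows.")
        assert len(sents) == 2
        assert sents[0].text == "miR-21 is induced (Fig. 2)."
        assert sents[1].text == "EMT follows."

    def test_no_split_before_lowercase(self):
        assert len(split_sentences("the p. value was low")) == 1

    def test_offsets_reconstruct_text(self):
        text = "One sentence.  Another sentence! A third?  Done."
        sents = split_sentences(text)
        for s in sents:
            assert text[s.char_start:s.char_end] == s.text
        # spans ordered and non-overlapping
        for a, b in zip(sents, sents[1:]):
            assert a.char_end <= b.char_start

    def test_split_before_digit(self):
        assert len(split_sentences("It was shown. 5 genes were tested.")) == 2


class TestDictionaryRecognition:
    def test_longest_match_wins(self):
        lex = load_lexicon(
            ["Liver\tOrgan\tMeSH:D008099\n", "Liver cancer\tNeoplasms\tMeSH:D008113\n"]
        )
        sent = sentence_of("Liver cancer metastasizes.")
        mentions = recognize_dictionary("X", sent, lex)
        assert [(m.surface, m.concept_type) for m in mentions] == [
            ("Liver cancer", ConceptType.NEOPLASMS)
        ]

    def test_adipose_tissue(self, lexicon):
        mentions = recognize_dictionary("X", sentence_of("Adipose tissue was examined."), lexicon)
        assert [(m.surface, m.concept_type) for m in mentions] == [
            ("Adipose tissue", ConceptType.TISSUES)
        ]

    def test_stress_fiber(self, lexicon):
        mentions = recognize_dictionary(
            "X", sentence_of("Stress fiber formation increased."), lexicon
        )
        assert [(m.surface, m.concept_type) for m in mentions] == [
            ("Stress fiber", ConceptType.CYTOSKELETON)
        ]

    def test_token_boundary_blocks_substring(self, lexicon):
        # "Snail" must not fire inside "Snailed" — token anchor
        lex = load_lexicon(["Snail\tGene\tEntrezGene:6615\n"])
        assert recognize_dictionary("X", sentence_of("Snailed along."), lex) == []

    def test_multi_token_requires_whitespace_gap(self):
        lex = load_lexicon(["Liver cancer\tNeoplasms\tMeSH:D008113\n"])
        assert recognize_dictionary("X", sentence_of("Liver, cancer"), lex) == []


class TestMirnaRecognition:
    def test_mir_181a(self):
        mentions = recognize_mirna("X", sentence_of("miR-181a is induced."))
        assert [m.surface for m in mentions] == ["miR-181a"]
        assert mentions[0].concept_type is ConceptType.MICRO_RNA

    def test_miracle_not_matched(self):
        assert recognize_mirna("X", sentence_of("miracle cure")) == []

    def test_cluster_form(self):
        mentions = recognize_mirna("X", sentence_of("the miR-200b/200c cluster"))
        assert [m.surface for m in mentions] == ["miR-200b/200c"]

    def test_let_form_and_microRNA_form(self):
        assert [m.surface for m in recognize_mirna("X", sentence_of("let-7a acts"))] == ["let-7a"]
        assert [m.surface for m in recognize_mirna("X", sentence_of("microRNA-21 acts"))] == [
            "microRNA-21"
        ]

    def test_normalization_from_lexicon(self, lexicon):
        mentions = recognize_mirna("X", sentence_of("miR-181a acts"), lexicon)
        assert mentions[0].normalized_id == "EntrezGene:406995"

    def test_unknown_mirna_unnormalized(self, lexicon):
        mentions = recognize_mirna("X", sentence_of("miR-9999 acts"), lexicon)
        assert mentions[0].normalized_id == "UNNORMALIZED"


class TestResolveConflicts:
    def _mention(self, start, end, surface, ctype, provenance):
        return ConceptMention(
            doc_id="X", sentence_index=0, char_start=start, char_end=end,
            surface=surface, concept_type=ConceptType(ctype), provenance=provenance,
        )

    def test_mirna_beats_dictionary_on_overlap(self):
        dict_m = self._mention(0, 3, "miR", "Gene", "dictionary")
        mirna_m = self._mention(0, 8, "miR-181a", "MicroRNA", "mirna_rule")
        resolved = resolve_conflicts([dict_m], [mirna_m])
        assert resolved == [mirna_m]

    def test_disjoint_mentions_concatenated_sorted(self):
        a = self._mention(10, 15, "Snail", "Gene", "dictionary")
        b = self._mention(0, 8, "miR-181a", "MicroRNA", "mirna_rule")
        assert resolve_conflicts([a], [b]) == [b, a]

    def test_identical_spans_keep_mirna(self):
        d = self._mention(0, 8, "miR-181a", "Gene", "dictionary")
        m = self._mention(0, 8, "miR-181a", "MicroRNA", "mirna_rule")
        resolved = resolve_conflicts([d], [m])
        assert len(resolved) == 1
        assert resolved[0].concept_type is ConceptType.MICRO_RNA


NINE_INSTANCES = [
    ("TGF-β", "Gene", "The TGF-β pathway is active."),
    ("miR-181a", "MicroRNA", "Levels of miR-181a were high."),
    ("Metastasis", "NeoplasmMetastasis", "We studied Metastasis in this model."),
    ("Stress fiber", "Cytoskeleton", "We observed Stress fiber assembly."),
    ("Cell aggregation", "CellMovement", "We observed Cell aggregation in culture."),
    ("Cell adhesion", "CellAdhesion", "We measured Cell adhesion in culture."),
    ("Liver cancer", "Neoplasms", "We studied Liver cancer in this cohort."),
    ("Liver", "Organ", "The Liver was examined."),
    ("Adipose tissue", "Tissues", "We sampled Adipose tissue from donors."),
]


class TestRecognitionProperties:
    @pytest.mark.parametrize("surface,ctype,carrier", NINE_INSTANCES)
    def test_nine_example_instances(self, lexicon, surface, ctype, carrier):
        doc = read_plain(carrier, "T")
        mentions = recognize_document(doc, lexicon)
        assert (surface, ConceptType(ctype)) in {
            (m.surface, m.concept_type) for m in mentions
        }

    def test_span_fidelity_and_no_overlap(self, lexicon):
        doc = read_plain(
            "TGF-β induces Snail in Liver cancer. miR-21 suppresses PTEN. "
            "Breast cancer metastasizes to the Lung.",
            "P",
        )
        mentions = recognize_document(doc, lexicon)
        assert mentions
        for m in mentions:
            assert doc.abstract_text[m.char_start:m.char_end] == m.surface
        per_sentence = {}
        for m in mentions:
            per_sentence.setdefault(m.sentence_index, []).append(m)
        for ms in per_sentence.values():
            ms.sort(key=lambda m: m.char_start)
            for a, b in zip(ms, ms[1:]):
                assert a.char_end <= b.char_start

    def test_deterministic(self, lexicon):
        doc = read_plain("TGF-β induces Snail and miR-21 in Liver cancer.", "D")
        assert recognize_document(doc, lexicon) == recognize_document(doc, lexicon)
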