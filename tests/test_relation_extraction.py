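import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metminer.concept_recognition import ConceptMention, recognize_sentence
from metminer.corpus_io import read_plain
from metminer.errors import ExtractionError
from metminer.lexicon import (
    ConceptType,
    PatternRule,
    RelationType,
    TriggerClass,
)
from metminer.relation_extraction import (
    RelationInstance,
    TaggedToken,
    extract_relations,
    find_matches,
    match_patterns,
    tag_sentence,
)

# Independent slot-tag semantics for the oracle (kept deliberately separate
# from the implementation's tables).
ORACLE_CONCEPTS = {
    "GENE": {"Gene", "MicroRNA"},
    "MIRNA": {"MicroRNA"},
    "METASTASIS": {"NeoplasmMetastasis", "Cytoskeleton", "CellMovement", "CellAdhesion"},
    "NEOPLASM_METASTASIS": {"NeoplasmMetastasis"},
    "CYTOSKELETON": {"Cytoskeleton"},
    "CELL_MOVEMENT": {"CellMovement"},
    "CELL_ADHESION": {"CellAdhesion"},
    "NEOPLASMS": {"Neoplasms"},
    "ORGAN": {"Organ"},
    "TISSUES": {"Tissues"},
}

TAG_ALPHABET = (
    [ct.value for ct in ConceptType]
    + [tc.value for tc in TriggerClass]
    + ["PLAIN"]
)


def oracle_slot_ok(slot_tag, token_tag):
    if slot_tag in ORACLE_CONCEPTS:
        return token_tag in ORACLE_CONCEPTS[slot_tag]
    return slot_tag == token_tag


def oracle_matches(tags, rule):
    """Brute force: test every index subsequence against slot/gap constraints."""
    out = []
    for combo in itertools.combinations(range(len(tags)), len(rule.slots)):
        if not all(oracle_slot_ok(rule.slots[s], tags[combo[s]]) for s in range(len(combo))):
            continue
        ok = True
        for a, b in zip(combo, combo[1:]):
            if b - a - 1 > rule.max_gap:
                ok = False
                break
            if any(tags[x] != "PLAIN" for x in range(a + 1, b)):
                ok = False
                break
        if ok:
            out.append(combo)
    return out


def tokens_for_tags(tags):
    """Synthesize TaggedTokens (with dummy mentions) for a tag sequence."""
    out = []
    concept_names = {ct.value for ct in ConceptType}
    for i, tag in enumerate(tags):
        mention = None
        if tag in concept_names:
            mention = ConceptMention(
                doc_id="X", sentence_index=0, char_start=10 * i,
                char_end=10 * i + 5, surface=f"tok{i}",
                concept_type=ConceptType(tag), provenance="gold",
            )
        out.append(
            TaggedToken(
                token_index=i, char_start=10 * i, char_end=10 * i + 5,
                surface=f"tok{i}", tag=tag, mention=mention,
            )
        )
    return out


class TestTagSentence:
    def test_gene_trigger_gene(self, lexicon, triggers):
        doc = read_plain("TGF-β induces Snail", "T")
        sent = doc.sentences[0]
        mentions = recognize_sentence("T", sent, lexicon)
        tagged = tag_sentence(sent, mentions, triggers)
        assert [t.tag for t in tagged] == ["Gene", "POSITIVE_REG", "Gene"]

    def test_all_plain_without_resources(self, triggers):
        doc = read_plain("Nothing of note here", "T")
        tagged = tag_sentence(doc.sentences[0], [], triggers)
        assert all(t.tag == "PLAIN" for t in tagged)

    def test_nominalization_tagged(self, triggers):
        doc = read_plain("inhibition of growth", "T")
        tagged = tag_sentence(doc.sentences[0], [], triggers)
        assert tagged[0].tag == "NEGATIVE_REG"
        assert tagged[0].surface == "inhibition"

    def test_multi_token_mention_collapses(self, lexicon, triggers):
        doc = read_plain("Liver cancer metastasizes to the Liver", "T")
        sent = doc.sentences[0]
        mentions = recognize_sentence("T", sent, lexicon)
        tagged = tag_sentence(sent, mentions, triggers)
        assert [t.tag for t in tagged] == [
            "Neoplasms", "METASTASIS_TRIGGER", "PLAIN", "PLAIN", "Organ",
        ]
        assert tagged[0].surface == "Liver cancer"

    def test_mention_outside_sentence_is_error(self, triggers):
        doc = read_plain("Short text here. And a second sentence.", "T")
        bad = ConceptMention(
            doc_id="T", sentence_index=0, char_start=20, char_end=26,
            surface="second", concept_type=ConceptType.GENE, provenance="gold",
        )
        with pytest.raises(ExtractionError, match="outside"):
            tag_sentence(doc.sentences[0], [bad], triggers)


class TestMatchPatterns:
    @pytest.fixture()
    def gg_pos(self):
        return PatternRule(
            rule_id="gg_pos", slots=("GENE", "POSITIVE_REG", "GENE"),
            subject_slot=0, trigger_slot=1, object_slot=2,
            relation_type=RelationType.POSITIVE_REGULATION, max_gap=3,
        )

    def test_adjacent_match(self, gg_pos):
        tagged = tokens_for_tags(["Gene", "POSITIVE_REG", "Gene"])
        rels = match_patterns(tagged, [gg_pos])
        assert len(rels) == 1
        assert rels[0].subject is tagged[0].mention
        assert rels[0].object is tagged[2].mention
        assert rels[0].relation_type is RelationType.POSITIVE_REGULATION

    def test_gap_exceeding_bound_blocks(self, gg_pos):
        tagged = tokens_for_tags(
            ["Gene", "PLAIN", "PLAIN", "PLAIN", "PLAIN", "POSITIVE_REG", "Gene"]
        )
        assert match_patterns(tagged, [gg_pos]) == []

    def test_gap_within_bound_matches(self, gg_pos):
        tagged = tokens_for_tags(["Gene", "PLAIN", "PLAIN", "PLAIN", "POSITIVE_REG", "Gene"])
        assert len(match_patterns(tagged, [gg_pos])) == 1

    def test_tagged_token_may_not_be_skipped(self, gg_pos):
        tagged = tokens_for_tags(["Gene", "Neoplasms", "POSITIVE_REG", "Gene"])
        assert match_patterns(tagged, [gg_pos]) == []

    def test_metastasis_rule_with_gap(self):
        rule = PatternRule(
            rule_id="m", slots=("NEOPLASMS", "METASTASIS_TRIGGER", "ORGAN"),
            subject_slot=0, trigger_slot=1, object_slot=2,
            relation_type=RelationType.METASTASIS, max_gap=3,
        )
        tagged = tokens_for_tags(["Neoplasms", "METASTASIS_TRIGGER", "PLAIN", "Organ"])
        rels = match_patterns(tagged, [rule])
        assert len(rels) == 1
        assert rels[0].relation_type is RelationType.METASTASIS

    def test_monotonicity_adding_rule(self, gg_pos, rules):
        tagged = tokens_for_tags(["Gene", "POSITIVE_REG", "Gene", "NEUTRAL_REG", "Neoplasms"])
        base = match_patterns(tagged, rules)
        extra = match_patterns(tagged, list(rules) + [
            PatternRule(
                rule_id="extra", slots=("GENE", "NEUTRAL_REG", "NEOPLASMS"),
                subject_slot=0, trigger_slot=1, object_slot=2,
                relation_type=RelationType.NEUTRAL_REGULATION, max_gap=5,
            )
        ])
        assert {r.match_key() for r in base} <= {r.match_key() for r in extra}

    def test_role_by_slot_supports_passive(self):
        rule = PatternRule(
            rule_id="passive", slots=("GENE", "POSITIVE_REG", "GENE"),
            subject_slot=2, trigger_slot=1, object_slot=0,
            relation_type=RelationType.POSITIVE_REGULATION, max_gap=3,
        )
        tagged = tokens_for_tags(["Gene", "POSITIVE_REG", "Gene"])
        rels = match_patterns(tagged, [rule])
        assert rels[0].subject is tagged[2].mention
        assert rels[0].object is tagged[0].mention


class TestOracleEquivalence:
    @given(
        tags=st.lists(st.sampled_from(TAG_ALPHABET), min_size=0, max_size=8)
    )
    @settings(max_examples=300, deadline=None)
    def test_find_matches_equals_bruteforce(self, tags, rules):
        for rule in rules:
            assert set(find_matches(tags, rule)) == set(oracle_matches(tags, rule))


class TestRelationInstanceInvariants:
    def test_metastasis_requires_neoplasms_subject(self):
        tagged = tokens_for_tags(["Organ", "METASTASIS_TRIGGER", "Organ"])
        with pytest.raises(ExtractionError, match="Neoplasms"):
            RelationInstance(
                doc_id="X", sentence_index=0,
                subject=tagged[0].mention, object=tagged[2].mention,
                trigger=tagged[1], relation_type=RelationType.METASTASIS,
                rule_id="r", supporting_sentence_text="s",
            )

    def test_subject_object_must_differ(self):
        tagged = tokens_for_tags(["Gene", "POSITIVE_REG"])
        with pytest.raises(ExtractionError, match="coincide"):
            RelationInstance(
                doc_id="X", sentence_index=0,
                subject=tagged[0].mention, object=tagged[0].mention,
                trigger=tagged[1], relation_type=RelationType.POSITIVE_REGULATION,
                rule_id="r", supporting_sentence_text="s",
            )


class TestExtractRelations:
    def test_two_sentence_fixture(self, lexicon, triggers, rules):
        doc = read_plain("TGF-β induces Snail. Snail promotes Metastasis.", "E1")
        rels = extract_relations(doc, lexicon, triggers, rules)
        assert [
            (r.subject.surface, r.relation_type.value, r.object.surface) for r in rels
        ] == [
            ("TGF-β", "positive_regulation", "Snail"),
            ("Snail", "positive_regulation", "Metastasis"),
        ]

    def test_no_triggers_no_relations(self, lexicon, triggers, rules):
        doc = read_plain("TGF-β and Snail were present in Liver cancer.", "E2")
        assert extract_relations(doc, lexicon, triggers, rules) == []

    def test_adverb_more_is_not_a_trigger(self, lexicon, triggers, rules):
        doc = read_plain(
            "Metachronous metastasis was observed more frequently in the cases "
            "with high PRL-3 expression.",
            "E3",
        )
        assert extract_relations(doc, lexicon, triggers, rules) == []

    def test_deterministic(self, lexicon, triggers, rules):
        doc = read_plain("TGF-β induces Snail. Snail promotes Metastasis.", "E4")
        assert extract_relations(doc, lexicon, triggers, rules) == extract_relations(
            doc, lexicon, triggers, rules
        )
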