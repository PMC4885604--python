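# Sentence templates for the synthetic-corpus generator.
#
# Placeholders: {<ConceptType>[:n]} fills with a lexicon surface of that
# type; {POS}/{NEG}/{NEU}/{MET}[:n] fill with an inflected trigger of the
# corresponding class. Repeating the same placeholder (same type and n)
# reuses the same filler. "relations" lists [subject, trigger, object]
# as indices of placeholder occurrences in text order; the relation type
# is implied by the trigger occurrence's class.
#
# Every template starts with an uppercase word so that consecutive units
# always segment into separate sentences even when a filler surface
# starts lowercase ("miR-21", "β-catenin").
templates:
  - template_id: gg_pos
    covered: true
    n_sentences: 1
    text: "Here, {Gene:1} {POS} {Gene:2} in vitro."
    relations: [[0, 1, 2]]
  - template_id: gg_neg
    covered: true
    n_sentences: 1
    text: "Moreover, {Gene:1} {NEG} {Gene:2} in tumor cells."
    relations: [[0, 1, 2]]
  - template_id: gg_neu
    covered: true
    n_sentences: 1
    text: "Importantly, {Gene:1} directly {NEU} {Gene:2}."
    relations: [[0, 1, 2]]
  - template_id: mir_gene
    covered: true
    n_sentences: 1
    text: "Notably, {MicroRNA} {NEG} {Gene} in vivo."
    relations: [[0, 1, 2]]
  - template_id: gene_metastasis
    covered: true
    n_sentences: 1
    text: "Furthermore, {Gene} {POS} {NeoplasmMetastasis}."
    relations: [[0, 1, 2]]
  - template_id: gene_cytoskeleton
    covered: true
    n_sentences: 1
    text: "Overall, {Gene} {POS} {Cytoskeleton} formation."
    relations: [[0, 1, 2]]
  - template_id: gene_movement
    covered: true
    n_sentences: 1
    text: "Likewise, {Gene} {NEG} {CellMovement}."
    relations: [[0, 1, 2]]
  - template_id: gene_adhesion
    covered: true
    n_sentences: 1
    text: "Similarly, {Gene} {NEU} {CellAdhesion}."
    relations: [[0, 1, 2]]
  - template_id: gene_neoplasm
    covered: true
    n_sentences: 1
    text: "Additionally, {Gene} {NEG} {Neoplasms} growth."
    relations: [[0, 1, 2]]
  - template_id: neoplasm_organ
    covered: true
    n_sentences: 1
    text: "Clinically, {Neoplasms} {MET} to the {Organ}."
    relations: [[0, 1, 2]]
  - template_id: neoplasm_tissue
    covered: true
    n_sentences: 1
    text: "Eventually, {Neoplasms} {MET} into {Tissues}."
    relations: [[0, 1, 2]]
  - template_id: chain_ggm
    covered: true
    n_sentences: 2
    text: "First, {Gene:1} {POS:1} {Gene:2}. Second, {Gene:2} {POS:2} {NeoplasmMetastasis}."
    relations: [[0, 1, 2], [3, 4, 5]]
  - template_id: chain_ggno
    covered: true
    n_sentences: 2
    text: "First, {Gene:1} {POS} {Gene:2}. Then, {Gene:2} {NEU} {Neoplasms:1}, and {Neoplasms:1} {MET} to the {Organ}."
    relations: [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
  - template_id: d_cohort
    covered: false
    n_sentences: 1
    text: "Patients with {Neoplasms} were enrolled in this study."
    relations: []
  - template_id: d_expression
    covered: false
    n_sentences: 1
    text: "Expression of {Gene} was detected in {Tissues} samples."
    relations: []
  - template_id: d_role
    covered: false
    n_sentences: 1
    text: "The role of {Gene} in {CellAdhesion} remains unclear."
    relations: []
  - template_id: d_biopsy
    covered: false
    n_sentences: 1
    text: "{Organ} biopsies were obtained from all subjects."
    relations: []
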