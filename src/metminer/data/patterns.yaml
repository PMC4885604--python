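# Bundled pattern rules. Slot tags are concept-type tags (GENE matches
# Gene|MicroRNA; METASTASIS matches the NeoplasmMetastasis umbrella) or
# trigger-class tags. Roles are carried by slot index.
rules:
  - rule_id: gg_pos
    slots: [GENE, POSITIVE_REG, GENE]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: positive_regulation
    max_gap: 3
  - rule_id: gg_neg
    slots: [GENE, NEGATIVE_REG, GENE]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: negative_regulation
    max_gap: 3
  - rule_id: gg_neu
    slots: [GENE, NEUTRAL_REG, GENE]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: neutral_regulation
    max_gap: 3
  - rule_id: gmet_pos
    slots: [GENE, POSITIVE_REG, METASTASIS]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: positive_regulation
    max_gap: 3
  - rule_id: gmet_neg
    slots: [GENE, NEGATIVE_REG, METASTASIS]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: negative_regulation
    max_gap: 3
  - rule_id: gmet_neu
    slots: [GENE, NEUTRAL_REG, METASTASIS]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: neutral_regulation
    max_gap: 3
  - rule_id: gneo_pos
    slots: [GENE, POSITIVE_REG, NEOPLASMS]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: positive_regulation
    max_gap: 3
  - rule_id: gneo_neg
    slots: [GENE, NEGATIVE_REG, NEOPLASMS]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: negative_regulation
    max_gap: 3
  - rule_id: gneo_neu
    slots: [GENE, NEUTRAL_REG, NEOPLASMS]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: neutral_regulation
    max_gap: 3
  - rule_id: neo_site_organ
    slots: [NEOPLASMS, METASTASIS_TRIGGER, ORGAN]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: metastasis
    max_gap: 3
  - rule_id: neo_site_tissue
    slots: [NEOPLASMS, METASTASIS_TRIGGER, TISSUES]
    subject_slot: 0
    trigger_slot: 1
    object_slot: 2
    relation_type: metastasis
    max_gap: 3
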