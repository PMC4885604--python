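# metminer

Dictionary- and pattern-based text mining of metastasis biology from
biomedical abstracts: typed concept mentions, trigger-word binary
relations, composed metastasis events, and literature-integrated
networks — with BioC XML interchange, a curation-table export and a
fully synthetic, seeded test corpus.

## What it does

Given an abstract (plain text or BioC XML), metminer

1. **segments sentences** (terminal punctuation + abbreviation guard);
2. **recognizes concepts** of nine closed types — Gene, MicroRNA,
   NeoplasmMetastasis, Cytoskeleton, CellMovement, CellAdhesion,
   Neoplasms, Organ, Tissues — by dictionary longest match (Entrez
   Gene / MeSH normalized IDs) plus a rule-based microRNA name
   recognizer;
3. **extracts binary relations** by matching slot-pattern rules (e.g.
   `GENE POSITIVE_REG GENE`) over sentences tagged with concept types
   and lemma-matched trigger words; relation types are
   positive/negative/neutral regulation and metastasis
   (Neoplasms ⇒ Tissues|Organ);
4. **composes events**: gene → gene → metastasis-concept chains (GGM)
   and gene → gene → neoplasm ⇒ site chains (GGNO), document-scoped;
5. **builds and integrates networks** keyed on normalized concept
   identity, with per-edge sentence-level evidence, serialized as graph
   JSON or GraphML.

Bundled resources under `src/metminer/data/`: a concept lexicon
(`lexicon.tsv`), a trigger lexicon (`triggers.tsv`, verbs/nominal verbs
only — adverbs are rejected at load time), pattern rules
(`patterns.yaml`) and sentence templates for the synthetic-corpus
generator (`templates.yaml`). All are illustrative defaults and can be
swapped via CLI flags.

## CLI

```sh
# generate a seeded synthetic corpus with gold annotations
metminer simulate --n-docs 10 --seed 7 --out sim/

# run the pipeline: BioC + curation TSV + graph JSON per document
metminer extract sim/*.txt --out mined/

# merge per-document networks
metminer integrate mined/*.graph.json --out merged.json --graphml merged.graphml

# score predictions against gold (strict + relaxed polarity)
metminer evaluate --gold sim/gold.bioc.xml --predicted mined/SYN-7-0000.bioc.xml --out report.json
# or run extraction with gold concept boundaries:
metminer evaluate --gold sim/gold.bioc.xml --out report.json
```

Plain-text input format: line 1 `doc_id`, line 2 title, remainder the
abstract. Logging goes to stderr (`--log-level`); all machine-readable
output goes to files. Reruns with identical inputs and seeds are
byte-identical.

## Package layout

| module | responsibility |
| --- | --- |
| `metminer.corpus_io` | documents/sentences, plain-text + BioC XML I/O, curation-table TSV |
| `metminer.lexicon` | concept types, lexicons, trigger classes, pattern rules |
| `metminer.concept_recognition` | sentence splitting, dictionary + miRNA recognizers |
| `metminer.relation_extraction` | slot tagging, pattern matching, relation pipeline |
| `metminer.event_network` | event composition, network build/merge, JSON/GraphML |
| `metminer.evaluation` | strict/relaxed P/R/F scoring with gold boundaries |
| `metminer.fixtures` | seeded synthetic corpora with planted gold annotations |
| `metminer.cli` | `extract`, `integrate`, `evaluate`, `simulate` commands |

Coordinates are 0-based, half-open character offsets throughout; BioC
`offset`/`length` is converted at the boundary. Known limitation:
negation scope is not modeled — "A did not inhibit B" still yields a
negative-regulation relation.
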