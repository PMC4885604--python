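"""Event composition and metastasis-network construction/integration.

Two event templates are composed from binary relations of one document
(chaining is document-scoped; relations from different sentences may
chain through a shared participant identified by node key):

* GGM:  gene → gene → metastasis-umbrella concept
* GGNO: gene → gene → neoplasm ⇒ tissue/organ site

Networks key nodes on the normalized ID when available, otherwise on the
case-folded surface plus concept type; edge identity includes the
relation type so opposite polarities stay distinct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .concept_recognition import ConceptMention
from .lexicon import (
    METASTASIS_UMBRELLA,
    REGULATION_TYPES,
    UNNORMALIZED,
    ConceptType,
    RelationType,
)
from .relation_extraction import RelationInstance

_GENE_LIKE = frozenset({ConceptType.GENE, ConceptType.MICRO_RNA})
_SITE_TYPES = frozenset({ConceptType.TISSUES, ConceptType.ORGAN})


def node_key(mention: ConceptMention) -> str:
    """Stable identity for network merging across mentions/documents."""
    if mention.normalized_id != UNNORMALIZED:
        return mention.normalized_id
    return f"{mention.concept_type.value}:{mention.surface.casefold()}"


@dataclass(frozen=True)
class MetEvent:
    """A composed event chain (GGM or GGNO)."""

    event_type: str  # "GGM" | "GGNO"
    participants: tuple[ConceptMention, ...]
    relations: tuple[RelationInstance, ...]

    def __post_init__(self) -> None:
        if self.event_type not in {"GGM", "GGNO"}:
            raise ValueError(f"invalid event type {self.event_type!r}")
        expected = 3 if self.event_type == "GGM" else 4
        if len(self.participants) != expected:
            raise ValueError(
                f"{self.event_type} event requires {expected} participants"
            )

    @property
    def chain_keys(self) -> tuple[str, ...]:
        return tuple(node_key(p) for p in self.participants)


def _is_gene_gene(r: RelationInstance) -> bool:
    return (
        r.relation_type in REGULATION_TYPES
        and r.subject.concept_type in _GENE_LIKE
        and r.object.concept_type in _GENE_LIKE
    )


def _is_gene_metastasis(r: RelationInstance) -> bool:
    return (
        r.relation_type in REGULATION_TYPES
        and r.subject.concept_type in _GENE_LIKE
        and r.object.concept_type in METASTASIS_UMBRELLA
    )


def _is_gene_neoplasm(r: RelationInstance) -> bool:
    return (
        r.relation_type in REGULATION_TYPES
        and r.subject.concept_type in _GENE_LIKE
        and r.object.concept_type is ConceptType.NEOPLASMS
    )


def _is_metastasis_link(r: RelationInstance) -> bool:
    return r.relation_type is RelationType.METASTASIS


def compose_events(relations: Sequence[RelationInstance]) -> list[MetEvent]:
    """Enumerate all GGM and GGNO chains among one document's relations.

    One event is emitted per distinct key chain; its contributing
    relations are every input relation realizing one of the chain links.
    """
    gg = [r for r in relations if _is_gene_gene(r)]
    gm = [r for r in relations if _is_gene_metastasis(r)]
    gn = [r for r in relations if _is_gene_neoplasm(r)]
    ns = [r for r in relations if _is_metastasis_link(r)]

    events: list[MetEvent] = []
    seen: set[tuple] = set()

    for r1 in gg:
        b_key = node_key(r1.object)
        for r2 in gm:
            if node_key(r2.subject) != b_key:
                continue
            chain = ("GGM", node_key(r1.subject), b_key, node_key(r2.object))
            if chain in seen:
                continue
            seen.add(chain)
            contributors = tuple(
                r for r in relations
                if (_is_gene_gene(r) and node_key(r.subject) == chain[1]
                    and node_key(r.object) == b_key)
                or (_is_gene_metastasis(r) and node_key(r.subject) == b_key
                    and node_key(r.object) == chain[3])
            )
            events.append(
                MetEvent(
                    event_type="GGM",
                    participants=(r1.subject, r1.object, r2.object),
                    relations=contributors,
                )
            )

    for r1 in gg:
        b_key = node_key(r1.object)
        for r2 in gn:
            if node_key(r2.subject) != b_key:
                continue
            n_key = node_key(r2.object)
            for r3 in ns:
                if node_key(r3.subject) != n_key:
                    continue
                chain = ("GGNO", node_key(r1.subject), b_key, n_key, node_key(r3.object))
                if chain in seen:
                    continue
                seen.add(chain)
                contributors = tuple(
                    r for r in relations
                    if (_is_gene_gene(r) and node_key(r.subject) == chain[1]
                        and node_key(r.object) == b_key)
                    or (_is_gene_neoplasm(r) and node_key(r.subject) == b_key
                        and node_key(r.object) == n_key)
                    or (_is_metastasis_link(r) and node_key(r.subject) == n_key
                        and node_key(r.object) == chain[4])
                )
                events.append(
                    MetEvent(
                        event_type="GGNO",
                        participants=(r1.subject, r1.object, r2.object, r3.object),
                        relations=contributors,
                    )
                )

    return events


# ---------------------------------------------------------------------------
# Networks


@dataclass
class NetworkNode:
    node_key: str
    label: str
    concept_type: ConceptType
    evidence_doc_ids: set[str] = field(default_factory=set)

    def merged_with(self, other: "NetworkNode") -> "NetworkNode":
        # lexicographically smallest label keeps merging order-independent
        return NetworkNode(
            node_key=self.node_key,
            label=min(self.label, other.label),
            concept_type=self.concept_type,
            evidence_doc_ids=self.evidence_doc_ids | other.evidence_doc_ids,
        )


@dataclass
class NetworkEdge:
    source_key: str
    target_key: str
    relation_type: RelationType
    #: (doc_id, sentence_index, sentence_text), deduplicated on the first two.
    evidence: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def edge_key(self) -> tuple[str, str, str]:
        return (self.source_key, self.target_key, self.relation_type.value)


class MetNetwork:
    """Node/edge graph keyed on normalized concept identity."""

    def __init__(self) -> None:
        self.nodes: dict[str, NetworkNode] = {}
        self.edges: dict[tuple[str, str, str], NetworkEdge] = {}

    # -- construction ------------------------------------------------------

    def _add_node(self, mention: ConceptMention, doc_id: str) -> str:
        key = node_key(mention)
        node = NetworkNode(
            node_key=key,
            label=mention.surface,
            concept_type=mention.concept_type,
            evidence_doc_ids={doc_id},
        )
        if key in self.nodes:
            self.nodes[key] = self.nodes[key].merged_with(node)
        else:
            self.nodes[key] = node
        return key

    def add_relation(self, relation: RelationInstance) -> None:
        src = self._add_node(relation.subject, relation.doc_id)
        dst = self._add_node(relation.object, relation.doc_id)
        key = (src, dst, relation.relation_type.value)
        edge = self.edges.get(key)
        if edge is None:
            edge = NetworkEdge(src, dst, relation.relation_type)
            self.edges[key] = edge
        ev = (relation.doc_id, relation.sentence_index, relation.supporting_sentence_text)
        if not any(e[0] == ev[0] and e[1] == ev[1] for e in edge.evidence):
            edge.evidence.append(ev)
            edge.evidence.sort(key=lambda e: (e[0], e[1]))

    # -- algebra -----------------------------------------------------------

    def merge(self, other: "MetNetwork") -> "MetNetwork":
        out = MetNetwork()
        for net in (self, other):
            for key, node in net.nodes.items():
                if key in out.nodes:
                    out.nodes[key] = out.nodes[key].merged_with(node)
                else:
                    out.nodes[key] = NetworkNode(
                        node.node_key, node.label, node.concept_type,
                        set(node.evidence_doc_ids),
                    )
            for ekey, edge in net.edges.items():
                target = out.edges.get(ekey)
                if target is None:
                    target = NetworkEdge(edge.source_key, edge.target_key, edge.relation_type)
                    out.edges[ekey] = target
                for ev in edge.evidence:
                    if not any(e[0] == ev[0] and e[1] == ev[1] for e in target.evidence):
                        target.evidence.append(ev)
                target.evidence.sort(key=lambda e: (e[0], e[1]))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetNetwork):
            return NotImplemented
        return self.to_json_obj() == other.to_json_obj()

    # -- serialization -----------------------------------------------------

    def to_json_obj(self) -> dict:
        return {
            "nodes": [
                {
                    "node_key": n.node_key,
                    "label": n.label,
                    "concept_type": n.concept_type.value,
                    "evidence_doc_ids": sorted(n.evidence_doc_ids),
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.node_key)
            ],
            "edges": [
                {
                    "source_key": e.source_key,
                    "target_key": e.target_key,
                    "relation_type": e.relation_type.value,
                    "evidence": [
                        {"doc_id": d, "sentence_index": i, "sentence_text": t}
                        for d, i, t in e.evidence
                    ],
                }
                for e in sorted(self.edges.values(), key=lambda e: e.edge_key)
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_json_obj(), indent=indent, ensure_ascii=False) + "\n"

    @classmethod
    def from_json_obj(cls, data: dict) -> "MetNetwork":
        net = cls()
        try:
            for n in data["nodes"]:
                net.nodes[n["node_key"]] = NetworkNode(
                    node_key=n["node_key"],
                    label=n["label"],
                    concept_type=ConceptType(n["concept_type"]),
                    evidence_doc_ids=set(n["evidence_doc_ids"]),
                )
            for e in data["edges"]:
                edge = NetworkEdge(
                    source_key=e["source_key"],
                    target_key=e["target_key"],
                    relation_type=RelationType(e["relation_type"]),
                    evidence=[
                        (ev["doc_id"], int(ev["sentence_index"]), ev["sentence_text"])
                        for ev in e["evidence"]
                    ],
                )
                if edge.source_key not in net.nodes or edge.target_key not in net.nodes:
                    raise KeyError(f"dangling edge endpoint in {edge.edge_key}")
                net.edges[edge.edge_key] = edge
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid network JSON: {exc}") from exc
        return net

    @classmethod
    def from_json(cls, text: str) -> "MetNetwork":
        return cls.from_json_obj(json.loads(text))

    def to_graphml(self) -> str:
        graph = nx.MultiDiGraph()
        for node in sorted(self.nodes.values(), key=lambda n: n.node_key):
            graph.add_node(
                node.node_key,
                label=node.label,
                concept_type=node.concept_type.value,
                evidence_doc_ids=",".join(sorted(node.evidence_doc_ids)),
            )
        for edge in sorted(self.edges.values(), key=lambda e: e.edge_key):
            graph.add_edge(
                edge.source_key,
                edge.target_key,
                key=edge.relation_type.value,
                relation_type=edge.relation_type.value,
                evidence=json.dumps(
                    [
                        {"doc_id": d, "sentence_index": i, "sentence_text": t}
                        for d, i, t in edge.evidence
                    ],
                    ensure_ascii=False,
                ),
            )
        return "\n".join(nx.generate_graphml(graph)) + "\n"


def build_network(
    relations: Iterable[RelationInstance],
    events: Iterable[MetEvent] | None = None,
    doc_id: str | None = None,
) -> MetNetwork:
    """Build a per-document network from binary relations.

    ``events`` and ``doc_id`` are accepted for interface symmetry; nodes
    and edges are derived from the relations (events reference the same
    relations and add no extra edges).
    """
    net = MetNetwork()
    for relation in relations:
        if doc_id is not None and relation.doc_id != doc_id:
            continue
        net.add_relation(relation)
    return net


def integrate_networks(networks: Sequence[MetNetwork]) -> MetNetwork:
    """Node-key-based union of networks; evidence concatenated and deduped."""
    merged = MetNetwork()
    for net in networks:
        merged = merged.merge(net)
    return merged
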