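"""Map merging and overlap statistics.

Comparing a literature-curated map against maps built for other contexts
(another cell type's curation, or a reference pathway database import)
quantifies how specific the curated literature is: overlap is computed on
normalised symbols — node overlap on entity ids, edge overlap on the full
(source, target, relation_type) triple — relative to a named reference map,
with a symmetric Jaccard index alongside.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from pathring.model import (
    BioRelation,
    MapValidationError,
    PathwayMap,
)

__all__ = ["OverlapReport", "overlap_stats", "merge_maps"]


@dataclass
class OverlapReport:
    reference_name: str
    other_name: str
    shared_nodes: set[str] = field(default_factory=set)
    shared_edges: set[tuple[str, str, str]] = field(default_factory=set)
    node_overlap_pct_of_reference: float = 0.0
    edge_overlap_pct_of_reference: float = 0.0
    node_jaccard: float = 0.0
    edge_jaccard: float = 0.0

    def to_dict(self) -> dict:
        return {
            "reference_name": self.reference_name,
            "other_name": self.other_name,
            "shared_nodes": sorted(self.shared_nodes),
            "shared_edges": sorted(map(list, self.shared_edges)),
            "node_overlap_pct_of_reference": self.node_overlap_pct_of_reference,
            "edge_overlap_pct_of_reference": self.edge_overlap_pct_of_reference,
            "node_jaccard": self.node_jaccard,
            "edge_jaccard": self.edge_jaccard,
        }


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def overlap_stats(reference: PathwayMap, other: PathwayMap) -> OverlapReport:
    """Directional overlap of ``other`` with a named ``reference`` map.

    Node percentage = |shared nodes| / |reference nodes| × 100; edge
    percentage analogous on (source, target, relation_type) triples.
    """
    reference.validate()
    other.validate()
    ref_nodes = reference.entity_ids()
    if not ref_nodes:
        raise MapValidationError(
            f"reference map {reference.name!r} is empty; overlap percentage undefined"
        )
    shared_nodes = ref_nodes & other.entity_ids()
    ref_edges = reference.relation_keys()
    shared_edges = ref_edges & other.relation_keys()
    return OverlapReport(
        reference_name=reference.name,
        other_name=other.name,
        shared_nodes=shared_nodes,
        shared_edges=shared_edges,
        node_overlap_pct_of_reference=100.0 * len(shared_nodes) / len(ref_nodes),
        edge_overlap_pct_of_reference=(
            100.0 * len(shared_edges) / len(ref_edges) if ref_edges else 0.0
        ),
        node_jaccard=_jaccard(ref_nodes, other.entity_ids()),
        edge_jaccard=_jaccard(ref_edges, other.relation_keys()),
    )


def merge_maps(
    a: PathwayMap, b: PathwayMap, name: str | None = None
) -> tuple[PathwayMap, dict[str, dict]]:
    """Union of two maps with per-element origin annotation.

    Returns ``(merged, origin)`` where ``origin`` maps ``"entities"`` and
    ``"relations"`` to dicts of element → {"a_only", "b_only", "both"} —
    the sets a renderer highlights when displaying shared content.
    Shared relations concatenate and de-duplicate their evidence.  A shared
    entity id with conflicting classes is a conflict error.
    """
    a.validate()
    b.validate()
    conflicts = [
        eid
        for eid in a.entity_ids() & b.entity_ids()
        if a.entities[eid].entity_class is not b.entities[eid].entity_class
    ]
    if conflicts:
        raise MapValidationError(
            f"entity class conflict between {a.name!r} and {b.name!r} "
            f"for ids: {sorted(conflicts)}"
        )
    merged = PathwayMap(name=name or f"{a.name}+{b.name}")
    origin: dict[str, dict] = {"entities": {}, "relations": {}}
    for eid in a.entity_ids() | b.entity_ids():
        src = a if eid in a.entities else b
        ent = copy.deepcopy(src.entities[eid])
        if eid in a.entities and eid in b.entities:
            ent.synonyms = a.entities[eid].synonyms | b.entities[eid].synonyms
            origin["entities"][eid] = "both"
        else:
            origin["entities"][eid] = "a_only" if eid in a.entities else "b_only"
        merged.add_entity(ent)
    for key in a.relation_keys() | b.relation_keys():
        in_a, in_b = key in a.relations, key in b.relations
        base = a.relations[key] if in_a else b.relations[key]
        rel = BioRelation(
            source=base.source,
            target=base.target,
            relation_type=base.relation_type,
            evidence=list(base.evidence),
        )
        if in_a and in_b:
            for ev in b.relations[key].evidence:
                rel.add_evidence(ev)
            origin["relations"][key] = "both"
        else:
            origin["relations"][key] = "a_only" if in_a else "b_only"
        merged.add_relation(rel)
    merged.validate()
    return merged, origin
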