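"""Evidence-based sub-map extraction.

Two views onto a dense map: metadata filters (show only relations evidenced
by particular articles, organisms, techniques or disease models — combined
criteria are a conjunction that a single article must satisfy) and
anchor neighbourhoods (the sub-map within a given undirected distance of an
entity of interest, e.g. everything connected to the "ECM remodelling"
phenotype).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import networkx as nx

from pathring.model import (
    BioRelation,
    Evidence,
    MapValidationError,
    PathwayMap,
    normalize_symbol,
)

__all__ = ["FilterCriteria", "filter_map", "neighborhood_submap"]


@dataclass(frozen=True)
class FilterCriteria:
    """Conjunction of evidence-metadata constraints; unset fields match all."""

    pubmed_ids: frozenset[int] | None = None
    organisms: frozenset[str] | None = None
    techniques: frozenset[str] | None = None
    disease_models: frozenset[str] | None = None

    def __post_init__(self) -> None:
        coerce = lambda v, f: None if v is None else frozenset(f(x) for x in v)
        object.__setattr__(self, "pubmed_ids", coerce(self.pubmed_ids, int))
        for name in ("organisms", "techniques", "disease_models"):
            object.__setattr__(self, name, coerce(getattr(self, name), str))

    @property
    def is_empty(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in ("pubmed_ids", "organisms", "techniques", "disease_models")
        )

    def matches(self, ev: Evidence) -> bool:
        """True iff this single article satisfies every set constraint."""
        if self.pubmed_ids is not None and ev.pubmed_id not in self.pubmed_ids:
            return False
        if self.organisms is not None and ev.organism not in self.organisms:
            return False
        if self.techniques is not None and ev.technique not in self.techniques:
            return False
        if self.disease_models is not None and ev.disease_model not in self.disease_models:
            return False
        return True


def filter_map(pmap: PathwayMap, criteria: FilterCriteria) -> PathwayMap:
    """Sub-map of relations with ≥1 evidence record matching all criteria.

    Kept relations retain only their matching evidence; entities left with no
    incident relation are dropped.  The result is a valid map and a subgraph
    of the input.
    """
    if criteria.is_empty:
        raise MapValidationError("filter criteria must set at least one field")
    out = PathwayMap(name=f"{pmap.name}|filtered")
    kept_entities: set[str] = set()
    kept_relations: list[BioRelation] = []
    for rel in pmap.relations.values():
        evidence = [ev for ev in rel.evidence if criteria.matches(ev)]
        if evidence:
            kept_relations.append(
                BioRelation(
                    source=rel.source,
                    target=rel.target,
                    relation_type=rel.relation_type,
                    evidence=list(evidence),
                )
            )
            kept_entities.update((rel.source, rel.target))
    for eid in kept_entities:
        out.add_entity(copy.deepcopy(pmap.entities[eid]))
    for rel in kept_relations:
        out.add_relation(rel)
    out.validate()
    return out


def neighborhood_submap(
    pmap: PathwayMap, anchor: str, depth: int | float = math.inf
) -> PathwayMap:
    """Induced sub-map of entities within ``depth`` undirected steps of ``anchor``.

    ``depth`` may be ``math.inf`` (or any non-positive-int float) to take the
    whole connected component.  All relations among the kept entities are
    retained with their full evidence.
    """
    anchor_id = normalize_symbol(anchor)
    if anchor_id not in pmap.entities:
        raise KeyError(f"anchor entity {anchor!r} not in map {pmap.name!r}")
    g = nx.Graph()
    g.add_nodes_from(pmap.entities)
    g.add_edges_from((src, tgt) for src, tgt, _ in pmap.relations)
    cutoff = None if math.isinf(depth) else int(depth)
    reachable = set(nx.single_source_shortest_path_length(g, anchor_id, cutoff=cutoff))
    out = PathwayMap(name=f"{pmap.name}|near:{anchor_id}")
    for eid in reachable:
        out.add_entity(copy.deepcopy(pmap.entities[eid]))
    for (src, tgt, _), rel in pmap.relations.items():
        if src in reachable and tgt in reachable:
            out.add_relation(copy.deepcopy(rel))
    out.validate()
    return out
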