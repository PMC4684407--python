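"""Core pathway-map data model.

A :class:`PathwayMap` is a directed multigraph-free network: nodes are
:class:`BioEntity` objects (one of seven classes mirroring a cell's spatial
organisation, from drugs outside the cell down to phenotypes at the centre),
and edges are :class:`BioRelation` objects — "activates" or "inhibits" —
each supported by one or more :class:`Evidence` records describing the
article that reported it (PubMed ID, organism, technique, disease model).

Entity identifiers are normalised case-insensitively with whitespace and
hyphens stripped, so that symbol-style variants ("MMP-2", "Mmp2", "mmp 2")
resolve to the same node; this canonical key is what cross-map comparison
operates on.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "EntityClass",
    "RelationType",
    "BioEntity",
    "Evidence",
    "BioRelation",
    "PathwayMap",
    "MapValidationError",
    "normalize_symbol",
    "edge_weight",
    "literature_summary",
]


class MapValidationError(ValueError):
    """Raised when a map, entity, relation or evidence violates an invariant."""


class EntityClass(str, enum.Enum):
    """The seven bio-entity classes, ordered roughly outside-in."""

    DRUG = "drug"
    EXTRACELLULAR_PROTEIN = "extracellular_protein"
    PHYSIOLOGICAL_CONDITION = "physiological_condition"
    RECEPTOR = "receptor"
    INTRACELLULAR_PROTEIN = "intracellular_protein"
    GENE_EXPRESSION = "gene_expression"
    PHENOTYPE = "phenotype"

    @classmethod
    def coerce(cls, value: "EntityClass | str") -> "EntityClass":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise MapValidationError(
                f"unknown entity_class {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


class RelationType(str, enum.Enum):
    ACTIVATES = "activates"
    INHIBITS = "inhibits"

    @classmethod
    def coerce(cls, value: "RelationType | str") -> "RelationType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise MapValidationError(
                f"unknown relation_type {value!r}; expected 'activates' or 'inhibits'"
            ) from None


_NORM_RE = re.compile(r"[\s\-]+")


def normalize_symbol(symbol: str) -> str:
    """Canonical entity key: casefolded with whitespace and hyphens removed.

    >>> normalize_symbol("MMP-2") == normalize_symbol("Mmp 2")
    True
    """
    return _NORM_RE.sub("", str(symbol)).casefold()


@dataclass(frozen=True)
class Evidence:
    """One article's support for a bio-relation."""

    pubmed_id: int
    organism: str = "unknown"
    technique: str = "unknown"
    disease_model: str = "unknown"

    def __post_init__(self) -> None:
        if int(self.pubmed_id) <= 0:
            raise MapValidationError(f"pubmed_id must be positive, got {self.pubmed_id}")
        object.__setattr__(self, "pubmed_id", int(self.pubmed_id))
        for fname in ("organism", "technique", "disease_model"):
            val = str(getattr(self, fname)).strip()
            if not val:
                raise MapValidationError(f"evidence field {fname!r} must be non-empty")
            object.__setattr__(self, fname, val)


@dataclass
class BioEntity:
    """A named node with one of the seven classes."""

    id: str
    entity_class: EntityClass
    label: str = ""
    synonyms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        norm = normalize_symbol(self.id)
        if not norm:
            raise MapValidationError(f"entity id {self.id!r} normalises to empty")
        if not self.label:
            self.label = str(self.id)
        self.id = norm
        self.entity_class = EntityClass.coerce(self.entity_class)
        self.synonyms = frozenset(str(s) for s in self.synonyms)


@dataclass
class BioRelation:
    """A directed activates/inhibits edge carrying ≥1 evidence record."""

    source: str
    target: str
    relation_type: RelationType
    evidence: list[Evidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.source = normalize_symbol(self.source)
        self.target = normalize_symbol(self.target)
        self.relation_type = RelationType.coerce(self.relation_type)
        if not self.evidence:
            raise MapValidationError(
                f"relation {self.source}->{self.target} has no evidence"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation_type.value)

    def add_evidence(self, ev: Evidence) -> None:
        """Append an evidence record, dropping exact duplicates."""
        if ev not in self.evidence:
            self.evidence.append(ev)

    def pubmed_ids(self) -> set[int]:
        return {ev.pubmed_id for ev in self.evidence}


def edge_weight(relation: BioRelation) -> int:
    """Number of distinct articles citing the relation (drives arrow width)."""
    if not relation.evidence:
        raise MapValidationError("relation has empty evidence")
    return len(relation.pubmed_ids())


class PathwayMap:
    """A validated collection of entities and evidence-annotated relations.

    Entity ids are unique (after normalisation); at most one relation exists
    per (source, target, relation_type) triple — further citations of the
    same triple merge into that relation's evidence list.  Self-loops are
    allowed (autocrine signalling occurs in the literature) but warned about.
    """

    def __init__(self, name: str = "map") -> None:
        self.name = str(name)
        self.entities: dict[str, BioEntity] = {}
        self.relations: dict[tuple[str, str, str], BioRelation] = {}

    # -- construction -----------------------------------------------------

    def add_entity(self, entity: BioEntity) -> BioEntity:
        existing = self.entities.get(entity.id)
        if existing is not None:
            if existing.entity_class is not entity.entity_class:
                raise MapValidationError(
                    f"entity {entity.id!r} declared twice with conflicting classes "
                    f"{existing.entity_class.value!r} vs {entity.entity_class.value!r}"
                )
            existing.synonyms = existing.synonyms | entity.synonyms
            return existing
        self.entities[entity.id] = entity
        return entity

    def add_relation(self, relation: BioRelation) -> BioRelation:
        for endpoint in (relation.source, relation.target):
            if endpoint not in self.entities:
                raise MapValidationError(
                    f"relation references undeclared entity {endpoint!r}"
                )
        if relation.source == relation.target:
            warnings.warn(
                f"self-loop on {relation.source!r} (autocrine?)", stacklevel=2
            )
        existing = self.relations.get(relation.key)
        if existing is not None:
            for ev in relation.evidence:
                existing.add_evidence(ev)
            return existing
        self.relations[relation.key] = relation
        return relation

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.entities)

    def __contains__(self, entity_id: str) -> bool:
        return normalize_symbol(entity_id) in self.entities

    def __iter__(self) -> Iterator[BioEntity]:
        return iter(self.entities.values())

    def entity_ids(self) -> set[str]:
        return set(self.entities)

    def relation_keys(self) -> set[tuple[str, str, str]]:
        return set(self.relations)

    def articles(self) -> set[int]:
        """All distinct PubMed IDs cited anywhere in the map."""
        return {
            ev.pubmed_id for rel in self.relations.values() for ev in rel.evidence
        }

    def entities_of_class(self, entity_class: EntityClass | str) -> list[BioEntity]:
        cls = EntityClass.coerce(entity_class)
        return [e for e in self.entities.values() if e.entity_class is cls]

    def validate(self) -> None:
        """Re-check every invariant; raises MapValidationError on violation."""
        for key, rel in self.relations.items():
            if rel.key != key:
                raise MapValidationError(f"relation stored under wrong key {key}")
            for endpoint in (rel.source, rel.target):
                if endpoint not in self.entities:
                    raise MapValidationError(
                        f"relation endpoint {endpoint!r} missing from entities"
                    )
            if not rel.evidence:
                raise MapValidationError(f"relation {key} has no evidence")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayMap):
            return NotImplemented
        if self.entity_ids() != other.entity_ids():
            return False
        if self.relation_keys() != other.relation_keys():
            return False
        for eid, ent in self.entities.items():
            if ent.entity_class is not other.entities[eid].entity_class:
                return False
        for key, rel in self.relations.items():
            if set(rel.evidence) != set(other.relations[key].evidence):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"<PathwayMap {self.name!r}: {len(self.entities)} entities, "
            f"{len(self.relations)} relations, {len(self.articles())} articles>"
        )

    @classmethod
    def from_parts(
        cls,
        entities: Iterable[BioEntity],
        relations: Iterable[BioRelation] = (),
        name: str = "map",
    ) -> "PathwayMap":
        m = cls(name=name)
        for e in entities:
            m.add_entity(e)
        for r in relations:
            m.add_relation(r)
        return m


_FACET_FIELDS = {"organism", "technique", "disease_model"}


def literature_summary(pmap: PathwayMap, facet: str) -> pd.DataFrame:
    """Per-category article counts for one evidence facet.

    An article (distinct PubMed ID) counts toward a category if at least one
    of its evidence records carries that category; because a single article
    can report several protocols, the percentages can sum to more than 100.

    Returns a DataFrame with columns ``category``, ``article_count``,
    ``percent_of_articles``, sorted by descending count.
    """
    if facet not in _FACET_FIELDS:
        raise ValueError(f"facet must be one of {sorted(_FACET_FIELDS)}, got {facet!r}")
    per_category: dict[str, set[int]] = {}
    for rel in pmap.relations.values():
        for ev in rel.evidence:
            per_category.setdefault(getattr(ev, facet), set()).add(ev.pubmed_id)
    total = len(pmap.articles())
    rows = [
        {
            "category": cat,
            "article_count": len(pmids),
            "percent_of_articles": 100.0 * len(pmids) / total,
        }
        for cat, pmids in per_category.items()
    ]
    df = pd.DataFrame(rows, columns=["category", "article_count", "percent_of_articles"])
    return df.sort_values(
        ["article_count", "category"], ascending=[False, True], ignore_index=True
    )
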