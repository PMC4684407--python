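"""Curation-table I/O and standard graph exports.

The on-disk curation format is plain UTF-8 TSV with two sections — entity
declarations and one-evidence-per-row relation records:

.. code-block:: text

    [entities]
    id      label   entity_class    synonyms
    angii   Ang II  drug    angiotensin ii
    at1r    AT1R    receptor
    [relations]
    source_id       target_id       relation_type   pubmed_id       organism        technique       disease_model
    angii   at1r    activates       12345   rat     cell_culture    homeostasis

The two sections may equally live in two separate files.  Repeated relation
rows (same source, target, relation type) merge into one relation whose
evidence list accumulates the per-row citations, de-duplicated exactly.

Graph exports go through networkx: GraphML round-trips the full model
(classes, labels, per-edge relation type, article count and evidence
records), SIF keeps only the ``source relation target`` topology.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx

from pathring.model import (
    BioEntity,
    BioRelation,
    EntityClass,
    Evidence,
    MapValidationError,
    PathwayMap,
    RelationType,
    edge_weight,
)

__all__ = [
    "CurationParseError",
    "read_curation_table",
    "write_curation_table",
    "to_networkx",
    "from_networkx",
    "export_graph",
    "read_graphml",
    "read_sif",
]

ENTITY_COLUMNS = ("id", "label", "entity_class", "synonyms")
RELATION_COLUMNS = (
    "source_id",
    "target_id",
    "relation_type",
    "pubmed_id",
    "organism",
    "technique",
    "disease_model",
)


class CurationParseError(ValueError):
    """A malformed curation-table row; the message names file and line."""


def _parse_sections(path: Path) -> dict[str, list[tuple[int, list[str]]]]:
    """Split a TSV file into named ``[section]`` blocks of (lineno, fields)."""
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current: list[tuple[int, list[str]]] | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            name = stripped[1:-1].strip().lower()
            current = sections.setdefault(name, [])
            continue
        if current is None:
            raise CurationParseError(
                f"{path}:{lineno}: data before any [entities]/[relations] section"
            )
        current.append((lineno, line.split("\t")))
    return sections


def _strip_header(
    rows: list[tuple[int, list[str]]], columns: Sequence[str]
) -> list[tuple[int, list[str]]]:
    if rows and [c.strip().lower() for c in rows[0][1][: len(columns)]] == list(
        columns[: len(rows[0][1])]
    ):
        return rows[1:]
    return rows


def _parse_entity_row(path: Path, lineno: int, fields: list[str]) -> BioEntity:
    if len(fields) < 3 or not fields[0].strip():
        raise CurationParseError(
            f"{path}:{lineno}: entity row needs at least id, label, entity_class "
            f"(got {len(fields)} fields)"
        )
    synonyms = frozenset(
        s.strip() for s in (fields[3].split("|") if len(fields) > 3 and fields[3] else [])
        if s.strip()
    )
    try:
        return BioEntity(
            id=fields[0],
            label=fields[1].strip() or fields[0],
            entity_class=fields[2],
            synonyms=synonyms,
        )
    except MapValidationError as exc:
        raise CurationParseError(f"{path}:{lineno}: {exc}") from exc


def _parse_relation_row(
    path: Path, lineno: int, fields: list[str]
) -> tuple[str, str, str, Evidence]:
    if len(fields) < 4:
        raise CurationParseError(
            f"{path}:{lineno}: relation row needs source_id, target_id, "
            f"relation_type, pubmed_id (got {len(fields)} fields)"
        )
    try:
        pmid = int(fields[3])
    except ValueError:
        raise CurationParseError(
            f"{path}:{lineno}: pubmed_id {fields[3]!r} is not an integer"
        ) from None
    padded = fields + ["unknown"] * (7 - len(fields))
    try:
        ev = Evidence(
            pubmed_id=pmid,
            organism=padded[4] or "unknown",
            technique=padded[5] or "unknown",
            disease_model=padded[6] or "unknown",
        )
        RelationType.coerce(fields[2])
    except MapValidationError as exc:
        raise CurationParseError(f"{path}:{lineno}: {exc}") from exc
    return fields[0], fields[1], fields[2], ev


def read_curation_table(
    path: str | Path,
    relations_path: str | Path | None = None,
    name: str | None = None,
) -> PathwayMap:
    """Read a curation table into a validated :class:`PathwayMap`.

    ``path`` may hold both ``[entities]`` and ``[relations]`` sections, or the
    entities alone with the relations in ``relations_path``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curation table not found: {path}")
    if relations_path is None:
        sections = _parse_sections(path)
        entity_rows = sections.get("entities", [])
        relation_rows = sections.get("relations", [])
        rel_path = path
    else:
        rel_path = Path(relations_path)
        if not rel_path.exists():
            raise FileNotFoundError(f"relations table not found: {rel_path}")
        entity_rows = [
            (lineno, line.split("\t"))
            for lineno, line in enumerate(
                path.read_text(encoding="utf-8").splitlines(), 1
            )
            if line.strip() and not line.lstrip().startswith(("#", "["))
        ]
        relation_rows = [
            (lineno, line.split("\t"))
            for lineno, line in enumerate(
                rel_path.read_text(encoding="utf-8").splitlines(), 1
            )
            if line.strip() and not line.lstrip().startswith(("#", "["))
        ]
    entity_rows = _strip_header(entity_rows, ENTITY_COLUMNS)
    relation_rows = _strip_header(relation_rows, RELATION_COLUMNS)

    pmap = PathwayMap(name=name or path.stem)
    for lineno, fields in entity_rows:
        pmap.add_entity(_parse_entity_row(path, lineno, fields))
    for lineno, fields in relation_rows:
        src, tgt, rtype, ev = _parse_relation_row(rel_path, lineno, fields)
        try:
            pmap.add_relation(
                BioRelation(source=src, target=tgt, relation_type=rtype, evidence=[ev])
            )
        except MapValidationError as exc:
            raise CurationParseError(f"{rel_path}:{lineno}: {exc}") from exc
    pmap.validate()
    return pmap


def write_curation_table(pmap: PathwayMap, path: str | Path) -> Path:
    """Write a map as a single two-section TSV; inverse of read_curation_table."""
    path = Path(path)
    lines = ["[entities]", "\t".join(ENTITY_COLUMNS)]
    for ent in sorted(pmap.entities.values(), key=lambda e: e.id):
        lines.append(
            "\t".join(
                [ent.id, ent.label, ent.entity_class.value, "|".join(sorted(ent.synonyms))]
            )
        )
    lines.append("[relations]")
    lines.append("\t".join(RELATION_COLUMNS))
    for key in sorted(pmap.relations):
        rel = pmap.relations[key]
        for ev in sorted(rel.evidence, key=lambda e: (e.pubmed_id, e.organism)):
            lines.append(
                "\t".join(
                    [
                        rel.source,
                        rel.target,
                        rel.relation_type.value,
                        str(ev.pubmed_id),
                        ev.organism,
                        ev.technique,
                        ev.disease_model,
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# -- networkx bridge and exports ------------------------------------------


def to_networkx(pmap: PathwayMap) -> nx.DiGraph:
    """Directed graph with full model attributes on nodes and edges."""
    g = nx.DiGraph(name=pmap.name)
    for ent in pmap.entities.values():
        g.add_node(
            ent.id,
            label=ent.label,
            entity_class=ent.entity_class.value,
            synonyms="|".join(sorted(ent.synonyms)),
        )
    for rel in pmap.relations.values():
        g.add_edge(
            rel.source,
            rel.target,
            relation_type=rel.relation_type.value,
            weight=edge_weight(rel),
            pubmed_ids="|".join(str(p) for p in sorted(rel.pubmed_ids())),
            evidence=json.dumps(
                [
                    [ev.pubmed_id, ev.organism, ev.technique, ev.disease_model]
                    for ev in rel.evidence
                ]
            ),
        )
    return g


def from_networkx(g: nx.DiGraph, name: str | None = None) -> PathwayMap:
    pmap = PathwayMap(name=name or g.graph.get("name", "map"))
    for node, attrs in g.nodes(data=True):
        syns = attrs.get("synonyms", "")
        pmap.add_entity(
            BioEntity(
                id=str(node),
                label=attrs.get("label", str(node)),
                entity_class=attrs.get(
                    "entity_class", EntityClass.INTRACELLULAR_PROTEIN
                ),
                synonyms=frozenset(s for s in str(syns).split("|") if s),
            )
        )
    for src, tgt, attrs in g.edges(data=True):
        if "evidence" in attrs:
            evidence = [
                Evidence(pubmed_id=p, organism=o, technique=t, disease_model=d)
                for p, o, t, d in json.loads(attrs["evidence"])
            ]
        else:
            evidence = [
                Evidence(pubmed_id=int(p))
                for p in str(attrs.get("pubmed_ids", "1")).split("|")
            ]
        pmap.add_relation(
            BioRelation(
                source=str(src),
                target=str(tgt),
                relation_type=attrs.get("relation_type", "activates"),
                evidence=evidence,
            )
        )
    pmap.validate()
    return pmap


def export_graph(pmap: PathwayMap, fmt: str, path: str | Path) -> Path:
    """Export to ``graphml`` (full fidelity) or ``sif`` (topology only)."""
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(to_networkx(pmap), path)
    elif fmt == "sif":
        lines = [
            f"{src}\t{rtype}\t{tgt}" for src, tgt, rtype in sorted(pmap.relations)
        ]
        orphans = pmap.entity_ids() - {
            e for key in pmap.relations for e in key[:2]
        }
        lines.extend(sorted(orphans))
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'sif'")
    return path


def read_graphml(path: str | Path, name: str | None = None) -> PathwayMap:
    return from_networkx(nx.read_graphml(Path(path)), name=name)


def read_sif(
    path: str | Path,
    name: str | None = None,
    default_class: EntityClass | str = EntityClass.INTRACELLULAR_PROTEIN,
) -> PathwayMap:
    """Read a SIF node/edge list, e.g. an exported reference-database pathway.

    Entity classes are not representable in SIF; every node gets
    ``default_class``.  Rows without a known PubMed ID get a placeholder
    evidence record (pubmed_id=1, all facets "unknown").
    """
    path = Path(path)
    pmap = PathwayMap(name=name or path.stem)
    cls = EntityClass.coerce(default_class)
    rows: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            pmap.add_entity(BioEntity(id=fields[0], entity_class=cls))
        elif len(fields) >= 3:
            for node in (fields[0], *fields[2:]):
                pmap.add_entity(BioEntity(id=node, entity_class=cls))
            for tgt in fields[2:]:
                rows.append((fields[0], tgt, fields[1]))
        else:
            raise CurationParseError(
                f"{path}:{lineno}: SIF row needs 1 or ≥3 fields, got {len(fields)}"
            )
    for src, tgt, rtype in rows:
        pmap.add_relation(
            BioRelation(
                source=src, target=tgt, relation_type=rtype, evidence=[Evidence(1)]
            )
        )
    pmap.validate()
    return pmap
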