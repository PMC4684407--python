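"""Concentric-ring polar layout.

Every node's position is a (radius, angle) pair.  The radius is fixed by the
entity class — mimicking a cell's spatial organisation, with phenotypes at
the centre and drugs/extracellular proteins on the outermost ring — except
intracellular proteins, which are spread over four inner rings by drawing a
uniform random integer radius in [4, 7].  Within each ring the nodes are
spaced uniformly: the i-th node (0-based, ordered lexicographically by id)
of a ring holding S(r) nodes sits at angle 360/S(r)·i degrees.  The pair is
then converted to Cartesian coordinates x = r·cos θ, y = r·sin θ.

The layout is a pure function of (map, seed): the random stream for the
intracellular radii consumes one draw per intracellular protein in
lexicographic id order, so inserting entities of other classes never
perturbs existing positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pathring.model import EntityClass, MapValidationError, PathwayMap

__all__ = [
    "CLASS_RADII",
    "INTRACELLULAR_RADIUS_RANGE",
    "LayoutPoint",
    "LayoutResult",
    "assign_radius",
    "assign_angles",
    "polar_to_cartesian",
    "layout_map",
]

#: Fixed ring radius per class; intracellular proteins are randomised instead.
CLASS_RADII: dict[EntityClass, int] = {
    EntityClass.PHENOTYPE: 2,
    EntityClass.GENE_EXPRESSION: 3,
    EntityClass.RECEPTOR: 8,
    EntityClass.PHYSIOLOGICAL_CONDITION: 9,
    EntityClass.DRUG: 10,
    EntityClass.EXTRACELLULAR_PROTEIN: 10,
}

#: Inclusive radius range for intracellular proteins.
INTRACELLULAR_RADIUS_RANGE: tuple[int, int] = (4, 7)


@dataclass(frozen=True)
class LayoutPoint:
    entity_id: str
    radius: float
    angle: float  # degrees, in [0, 360)
    x: float
    y: float


@dataclass
class LayoutResult:
    """Positions for every entity of a laid-out map, plus the ring census S(r)."""

    points: dict[str, LayoutPoint] = field(default_factory=dict)
    seed: int = 0
    ring_census: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "ring_census": {str(r): n for r, n in sorted(self.ring_census.items())},
            "points": [
                {
                    "entity_id": p.entity_id,
                    "radius": p.radius,
                    "angle_degrees": p.angle,
                    "x": p.x,
                    "y": p.y,
                }
                for p in sorted(self.points.values(), key=lambda p: p.entity_id)
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return path


def assign_radius(
    entity_class: EntityClass | str, rng: np.random.Generator
) -> int:
    """Ring radius for one entity; consumes one draw only for intracellular proteins."""
    cls = EntityClass.coerce(entity_class)
    if cls is EntityClass.INTRACELLULAR_PROTEIN:
        lo, hi = INTRACELLULAR_RADIUS_RANGE
        return int(rng.integers(lo, hi + 1))
    try:
        return CLASS_RADII[cls]
    except KeyError:  # pragma: no cover - enum is exhaustive
        raise MapValidationError(f"no radius rule for class {cls!r}") from None


def assign_angles(n_nodes: int) -> list[float]:
    """Uniform angular positions [360/n·i for i in 0..n-1] in degrees."""
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be ≥ 1, got {n_nodes}")
    return [360.0 / n_nodes * i for i in range(n_nodes)]


def polar_to_cartesian(radius: float, angle_degrees: float) -> tuple[float, float]:
    if radius < 0:
        raise ValueError(f"radius must be ≥ 0, got {radius}")
    theta = math.radians(angle_degrees)
    return radius * math.cos(theta), radius * math.sin(theta)


def layout_map(pmap: PathwayMap, seed: int = 0) -> LayoutResult:
    """Lay out a whole map deterministically.

    Radii are assigned in within-class lexicographic id order (the
    intracellular random stream is consumed in that order); each integer
    radius is its own ring for the angle computation.
    """
    pmap.validate()
    rng = np.random.default_rng(seed)
    radii: dict[str, int] = {}
    # fixed-radius classes first, then intracellular in lexicographic order
    for ent in sorted(pmap.entities.values(), key=lambda e: e.id):
        if ent.entity_class is not EntityClass.INTRACELLULAR_PROTEIN:
            radii[ent.id] = assign_radius(ent.entity_class, rng)
    for ent in sorted(
        pmap.entities_of_class(EntityClass.INTRACELLULAR_PROTEIN),
        key=lambda e: e.id,
    ):
        radii[ent.id] = assign_radius(ent.entity_class, rng)

    rings: dict[int, list[str]] = {}
    for eid, r in radii.items():
        rings.setdefault(r, []).append(eid)

    result = LayoutResult(seed=seed, ring_census={r: len(ids) for r, ids in rings.items()})
    for r, ids in rings.items():
        ids.sort()
        for eid, angle in zip(ids, assign_angles(len(ids))):
            x, y = polar_to_cartesian(r, angle)
            result.points[eid] = LayoutPoint(
                entity_id=eid, radius=float(r), angle=angle, x=x, y=y
            )
    return result
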