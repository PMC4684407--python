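"""Static rendering of a laid-out map (SVG/PNG via matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from pathring.layout import LayoutResult
from pathring.model import EntityClass, PathwayMap, RelationType, edge_weight

__all__ = ["CLASS_COLORS", "render_layout"]

# node colours by class, matching the concentric-ring convention
CLASS_COLORS: dict[EntityClass, str] = {
    EntityClass.DRUG: "#d62728",  # red
    EntityClass.EXTRACELLULAR_PROTEIN: "#7f7f7f",  # grey
    EntityClass.PHYSIOLOGICAL_CONDITION: "#ff7f0e",  # orange
    EntityClass.RECEPTOR: "#2ca02c",  # green
    EntityClass.INTRACELLULAR_PROTEIN: "#7f7f7f",  # grey
    EntityClass.GENE_EXPRESSION: "#17becf",  # cyan
    EntityClass.PHENOTYPE: "#ffdd44",  # yellow
}


def render_layout(
    pmap: PathwayMap,
    layout: LayoutResult,
    path: str | Path,
    node_colors: dict[str, str] | None = None,
    with_labels: bool = True,
) -> Path:
    """Draw nodes on their rings and evidence-weighted arrows between them.

    Arrow width grows with the number of citing articles; "inhibits" edges
    are dashed.  ``node_colors`` (entity id → hex colour) overrides the class
    palette, e.g. for a fold-change overlay.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 8))
    for rel in pmap.relations.values():
        p1, p2 = layout.points[rel.source], layout.points[rel.target]
        ax.annotate(
            "",
            xy=(p2.x, p2.y),
            xytext=(p1.x, p1.y),
            arrowprops=dict(
                arrowstyle="-|>",
                lw=0.5 + 0.5 * edge_weight(rel),
                linestyle="--" if rel.relation_type is RelationType.INHIBITS else "-",
                color="#555555",
                alpha=0.6,
            ),
        )
    for ent in pmap.entities.values():
        pt = layout.points[ent.id]
        color = (node_colors or {}).get(ent.id, CLASS_COLORS[ent.entity_class])
        ax.scatter([pt.x], [pt.y], s=120, c=color, edgecolors="black", zorder=3)
        if with_labels:
            ax.annotate(
                ent.label, (pt.x, pt.y), textcoords="offset points",
                xytext=(4, 4), fontsize=7,
            )
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
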