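"""Synthetic curation tables and expression matrices with known ground truth.

The map generator emulates the statistical shape of a literature-curated
pathway map: requested counts per entity class, random directed
activates/inhibits relations, and per-relation evidence whose categorical
metadata follow configurable facet distributions.  The defaults mirror the
published literature profile of the cardiac-fibroblast corpus: organisms
rat-heavy (rat 0.66), techniques cell-culture-heavy (0.60), disease models
split between homeostasis and fibrosis.

The expression generator emulates a small two-group microarray comparison
(defaults: 3 vs 3 samples): log2-scale values are a per-feature baseline
plus Gaussian noise, with a stated log2 fold-change added to group 1 for the
planted features.  Both generators are pure functions of their spec + seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pathring.model import (
    BioEntity,
    BioRelation,
    EntityClass,
    Evidence,
    PathwayMap,
)
from pathring.overlay import ExpressionMatrix

__all__ = ["MapSimSpec", "ExprSimSpec", "synth_map", "synth_expression"]

# Facet profiles mimicking the curated-literature evidence distributions
DEFAULT_ORGANISM_PROBS = {"rat": 0.66, "mouse": 0.22, "human": 0.12}
DEFAULT_TECHNIQUE_PROBS = {"cell_culture": 0.60, "in_vivo": 0.30, "in_vitro": 0.10}
DEFAULT_DISEASE_PROBS = {"homeostasis": 0.45, "fibrosis": 0.35, "other": 0.20}

DEFAULT_CLASS_COUNTS = {
    EntityClass.DRUG: 3,
    EntityClass.EXTRACELLULAR_PROTEIN: 6,
    EntityClass.PHYSIOLOGICAL_CONDITION: 2,
    EntityClass.RECEPTOR: 6,
    EntityClass.INTRACELLULAR_PROTEIN: 12,
    EntityClass.GENE_EXPRESSION: 6,
    EntityClass.PHENOTYPE: 3,
}


def _check_probs(name: str, probs: dict[str, float]) -> None:
    if not probs or abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must sum to 1, got {probs}")


@dataclass
class MapSimSpec:
    """Recipe for one synthetic pathway map."""

    class_counts: dict[EntityClass, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_relations: int = 40
    organism_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGANISM_PROBS)
    )
    technique_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TECHNIQUE_PROBS)
    )
    disease_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_PROBS)
    )
    #: probability of each extra citation count 1, 2, 3, ... per relation
    citations_probs: tuple[float, ...] = (0.6, 0.25, 0.1, 0.05)
    seed: int = 0

    def validate(self) -> None:
        coerced = {}
        for cls, count in self.class_counts.items():
            if count < 0:
                raise ValueError(f"negative count for class {cls}")
            coerced[EntityClass.coerce(cls)] = int(count)
        self.class_counts = coerced
        _check_probs("organism", self.organism_probs)
        _check_probs("technique", self.technique_probs)
        _check_probs("disease_model", self.disease_probs)
        _check_probs("citations", dict(enumerate(self.citations_probs)))
        n = sum(self.class_counts.values())
        # activates + inhibits per ordered pair incl. self-loops
        max_relations = 2 * n * n
        if self.n_relations > max_relations:
            raise ValueError(
                f"n_relations={self.n_relations} exceeds the {max_relations} "
                f"possible unique (source, target, type) triples for {n} entities"
            )


def _draw(rng: np.random.Generator, probs: dict[str, float]) -> str:
    cats = list(probs)
    return cats[rng.choice(len(cats), p=list(probs.values()))]


def synth_map(spec: MapSimSpec) -> tuple[PathwayMap, pd.DataFrame]:
    """Generate a valid map plus a ground-truth evidence table.

    The truth table has one row per evidence record with columns
    source, target, relation_type, pubmed_id, organism, technique,
    disease_model — exactly what the curation-table reader ingests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pmap = PathwayMap(name=f"synthetic-{spec.seed}")
    for cls, count in spec.class_counts.items():
        for i in range(count):
            pmap.add_entity(
                BioEntity(id=f"{cls.value}_{i:03d}", entity_class=cls)
            )
    ids = sorted(pmap.entity_ids())
    n = len(ids)
    triples: list[tuple[str, str, str]] = []
    if spec.n_relations and n:
        all_triples = n * n * 2
        chosen = rng.choice(all_triples, size=spec.n_relations, replace=False)
        for code in sorted(chosen):
            rtype = "activates" if code % 2 == 0 else "inhibits"
            pair = code // 2
            triples.append((ids[pair // n], ids[pair % n], rtype))
    next_pmid = itertools.count(10_000_001)
    rows = []
    for src, tgt, rtype in triples:
        n_cites = 1 + int(
            rng.choice(len(spec.citations_probs), p=list(spec.citations_probs))
        )
        evidence = [
            Evidence(
                pubmed_id=next(next_pmid),
                organism=_draw(rng, spec.organism_probs),
                technique=_draw(rng, spec.technique_probs),
                disease_model=_draw(rng, spec.disease_probs),
            )
            for _ in range(n_cites)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # synthetic self-loops are expected
            pmap.add_relation(
                BioRelation(source=src, target=tgt, relation_type=rtype, evidence=evidence)
            )
        rows.extend(
            {
                "source": src,
                "target": tgt,
                "relation_type": rtype,
                "pubmed_id": ev.pubmed_id,
                "organism": ev.organism,
                "technique": ev.technique,
                "disease_model": ev.disease_model,
            }
            for ev in evidence
        )
    pmap.validate()
    truth = pd.DataFrame(
        rows,
        columns=[
            "source",
            "target",
            "relation_type",
            "pubmed_id",
            "organism",
            "technique",
            "disease_model",
        ],
    )
    return pmap, truth


@dataclass
class ExprSimSpec:
    """Recipe for one synthetic two-group expression matrix.

    Defaults emulate the study design this pipeline targets: 3 samples per
    group, Gaussian log2-scale noise of SD 0.5, baselines drawn so that
    linear-scale signals are log-normal.
    """

    n_features: int = 1000
    n_per_group: int = 3
    planted_features: dict[str, float] = field(default_factory=dict)
    #: explicit feature ids (e.g. map entity ids so nulls can live in the map);
    #: when None, ids are the planted names plus auto-numbered fillers
    feature_pool: list[str] | None = None
    noise_sd: float = 0.5
    baseline_mean: float = 7.0  # log2 units
    baseline_sd: float = 2.0
    group_labels: tuple[str, str] = ("CFb", "TFb")
    feature_prefix: str = "gene"
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_per_group < 2:
            raise ValueError("need ≥2 samples per group")
        known = set(self.feature_ids())
        stray = set(self.planted_features) - known
        if stray:
            raise ValueError(f"planted features not in feature ids: {sorted(stray)}")

    def feature_ids(self) -> list[str]:
        if self.feature_pool is not None:
            return list(self.feature_pool)
        named = list(self.planted_features)
        auto = [
            f"{self.feature_prefix}{i:05d}"
            for i in range(self.n_features - len(named))
        ]
        return named + auto


def synth_expression(spec: ExprSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a log2-scale matrix plus a truth table of planted effects.

    values = baseline(feature) + effect·[group==group1] + N(0, noise_sd²);
    only planted features have a non-zero effect, added to group 1.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    features = spec.feature_ids()
    n = len(features)
    n1 = n2 = spec.n_per_group
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    noise = rng.normal(0.0, spec.noise_sd, size=(n, n1 + n2))
    effect = np.array([spec.planted_features.get(f, 0.0) for f in features])
    values = baseline[:, None] + noise
    values[:, :n1] += effect[:, None]
    g1, g2 = spec.group_labels
    samples = [f"{g1}_{i+1}" for i in range(n1)] + [f"{g2}_{i+1}" for i in range(n2)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=samples),
        groups=pd.Series([g1] * n1 + [g2] * n2, index=samples),
        log2_scale=True,
    )
    truth = pd.DataFrame(
        {
            "feature_id": list(spec.planted_features),
            "true_log2_fc": list(spec.planted_features.values()),
        }
    )
    return matrix, truth
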