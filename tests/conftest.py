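import pytest

from pathring.model import (
    BioEntity,
    BioRelation,
    Evidence,
    PathwayMap,
)


def make_toy_map() -> PathwayMap:
    """A small cardiac-flavoured map touching all seven entity classes."""
    entities = [
        BioEntity("AngII", "drug", label="Ang II"),
        BioEntity("TGFb", "extracellular_protein", label="TGF-beta"),
        BioEntity("PressureOverload", "physiological_condition"),
        BioEntity("AT1R", "receptor"),
        BioEntity("TGFBR1", "receptor"),
        BioEntity("MMP-2", "intracellular_protein", label="MMP-2"),
        BioEntity("Smad3", "intracellular_protein"),
        BioEntity("Col1a1", "gene_expression"),
        BioEntity("ECM remodelling", "phenotype"),
    ]
    relations = [
        BioRelation("AngII", "AT1R", "activates",
                    [Evidence(101, "rat", "cell_culture", "homeostasis"),
                     Evidence(102, "mouse", "in_vivo", "fibrosis")]),
        BioRelation("AT1R", "MMP-2", "activates",
                    [Evidence(102, "mouse", "in_vivo", "fibrosis")]),
        BioRelation("MMP-2", "ECM remodelling", "activates",
                    [Evidence(103, "human", "in_vitro", "other"),
                     Evidence(101, "rat", "cell_culture", "homeostasis")]),
        BioRelation("TGFb", "TGFBR1", "activates",
                    [Evidence(104, "rat", "cell_culture", "fibrosis")]),
        BioRelation("TGFBR1", "Smad3", "activates",
                    [Evidence(104, "rat", "cell_culture", "fibrosis")]),
        BioRelation("Smad3", "Col1a1", "activates",
                    [Evidence(105, "mouse", "in_vivo", "homeostasis")]),
        BioRelation("PressureOverload", "TGFb", "activates",
                    [Evidence(106, "rat", "in_vivo", "fibrosis")]),
        BioRelation("Smad3", "MMP-2", "inhibits",
                    [Evidence(103, "human", "in_vitro", "other")]),
    ]
    return PathwayMap.from_parts(entities, relations, name="toy")


@pytest.fixture
def toy_map() -> PathwayMap:
    return make_toy_map()
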