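import pytest

from relrank import (
    Document,
    EntityId,
    EntityType,
    GoldRelation,
    GoldRelationSet,
    TermEntry,
)


@pytest.fixture
def drug_d1():
    return EntityId("D1", EntityType.DRUG)


@pytest.fixture
def gene_g1():
    return EntityId("G1", EntityType.GENE)


@pytest.fixture
def tiny_dictionary():
    return [
        TermEntry("aspirin", EntityId("D1", EntityType.DRUG)),
        TermEntry("acetylsalicylic acid", EntityId("D1", EntityType.DRUG)),
        TermEntry("ptgs2", EntityId("G1", EntityType.GENE)),
        TermEntry("cox-2", EntityId("G1", EntityType.GENE)),
        TermEntry("fc gamma receptor", EntityId("G2", EntityType.GENE)),
        TermEntry("asthma", EntityId("Di1", EntityType.DISEASE)),
        # ambiguous surface: two genes share "neuronal"
        TermEntry("neuronal", EntityId("G3", EntityType.GENE)),
        TermEntry("neuronal", EntityId("G4", EntityType.GENE)),
    ]


@pytest.fixture
def tiny_doc():
    return Document(
        doc_id="d1",
        title="Aspirin inhibits PTGS2",
        abstract=(
            "Aspirin reduces asthma symptoms. The Fc ( gamma ) - receptor "
            "binds aspirin. Neuronal effects were seen."
        ),
        mesh=[("Asthma", ["drug therapy"])],
        chemicals=["Aspirin"],
    )


@pytest.fixture
def tiny_gold():
    return GoldRelationSet(
        [
            GoldRelation(
                "d1",
                EntityId("D1", EntityType.DRUG),
                EntityId("G1", EntityType.GENE),
            ),
            GoldRelation(
                "d1",
                EntityId("D1", EntityType.DRUG),
                EntityId("Di1", EntityType.DISEASE),
            ),
        ]
    )
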