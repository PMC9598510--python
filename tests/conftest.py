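import pytest

from crossddi.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One default-configuration synthetic dataset shared across the session."""
    out = tmp_path_factory.mktemp("synth_default")
    truth = generate_dataset(SyntheticConfig(seed=20260926), out)
    return out, truth


@pytest.fixture
def toy_interactome_inputs():
    """Hand-sized instance: p1:{A}, p2:{A,B}; g1:{X}, g2:{Y}; DDI {(A,X),(B,Y)}."""
    from crossddi.cancer_catalog import CancerCatalog, CancerGene
    from crossddi.core_io import DDIEntry, DDITable, DomainAnnotation

    annotations = [
        DomainAnnotation("p1", "A"),
        DomainAnnotation("p2", "A"),
        DomainAnnotation("p2", "B"),
    ]
    catalog = CancerCatalog(
        [
            CancerGene("g1", "TSG", frozenset({"X"})),
            CancerGene("g2", "OCG", frozenset({"Y"})),
        ]
    )
    ddi = DDITable([DDIEntry.make("A", "X"), DDIEntry.make("B", "Y")])
    return annotations, catalog, ddi
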