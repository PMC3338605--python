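import pytest

from pathlinker.analysis import PathwayCollection
from pathlinker.model import Interaction, ProteinRef, build_network


def star_network(center="Q", n_leaves=9, species="worm",
                 source="BioGRID", evidence="small_scale_physical"):
    leaves = [f"N{i}" for i in range(1, n_leaves + 1)]
    proteins = [ProteinRef(center, species=species)] + [
        ProteinRef(x, species=species) for x in leaves
    ]
    interactions = [
        Interaction(center, x, frozenset({source}), frozenset({evidence}))
        for x in leaves
    ]
    return build_network(interactions, proteins)


@pytest.fixture
def star9():
    return star_network()


@pytest.fixture
def small_collection():
    return PathwayCollection(
        pathways={
            ("SignaLink", "WNT"): frozenset({"N1", "N2", "Z1"}),
            ("KEGG", "MAPK"): frozenset({"N3", "Z2", "Z3"}),
        },
        universe_size=100,
    )
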