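import networkx as nx
import pytest

from reprognet.interactome import Interactome
from reprognet.io import ChemTargetRecord


def make_interactome(edges) -> Interactome:
    return Interactome.from_edges(edges)


@pytest.fixture
def triangle() -> Interactome:
    return make_interactome([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def two_pairs() -> Interactome:
    return make_interactome([("A", "B"), ("C", "D")])


@pytest.fixture
def path10() -> Interactome:
    return make_interactome([(f"V{i}", f"V{i+1}") for i in range(1, 10)])


@pytest.fixture
def two_cliques25() -> Interactome:
    g = nx.disjoint_union(nx.complete_graph(25), nx.complete_graph(25))
    return Interactome(nx.relabel_nodes(g, lambda i: f"N{i:02d}"))


def chem_record(chemical, protein, combined=0.9) -> ChemTargetRecord:
    return ChemTargetRecord(
        chemical_id=chemical,
        protein=protein,
        channel_scores={
            "experimental": combined,
            "database": 0.0,
            "textmining": 0.0,
            "prediction": 0.0,
        },
        combined_score=combined,
    )
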