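"""Shared fixtures: hand-sized graphs and a small synthetic dataset."""

from __future__ import annotations

import networkx as nx
import pytest

import pathscreen.synthetic as syn
from pathscreen.io_formats import (
    DrugTargetMap,
    GeneSetCollection,
    Interactome,
    PhenotypeCatalog,
)


@pytest.fixture
def toy_interactome() -> Interactome:
    """Hand graph with known path products from target T.

    Downstream of T at depth <= 2: A = 0.9 (direct), B = 0.4 (direct),
    C = 0.9 * 0.8 = 0.72 (via A). D is 3 hops away, unreachable at depth 2.
    """
    g = nx.Graph()
    g.add_edge("T", "A", score=0.9)
    g.add_edge("T", "B", score=0.4)
    g.add_edge("A", "C", score=0.8)
    g.add_edge("C", "D", score=0.9)
    return Interactome(g)


@pytest.fixture
def toy_catalog() -> PhenotypeCatalog:
    return PhenotypeCatalog(
        entries={
            "phenotype one": {"A", "B", "C"},
            "phenotype two": {"D"},
            "phenotype three": {"T", "A"},
        }
    )


@pytest.fixture
def toy_gene_sets() -> GeneSetCollection:
    return GeneSetCollection(
        terms={
            "TERM:1": ("alpha set", {"A", "B", "C"}),
            "TERM:2": ("beta set", {"D"}),
            "TERM:3": ("gamma set", {"T", "A", "D"}),
        }
    )


@pytest.fixture
def toy_library() -> DrugTargetMap:
    return DrugTargetMap(
        entries={"DB00001": ["T"], "DB00002": ["A", "B"]},
        vocabulary={"DRUGONE": "DB00001", "DRUGTWO": "DB00002"},
    )


SMALL_SCENARIO_KWARGS = dict(
    n_genes=120,
    n_drugs=60,
    n_planted_favorable=4,
    n_planted_unfavorable=4,
    n_phenotypes=8,
    genes_per_phenotype=10,
    n_terms=10,
    genes_per_term=8,
)


@pytest.fixture(scope="session")
def small_scenario() -> syn.SyntheticScenario:
    return syn.SyntheticScenario(seed=11, **SMALL_SCENARIO_KWARGS)


@pytest.fixture(scope="session")
def small_dataset(small_scenario) -> syn.SyntheticDataset:
    return syn.generate_dataset(small_scenario)
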