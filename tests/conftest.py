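"""Shared fixtures: packaged worked-example tables and small toy worlds."""
from __future__ import annotations

import numpy as np
import pytest

import ccipath as cp
from ccipath import fixtures as fx


@pytest.fixture(scope="session")
def dihydrouracil_net() -> cp.InteractionNetwork:
    return fx.dihydrouracil_network()


@pytest.fixture(scope="session")
def dihydrouracil_ann() -> cp.AnnotationTable:
    return fx.dihydrouracil_annotations()


@pytest.fixture(scope="session")
def novel_net() -> cp.InteractionNetwork:
    return fx.novel_query_network()


@pytest.fixture(scope="session")
def novel_ann() -> cp.AnnotationTable:
    return fx.novel_query_annotations()


@pytest.fixture()
def toy_world() -> tuple[cp.InteractionNetwork, cp.AnnotationTable]:
    """Four compounds, perfectly assortative single-label cliques."""
    ann = cp.AnnotationTable({"A": [1], "B": [1], "C": [2], "D": [2]})
    net = cp.InteractionNetwork.from_edges(
        [("A", "B", 0.9), ("C", "D", 0.8)]
    )
    return net, ann


def naive_class_scores(
    query: str, network: cp.InteractionNetwork, annotations: cp.AnnotationTable
) -> np.ndarray:
    """Independent oracle: an explicit double loop over (edge, class) pairs."""
    scores = np.zeros(cp.N_CLASSES)
    for a, b, w in network.edges():
        partner = None
        if a == query:
            partner = b
        elif b == query:
            partner = a
        if partner is None or partner not in annotations:
            continue
        for code in range(1, cp.N_CLASSES + 1):
            if code in annotations.classes_of(partner):
                scores[code - 1] += w
    return scores
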