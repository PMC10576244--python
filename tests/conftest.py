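import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from salparch.mk import DiscreteTipData
from salparch.ontology import (
    build_rate_model,
    assemble_Q,
    salp_ontology,
)
from salparch.synthetic_data import simulate_yule_tree


@pytest.fixture(scope="session")
def salp_graph():
    return salp_ontology()


@pytest.fixture(scope="session")
def salp_space(salp_graph):
    return salp_graph.space


def random_tree(rng: np.random.Generator, n_tips: int, jitter: bool = True):
    """Random rooted tree: Yule topology, optionally non-ultrametric lengths."""
    tree = simulate_yule_tree(n_tips, 1.0, seed=int(rng.integers(2**31)))
    if jitter:
        for node in tree.nodes:
            if node.parent is not None:
                node.branch_length = float(rng.exponential(0.5)) + 0.01
    return tree


def random_Q(rng: np.random.Generator, graph, kind: str):
    model = build_rate_model(graph, kind)
    params = rng.uniform(0.05, 1.5, size=model.n_params)
    return assemble_Q(model, params)


def random_tips(rng: np.random.Generator, tree, space) -> DiscreteTipData:
    """Random tip states with occasional ambiguity sets and missing data."""
    assignment = {}
    for label in tree.tip_labels:
        u = rng.random()
        if u < 0.05:
            assignment[label] = frozenset(space.states)
        elif u < 0.2:
            pair = rng.choice(len(space), size=2, replace=False)
            assignment[label] = frozenset(space.states[i] for i in pair)
        else:
            assignment[label] = space.states[int(rng.integers(len(space)))]
    return DiscreteTipData(assignment)
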