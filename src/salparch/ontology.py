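"""Developmental ontology of colony architectures and its CTMC rate models.

Salp colony architectures arise from each other by the gain and loss of
specific developmental transformation mechanisms (zooid rotation, stolon
twisting, peduncle growth, loss of zooid attachment...). That developmental
adjacency is encoded here as an undirected graph over architecture states
(:class:`OntologyGraph`); an *ordered* Markov model only permits transitions
along graph edges, so a lineage must pass back through intermediate
architectures (ultimately the transversal form) to reach a different
developmental pathway.

:func:`build_rate_model` compiles a graph into a parameterized rate-matrix
structure of one of four kinds:

``ordered_asymmetric``
    one free rate per allowed directed transition (2 per ontology edge; the
    salp preset's six edges yield 12 parameters),
``ordered_single``
    a single shared rate on all allowed transitions,
``equal_rates``
    all k(k-1) transitions allowed, one shared rate,
``all_rates_different``
    all transitions allowed, each with its own rate (42 for 7 states).

:func:`assemble_Q` turns a parameter vector into a concrete generator matrix
Q, with forbidden transitions pinned at exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "FORBIDDEN",
    "StateSpace",
    "OntologyGraph",
    "RateModel",
    "RateMatrix",
    "build_rate_model",
    "assemble_Q",
    "extract_params",
    "reachability",
    "salp_ontology",
    "RATE_MODEL_KINDS",
]

FORBIDDEN = -1  # sentinel parameter id for structurally-zero rates

RATE_MODEL_KINDS = (
    "ordered_asymmetric",
    "ordered_single",
    "equal_rates",
    "all_rates_different",
)


@dataclass(frozen=True)
class StateSpace:
    """Ordered list of architecture state names."""

    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("state names must be unique")
        if not self.states:
            raise ValueError("state space is empty")

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None


@dataclass(frozen=True)
class OntologyGraph:
    """Undirected developmental-adjacency graph over a state space."""

    space: StateSpace
    edges: frozenset[frozenset[str]]

    @classmethod
    def from_lists(
        cls, states: Sequence[str], edges: Sequence[Sequence[str]]
    ) -> "OntologyGraph":
        space = StateSpace(tuple(states))
        es = set()
        for a, b in edges:
            space.index(a)
            space.index(b)
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            e = frozenset((a, b))
            if e in es:
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            es.add(e)
        return cls(space, frozenset(es))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.space.states)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": list(self.space.states),
                "edges": sorted(sorted(e) for e in self.edges),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "OntologyGraph":
        obj = json.loads(text)
        return cls.from_lists(obj["states"], obj["edges"])


@dataclass(frozen=True)
class RateModel:
    """Parameterization of a rate matrix: directed pair -> parameter id.

    ``param_index[i, j]`` holds the dense parameter id for the transition
    from state i to state j (row-major over the ordered state list), or
    ``FORBIDDEN`` for structurally-zero entries. Diagonals are ``FORBIDDEN``.
    """

    space: StateSpace
    kind: str
    param_index: np.ndarray  # (k, k) int array
    n_params: int

    def __post_init__(self) -> None:
        if self.kind not in RATE_MODEL_KINDS:
            raise ValueError(f"unknown rate-model kind {self.kind!r}")


@dataclass(frozen=True)
class RateMatrix:
    """Concrete CTMC generator: off-diagonal rates, rows summing to zero."""

    space: StateSpace
    Q: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        k = len(self.space)
        if Q.shape != (k, k):
            raise ValueError("Q shape does not match state space")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-10 * max(1.0, np.abs(Q).max()):
            raise ValueError("rows of Q must sum to zero")
        object.__setattr__(self, "Q", Q)

    @property
    def k(self) -> int:
        return len(self.space)


def build_rate_model(graph: OntologyGraph, kind: str) -> RateModel:
    """Compile an ontology graph into a parameterized rate-matrix structure.

    Parameter ids are dense 0..n_params-1 and assigned in row-major order over
    the directed pairs of the ordered state list, so posterior summaries are
    comparable across runs.
    """
    if kind not in RATE_MODEL_KINDS:
        raise ValueError(f"unknown rate-model kind {kind!r}")
    ordered = kind in ("ordered_asymmetric", "ordered_single")
    if ordered and not graph.is_connected():
        raise ValueError(
            "ordered rate models require a connected ontology graph: "
            "some states would be unreachable"
        )
    states = graph.space.states
    k = len(states)
    idx = np.full((k, k), FORBIDDEN, dtype=int)
    shared = kind in ("ordered_single", "equal_rates")
    next_id = 0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if ordered and not graph.adjacent(states[i], states[j]):
                continue
            if shared:
                idx[i, j] = 0
            else:
                idx[i, j] = next_id
                next_id += 1
    n_params = 1 if shared else next_id
    return RateModel(graph.space, kind, idx, n_params)


def assemble_Q(model: RateModel, params: Sequence[float]) -> RateMatrix:
    """Build the generator Q from a parameter vector.

    ``Q[i, j] = params[param_index[i, j]]`` for allowed pairs, exactly 0 for
    forbidden ones; diagonals make rows sum to zero.
    """
    p = np.asarray(params, dtype=float)
    if p.shape != (model.n_params,):
        raise ValueError(
            f"expected {model.n_params} parameters, got shape {p.shape}"
        )
    if np.any(p < 0):
        raise ValueError("rate parameters must be nonnegative")
    k = len(model.space)
    Q = np.zeros((k, k))
    mask = model.param_index >= 0
    Q[mask] = p[model.param_index[mask]]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(model.space, Q)


def extract_params(model: RateModel, ratematrix: RateMatrix) -> np.ndarray:
    """Inverse of :func:`assemble_Q` (first occurrence wins for shared ids)."""
    p = np.zeros(model.n_params)
    seen = np.zeros(model.n_params, dtype=bool)
    k = len(model.space)
    for i in range(k):
        for j in range(k):
            pid = model.param_index[i, j]
            if pid >= 0 and not seen[pid]:
                p[pid] = ratematrix.Q[i, j]
                seen[pid] = True
    return p


def reachability(graph: OntologyGraph, from_state: str, to_state: str) -> int:
    """Shortest edge-path length between two states in the ontology graph.

    The minimum number of developmental transitions needed to reach one
    architecture from another; 0 for a state and itself.
    """
    graph.space.index(from_state)
    graph.space.index(to_state)
    return int(
        nx.shortest_path_length(graph.to_networkx(), from_state, to_state)
    )


def salp_ontology() -> OntologyGraph:
    """The packaged salp developmental ontology: 7 architectures, 6 edges.

    Edges: transversal-oblique, oblique-linear, linear-bipinnate,
    transversal-helical, transversal-whorl, whorl-cluster. Reaching a
    different pathway (e.g. helical from linear) requires passing back
    through the transversal form.
    """
    text = (
        resources.files("salparch").joinpath("data/salp_ontology.json").read_text()
    )
    return OntologyGraph.from_json(text)
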