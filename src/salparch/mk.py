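"""Continuous-time Markov chain machinery on trees.

Implements the discrete-character engine behind the ordered-Markov analyses:

* :func:`transition_probabilities` — the CTMC kernel P(t) = exp(Qt), via
  eigendecomposition with a scaling-and-squaring fallback;
* :func:`pruning_loglik` — Felsenstein's pruning algorithm (postorder dynamic
  program over conditional tip likelihoods, with per-node scaling);
* :func:`ml_fit` — maximum-likelihood rate estimation on the log-rate scale
  with multiple restarts;
* :func:`marginal_asr` — marginal ancestral-state probabilities at every
  internal node, by combining downward conditional likelihoods with upward
  messages (valid for non-reversible generators, as ordered models are).

The workhorse is :class:`LikelihoodEngine`, which freezes the tree traversal
and tip partials once so repeated likelihood evaluations (optimization, MCMC)
only pay for the linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from salparch.ontology import RateMatrix, RateModel, StateSpace, assemble_Q
from salparch.treeio import PhyloTree

__all__ = [
    "DiscreteTipData",
    "RootPrior",
    "AsrResult",
    "MlFit",
    "LikelihoodEngine",
    "transition_probabilities",
    "pruning_loglik",
    "ml_fit",
    "marginal_asr",
]


@dataclass
class DiscreteTipData:
    """Per-species discrete states; ambiguity sets encode partial knowledge.

    ``assignment`` maps species label to either a single state name or a set
    of state names ("?" in TSV input means the full set: missing data).
    """

    assignment: dict[str, str | frozenset[str]]

    def states_of(self, label: str) -> frozenset[str]:
        v = self.assignment[label]
        return frozenset((v,)) if isinstance(v, str) else frozenset(v)

    def partial(self, label: str, space: StateSpace) -> np.ndarray:
        """Indicator vector over the state space (the pruning tip partial)."""
        out = np.zeros(len(space))
        for s in self.states_of(label):
            out[space.index(s)] = 1.0
        return out

    def validate(self, tree: PhyloTree, space: StateSpace) -> None:
        missing = [t for t in tree.tip_labels if t not in self.assignment]
        if missing:
            raise KeyError(f"tip(s) absent from discrete data: {missing}")
        for label in tree.tip_labels:
            states = self.states_of(label)
            if not states:
                raise ValueError(f"empty ambiguity set for {label!r}")
            for s in states:
                space.index(s)

    @classmethod
    def from_tsv(cls, text: str, space: StateSpace) -> "DiscreteTipData":
        """Parse 'species<TAB>state' rows; comma-separated sets and '?' allowed."""
        assignment: dict[str, str | frozenset[str]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"expected 2 tab-separated columns: {line!r}")
            label, raw = parts
            if label == "species" and raw == "state":
                continue  # header
            if raw == "?":
                assignment[label] = frozenset(space.states)
            elif "," in raw:
                assignment[label] = frozenset(raw.split(","))
            else:
                assignment[label] = raw
        return cls(assignment)

    def to_tsv(self) -> str:
        lines = ["species\tstate"]
        for label in sorted(self.assignment):
            v = self.assignment[label]
            lines.append(f"{label}\t{v if isinstance(v, str) else ','.join(sorted(v))}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RootPrior:
    """Distribution over states at the root (default: uniform)."""

    probs: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("root prior must be a probability vector")
        object.__setattr__(self, "probs", p)

    @classmethod
    def uniform(cls, k: int) -> "RootPrior":
        return cls(np.full(k, 1.0 / k), kind="uniform")


@dataclass
class AsrResult:
    """Marginal state probabilities per internal node, plus MAP states.

    ``node_probs[v]`` is the posterior probability vector over states at
    internal node ``v``; ``map_state[v]`` is the argmax (ties break on state
    order in the state space).
    """

    space: StateSpace
    node_probs: dict[int, np.ndarray]
    map_state: dict[int, str]
    method: str

    def to_tsv(self) -> str:
        cols = "\t".join(self.space.states)
        lines = [f"node_id\t{cols}\tmap_state"]
        for v in sorted(self.node_probs):
            p = "\t".join(f"{x:.6f}" for x in self.node_probs[v])
            lines.append(f"{v}\t{p}\t{self.map_state[v]}")
        return "\n".join(lines) + "\n"


@dataclass
class MlFit:
    """Result of :func:`ml_fit`: rate MLEs and optimization diagnostics."""

    params: np.ndarray
    loglik: float
    converged: bool
    restarts: list[dict] = field(default_factory=list)


# -- transition probabilities -------------------------------------------------


class Propagator:
    """P(t) = exp(Qt) for many t, via a one-off eigendecomposition of Q.

    Generators of ordered models are typically non-symmetric but
    diagonalizable; when the eigenvector matrix is ill-conditioned or the
    reconstruction is inaccurate, each P(t) falls back to scaling-and-squaring
    (``scipy.linalg.expm``). Rows are renormalized to sum to exactly one; a
    row-sum deviation beyond 1e-8 raises, as that signals a broken generator.
    """

    def __init__(self, Q: np.ndarray, tol: float = 1e-12):
        self.Q = np.asarray(Q, dtype=float)
        self.k = self.Q.shape[0]
        self._use_eig = False
        if np.allclose(self.Q, self.Q.T, atol=1e-14):
            w, V = np.linalg.eigh(self.Q)
            self.w, self.V, self.Vinv = w.astype(complex), V, V.T
            self._use_eig = True
        else:
            try:
                w, V = scipy.linalg.eig(self.Q)
                Vinv = np.linalg.inv(V)
                recon = (V * w) @ Vinv
                cond = np.linalg.cond(V)
                if cond < 1e8 and np.max(np.abs(recon - self.Q)) < 1e-9 * max(
                    1.0, np.abs(self.Q).max()
                ):
                    self.w, self.V, self.Vinv = w, V, Vinv
                    self._use_eig = True
            except np.linalg.LinAlgError:
                pass

    def many(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for each t in ``ts``; exact identity at t = 0."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("elapsed time must be nonnegative")
        out = np.empty((len(ts), self.k, self.k))
        if self._use_eig:
            # a generator always has the simple eigenvalue 0 (zero row sums)
            # and the rest with nonpositive real part; pin both facts so
            # numerical noise, which scales with |Q|, cannot leak into exp
            w = self.w.copy()
            w[int(np.argmax(w.real))] = 0.0
            w = np.minimum(w.real, 0.0) + 1j * w.imag
            ewt = np.exp(np.outer(ts, w))  # (T, k)
            out[:] = np.einsum("ij,tj,jl->til", self.V, ewt, self.Vinv).real
        else:
            for i, t in enumerate(ts):
                out[i] = scipy.linalg.expm(self.Q * t)
        out[ts == 0.0] = np.eye(self.k)
        np.clip(out, 0.0, None, out=out)
        rowsums = out.sum(axis=2)
        if np.max(np.abs(rowsums - 1.0)) > 1e-8:
            if self._use_eig:
                # eigenvector conditioning deteriorated at this rate scale;
                # redo with scaling-and-squaring before giving up
                for i, t in enumerate(ts):
                    out[i] = scipy.linalg.expm(self.Q * t)
                out[ts == 0.0] = np.eye(self.k)
                np.clip(out, 0.0, None, out=out)
                rowsums = out.sum(axis=2)
            if np.max(np.abs(rowsums - 1.0)) > 1e-8:
                raise ArithmeticError(
                    "transition matrix rows deviate from 1 beyond tolerance; "
                    "Q is numerically broken"
                )
        out /= rowsums[:, :, None]
        return out

    def one(self, t: float) -> np.ndarray:
        return self.many(np.array([t]))[0]


def transition_probabilities(Q: RateMatrix, t: float) -> np.ndarray:
    """The k x k stochastic matrix P(t) = exp(Qt)."""
    if t < 0:
        raise ValueError("elapsed time must be nonnegative")
    return Propagator(Q.Q).one(float(t))


# -- pruning likelihood -------------------------------------------------------


class LikelihoodEngine:
    """Frozen tree traversal + tip partials for fast repeated likelihoods.

    Partials are renormalized at every node and the scale is accumulated in
    log space, so deep trees and tiny rates never underflow.
    """

    def __init__(
        self,
        tree: PhyloTree,
        tips: DiscreteTipData,
        space: StateSpace,
        prior: RootPrior | None = None,
    ):
        tips.validate(tree, space)
        self.tree = tree
        self.space = space
        self.k = len(space)
        self.prior = prior if prior is not None else RootPrior.uniform(self.k)
        if len(self.prior.probs) != self.k:
            raise ValueError("root prior length does not match state space")
        self.post = tree.postorder()
        self.children = [tree.nodes[v].children for v in range(len(tree.nodes))]
        self.bl = np.array([n.branch_length for n in tree.nodes])
        self.tip_partials: dict[int, np.ndarray] = {
            n.id: tips.partial(n.label, space)  # type: ignore[arg-type]
            for n in tree.tips()
        }

    def down_pass(self, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Conditional likelihoods bottom-up.

        Returns ``(L, log_scale, P)``: per-node normalized partials (n, k),
        per-node accumulated log scaling factors, and the stacked per-branch
        transition matrices P[v] = P(branch length of v).
        """
        prop = Propagator(Q)
        P = prop.many(self.bl)
        n = len(self.tree.nodes)
        L = np.empty((n, self.k))
        log_scale = np.zeros(n)
        for v in self.post:
            kids = self.children[v]
            if not kids:
                L[v] = self.tip_partials[v]
                continue
            part = np.ones(self.k)
            acc = 0.0
            for c in kids:
                part = part * (P[c] @ L[c])
                acc += log_scale[c]
            s = part.sum()
            if s <= 0:
                # data impossible under this Q (e.g. forbidden pattern, rate 0)
                log_scale[v] = -np.inf
                L[v] = np.full(self.k, 1.0 / self.k)
                continue
            L[v] = part / s
            log_scale[v] = acc + np.log(s)
        return L, log_scale, P

    def loglik(self, Q: np.ndarray) -> float:
        L, log_scale, _ = self.down_pass(Q)
        root_lik = float(self.prior.probs @ L[self.tree.root])
        if root_lik <= 0 or not np.isfinite(log_scale[self.tree.root]):
            return -np.inf
        return float(np.log(root_lik) + log_scale[self.tree.root])

    def marginals(self, Q: np.ndarray) -> dict[int, np.ndarray]:
        """Marginal state probabilities at every internal node.

        Belief propagation: the upward message U[v] carries the evidence from
        everything outside v's subtree, so p(v = s | data) is proportional to
        U[v][s] * L[v][s]. Works for non-reversible Q (no rerooting assumed).
        """
        L, _, P = self.down_pass(Q)
        n = len(self.tree.nodes)
        U = np.empty((n, self.k))
        U[self.tree.root] = self.prior.probs
        probs: dict[int, np.ndarray] = {}
        for v in self.tree.preorder():
            kids = self.children[v]
            if not kids:
                continue
            p = U[v] * L[v]
            total = p.sum()
            if total <= 0:
                raise ArithmeticError("zero-probability data under this Q")
            probs[v] = p / total
            msgs = [P[c] @ L[c] for c in kids]
            for i, c in enumerate(kids):
                w = U[v].copy()
                for j, m in enumerate(msgs):
                    if j != i:
                        w = w * m
                u = P[c].T @ w
                s = u.sum()
                U[c] = u / s if s > 0 else np.full(self.k, 1.0 / self.k)
        return probs


def pruning_loglik(
    tree: PhyloTree,
    tips: DiscreteTipData,
    Q: RateMatrix,
    prior: RootPrior | None = None,
) -> float:
    """Felsenstein pruning log-likelihood of the tip data given Q and the tree."""
    engine = LikelihoodEngine(tree, tips, Q.space, prior)
    return engine.loglik(Q.Q)


def marginal_asr(
    tree: PhyloTree,
    tips: DiscreteTipData,
    Q: RateMatrix,
    prior: RootPrior | None = None,
) -> AsrResult:
    """Marginal ancestral-state probabilities at every internal node."""
    engine = LikelihoodEngine(tree, tips, Q.space, prior)
    probs = engine.marginals(Q.Q)
    map_state = {
        v: Q.space.states[int(np.argmax(p))] for v, p in probs.items()
    }
    return AsrResult(Q.space, probs, map_state, method="ml_marginal")


# -- maximum-likelihood rate fitting ------------------------------------------


def ml_fit(
    tree: PhyloTree,
    tips: DiscreteTipData,
    model: RateModel,
    prior: RootPrior | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    log_bounds: tuple[float, float] = (-12.0, 6.0),
) -> MlFit:
    """Maximize the pruning likelihood over the model's free rates.

    Rates are optimized on the log scale within ``log_bounds`` (nats), with
    one heuristic start (one expected change per tree height) plus seeded
    random restarts. Deterministic given ``seed``.
    """
    engine = LikelihoodEngine(tree, tips, model.space, prior)
    lo, hi = log_bounds

    def neg_loglik(log_p: np.ndarray) -> float:
        Q = assemble_Q(model, np.exp(log_p))
        ll = engine.loglik(Q.Q)
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    height = max(tree.tree_height(), 1e-9)
    starts = [np.full(model.n_params, np.clip(np.log(1.0 / height), lo, hi))]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(lo + 2, hi - 4, size=model.n_params))

    best = None
    restarts: list[dict] = []
    for x0 in starts:
        res = scipy.optimize.minimize(
            neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * model.n_params,
        )
        restarts.append(
            {"x0": x0.copy(), "loglik": -float(res.fun), "success": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"rate optimization failed on all restarts: {restarts}")
    params = np.exp(best.x)
    return MlFit(
        params=params,
        loglik=-float(best.fun),
        converged=bool(best.success),
        restarts=restarts,
    )
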