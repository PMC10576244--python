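"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational paths: likelihoods are
computed by exhaustive enumeration over all node-state assignments (versus
the pruning dynamic program), ancestral Gaussian conditioning by rerooted
GLS, and covariances by explicit root-to-tip path enumeration.

The state-enumeration oracles share the package's transition kernel
(:func:`salparch.mk.transition_probabilities`) on purpose: branch entries for
developmentally distant state pairs at short times are ~t^d and carry no
relative precision under any independent matrix exponential, so sharing the
kernel isolates what these oracles actually check — the summation over tree
histories. The kernel itself is validated separately against closed forms,
Chapman-Kolmogorov, and first-order series structure.
"""

from __future__ import annotations

import itertools

import numpy as np

from salparch.mk import DiscreteTipData, RootPrior, transition_probabilities
from salparch.ontology import RateMatrix
from salparch.treeio import PhyloTree


def enumerate_likelihood(
    tree: PhyloTree,
    tips: DiscreteTipData,
    Q: RateMatrix,
    prior: RootPrior,
) -> tuple[float, dict[int, np.ndarray]]:
    """(log-likelihood, marginal node posteriors) by exhaustive enumeration.

    Sums pi(root) * prod_branches P(t)[parent, child] over every assignment of
    states to all nodes (tip states range over their ambiguity sets).
    """
    k = len(Q.space)
    P = {
        n.id: transition_probabilities(Q, n.branch_length)
        for n in tree.nodes
        if n.parent is not None
    }
    node_ids = [n.id for n in tree.nodes]
    choices = []
    for nid in node_ids:
        node = tree.nodes[nid]
        if node.is_tip:
            allowed = sorted(Q.space.index(s) for s in tips.states_of(node.label))
        else:
            allowed = list(range(k))
        choices.append(allowed)
    total = 0.0
    acc = {nid: np.zeros(k) for nid in node_ids if not tree.nodes[nid].is_tip}
    for combo in itertools.product(*choices):
        state = dict(zip(node_ids, combo))
        w = prior.probs[state[tree.root]]
        for nid, s in state.items():
            parent = tree.nodes[nid].parent
            if parent is not None:
                w *= P[nid][state[parent], s]
            if w == 0.0:
                break
        if w == 0.0:
            continue
        total += w
        for nid in acc:
            acc[nid][state[nid]] += w
    if total <= 0:
        return -np.inf, {nid: np.full(k, np.nan) for nid in acc}
    return float(np.log(total)), {nid: a / total for nid, a in acc.items()}


def rerooted_gls_asr(
    tree: PhyloTree, x_by_label: dict[str, float], sigma2: float
) -> dict[int, tuple[float, float]]:
    """ML ancestral estimates by rerooting: for each internal node v, the GLS
    root estimate under the covariance of the tree re-centered on v, with
    variance sigma2 / (1' C_v^{-1} 1). Covariances come from patristic
    distances: C_v[i, j] = (d(v,i) + d(v,j) - d(i,j)) / 2.
    """
    tips = tree.tips()
    labels = [t.label for t in tips]
    x = np.array([x_by_label[lab] for lab in labels])
    d = tree.depths()

    def dist(i: int, j: int) -> float:
        return float(d[i] + d[j] - 2 * d[tree.mrca(i, j)])

    out: dict[int, tuple[float, float]] = {}
    for node in tree.nodes:
        if node.is_tip:
            continue
        v = node.id
        n = len(tips)
        Cv = np.empty((n, n))
        for i, ti in enumerate(tips):
            for j, tj in enumerate(tips):
                Cv[i, j] = 0.5 * (dist(v, ti.id) + dist(v, tj.id) - dist(ti.id, tj.id))
        ones = np.ones(n)
        Ci1 = np.linalg.solve(Cv, ones)
        Cix = np.linalg.solve(Cv, x)
        denom = float(ones @ Ci1)
        est = float(ones @ Cix) / denom
        var = sigma2 / denom
        out[v] = (est, var)
    return out


def path_enumeration_vcv(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Shared-path covariance by explicitly listing each tip's root path."""
    paths: dict[str, list[int]] = {}
    for tip in tree.tips():
        p = []
        v = tip.id
        while tree.nodes[v].parent is not None:
            p.append(v)
            v = tree.nodes[v].parent
        paths[tip.label] = p
    labels = sorted(paths)
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(paths[a]) & set(paths[b])
            C[i, j] = sum(tree.nodes[v].branch_length for v in shared)
    return labels, C


def exact_tip_pattern_distribution(
    tree: PhyloTree, Q: RateMatrix, prior: RootPrior
) -> dict[tuple[int, ...], float]:
    """Joint distribution over tip-state patterns by enumerating node states."""
    k = len(Q.space)
    P = {
        n.id: transition_probabilities(Q, n.branch_length)
        for n in tree.nodes
        if n.parent is not None
    }
    tip_ids = [t.id for t in tree.tips()]
    node_ids = [n.id for n in tree.nodes]
    out: dict[tuple[int, ...], float] = {}
    for combo in itertools.product(range(k), repeat=len(node_ids)):
        state = dict(zip(node_ids, combo))
        w = prior.probs[state[tree.root]]
        for nid, s in state.items():
            parent = tree.nodes[nid].parent
            if parent is not None:
                w *= P[nid][state[parent], s]
            if w == 0.0:
                break
        if w == 0.0:
            continue
        key = tuple(state[t] for t in tip_ids)
        out[key] = out.get(key, 0.0) + w
    return out
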