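"""Bayesian rate inference and stochastic character mapping.

:func:`mcmc_rates` runs a Metropolis-Hastings chain over the free rates of a
(possibly ordered) Markov model, with independent exponential priors and a
multiplicative log-normal random walk updating one rate per iteration in
round-robin; the proposal scale is auto-tuned during burn-in toward a 20-40%
acceptance rate. :func:`bayes_asr` averages marginal ancestral-state
probabilities over the posterior sample, which is how node posterior
probabilities (PPs) are reported on the tree.

:func:`stochastic_map` draws full character histories (change times and types
on every branch) consistent with the tip data and a fixed rate matrix:
internal node states are drawn jointly from their posterior
(:func:`sample_joint_node_states`), then each branch is filled in by
endpoint-conditioned path sampling — forward-path rejection with a capped
number of attempts, falling back to uniformization, which stays efficient for
the sparse generators of ordered models where rejection can stall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from salparch.mk import (
    AsrResult,
    DiscreteTipData,
    LikelihoodEngine,
    Propagator,
    RootPrior,
)
from salparch.ontology import RateMatrix, RateModel, assemble_Q
from salparch.treeio import PhyloTree

__all__ = [
    "McmcConfig",
    "PosteriorChain",
    "SimmapHistory",
    "SimmapSummary",
    "mcmc_rates",
    "bayes_asr",
    "sample_joint_node_states",
    "stochastic_map",
]


@dataclass(frozen=True)
class McmcConfig:
    """Settings for the Metropolis-Hastings rate sampler.

    ``prior_mean`` is the mean of the independent exponential prior on each
    rate; when None it defaults to 10 / tree height, i.e. weakly informative
    on the expected-number-of-changes scale.
    """

    n_iter: int = 20_000
    burn_in: float = 0.25
    thin: int = 10
    seed: int = 0
    prior_mean: float | None = None
    proposal_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be a fraction in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorChain:
    """Post-burn-in, thinned MCMC output."""

    params: np.ndarray  # (n_samples, n_params)
    logliks: np.ndarray
    logpriors: np.ndarray
    acceptance_rate: float
    ess: np.ndarray
    low_ess_warning: bool
    prior_mean: float

    def summary(self) -> dict:
        q = np.quantile(self.params, [0.025, 0.5, 0.975], axis=0)
        return {
            "mean": self.params.mean(axis=0),
            "q025": q[0],
            "median": q[1],
            "q975": q[2],
            "acceptance_rate": self.acceptance_rate,
            "ess": self.ess,
        }

    def to_tsv(self) -> str:
        n_params = self.params.shape[1]
        header = "sample\t" + "\t".join(f"rate_{i}" for i in range(n_params))
        lines = [header + "\tloglik\tlogprior"]
        for i in range(self.params.shape[0]):
            row = "\t".join(f"{x:.8g}" for x in self.params[i])
            lines.append(f"{i}\t{row}\t{self.logliks[i]:.6f}\t{self.logpriors[i]:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class SimmapHistory:
    """One sampled character history.

    ``changes[v]`` lists, for the branch subtending node ``v``, the
    transitions as ``(time offset from the parent node, new state name)`` in
    chronological order; ``node_states`` gives the state at every node.
    """

    changes: dict[int, list[tuple[float, str]]]
    node_states: dict[int, str]

    def n_changes(self) -> int:
        return sum(len(v) for v in self.changes.values())

    def transition_counts(self, space) -> np.ndarray:
        k = len(space)
        counts = np.zeros((k, k))
        for v, events in self.changes.items():
            prev_name = self._parent_state(v)
            for _, new in events:
                counts[space.index(prev_name), space.index(new)] += 1
                prev_name = new
        return counts

    def _parent_state(self, v: int) -> str:
        return self.node_states[self._parents[v]]

    # set by stochastic_map so transition_counts can resolve parents
    _parents: dict[int, int] = field(default_factory=dict, repr=False)


@dataclass
class SimmapSummary:
    """Monte-Carlo summaries over a set of sampled histories."""

    space: object
    node_state_freq: dict[int, np.ndarray]
    expected_transitions: np.ndarray  # (k, k) mean count per history
    expected_dwell: np.ndarray  # (k,) mean total time per state
    n_sim: int

    def to_tsv(self) -> str:
        states = self.space.states
        lines = ["node_id\t" + "\t".join(states)]
        for v in sorted(self.node_state_freq):
            row = "\t".join(f"{x:.6f}" for x in self.node_state_freq[v])
            lines.append(f"{v}\t{row}")
        return "\n".join(lines) + "\n"


# -- MCMC ---------------------------------------------------------------------


def mcmc_rates(
    tree: PhyloTree,
    tips: DiscreteTipData,
    model: RateModel,
    prior: RootPrior | None = None,
    cfg: McmcConfig = McmcConfig(),
) -> PosteriorChain:
    """Metropolis-Hastings sampling of the model's free rates.

    Independent Exponential(prior_mean) priors; one-rate-at-a-time
    multiplicative log-normal proposals; deterministic given ``cfg.seed``.
    """
    engine = LikelihoodEngine(tree, tips, model.space, prior)
    rng = np.random.default_rng(cfg.seed)
    prior_mean = (
        cfg.prior_mean
        if cfg.prior_mean is not None
        else 10.0 / max(tree.tree_height(), 1e-9)
    )
    if prior_mean <= 0:
        raise ValueError("prior_mean must be positive")
    npar = model.n_params

    def logprior(p: np.ndarray) -> float:
        return float(-np.sum(p) / prior_mean - npar * math.log(prior_mean))

    params = rng.exponential(prior_mean, size=npar)
    ll = engine.loglik(assemble_Q(model, params).Q)
    lp = logprior(params)
    scales = np.full(npar, cfg.proposal_scale)
    n_burn = int(cfg.n_iter * cfg.burn_in)

    keep_params: list[np.ndarray] = []
    keep_ll: list[float] = []
    keep_lp: list[float] = []
    n_acc = 0
    n_prop = 0
    win_acc = np.zeros(npar)
    win_tot = np.zeros(npar)

    for it in range(cfg.n_iter):
        j = it % npar
        step = rng.normal(0.0, scales[j])
        prop = params.copy()
        prop[j] = params[j] * math.exp(step)
        ll_p = engine.loglik(assemble_Q(model, prop).Q)
        lp_p = logprior(prop)
        # multiplicative proposal: Hastings ratio contributes log(x'/x)
        log_alpha = (ll_p + lp_p) - (ll + lp) + step
        win_tot[j] += 1
        n_prop += 1
        if math.log(rng.random()) < log_alpha:
            params, ll, lp = prop, ll_p, lp_p
            win_acc[j] += 1
            n_acc += 1
        if it < n_burn and win_tot[j] >= 50:
            rate = win_acc[j] / win_tot[j]
            if rate > 0.4:
                scales[j] = min(scales[j] * 1.3, 10.0)
            elif rate < 0.2:
                scales[j] = max(scales[j] / 1.3, 1e-3)
            win_acc[j] = win_tot[j] = 0
        if it >= n_burn and (it - n_burn) % cfg.thin == 0:
            keep_params.append(params.copy())
            keep_ll.append(ll)
            keep_lp.append(lp)

    samples = np.array(keep_params)
    ess = _ess(samples)
    return PosteriorChain(
        params=samples,
        logliks=np.array(keep_ll),
        logpriors=np.array(keep_lp),
        acceptance_rate=n_acc / max(n_prop, 1),
        ess=ess,
        low_ess_warning=bool(np.any(ess < 100)),
        prior_mean=prior_mean,
    )


def _ess(samples: np.ndarray) -> np.ndarray:
    """Effective sample size per parameter (initial positive sequence)."""
    n, npar = samples.shape
    out = np.empty(npar)
    for j in range(npar):
        x = samples[:, j] - samples[:, j].mean()
        var = float(x @ x) / n
        if var == 0 or n < 4:
            out[j] = float(n)
            continue
        # FFT autocovariance
        m = 1 << (2 * n - 1).bit_length()
        f = np.fft.rfft(x, m)
        acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
        rho = acov / acov[0]
        s = 0.0
        for lag in range(1, n):
            if rho[lag] + (rho[lag + 1] if lag + 1 < n else 0.0) < 0:
                break
            s += rho[lag]
        out[j] = n / max(1.0 + 2.0 * s, 1e-12)
    return out


def bayes_asr(
    tree: PhyloTree,
    tips: DiscreteTipData,
    model: RateModel,
    prior: RootPrior | None = None,
    cfg: McmcConfig = McmcConfig(),
    max_asr_samples: int = 200,
) -> tuple[AsrResult, PosteriorChain]:
    """Posterior-averaged marginal ancestral states.

    Node probabilities are the average of fixed-Q marginal reconstructions
    over (at most ``max_asr_samples`` evenly spaced) posterior rate draws.
    """
    chain = mcmc_rates(tree, tips, model, prior, cfg)
    engine = LikelihoodEngine(tree, tips, model.space, prior)
    n = chain.params.shape[0]
    take = np.unique(np.linspace(0, n - 1, min(max_asr_samples, n)).astype(int))
    acc: dict[int, np.ndarray] = {}
    for i in take:
        Q = assemble_Q(model, chain.params[i])
        for v, p in engine.marginals(Q.Q).items():
            acc[v] = acc.get(v, 0.0) + p
    probs = {v: p / len(take) for v, p in acc.items()}
    map_state = {v: model.space.states[int(np.argmax(p))] for v, p in probs.items()}
    return AsrResult(model.space, probs, map_state, method="bayes"), chain


# -- joint node-state sampling ------------------------------------------------


def _sample_joint_indices(
    engine: LikelihoodEngine, L: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> dict[int, int]:
    """Draw node-state indices from the joint posterior, root downward."""
    tree = engine.tree
    states: dict[int, int] = {}
    w = engine.prior.probs * L[tree.root]
    states[tree.root] = int(rng.choice(engine.k, p=w / w.sum()))
    for v in tree.preorder():
        for c in engine.children[v]:
            w = P[c][states[v]] * L[c]
            states[c] = int(rng.choice(engine.k, p=w / w.sum()))
    return states


def sample_joint_node_states(
    tree: PhyloTree,
    tips: DiscreteTipData,
    Q: RateMatrix,
    prior: RootPrior | None = None,
    seed: int = 0,
) -> dict[int, str]:
    """One draw from the joint posterior of node states given tips and Q."""
    engine = LikelihoodEngine(tree, tips, Q.space, prior)
    L, _, P = engine.down_pass(Q.Q)
    rng = np.random.default_rng(seed)
    idx = _sample_joint_indices(engine, L, P, rng)
    return {v: Q.space.states[s] for v, s in idx.items()}


# -- endpoint-conditioned path sampling ---------------------------------------


def _forward_path(
    rng: np.random.Generator, Q: np.ndarray, a: int, t: float
) -> tuple[int, list[tuple[float, int]]]:
    """Gillespie simulation from state ``a`` over time ``t``."""
    state = a
    now = 0.0
    changes: list[tuple[float, int]] = []
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            return state, changes
        now += rng.exponential(1.0 / rate)
        if now >= t:
            return state, changes
        w = Q[state].clip(min=0.0)
        w[state] = 0.0
        state = int(rng.choice(len(w), p=w / w.sum()))
        changes.append((now, state))


class _UniformizationSampler:
    """Endpoint-conditioned CTMC bridges by uniformization.

    The chain is embedded in a Poisson(mu t) number of candidate jumps with
    transition kernel R = I + Q/mu; the jump count is drawn from its exact
    conditional distribution, the intermediate states by backward sampling
    over powers of R, the jump times as uniform order statistics, and virtual
    (self) jumps are discarded.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.k = Q.shape[0]
        self.mu = float(max(-np.diag(Q).min(), 1e-300))
        self.R = np.eye(self.k) + Q / self.mu
        self._Rpow = [np.eye(self.k), self.R]

    def _rpow(self, n: int) -> np.ndarray:
        while len(self._Rpow) <= n:
            self._Rpow.append(self._Rpow[-1] @ self.R)
        return self._Rpow[n]

    def sample(
        self,
        rng: np.random.Generator,
        a: int,
        b: int,
        t: float,
        P_ab: float,
    ) -> list[tuple[float, int]]:
        if P_ab <= 0:
            raise ArithmeticError("endpoint pair has zero probability")
        mt = self.mu * t
        # draw the number of uniformized jumps n | a, b, t
        u = rng.random() * P_ab
        n = 0
        log_pois = -mt
        cum = 0.0
        while True:
            term = math.exp(log_pois) * self._rpow(n)[a, b]
            cum += term
            if cum >= u or n > mt + 50 * math.sqrt(mt + 10) + 200:
                break
            n += 1
            log_pois += math.log(mt) - math.log(n)
        # backward sampling of the uniformized state sequence
        seq = [a]
        for i in range(1, n):
            prev = seq[-1]
            w = self.R[prev] * self._rpow(n - i)[:, b]
            w = w.clip(min=0.0)
            s = w.sum()
            seq.append(int(rng.choice(self.k, p=w / s)) if s > 0 else b)
        if n > 0:
            seq.append(b)
        times = np.sort(rng.random(n)) * t
        changes = [
            (float(times[i]), seq[i + 1])
            for i in range(n)
            if seq[i + 1] != seq[i]
        ]
        return changes


def stochastic_map(
    tree: PhyloTree,
    tips: DiscreteTipData,
    Q: RateMatrix,
    n_sim: int = 100,
    seed: int = 0,
    prior: RootPrior | None = None,
    rejection_cap: int = 1000,
) -> tuple[list[SimmapHistory], SimmapSummary]:
    """Sample ``n_sim`` full character histories consistent with the tips.

    Node states are drawn jointly; each branch is then bridged between its
    endpoint states by forward-path rejection (capped at ``rejection_cap``
    attempts), with an automatic switch to uniformization sampling.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    engine = LikelihoodEngine(tree, tips, Q.space, prior)
    L, _, P = engine.down_pass(Q.Q)
    rng = np.random.default_rng(seed)
    unif = _UniformizationSampler(Q.Q)
    states = Q.space.states
    k = len(states)
    parents = {
        n.id: n.parent for n in tree.nodes if n.parent is not None
    }

    histories: list[SimmapHistory] = []
    freq_acc: dict[int, np.ndarray] = {v: np.zeros(k) for v in range(len(tree.nodes))}
    trans_acc = np.zeros((k, k))
    dwell_acc = np.zeros(k)

    for _ in range(n_sim):
        node_idx = _sample_joint_indices(engine, L, P, rng)
        changes: dict[int, list[tuple[float, str]]] = {}
        for v, pid in parents.items():
            a, b = node_idx[pid], node_idx[v]
            t = tree.nodes[v].branch_length
            if t == 0.0:
                changes[v] = []
                continue
            path: list[tuple[float, int]] | None = None
            for _attempt in range(rejection_cap):
                end, cand = _forward_path(rng, Q.Q, a, t)
                if end == b:
                    path = cand
                    break
            if path is None:
                path = unif.sample(rng, a, b, t, float(P[v][a, b]))
            changes[v] = [(off, states[s]) for off, s in path]
            # accumulate transition counts and dwell times
            cur = a
            last = 0.0
            for off, s in path:
                trans_acc[cur, s] += 1
                dwell_acc[cur] += off - last
                cur, last = s, off
            dwell_acc[cur] += t - last
        hist = SimmapHistory(
            changes=changes,
            node_states={v: states[s] for v, s in node_idx.items()},
        )
        hist._parents = parents
        histories.append(hist)
        for v, s in node_idx.items():
            freq_acc[v][s] += 1

    summary = SimmapSummary(
        space=Q.space,
        node_state_freq={v: f / n_sim for v, f in freq_acc.items()},
        expected_transitions=trans_acc / n_sim,
        expected_dwell=dwell_acc / n_sim,
        n_sim=n_sim,
    )
    return histories, summary
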