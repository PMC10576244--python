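"""Brownian-motion comparative methods for the dorsoventral zooid-stolon angle.

The zooid-stolon angle — how far each zooid's oral-aboral axis is rotated
away from the colony axis — spans 90° (transversal chains, zooids
perpendicular to the stolon) down toward 0° (linear chains, zooids parallel).
Treated as a continuously evolving trait under Brownian motion (BM), it
supports:

* :func:`bm_fit` — ML estimation of the BM rate sigma^2 and the root state,
  optionally absorbing intraspecific measurement error through each species'
  standard error (V = sigma^2 C + diag(se^2));
* :func:`bm_asr` — ML ancestral estimates with 95% confidence intervals at
  every internal node, by Gaussian conditioning on the tips with a flat prior
  on the root value (equivalent, without measurement error, to the rerooted
  GLS estimate);
* :func:`blomberg_k` — Blomberg's K phylogenetic-signal statistic with a
  permutation test, including the measurement-error variant that rescales the
  covariance to C + diag(se^2)/sigma^2;
* :func:`signal_across_trees` — the K sensitivity sweep over a posterior/
  bootstrap set of tree topologies.

Angles are treated as plain linear quantities: observed values live in
[0°, 90°], far from any circular wraparound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from salparch.treeio import PhyloTree, vcv

__all__ = [
    "ContinuousTipData",
    "BmFit",
    "ContAsrResult",
    "SignalResult",
    "bm_fit",
    "bm_asr",
    "blomberg_k",
    "signal_across_trees",
    "classify_architecture_by_angle",
]


@dataclass
class ContinuousTipData:
    """Species-level angle summaries: mean (deg), standard error, replicate count."""

    data: dict[str, tuple[float, float, int]]  # species -> (mean, se, n)

    def __post_init__(self) -> None:
        for sp, (m, se, n) in self.data.items():
            if not 0.0 <= m < 180.0:
                raise ValueError(f"angle {m} for {sp!r} outside [0, 180)")
            if se < 0:
                raise ValueError(f"negative SE for {sp!r}")
            if n < 1:
                raise ValueError(f"replicate count < 1 for {sp!r}")

    def species(self) -> list[str]:
        return list(self.data)

    def arrays(self, order: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        missing = [s for s in order if s not in self.data]
        if missing:
            raise KeyError(f"species missing from angle data: {missing}")
        m = np.array([self.data[s][0] for s in order])
        se = np.array([self.data[s][1] for s in order])
        n = np.array([self.data[s][2] for s in order])
        return m, se, n

    @classmethod
    def from_tsv(cls, text: str) -> "ContinuousTipData":
        data: dict[str, tuple[float, float, int]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("species\t"):
                continue
            sp, m, se, n = line.split("\t")
            data[sp] = (float(m), float(se), int(n))
        return cls(data)

    def to_tsv(self) -> str:
        lines = ["species\tmean_angle_deg\tse_deg\tn_zooids"]
        for sp in sorted(self.data):
            m, se, n = self.data[sp]
            lines.append(f"{sp}\t{m:.17g}\t{se:.17g}\t{n}")
        return "\n".join(lines) + "\n"


@dataclass
class BmFit:
    """Fitted Brownian motion: rate (deg^2 per unit time), root state, loglik."""

    sigma2: float
    root_state: float
    loglik: float
    use_se: bool = False


@dataclass
class ContAsrResult:
    """Ancestral estimates with 95% CIs at internal nodes."""

    estimates: dict[int, float]
    ci_low: dict[int, float]
    ci_high: dict[int, float]

    def to_tsv(self) -> str:
        lines = ["node_id\testimate\tci_low\tci_high"]
        for v in sorted(self.estimates):
            lines.append(
                f"{v}\t{self.estimates[v]:.6f}\t{self.ci_low[v]:.6f}"
                f"\t{self.ci_high[v]:.6f}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class SignalResult:
    """Blomberg's K with its permutation p-value."""

    K: float
    p_value: float
    n_permutations: int
    sigma2_hat: float


# -- internals ----------------------------------------------------------------


def _gls_root(C: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """GLS estimate of the root value and C^{-1} (via solves)."""
    ones = np.ones(len(x))
    try:
        Ci_x = np.linalg.solve(C, x)
        Ci_1 = np.linalg.solve(C, ones)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance (duplicate zero-distance tips?)"
        ) from None
    a_hat = float(ones @ Ci_x) / float(ones @ Ci_1)
    return a_hat, Ci_1


def _mvn_loglik_profile(C: np.ndarray, x: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood of x ~ N(a_hat 1, V) with a_hat the GLS mean under V."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    ones = np.ones(n)
    Vi_x = np.linalg.solve(V, x)
    Vi_1 = np.linalg.solve(V, ones)
    a = float(ones @ Vi_x) / float(ones @ Vi_1)
    r = x - a
    quad = float(r @ np.linalg.solve(V, r))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def bm_fit(
    tree: PhyloTree, x: ContinuousTipData, use_se: bool = False
) -> BmFit:
    """ML Brownian-motion fit of rate and root state.

    Without measurement error the ML rate has the closed form
    sigma^2 = (x - a 1)' C^{-1} (x - a 1) / n. With ``use_se`` the tip
    covariance is V = sigma^2 C + diag(se^2) and sigma^2 is profiled by
    bounded one-dimensional ML.
    """
    order = tree.tip_labels
    m, se, _ = x.arrays(order)
    C = vcv(tree, tip_order=order).C
    n = len(m)

    if not use_se:
        a_hat, _ = _gls_root(C, m)
        r = m - a_hat
        sigma2 = float(r @ np.linalg.solve(C, r)) / n
        if sigma2 == 0.0:
            # degenerate: identical tip values
            return BmFit(0.0, a_hat, np.inf, use_se=False)
        V = sigma2 * C
        return BmFit(sigma2, a_hat, _mvn_loglik_profile(C, m, V), use_se=False)

    D = np.diag(se**2)
    var_scale = max(float(np.var(m)), 1e-8)

    def neg_ll(log_s2: float) -> float:
        V = np.exp(log_s2) * C + D
        return -_mvn_loglik_profile(C, m, V)

    res = scipy.optimize.minimize_scalar(
        neg_ll,
        bounds=(np.log(var_scale) - 20.0, np.log(var_scale) + 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma2 = float(np.exp(res.x))
    V = sigma2 * C + D
    ones = np.ones(n)
    a_hat = float(ones @ np.linalg.solve(V, m)) / float(
        ones @ np.linalg.solve(V, ones)
    )
    return BmFit(sigma2, a_hat, -float(res.fun), use_se=True)


def bm_asr(
    tree: PhyloTree, x: ContinuousTipData, fit: BmFit | None = None
) -> ContAsrResult:
    """ML ancestral angle estimates with 95% confidence intervals.

    Each internal node's estimate is its conditional expectation under the
    joint BM Gaussian given the tips, with a flat prior on the (unknown) root
    value; the variance folds in the root-estimate uncertainty. CIs are
    estimate +/- 1.96 sd with the fitted sigma^2 plugged in.
    """
    if fit is None:
        fit = bm_fit(tree, x)
    order = tree.tip_labels
    m, se, _ = x.arrays(order)
    C = vcv(tree, tip_order=order).C
    n = len(m)
    s2 = fit.sigma2
    Sxx = s2 * C
    if fit.use_se:
        Sxx = Sxx + np.diag(se**2)

    depths = tree.depths()
    tip_ids = [tree.tip_by_label(lab).id for lab in order]
    internal = [v.id for v in tree.nodes if not v.is_tip]

    estimates: dict[int, float] = {}
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}

    if s2 == 0.0:
        # all conditional estimates collapse onto the (constant-compatible) root
        for v in internal:
            estimates[v] = fit.root_state
            lo[v] = hi[v] = fit.root_state
        return ContAsrResult(estimates, lo, hi)

    ones = np.ones(n)
    Sxx_inv_1 = np.linalg.solve(Sxx, ones)
    Sxx_inv_x = np.linalg.solve(Sxx, m)
    var_a = 1.0 / float(ones @ Sxx_inv_1)
    a_hat = var_a * float(ones @ Sxx_inv_x)
    resid_w = Sxx_inv_x - a_hat * Sxx_inv_1  # = Sxx^{-1} (x - a_hat 1)

    for v in internal:
        svx = np.array(
            [s2 * depths[tree.mrca(v, ti)] for ti in tip_ids]
        )  # shared-path covariance node v vs each tip
        svv = s2 * depths[v]
        est = a_hat + float(svx @ resid_w)
        w = np.linalg.solve(Sxx, svx)
        cond_var = svv - float(svx @ w) + (1.0 - float(svx @ Sxx_inv_1)) ** 2 * var_a
        sd = np.sqrt(max(cond_var, 0.0))
        estimates[v] = est
        lo[v] = est - 1.96 * sd
        hi[v] = est + 1.96 * sd
    return ContAsrResult(estimates, lo, hi)


# -- phylogenetic signal ------------------------------------------------------


def _k_statistic(C: np.ndarray, m: np.ndarray) -> float:
    """Blomberg's K for data m on covariance C (no measurement error)."""
    n = len(m)
    ones = np.ones(n)
    Ci_1 = np.linalg.solve(C, ones)
    Ci_m = np.linalg.solve(C, m)
    denom_1 = float(ones @ Ci_1)
    a = float(ones @ Ci_m) / denom_1
    r = m - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ np.linalg.solve(C, r)) / (n - 1)
    if mse == 0.0:
        raise ZeroDivisionError("constant trait: K undefined")
    observed = mse0 / mse
    expected = (float(np.trace(C)) - n / denom_1) / (n - 1)
    return observed / expected


def blomberg_k(
    tree: PhyloTree,
    x: ContinuousTipData,
    use_se: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Blomberg's K with a tip-permutation test.

    K compares the observed ratio of non-phylogenetic to phylogenetic mean
    squared error against its Brownian-motion expectation; K = 1 under BM,
    K > 1 indicates stronger-than-BM conservatism. With ``use_se`` the
    covariance is rescaled to C* = C + diag(se^2)/sigma^2 with sigma^2 from
    the measurement-error BM fit, and sigma^2 is re-estimated under every
    permutation (mean, se) pairs stay together.
    """
    order = tree.tip_labels
    n = len(order)
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m, se, nrep = x.arrays(order)
    if np.ptp(m) == 0.0:
        raise ZeroDivisionError("constant trait: K undefined")
    C = vcv(tree, tip_order=order).C

    def k_of(mv: np.ndarray, sev: np.ndarray) -> tuple[float, float]:
        if use_se:
            xt = ContinuousTipData(
                {sp: (float(mv[i]), float(sev[i]), int(nrep[i]))
                 for i, sp in enumerate(order)}
            )
            fit = bm_fit(tree, xt, use_se=True)
            s2 = fit.sigma2
            Cs = C + np.diag(sev**2) / s2 if s2 > 0 else C
            return _k_statistic(Cs, mv), s2
        return _k_statistic(C, mv), float("nan")

    K_obs, s2_hat = k_of(m, se)
    if not use_se:
        fit = bm_fit(tree, x, use_se=False)
        s2_hat = fit.sigma2

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        K_p, _ = k_of(m[perm], se[perm])
        if K_p >= K_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return SignalResult(K=K_obs, p_value=p, n_permutations=n_perm, sigma2_hat=s2_hat)


def signal_across_trees(
    trees: list[PhyloTree],
    x: ContinuousTipData,
    use_se: bool = False,
    n_perm: int = 99,
    seed: int = 0,
) -> tuple[list[SignalResult], dict[str, float]]:
    """K on every tree in a posterior/bootstrap set, with a five-number summary."""
    if not trees:
        raise ValueError("empty tree list")
    species = set(x.species())
    for i, t in enumerate(trees):
        missing = [lab for lab in t.tip_labels if lab not in species]
        extra = [lab for lab in species if lab not in t.tip_labels]
        if missing or extra:
            raise ValueError(
                f"tree {i}: tip/data mismatch (tree-only: {missing}, data-only: {extra})"
            )
    results = [
        blomberg_k(t, x, use_se=use_se, n_perm=n_perm, seed=seed + i)
        for i, t in enumerate(trees)
    ]
    ks = np.array([r.K for r in results])
    summary = {
        "min": float(ks.min()),
        "q1": float(np.quantile(ks, 0.25)),
        "median": float(np.median(ks)),
        "q3": float(np.quantile(ks, 0.75)),
        "max": float(ks.max()),
    }
    return results, summary


def classify_architecture_by_angle(
    mean_angle: float,
    linear_threshold: float = 40.0,
    transversal_threshold: float = 80.0,
) -> str:
    """Coarse architecture class from the zooid-stolon angle.

    Below 40° a chain is linear-like (zooids near-parallel to the stolon);
    at 80° and above it is transversal-like (near-perpendicular, as in
    transversal chains, whorls, and clusters); in between it is oblique.
    """
    if not 0.0 <= mean_angle < 180.0:
        raise ValueError(f"angle {mean_angle} outside [0, 180)")
    if mean_angle < linear_threshold:
        return "linear-like"
    if mean_angle >= transversal_threshold:
        return "transversal-like"
    return "oblique"
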