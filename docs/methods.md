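# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `salparch`. It is written for users who want to know exactly
what is computed, under which assumptions, and what the synthetic-data tests
do and do not establish about real data.

## The developmental ontology and ordered Markov models

Colony architectures are treated as states of a continuous-time Markov chain
(CTMC) on a rooted time tree. The biological structure enters through the
*developmental ontology*: an undirected graph over the seven architectures
(transversal, oblique, linear, bipinnate, helical, whorl, cluster) with six
edges — transversal–oblique, oblique–linear, linear–bipinnate,
transversal–helical, transversal–whorl, whorl–cluster. Each edge corresponds
to the gain or loss of one developmental transformation mechanism; paths
between non-adjacent architectures must traverse the intermediate forms.

A rate model compiles the graph into a parameterized generator Q:

| kind | allowed transitions | free parameters (salp preset) |
|---|---|---|
| `ordered_asymmetric` | ontology edges, each direction its own rate | 12 |
| `ordered_single` | ontology edges, one shared rate | 1 |
| `equal_rates` | all pairs, one shared rate | 1 |
| `all_rates_different` | all pairs, each its own rate | 42 |

Forbidden entries are exact zeros, so one-step transition probabilities
between non-adjacent states vanish to first order in time: P(t)[i,j] =
O(t^d), d the graph distance. Q is *not* normalized to unit expected rate:
rates are free parameters on a fixed time tree, in units of expected
transitions per unit branch length. Parameter ids are assigned row-major
over the ordered state list, so posterior summaries are comparable across
runs. The preset ontology does not include an oblique–bipinnate edge: the
bipinnate form is reached through linear only, which is the reading the
six-edge pathway model implies (taxa that blur this, like *Brooksia*, are a
documented exception to the ontology, not part of the preset).

## Likelihood machinery

**Transition probabilities.** P(t) = exp(Qt) is computed by
eigendecomposition (symmetric generators via `eigh`; general ones via `eig`
when the eigenvector matrix is well-conditioned, condition number < 1e8, and
reconstructs Q to 1e-9 relative). Two exact facts about generators are
pinned against numerical noise: the simple zero eigenvalue is clamped to
exactly 0, and eigenvalue real parts are clamped to ≤ 0. If the resulting
rows still deviate from 1 by more than 1e-8 (which can happen for extreme
rate magnitudes proposed during MCMC), the computation falls back to
scaling-and-squaring (`scipy.linalg.expm`); only if that also fails is an
error raised. Rows are renormalized to sum to exactly 1; t = 0 returns the
identity without an exponential. A caveat documented for oracle design:
entries for developmentally distant pairs at short times are of size ~t^d
and carry absolute (not relative) precision under any dense matrix
exponential, so independent kernels agree to ~1e-15 absolutely but can
disagree relatively on such entries.

**Pruning.** Felsenstein's postorder dynamic program with per-node
renormalization; scaling factors accumulate in log space, so tiny rates and
deep trees do not underflow. Ambiguity sets (including "?" = fully missing)
enter as indicator tip partials. Patterns impossible under a given Q yield
−inf log-likelihood rather than an exception (the MCMC treats them as
rejections).

**Marginal ancestral states.** Belief propagation: a preorder pass computes
upward messages U[v] carrying all evidence outside v's subtree, and the
marginal at v is ∝ U[v]·L[v]. This is valid for non-reversible generators —
ordered asymmetric models are not reversible, so the common rerooting trick
is deliberately avoided. MAP-state ties break on state order in the state
space.

**ML fitting.** Rates are optimized on the log scale in [−12, 6] nats by
L-BFGS-B with one heuristic start (one expected change per tree height) plus
seeded random restarts (default 5). A boundary fit at e^-12 is the expected
outcome for invariant characters.

## Bayesian inference and stochastic mapping

**Priors.** Independent Exponential(mean = 10/tree height) on each rate —
weakly informative on the expected-number-of-changes scale. The mean is
configurable.

**Sampler.** Metropolis-Hastings with multiplicative log-normal proposals,
one rate updated per iteration in round-robin. Proposal scales auto-tune
during burn-in toward 20–40% acceptance, bounded in [1e-3, 10] so a
likelihood-free posterior cannot drive them unbounded. Defaults: 20,000
iterations, 25% burn-in, thinning 10. Effective sample sizes use the initial
positive sequence estimator; any parameter with ESS < 100 sets a warning
flag on the chain (not fatal). Chains are exactly reproducible from the
seed.

**Node PPs.** `bayes_asr` averages fixed-Q marginal reconstructions over (at
most 200, evenly spaced) posterior rate draws — i.e. PPs are marginal
probabilities averaged over the rate posterior, not frequencies of sampled
joint histories. Joint-history sampling is available separately
(`sample_joint_node_states`, `stochastic_map`) for users who want the other
convention.

**Stochastic mapping.** For a fixed Q (ML plug-in by default, matching
common practice), internal node states are drawn jointly — root from its
marginal, children conditionally downward — and each branch is bridged
between its endpoint states. The bridge sampler first tries rejection
(forward Gillespie paths, capped at 1,000 attempts per branch) and then
switches to uniformization: the jump count is drawn from its exact
conditional distribution under the uniformized chain R = I + Q/μ, the state
sequence by backward sampling over powers of R, jump times as uniform order
statistics, and virtual jumps are discarded. The fallback matters for
ordered generators, where rejection stalls on developmentally distant
endpoint pairs. Summaries report per-node state frequencies, expected
transition counts by type, and expected dwell times (which sum exactly to
the tree length).

## Brownian motion, measurement error, and Blomberg's K

**Model.** The zooid-stolon angle evolves as Brownian motion with rate σ²
(deg² per unit branch length) around an unknown root value. Tip covariance
is σ²C with C the shared-path matrix; with measurement error the observed
covariance is V = σ²C + diag(se²), where se is each species' standard error
(sd/√n over replicate zooid measurements). Angles are treated as plain
linear quantities: observed values lie in [0°, 90°], far from circular
wraparound, so no circular statistics are used.

**Fitting.** Without SE, the root is the GLS estimate and σ̂² has the
closed-form ML solution (divide by n, not n−1; the K formula below uses n−1
internally regardless, matching the standard implementations' behavior).
With SE, σ² is profiled by bounded one-dimensional ML on the log scale. Note
that R's `ace` reports a rate scaled by n/(2n−2) relative to this marginal
ML convention because it maximizes the joint likelihood of states and rate;
the test suite pins down that correspondence exactly.

**Ancestral estimates.** Each internal node's estimate is its conditional
expectation under the joint BM Gaussian given the tips with a flat prior on
the root value; the conditional variance includes the root-uncertainty term
(1 − Σ_vx V⁻¹1)²·var(â). Without measurement error this is algebraically
identical to the rerooted GLS estimate, which the tests exploit as an
independent oracle. CIs use the 1.96 normal multiplier (95%).

**Blomberg's K.** K = (MSE0/MSE) / E_BM[MSE0/MSE], with MSE0 the ordinary
mean squared deviation from the phylogenetic mean, MSE its GLS counterpart,
and the expectation term (tr C* − n/(1'C*⁻¹1))/(n−1). With measurement
error, C* = C + diag(se²)/σ̂² with σ̂² from the SE-aware fit; this is the
standard known-SE construction, chosen from several variants the literature
leaves open, and isolated behind the `use_se` flag. K = 1 is the BM
expectation (exactly 1 on a star tree, an algebraic identity the tests
assert); K > 1 indicates conservatism. Significance uses a permutation test
(default 999 permutations) that shuffles (mean, se) pairs jointly across
tips, preserving the error structure under the null; with `use_se`, σ² is
re-estimated per permutation. p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1). The
multi-tree sweep recomputes K per tree and reports the five-number summary.

## Tree preparation

**Ultrametricity.** `is_ultrametric` checks root-to-tip distances against
their mean at a relative tolerance. `make_ultrametric` is mean-path-length
(MPL) dating: each internal node's age is the mean path length to its
descendant tips, clamped to its parent's age so branch lengths stay
nonnegative; tips sit at age 0. This is a deterministic, order-preserving
substitute for penalized-likelihood dating, adequate for synthetic pipelines
— it is *not* a molecular-clock method and should not be used to date real
chronograms.

**Representative pruning.** When several specimens of one species are
present, one tip per species is retained: species are processed in
alphabetical order, and within a species the tip maximizing the summed
patristic distance to all other species' current candidate tips wins, with
ties broken by lexicographic tip label (the ambiguity in how equally distant
duplicates should be resolved is real; this rule is a documented choice, not
an inference). Nested duplicates — the specimens most likely to be hybrids
or misidentifications — are thereby dropped. Patristic distances among
retained tips are unchanged; resulting unary nodes collapse with branch
lengths summed.

**Newick dialect.** Internal node labels are read as support values;
bracketed `[&key=value]` comments carry per-node annotations (e.g. state
PPs) and survive round trips. Missing branch lengths parse as 0 with a
warning; negative lengths are rejected.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical shape* of the study design:

* `simulate_yule_tree` — pure-birth trees (ultrametric by construction),
  with the conventional trailing Exp(nλ) interval so the expected height is
  Σ_{k=2..n} 1/(kλ). Birth–death trees are a possible extension, not
  implemented.
* `simulate_discrete_history` — exact forward Gillespie simulation of the
  CTMC along each branch; under an ordered Q no sampled history can cross a
  non-edge (a constructional guarantee the test suite asserts anyway).
* `simulate_bm_angles` — BM tip values plus Normal(0, within_sd) replicate
  noise, summarized exactly as a field study would: mean, SE = sample
  sd/√n, and n. Values are clipped to [0°, 180°) and every clip is logged;
  at preset parameters clips are rare, keeping the BM assumption testable.

`salp_preset` fixes the study-scale conditions: 22 species on a unit-height
Yule tree; ordered-asymmetric rates of 1.0 (away from transversal) and 0.5
(toward it) per unit height — asymmetric so derived architectures arise
repeatedly while reversals remain plausible, and scaled so at least three
architectures are observed in ≥95% of seeds; root state fixed at oblique;
root angle 45° with σ² = 500 deg² and 2–4 replicate measurements at 5°
within-colony noise.

One deliberate modeling device: the preset's angles are simulated under BM
on a node-height-transformed copy of the tree (delta = 0.3, i.e. depths
mapped to T·(d/T)^0.3), while all analyses run on the untransformed tree.
Pure BM cannot produce conservatism — K is scale-invariant in σ², E[K] ≈ 1
for any rate, and measurement noise only pushes K down — so emulating the
strong signal real salp angles show (K well above 1) requires concentrating
divergence near the root. delta = 0.3 was calibrated once by simulation to
give mean K ≈ 1.5 across seeds; individual seeds still vary widely (roughly
0.4–3), which is the honest sampling behavior of K at n = 22.

What passing tests therefore show: the estimators recover the parameters of
their own generating processes at study scale, the samplers are calibrated,
and every algebraic identity holds. What they do not show: robustness to
model violations real salp data may carry — non-BM angle evolution beyond
the delta device, rate heterogeneity across lineages, correlated characters,
or tree-estimation error beyond branch-length jitter.

## Problem sizes and defaults used in verification

The test suite verifies the pruning likelihood and marginal reconstructions
against exhaustive enumeration on 1,000 random trees of 2–5 tips; BM
reconstructions against the rerooted-GLS oracle on trees of up to 8 tips;
simulator-vs-likelihood agreement by χ² on 20,000 forward draws of a 4-tip
tree; stochastic-mapping consistency on 10,000 maps of a 5-tip tree; MCMC
calibration on 50 replicate 22-species datasets at 20,000 iterations each;
and continuous recovery at 300 tips (rate) and 100-tip Yule trees (K). The
acceptance script runs the full pipeline once at the preset scale with
999-permutation significance and a 25-tree sensitivity sweep. These sizes
were chosen as the smallest at which the sampling-based checks have clear
resolution.

## Known limitations

* Single discrete character; no rate heterogeneity across characters or
  hidden rate classes.
* The root prior defaults to uniform over states (the non-reversible ordered
  models have no canonical stationary prior); custom priors are supported
  but no root-frequency estimation is attempted.
* MPL dating is a pipeline utility, not a dating method.
* No model comparison machinery (marginal likelihoods, reversible jump);
  competing rate models are compared descriptively.
* K's null permutation assumes exchangeable tips under the null; heavily
  unbalanced measurement error violates this only mildly (pairs are
  permuted together) but is not otherwise modeled.
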