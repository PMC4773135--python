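# Methods

## Model

`gbnlearn` models a set of continuous measurements (e.g., expression levels
of a small panel of genes) as a Gaussian Bayesian network: a DAG `G` in which
each node is a linear function of its parents plus independent Gaussian
noise,

    X_j | X_Pa(j) ~ N( m_j + Σ_{i∈Pa(j)} w_ij X_i , σ_j² ).

The joint observational distribution is multivariate normal with covariance
`(I − W)⁻ᵀ diag(σ²) (I − W)⁻¹`, where `W` is the weighted adjacency matrix.

Interventions (knockouts clamp a node at zero; knockdowns at a lowered
value) are modeled by graph mutilation: the clamped nodes' incoming edges
are removed and the clamped values are substituted wherever those nodes
appear as parents. The likelihood of an intervention instance is the product
of the conditional densities of the unclamped nodes only; nodes upstream of
a clamp are unaffected. Clamped values are stored inside the instance
vectors, so a dataset is a dense matrix plus an intervention annotation per
row.

Assumptions worth stating: acyclicity (feedback loops are outside the model
class), linearity of parent effects, homoscedastic Gaussian noise per node,
and hard (deterministic-value) interventions whose target values are known
to the learner.

## Structure scoring

The likelihood factorizes over families (a node and its parents) even with
clamping, so each family carries an independent normal–inverse-Gamma prior

    σ_j² ~ Inv-Gamma(α_j, β_j),    θ_j | σ_j² ~ N(μ_j, σ_j² Λ_j⁻¹),

with `θ_j = (m_j, w_{p₁j}, …, w_{p_d j})`. The family dataset `(X_j, y_j)`
collects the rows of instances where node j is unclamped (a clamped parent
still contributes its value to the design). The conjugate update is

    Λ′ = XᵀX + Λ,   μ′ = Λ′⁻¹(Λμ + Xᵀy),
    α′ = α + t/2,   β′ = β + (yᵀy + μᵀΛμ − μ′ᵀΛ′μ′)/2,

where `t` is the family's row count, and the per-family log evidence is

    −(t/2)·log 2π + ½·(log det Λ − log det Λ′)
      + α log β − α′ log β′ + log Γ(α′) − log Γ(α).

Two numerical/interpretive choices here were genuinely open and are fixed as
follows. First, the determinant ratio enters under a square root: this is
the standard NIG evidence and is what agrees with direct numerical
integration of the model (the test suite checks relative agreement to 1e-4
against quadrature oracles on one- and two-node families). Second, the α
update uses the family-specific row count `t/2` rather than the full data
count: with per-family clamping this is the only choice under which the
per-family evidences multiply to the joint marginal likelihood with its
`(2π)^{−c/2}` normalization, `c` being the total number of unclamped
entries. Both choices are validated by the quadrature oracle.

Default hyperparameters are `α=1, β=1, μ=0, Λ=I` for every family dimension,
overridable through `Priors`. All probability computations run in log space;
log-determinants come from `slogdet`.

### Rank-one predictive likelihoods

The selector needs `p(x | I, G, D, 𝕀)` for many hypothetical outcomes `x`.
Each is an evidence ratio whose only change is a single added row `v` per
family, so the cached posterior `(Λ′⁻¹, log det Λ′, μ′, α′, β′)` is updated
with the Sherman–Morrison formula and the matrix determinant lemma in
`O(d²)`, never touching the accumulated data. The resulting per-family
increment is the Student-t predictive density

    t( df = 2α′, loc = vᵀμ′, scale² = β′(1 + vᵀΛ′⁻¹v)/α′ )

evaluated at the node's value; the test suite checks the rank-one path
against full evidence recomputation to 1e-8 and against dense
inverse/determinant recomputation to relative 1e-10.

## Posterior sampling over DAGs

Metropolis–Hastings with a proposal uniform over the single-edge
neighborhood (insertion, deletion, reversal), restricted to moves that keep
the graph acyclic and within a maximum in-degree (default 5); the structure
prior is uniform over DAGs inside the cap. Moves that would violate either
constraint are excluded from the neighborhood rather than proposed and
rejected, so the Hastings correction `|N(G)|/|N(G′)|` is required and
included. Only the one or two families changed by a move are rescored, and
family evidences are memoized per (node, parent-set) for a fixed dataset, so
chains sharing a dataset share scores. Reversal legality uses the fact that
in a DAG any length-≥2 path i→…→j cannot pass through the edge (i, j)
itself, so a single reachability computation per step suffices.

Chains start from the empty graph by default (a greedy hill-climb start is
available). Belief updates after acquiring one instance re-use the previous
sample as initialization and advance each chain independently (default 100
steps) with per-chain RNG substreams, so propagation is order-independent.
On three-node problems, where all 25 DAGs can be enumerated, the chain's
stationary distribution matches the exact posterior within total variation
0.05 at 10⁵ steps.

## Intervention selection

The utility of a candidate intervention is the mutual information between
the graph and the hypothetical outcome given current data, estimated as in
the greedy information-theoretic design framework: S posterior graph
samples, R outcome draws from the proposal `q` = posterior predictive of the
empty graph (every node independent, clamped coordinates fixed), and
self-normalized importance weights per graph. The estimator groups
duplicate graph samples and weights by multiplicity — algebraically
identical, faster when chains have converged, and it makes ψ̂ exactly zero
for a degenerate belief. Outcome draws are shared across graphs within one
candidate evaluation, as the estimator requires; RNG substreams are keyed by
(round, candidate index), so candidates are evaluated on independent draws
and re-runs are reproducible. Ties at the argmax break toward the lowest
candidate index.

The default candidate set is all single-node knockouts (clamp at zero).
Pre-generated outcome pools are consumed without replacement; candidates
with exhausted pools drop out of the search, and the loop stops early with a
warning if the pool empties.

## Simulated ground truth

The simulator draws a random DAG by drawing a uniform topological order and
including each forward pair independently (default edge probability 0.25,
in-degree cap applied during generation — the structure law is a package
choice; only the network size is prescribed by the study protocol), then
samples edge weights uniformly on (−1,−.25) ∪ (.25,1), base levels from
N(0,1), and sets every noise sd to σ = 0.05. The study protocol uses 10
observational instances and two pre-generated knockout outcomes per node.

What the simulation does *not* emulate about real expression data: feedback
loops, non-Gaussian and heteroscedastic measurement noise, partial
knockdowns with unknown achieved levels, hidden confounders, and
activity-vs-abundance mismatches of real perturbations. Passing the
simulated benchmarks therefore demonstrates correctness of the inference
and selection machinery under the model's own assumptions, not robustness
to their violation.

## Evaluation

Edges are ranked by `|E[ŵ_MAP]|`, averaging each sampled graph's posterior
mean weight (zero for absent edges) over the belief sample. AUROC uses
tie-block averaging and AUPRC the standard step integral (both via
scikit-learn); the default evaluation is on directed ordered pairs, with an
undirected-skeleton mode available. MSE is taken over all n(n−1) ordered
pairs against the generating weights.

Convergence of a learner is the KL divergence of the final belief from the
current belief over a fixed candidate-graph set: 5000 (2000 in the reduced
budget) random DAGs drawn once per run from the same structure law as the
simulator and held fixed across rounds; posteriors are normalized over this
set (the uniform structure prior cancels). KL(final ‖ current) reaches
exactly zero when the learner has consumed the whole pool.

## Budgets and reduced settings

The full protocol uses S=1000 graph samples, R=100 outcome draws, burn-in
10,000, thinning 100, propagation 100 steps, and 5000 candidate graphs. The
test suite and the acceptance script run S=300 and 2000 candidate graphs —
a linear-cost reduction in the two dominant terms — while keeping R=100:
outcome draws are cheap, and ψ̂ rankings at R=50 were noticeably less stable
between repetitions than at R=100.

## Known limitations

- The ψ̂ estimator self-normalizes importance weights from a broad
  independent proposal; in ten dimensions its effective sample size per
  graph is often near one. Its variance is largest (with a downward bias)
  for precisely the candidates whose predictive distributions disagree most
  with the proposal — the most informative ones — so at R ≈ 100 the
  selector occasionally misses a critical intervention for several rounds.
  Negative ψ̂ values are a symptom of this regime; raising R is the remedy
  when the selection step is not the runtime bottleneck.
- Marginal-likelihood structure identification degrades when σ is tiny
  relative to signal: nodes become near-deterministic functions of each
  other, so collinear proxies can substitute for true parents and the
  posterior spreads over structurally different but near-equivalent graphs.
  Under the default priors, final-accuracy AUROC on the simulated protocol
  typically lands in the 0.8–0.95 range per seed rather than uniformly above
  0.9; the convergence ordering (active faster than random) is robust.
- The NIG prior is not score-equivalent across Markov-equivalent DAGs
  (unlike a BGe-style prior); observational data alone can weakly prefer one
  orientation.
- Exhaustive candidate search scales linearly in the candidate set; joint
  interventions are representable but the combinatorial candidate explosion
  is the user's to manage.
- Intended for small networks; the super-exponential DAG space makes the
  sampler impractical well before n = 30 on a single CPU.
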