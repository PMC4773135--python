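# gbnlearn

Bayesian active learning of causal **Gaussian Bayesian networks** (GBNs)
from mixed observational and intervention data, for small gene-regulatory or
signaling networks (≲ 30 nodes) where knockout/knockdown experiments are
expensive and must be prioritized.

## The model and the method

A GBN is a DAG `G` over variables `X_1 … X_n` with linear-Gaussian
conditionals

```
X_j | X_Pa(j)  ~  N( m_j + Σ_{i∈Pa(j)} w_ij X_i ,  σ_j² )
```

An intervention clamps a subset of nodes at fixed values `(i, c_i)`; the rest
of the system follows the *mutilated* graph with the clamped nodes' incoming
edges removed, so upstream nodes are unaffected. The likelihood of an
intervention instance is the product of the family terms of the **unclamped**
nodes only.

Each family (node + parents) carries a conjugate normal–inverse-Gamma prior
on `(θ_j, σ_j²)`, giving a closed-form marginal likelihood `p(D | 𝕀, G)`
(the structure score). Graphs are sampled from `p(G | D, 𝕀)` by
Metropolis–Hastings over single-edge insertions/deletions/reversals, with a
uniform structure prior under an in-degree cap and the Hastings correction
for unequal neighborhood sizes.

Experiments are chosen greedily by the mutual information between the graph
and the outcome of a candidate intervention `I`,

```
ψ(I) = MI(G ; X | D, 𝕀)
```

estimated with `S` posterior graph samples and `R` outcome draws from an
importance proposal (the empty-graph posterior predictive), using
self-normalized weights. Each predictive density `p(x | I, G, D, 𝕀)` is an
evidence ratio computed in `O(d²)` per family through Sherman–Morrison /
matrix-determinant-lemma rank-one updates of the cached posterior precision.

Accuracy is summarized by AUROC/AUPRC over edges ranked by the
model-averaged MAP weight `|E[ŵ_ij | D, 𝕀]|`, the MSE of the signed weights
against the generating parameters, and a convergence measure: the KL
divergence of the *final* belief (posterior over a fixed random
candidate-graph set under the complete dataset) from the current belief.

## Worked example

Simulate a 6-node ground truth, run the active learner for five rounds, and
evaluate the ranked edges:

```
$ gbnlearn simulate --nodes 6 --seed 4 --observational 10 --outdir sim
wrote ground truth and data for 6 nodes to sim

$ gbnlearn run --truth-edges sim/truth_edges.tsv --truth-params sim/truth_params.tsv \
    --data sim/expression.tsv --interventions sim/interventions.tsv \
    --pool-data sim/pool_expression.tsv --pool-interventions sim/pool_interventions.tsv \
    --learner active --rounds 5 --samples 200 --outcome-samples 50 \
    --burn-in 2000 --thinning 20 --candidate-graphs 500 --seed 4 --outdir run
active learner finished 5 rounds; metrics in run/metrics.tsv

$ cat run/metrics.tsv
round	kl	auroc	auprc	mse
0	1.826331378	0.3888888889	0.2342909056	0.06652385403
1	1.610008482	0.4305555556	0.2439505271	0.06369343077
2	0.5575904443	0.5138888889	0.3507936508	0.05253366526
3	0.1539687321	0.6597222222	0.4183740236	0.04830212367
4	0.09903105637	0.6527777778	0.4333994709	0.04743503192
5	0.06148543275	0.6597222222	0.4501322751	0.04668235958

$ head -4 run/network.tsv
source	target	score	signed_weight
G3	G6	0.587589021688	0.587589021688
G4	G3	0.118632902114	-0.118632902114
G1	G6	0.0847985622986	0.0847985622986
```

Per-round `kl` is the divergence of the final belief from the current one —
it falls from 1.83 to 0.06 as the learner acquires the five interventions
that matter, meaning five experiments recovered most of what the full pool
would teach. `auroc`/`auprc` score the ranked directed-edge list against the
simulated truth (they climb as orientations resolve; the tiny demo budget of
200 graph samples keeps them modest); `mse` is the squared error of the
model-averaged edge weights. `run/network.tsv` holds the final ranked edges,
`run/trajectory.jsonl` the chosen intervention and ψ table per round, and
`run/manifest.json` everything needed to reproduce the run.

The same loop is available as a library:

```python
from gbnlearn import (ActiveConfig, CandidatePool, McmcConfig, Priors,
                      generate_random_dag, generate_random_gbn, run_active_loop)
```

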