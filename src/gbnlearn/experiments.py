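"""Reproducible simulated-study harness.

One trial: draw a random 10-node ground-truth GBN (edge weights uniform on
(-1,-.25) U (.25,1), base levels standard normal, noise sd 0.05), sample 10
observational instances, pre-generate 2 knockout outcomes per node (clamp at
zero), run the active or random learner consuming the pool without
replacement, and track per round the KL divergence of the final belief (the
posterior over a fixed random candidate-graph set under the complete data)
from the current belief, plus AUROC/AUPRC/MSE of the model-averaged network.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .active import ActiveConfig, CandidatePool, run_active_loop, run_random_loop
from .evaluation import (
    auroc_auprc,
    generate_candidate_graphs,
    map_edge_scores,
    mse_weights,
)
from .gbn import GBN, OBSERVATIONAL, DAG, Dataset, generate_random_dag, generate_random_gbn, sample_data
from .mcmc import McmcConfig, sample_graphs
from .scoring import Priors, ScoreCache

__all__ = ["SimulationProtocol", "TrialResult", "run_convergence_trial", "full_data_belief"]


@dataclasses.dataclass(frozen=True)
class SimulationProtocol:
    """Study conditions for the simulated convergence experiment."""

    n_nodes: int = 10
    edge_prob: float = 0.25
    sigma: float = 0.05
    n_observational: int = 10
    knockout_copies: int = 2
    knockout_value: float = 0.0
    n_rounds: int = 20
    n_graph_samples: int = 1000  # S
    n_outcome_samples: int = 100  # R
    burn_in: int = 10_000
    thinning: int = 100
    propagate_steps: int = 100
    max_in_degree: int = 5
    n_candidate_graphs: int = 5000

    def mcmc_config(self, seed: int) -> McmcConfig:
        return McmcConfig(
            n_samples=self.n_graph_samples,
            burn_in=self.burn_in,
            thinning=self.thinning,
            max_in_degree=self.max_in_degree,
            propagate_steps=self.propagate_steps,
            seed=seed,
        )


@dataclasses.dataclass
class TrialResult:
    seed: int
    learner: str
    truth: GBN
    rounds: list[int]
    kl: list[float]
    auroc: list[float]
    auprc: list[float]
    mse: list[float]

    def kl_at(self, round_index: int) -> float:
        return self.kl[self.rounds.index(round_index)]


def _ground_truth(protocol: SimulationProtocol, seed: int, truth_seed: int | None = None):
    """Ground-truth model plus per-trial data.  The network and its
    parameters are keyed by ``truth_seed`` (default: the trial seed), so
    several trials can share one truth while redrawing data and pool."""
    ts = seed if truth_seed is None else truth_seed
    dag = generate_random_dag(
        protocol.n_nodes, protocol.edge_prob, protocol.max_in_degree, [ts, 100]
    )
    gbn = generate_random_gbn(dag, [ts, 101], sigma=protocol.sigma)
    obs = sample_data(gbn, count=protocol.n_observational, seed=[seed, 102])
    initial = Dataset(obs, (OBSERVATIONAL,) * protocol.n_observational)
    pool = CandidatePool.pregenerated_knockouts(
        gbn, protocol.knockout_copies, protocol.knockout_value, [seed, 103]
    )
    final = initial
    for idx, outs in enumerate(pool.outcomes):
        for x in outs:
            final = final.append(x, pool.candidates[idx])
    return gbn, initial, pool, final


def _log_posterior(candidates: Sequence[DAG], dataset: Dataset, priors: Priors) -> np.ndarray:
    cache = ScoreCache(dataset, priors)
    logp = np.array([cache.log_marginal(g) for g in candidates])
    return logp - logsumexp(logp)


def run_convergence_trial(
    seed: int,
    learner: str = "active",
    protocol: SimulationProtocol = SimulationProtocol(),
    priors: Priors | None = None,
    eval_rounds: Sequence[int] | None = None,
    truth_seed: int | None = None,
) -> TrialResult:
    """One seeded trial of the simulated experiment; metrics are evaluated at
    ``eval_rounds`` (default: every round reached).  Pass ``truth_seed`` to
    repeat trials against one shared ground-truth network."""
    priors = priors if priors is not None else Priors()
    gbn, initial, pool, final_dataset = _ground_truth(protocol, seed, truth_seed)
    config = ActiveConfig(
        n_rounds=protocol.n_rounds,
        n_outcome_samples=protocol.n_outcome_samples,
        mcmc=protocol.mcmc_config(seed),
        seed=seed,
    )
    runner = run_active_loop if learner == "active" else run_random_loop
    trajectory = runner(pool, initial, config, priors)
    candidates = generate_candidate_graphs(
        protocol.n_nodes,
        protocol.n_candidate_graphs,
        protocol.edge_prob,
        protocol.max_in_degree,
        seed if truth_seed is None else truth_seed,
    )
    log_final = _log_posterior(candidates, final_dataset, priors)
    p_final = np.exp(log_final)
    wanted = set(eval_rounds) if eval_rounds is not None else None
    rounds, kl, auroc, auprc, mse = [], [], [], [], []
    for rec in trajectory.rounds:
        if wanted is not None and rec.round not in wanted:
            continue
        log_cur = _log_posterior(candidates, rec.dataset, priors)
        kl.append(float(p_final @ (log_final - log_cur)))
        scores = map_edge_scores(rec.belief, rec.dataset, priors)
        a, p = auroc_auprc(scores, gbn.dag)
        rounds.append(rec.round)
        auroc.append(a)
        auprc.append(p)
        mse.append(mse_weights(scores, gbn))
    return TrialResult(seed, learner, gbn, rounds, kl, auroc, auprc, mse)


def full_data_belief(
    seed: int,
    protocol: SimulationProtocol = SimulationProtocol(),
    priors: Priors | None = None,
):
    """Posterior sampling on the complete pregenerated data set (initial
    observational instances plus every pool outcome); returns the truth, the
    full dataset, and the belief sample."""
    priors = priors if priors is not None else Priors()
    gbn, _, _, final_dataset = _ground_truth(protocol, seed)
    belief = sample_graphs(final_dataset, priors, protocol.mcmc_config(seed))
    return gbn, final_dataset, belief
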