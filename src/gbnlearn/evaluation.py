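"""Network reconstruction metrics.

Edges are ranked by |E[w_MAP]|, the absolute model-averaged maximum a
posteriori edge weight over posterior graph samples; accuracy is summarized
by AUROC/AUPRC on the ranked directed-edge list and by the mean squared
error of the signed weights against the generating parameters.  Convergence
of a learner is tracked as the KL divergence of the final belief (posterior
over a fixed random candidate-graph set computed on the complete data set)
from the current belief.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import average_precision_score, roc_auc_score

from .gbn import DAG, GBN, Dataset, generate_random_dag
from .mcmc import BeliefSample
from .scoring import Priors, ScoreCache

__all__ = [
    "EdgeScoreMatrix",
    "map_edge_scores",
    "auroc_auprc",
    "mse_weights",
    "kl_to_final",
    "generate_candidate_graphs",
]


@dataclasses.dataclass
class EdgeScoreMatrix:
    """Per-ordered-pair scores; ``scores = |signed_weights|``, diagonal zero."""

    scores: np.ndarray
    signed_weights: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.signed_weights = np.asarray(self.signed_weights, dtype=float)
        if self.scores.shape != self.signed_weights.shape:
            raise ValueError("scores and signed_weights shapes differ")

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def map_edge_scores(
    belief_sample: BeliefSample, dataset: Dataset, priors: Priors
) -> EdgeScoreMatrix:
    """Bayesian model averaging of MAP edge weights.

    For each sampled graph, the MAP weight of a present edge (i, j) is the
    matching entry of the family posterior mean mu'_j (zero when absent);
    the average over samples gives the signed weight and its absolute value
    the ranking score."""
    cache = ScoreCache(dataset, priors)
    uniq, counts = belief_sample.unique_counts()
    n = uniq[0].n
    signed = np.zeros((n, n))
    for g, c in zip(uniq, counts):
        for j in range(n):
            parents = g.parents(j)
            if not parents:
                continue
            mu = cache.family(j, parents)[1].mean
            for pos, i in enumerate(parents):
                signed[i, j] += c * mu[pos + 1]
    signed /= belief_sample.size
    return EdgeScoreMatrix(scores=np.abs(signed), signed_weights=signed)


def _offdiag(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    return mat[~np.eye(n, dtype=bool)]


def auroc_auprc(score_matrix: EdgeScoreMatrix, truth_dag: DAG) -> tuple[float, float]:
    """AUROC and AUPRC over the n(n-1) ordered pairs ranked by score, with
    the true directed edges as positives.  Tied scores are handled by
    tie-block averaging (ROC) and threshold-wise steps (PR)."""
    if truth_dag.n != score_matrix.n:
        raise ValueError("truth graph and score matrix sizes differ")
    y_true = _offdiag(truth_dag.adjacency()).astype(int)
    y_score = _offdiag(score_matrix.scores)
    if y_true.sum() == 0:
        raise ValueError("truth graph has no edges; AUROC/AUPRC undefined")
    return float(roc_auc_score(y_true, y_score)), float(
        average_precision_score(y_true, y_score)
    )


def mse_weights(signed_weights: np.ndarray | EdgeScoreMatrix, truth_gbn: GBN) -> float:
    """Mean squared error of signed weights over all n(n-1) ordered pairs
    (truth zero for absent edges)."""
    if isinstance(signed_weights, EdgeScoreMatrix):
        signed_weights = signed_weights.signed_weights
    est = np.asarray(signed_weights, dtype=float)
    truth = truth_gbn.weight_matrix()
    if est.shape != truth.shape:
        raise ValueError("estimate and truth sizes differ")
    return float(np.mean((_offdiag(est) - _offdiag(truth)) ** 2))


def _log_posterior_over(
    candidates: Sequence[DAG], dataset: Dataset, priors: Priors
) -> np.ndarray:
    """Normalized log posterior over the fixed candidate set (uniform prior
    inside the in-degree cap, hence a constant that cancels)."""
    cache = ScoreCache(dataset, priors)
    logp = np.array([cache.log_marginal(g) for g in candidates])
    return logp - logsumexp(logp)


def kl_to_final(
    current_dataset: Dataset,
    final_dataset: Dataset,
    candidate_graphs: Sequence[DAG],
    priors: Priors,
) -> float:
    """KL(p_final || p_current) of the posteriors over a fixed candidate-graph
    set, each normalized over the set by logsumexp.  Zero when the current
    data already equal the final data."""
    if not len(candidate_graphs):
        raise ValueError("candidate graph set must be non-empty")
    log_cur = _log_posterior_over(candidate_graphs, current_dataset, priors)
    log_fin = _log_posterior_over(candidate_graphs, final_dataset, priors)
    p_fin = np.exp(log_fin)
    return float(np.dot(p_fin, log_fin - log_cur))


def generate_candidate_graphs(
    n: int,
    count: int = 5000,
    edge_prob: float = 0.25,
    max_in_degree: int = 5,
    seed: int = 0,
) -> list[DAG]:
    """A fixed random candidate set for the convergence metric, drawn once per
    run and reused across rounds."""
    rng = np.random.default_rng([int(seed), 7919])
    return [
        generate_random_dag(n, edge_prob, max_in_degree, rng) for _ in range(count)
    ]
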