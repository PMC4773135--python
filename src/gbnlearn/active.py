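"""Information-theoretic intervention selection and the iterative learning loop.

The utility of a candidate intervention I is the mutual information between
the graph G and the experiment outcome X given the data so far,

    psi(I) = MI(G; X | D, II)
           = E_{G ~ p(G|D,II)} [ KL( p(X|G,I,D,II) || p(X|I,D,II) ) ],

estimated with S posterior graph samples and R outcome draws from the
importance proposal q = p(X | G_empty, I, D, II), the posterior predictive of
the empty graph where every node is independent.  With self-normalized
weights v_rs = p(x_r|I,G_s,D,II)/q(x_r) (normalized over r per graph),

    psi_hat = (1/S) sum_s sum_r v_rs log[ p(x_r|I,G_s,D,II)
                                          / (1/S) sum_s' p(x_r|I,G_s',D,II) ].

All predictive densities come from the cached family posteriors via rank-one
updates, so each evaluation costs O(d^2) per family regardless of the number
of samples accumulated.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .gbn import GBN, Dataset, Intervention, sample_data
from .mcmc import BeliefSample, McmcConfig, propagate, sample_graphs
from .scoring import Priors, ScoreCache, log_predictive_batch

__all__ = [
    "ActiveConfig",
    "CandidatePool",
    "MiEstimate",
    "RoundRecord",
    "Trajectory",
    "sample_outcomes_q",
    "importance_weights",
    "estimate_mi",
    "select_intervention",
    "run_active_loop",
    "run_random_loop",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass(frozen=True)
class ActiveConfig:
    """Loop budgets: T rounds, R outcome samples per candidate, and the MCMC
    settings (S graph samples, propagation steps) used for belief updates."""

    n_rounds: int = 20
    n_outcome_samples: int = 100
    mcmc: McmcConfig = dataclasses.field(default_factory=McmcConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if self.n_outcome_samples < 1:
            raise ValueError("n_outcome_samples must be >= 1")

    @property
    def n_graph_samples(self) -> int:
        return self.mcmc.n_samples


@dataclasses.dataclass
class CandidatePool:
    """Candidate interventions, optionally with pre-generated outcomes that
    are consumed without replacement; exhausted candidates drop out."""

    candidates: list[Intervention]
    outcomes: list[list[np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.outcomes is not None and len(self.outcomes) != len(self.candidates):
            raise ValueError("one outcome list per candidate is required")

    @classmethod
    def knockouts(cls, n: int, value: float = 0.0) -> "CandidatePool":
        """All single-node knockouts (clamp at ``value``), unlimited outcomes."""
        return cls([Intervention.knockout(j, value) for j in range(n)])

    @classmethod
    def pregenerated_knockouts(
        cls,
        gbn: GBN,
        copies: int = 2,
        value: float = 0.0,
        seed: int | Sequence[int] = 0,
    ) -> "CandidatePool":
        """Pre-generate ``copies`` outcomes of each single-node knockout from
        the ground-truth model; learners consume them without replacement."""
        base = list(seed) if isinstance(seed, (list, tuple)) else [int(seed)]
        cands = [Intervention.knockout(j, value) for j in range(gbn.n)]
        outs = [
            [row for row in sample_data(gbn, iv, copies, np.random.default_rng(base + [j]))]
            for j, iv in enumerate(cands)
        ]
        return cls(cands, outs)

    def available(self) -> list[int]:
        if self.outcomes is None:
            return list(range(len(self.candidates)))
        return [i for i, lst in enumerate(self.outcomes) if lst]

    def take_outcome(
        self,
        index: int,
        gbn: GBN | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Consume a pre-generated outcome, or sample a fresh one from the
        ground-truth model when the pool is unlimited."""
        if self.outcomes is not None:
            if not self.outcomes[index]:
                raise IndexError(f"candidate {index} has no outcomes left")
            return self.outcomes[index].pop(0)
        if gbn is None:
            raise ValueError("an unlimited pool needs a ground-truth GBN to sample from")
        return sample_data(gbn, self.candidates[index], 1, rng)[0]

    def total_remaining(self) -> int | None:
        if self.outcomes is None:
            return None
        return sum(len(lst) for lst in self.outcomes)


@dataclasses.dataclass
class MiEstimate:
    intervention: Intervention
    psi: float
    per_graph_terms: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.psi):
            raise ValueError("psi must be finite")


def sample_outcomes_q(
    intervention: Intervention,
    dataset: Dataset,
    priors: Priors,
    R: int,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw R outcomes from q = the empty-graph posterior predictive.

    Clamped coordinates take the intervention values; each unclamped node is
    drawn from its intercept-only NIG posterior predictive (sigma^2 from the
    inverse-Gamma, the base level from its conditional normal, then the
    observation).  Returns the draws and their exact log q densities (sums of
    per-node Student-t predictive log densities)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cache = ScoreCache(dataset, priors)
    n = dataset.n
    clamps = intervention.as_dict()
    X = np.empty((R, n))
    logq = np.zeros(R)
    for j in range(n):
        if j in clamps:
            X[:, j] = clamps[j]
            continue
        post = cache.family(j, ())[1]
        a, b = post.alpha, post.beta
        lam = float(post.precision[0, 0])
        mu = float(post.mean[0])
        sigma2 = b / rng.gamma(a, size=R)
        theta = mu + rng.standard_normal(R) * np.sqrt(sigma2 / lam)
        X[:, j] = theta + rng.standard_normal(R) * np.sqrt(sigma2)
        # Student-t predictive: df 2a, location mu, scale^2 b(1 + 1/lam)/a
        q = 1.0 / lam
        a2, b2 = a + 0.5, b + (X[:, j] - mu) ** 2 / (2.0 * (1.0 + q))
        logq += (
            -0.5 * _LOG_2PI
            - 0.5 * math.log1p(q)
            + a * math.log(b)
            - a2 * np.log(b2)
            + gammaln(a2)
            - gammaln(a)
        )
    return X, logq


def importance_weights(log_p_matrix: np.ndarray, log_q_vector: np.ndarray) -> np.ndarray:
    """Self-normalized weights v_rs = vtilde_rs / sum_r' vtilde_r's with
    vtilde_rs = p(x_r|I,G_s,D,II)/q(x_r); each column sums to one."""
    logp = np.atleast_2d(np.asarray(log_p_matrix, dtype=float))
    logq = np.asarray(log_q_vector, dtype=float).ravel()
    if logq.size != logp.shape[0]:
        raise ValueError("log_q length must equal the number of outcome rows")
    logw = logp - logq[:, None]
    col_max = logw.max(axis=0)
    if not np.all(np.isfinite(col_max)):
        raise FloatingPointError("degenerate importance weights: a column is all -inf")
    w = np.exp(logw - col_max)
    return w / w.sum(axis=0)


def estimate_mi(
    intervention: Intervention,
    belief_sample: BeliefSample,
    dataset: Dataset,
    priors: Priors,
    R: int,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> MiEstimate:
    """Monte-Carlo estimate of psi(I) = MI(G; X | D, II).

    Identical graph samples are grouped and weighted by multiplicity, which
    is algebraically the same estimator and makes psi_hat exactly zero for a
    degenerate belief."""
    X, logq = sample_outcomes_q(intervention, dataset, priors, R, seed)
    cache = ScoreCache(dataset, priors)
    uniq, counts = belief_sample.unique_counts()
    S = belief_sample.size
    frac = counts / S  # sums to 1
    logp = np.column_stack(
        [log_predictive_batch(g, cache.posteriors_for(g), X, intervention) for g in uniq]
    )  # (R, U)
    # log of the model-averaged predictive (1/S) sum_s p(x_r | G_s)
    m = logp.max(axis=1)
    log_mean = m + np.log(np.exp(logp - m[:, None]) @ frac)
    v = importance_weights(logp, logq)  # (R, U), columns normalized
    diffs = logp - log_mean[:, None]
    per_graph = (v * diffs).sum(axis=0)  # KL estimate per unique graph
    psi = float(per_graph @ frac)
    return MiEstimate(intervention=intervention, psi=psi, per_graph_terms=per_graph)


def select_intervention(
    pool: CandidatePool,
    belief_sample: BeliefSample,
    dataset: Dataset,
    priors: Priors,
    config: ActiveConfig,
    round_index: int = 0,
) -> tuple[int, list[MiEstimate]]:
    """Evaluate psi_hat for every available candidate (independent RNG
    substream keyed by round and candidate) and return the argmax, ties broken
    by lowest candidate index."""
    avail = pool.available()
    if not avail:
        raise RuntimeError("candidate pool is exhausted")
    estimates: list[MiEstimate] = []
    best_idx, best_psi = avail[0], -np.inf
    for idx in avail:
        est = estimate_mi(
            pool.candidates[idx],
            belief_sample,
            dataset,
            priors,
            config.n_outcome_samples,
            seed=[config.seed, 104729, round_index, idx],
        )
        estimates.append(est)
        if est.psi > best_psi:
            best_idx, best_psi = idx, est.psi
    return best_idx, estimates


@dataclasses.dataclass
class RoundRecord:
    round: int
    intervention: Intervention | None  # None for the initial round
    candidate_index: int | None
    dataset: Dataset
    belief: BeliefSample
    psi: list[MiEstimate] | None = None


@dataclasses.dataclass
class Trajectory:
    rounds: list[RoundRecord]

    @property
    def final_belief(self) -> BeliefSample:
        return self.rounds[-1].belief

    @property
    def final_dataset(self) -> Dataset:
        return self.rounds[-1].dataset

    def chosen_interventions(self) -> list[Intervention]:
        return [r.intervention for r in self.rounds[1:]]

    def __len__(self) -> int:
        return len(self.rounds)


def _resolve_source(source, pool: CandidatePool | None):
    if isinstance(source, GBN):
        gbn = source
        if pool is None:
            pool = CandidatePool.knockouts(gbn.n)
        return gbn, pool
    if isinstance(source, CandidatePool):
        if source.outcomes is None:
            raise ValueError(
                "a bare CandidatePool needs pre-generated outcomes; "
                "pass a GBN to sample fresh ones"
            )
        return None, source
    raise TypeError("source must be a GBN or a CandidatePool")


def _run_loop(source, initial_dataset, config, priors, pool, make_choose):
    gbn, pool = _resolve_source(source, pool)
    priors = priors if priors is not None else Priors()
    choose = make_choose(pool, priors)
    mc = dataclasses.replace(config.mcmc, seed=int(np.random.default_rng(
        [config.seed, 0]).integers(2**31)))
    belief = sample_graphs(initial_dataset, priors, mc)
    dataset = initial_dataset
    records = [RoundRecord(0, None, None, dataset, belief)]
    for t in range(1, config.n_rounds + 1):
        avail = pool.available()
        if not avail:
            warnings.warn(
                f"candidate pool exhausted after {t - 1} rounds; stopping early",
                stacklevel=2,
            )
            break
        idx, estimates = choose(t, avail, belief, dataset)
        outcome = pool.take_outcome(
            idx, gbn, np.random.default_rng([config.seed, 1, t])
        )
        intervention = pool.candidates[idx]
        dataset = dataset.append(outcome, intervention)
        belief = propagate(
            belief,
            dataset,
            priors,
            config.mcmc.propagate_steps,
            config.mcmc.max_in_degree,
            seed=[config.seed, 2, t],
        )
        records.append(RoundRecord(t, intervention, idx, dataset, belief, estimates))
    return Trajectory(records)


def run_active_loop(
    source: GBN | CandidatePool,
    initial_dataset: Dataset,
    config: ActiveConfig,
    priors: Priors | None = None,
    pool: CandidatePool | None = None,
) -> Trajectory:
    """T rounds of: select the MI-maximizing intervention, acquire its
    outcome, append it to the data, and propagate the belief by MCMC."""

    def make_choose(resolved_pool, pr):
        def choose(t, avail, belief, dataset):
            return select_intervention(
                resolved_pool, belief, dataset, pr, config, round_index=t
            )

        return choose

    return _run_loop(source, initial_dataset, config, priors, pool, make_choose)


def run_random_loop(
    source: GBN | CandidatePool,
    initial_dataset: Dataset,
    config: ActiveConfig,
    priors: Priors | None = None,
    pool: CandidatePool | None = None,
) -> Trajectory:
    """Baseline: identical bookkeeping with the selection replaced by a
    uniform draw over the available candidates."""

    def make_choose(resolved_pool, pr):
        def choose(t, avail, belief, dataset):
            rng = np.random.default_rng([config.seed, 3, t])
            return int(rng.choice(avail)), None

        return choose

    return _run_loop(source, initial_dataset, config, priors, pool, make_choose)
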