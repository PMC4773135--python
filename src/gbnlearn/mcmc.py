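"""Metropolis-Hastings sampling of DAGs from p(G | D, II).

The proposal is uniform over the single-edge neighborhood (insertion,
deletion, reversal) restricted to moves that keep the graph acyclic and
within the in-degree cap; the structure prior is uniform over DAGs inside
the cap.  The Hastings correction |N(G)| / |N(G')| is included, and only the
families changed by a move are rescored (memoized in the shared ScoreCache).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .gbn import DAG, Dataset
from .scoring import Priors, ScoreCache

__all__ = [
    "McmcConfig",
    "BeliefSample",
    "ChainState",
    "neighborhood",
    "mh_step",
    "sample_graphs",
    "propagate",
]

# move kinds
_INSERT, _DELETE, _REVERSE = 0, 1, 2


@dataclasses.dataclass(frozen=True)
class McmcConfig:
    """Budgets for posterior graph sampling.

    Defaults mirror the simulated-experiment settings: S=1000 samples,
    burn-in 10,000, thinning 100, propagation 100 steps, in-degree cap 5.
    """

    n_samples: int = 1000
    burn_in: int = 10_000
    thinning: int = 100
    max_in_degree: int = 5
    propagate_steps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if min(self.burn_in, self.thinning, self.propagate_steps, self.max_in_degree) < 0:
            raise ValueError("budgets must be non-negative")


@dataclasses.dataclass
class BeliefSample:
    """S posterior DAG samples representing p(G | D, II)."""

    graphs: list[DAG]

    def __post_init__(self) -> None:
        if not self.graphs:
            raise ValueError("a belief sample must contain at least one graph")

    @property
    def size(self) -> int:
        return len(self.graphs)

    def edge_frequencies(self) -> np.ndarray:
        n = self.graphs[0].n
        freq = np.zeros((n, n))
        for g in self.graphs:
            freq += g.adjacency()
        return freq / self.size

    def unique_counts(self) -> tuple[list[DAG], np.ndarray]:
        """Distinct graphs and their multiplicities (order of first occurrence)."""
        seen: dict[bytes, int] = {}
        uniq: list[DAG] = []
        counts: list[int] = []
        for g in self.graphs:
            key = g.adjacency().tobytes()
            if key in seen:
                counts[seen[key]] += 1
            else:
                seen[key] = len(uniq)
                uniq.append(g)
                counts.append(1)
        return uniq, np.asarray(counts)

    def __iter__(self):
        return iter(self.graphs)

    def __len__(self) -> int:
        return self.size


_EYE_CACHE: dict[int, np.ndarray] = {}


def _strict_closure(adj_int: np.ndarray) -> np.ndarray:
    """Reachability by paths of length >= 1, via repeated squaring (path
    length doubles per iteration, so ceil(log2(n-1)) rounds suffice)."""
    n = adj_int.shape[0]
    C = adj_int
    rounds = max(1, int(np.ceil(np.log2(max(n - 1, 2)))))
    for _ in range(rounds):
        C = ((C + C @ C) > 0).view(np.uint8)
    return C


class _MoveSet:
    """Legal single-edge moves as boolean masks plus their counts."""

    __slots__ = ("ins", "dele", "rev", "counts", "total")

    def __init__(self, ins: np.ndarray, dele: np.ndarray, rev: np.ndarray):
        self.ins, self.dele, self.rev = ins, dele, rev
        self.counts = (int(ins.sum()), int(dele.sum()), int(rev.sum()))
        self.total = sum(self.counts)

    def decode(self, k: int, n: int) -> tuple[int, int, int]:
        """The k-th move in canonical (insert, delete, reverse; row-major)
        order, as (kind, i, j)."""
        for kind, mask, c in zip(
            (_INSERT, _DELETE, _REVERSE), (self.ins, self.dele, self.rev), self.counts
        ):
            if k < c:
                flat = int(np.flatnonzero(mask.ravel())[k])
                return kind, flat // n, flat % n
            k -= c
        raise IndexError("move index out of range")


def _legal_moves(adj: np.ndarray, cap: int) -> _MoveSet:
    """Legal single-edge moves: insertions and reversals must keep the graph
    acyclic and within the in-degree cap at the new head; moves violating
    either are excluded from the neighborhood rather than rejected later."""
    n = adj.shape[0]
    eye = _EYE_CACHE.get(n)
    if eye is None:
        eye = _EYE_CACHE.setdefault(n, np.eye(n, dtype=bool))
    A = adj.view(np.uint8)
    R = _strict_closure(A)
    indeg = A.sum(axis=0)
    under_cap = indeg < cap
    # inserting (i, j) creates a cycle iff j already reaches i
    ins = (~adj) & (R.T == 0) & ~eye & under_cap[None, :]
    # reversal of (i, j) to (j, i): illegal iff an i->...->j path of length
    # >= 2 exists (in a DAG such a path cannot use the edge (i, j) itself),
    # or the new head i is at the in-degree cap.
    alt = (A @ R) > 0
    rev = adj & ~alt & under_cap[:, None]
    return _MoveSet(ins, adj, rev)


def neighborhood(dag: DAG, max_in_degree: int) -> list[DAG]:
    """All DAGs one legal insertion, deletion, or reversal away, in a
    deterministic canonical order.  Moves that would create a cycle or exceed
    the in-degree cap are excluded."""
    adj = dag.adjacency()
    moves = _legal_moves(adj, max_in_degree)
    out = []
    for k in range(moves.total):
        kind, i, j = moves.decode(k, dag.n)
        nbr = adj.copy()
        if kind == _INSERT:
            nbr[i, j] = True
        elif kind == _DELETE:
            nbr[i, j] = False
        else:
            nbr[i, j] = False
            nbr[j, i] = True
        out.append(DAG.from_adjacency(nbr, dag.labels))
    return out


@dataclasses.dataclass
class ChainState:
    """Current graph with per-family log evidences and cached legal moves."""

    adj: np.ndarray  # (n, n) bool
    family_logev: np.ndarray  # (n,)
    moves: _MoveSet
    labels: tuple[str, ...] | None = None

    @classmethod
    def from_dag(cls, dag: DAG, cache: ScoreCache, max_in_degree: int) -> "ChainState":
        adj = dag.adjacency()
        logev = np.array(
            [cache.family(j, dag.parents(j))[0] for j in range(dag.n)]
        )
        return cls(adj, logev, _legal_moves(adj, max_in_degree), dag.labels)

    @property
    def log_score(self) -> float:
        return float(self.family_logev.sum())

    @property
    def graph(self) -> DAG:
        return DAG.from_adjacency(self.adj, self.labels)

    def n_moves(self) -> int:
        return self.moves.total


def mh_step(
    state: ChainState,
    cache: ScoreCache,
    max_in_degree: int,
    rng: np.random.Generator,
) -> ChainState:
    """One Metropolis-Hastings step: propose uniformly over the single-edge
    neighborhood, accept with min(1, score ratio x |N(G)|/|N(G')|).  Only the
    changed families are rescored."""
    n_old = state.moves.total
    k = int(rng.integers(n_old))
    kind, i, j = state.moves.decode(k, state.adj.shape[0])
    new_adj = state.adj.copy()
    if kind == _INSERT:
        new_adj[i, j] = True
        changed = (j,)
    elif kind == _DELETE:
        new_adj[i, j] = False
        changed = (j,)
    else:
        new_adj[i, j] = False
        new_adj[j, i] = True
        changed = (i, j)
    new_logev = state.family_logev.copy()
    delta = 0.0
    for node in changed:
        new_logev[node] = cache.family_log_evidence_from_adj(new_adj, node)
        delta += new_logev[node] - state.family_logev[node]
    new_moves = _legal_moves(new_adj, max_in_degree)
    log_ratio = delta + math.log(n_old) - math.log(new_moves.total)
    if log_ratio >= 0 or math.log(rng.random()) < log_ratio:
        return ChainState(new_adj, new_logev, new_moves, state.labels)
    return state


def sample_graphs(
    dataset: Dataset,
    priors: Priors,
    config: McmcConfig,
    start: DAG | None = None,
) -> BeliefSample:
    """Run one chain (burn-in, then one sample every ``thinning`` steps) and
    return S graph samples.  The default start is the empty graph."""
    if start is None:
        start = DAG.from_edges(dataset.n, (), dataset.labels)
    cache = ScoreCache(dataset, priors)
    rng = np.random.default_rng(config.seed)
    state = ChainState.from_dag(start, cache, config.max_in_degree)
    for _ in range(config.burn_in):
        state = mh_step(state, cache, config.max_in_degree, rng)
    samples: list[DAG] = []
    for _ in range(config.n_samples):
        for _ in range(config.thinning):
            state = mh_step(state, cache, config.max_in_degree, rng)
        samples.append(state.graph)
    return BeliefSample(samples)


def propagate(
    belief: BeliefSample,
    dataset: Dataset,
    priors: Priors,
    steps: int,
    max_in_degree: int,
    seed: int | Sequence[int] = 0,
) -> BeliefSample:
    """Advance each of the S chains independently by ``steps`` MH steps
    against the (updated) dataset.  Chains use independent substreams derived
    from ``seed``, so results do not depend on evaluation order."""
    cache = ScoreCache(dataset, priors)
    base = list(seed) if isinstance(seed, (list, tuple)) else [int(seed)]
    out: list[DAG] = []
    for c, g in enumerate(belief.graphs):
        rng = np.random.default_rng(base + [c])
        state = ChainState.from_dag(g, cache, max_in_degree)
        for _ in range(steps):
            state = mh_step(state, cache, max_in_degree, rng)
        out.append(state.graph)
    return BeliefSample(out)
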