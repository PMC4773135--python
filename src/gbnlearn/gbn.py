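"""Gaussian Bayesian network model, interventional sampling, and the simulator.

A Gaussian Bayesian network (GBN) is a directed acyclic graph in which each
node follows a linear-Gaussian conditional distribution given its parents:

    X_j | X_Pa(j)  ~  Normal(m_j + sum_i w_ij X_i,  sigma_j^2)

An intervention clamps a subset of nodes at fixed values; the remaining
nodes are sampled from the mutilated graph in which the incoming edges of
clamped nodes are removed, so that nodes upstream of a clamped node are
unaffected.
"""

from __future__ import annotations

import dataclasses
import math
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DAG",
    "GBN",
    "Intervention",
    "Dataset",
    "is_acyclic",
    "topological_order",
    "generate_random_dag",
    "generate_random_gbn",
    "sample_data",
    "log_density",
]

_LOG_2PI = math.log(2.0 * math.pi)


def _as_rng(seed: int | Sequence[int] | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _validate_edges(n: int, edges: Iterable[tuple[int, int]]) -> None:
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i}, {j}) out of range for {n} nodes")
        if i == j:
            raise ValueError(f"self-edge on node {i} is not allowed")


def is_acyclic(n: int, edges: Iterable[tuple[int, int]]) -> bool:
    """True iff the directed graph on ``n`` nodes admits a topological order."""
    edges = set(edges)
    _validate_edges(n, edges)
    indeg = [0] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        indeg[j] += 1
        children[i].append(j)
    stack = [v for v in range(n) if indeg[v] == 0]
    seen = 0
    while stack:
        v = stack.pop()
        seen += 1
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    return seen == n


@dataclasses.dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over ``n`` labeled nodes.

    Edges are ordered pairs ``(i, j)`` meaning ``i -> j``.  Node indices are
    0-based internally; ``labels`` are preserved for I/O only.
    """

    n: int
    edges: frozenset[tuple[int, int]]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset((int(i), int(j)) for i, j in self.edges))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != self.n:
                raise ValueError("labels length must equal n")
        if not is_acyclic(self.n, self.edges):
            raise ValueError("graph contains a directed cycle")

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: Iterable[tuple[int, int]] = (),
        labels: Sequence[str] | None = None,
    ) -> "DAG":
        return cls(n=n, edges=frozenset(edges), labels=tuple(labels) if labels else None)

    @classmethod
    def from_adjacency(cls, adj: np.ndarray, labels: Sequence[str] | None = None) -> "DAG":
        ii, jj = np.nonzero(adj)
        return cls.from_edges(adj.shape[0], zip(ii.tolist(), jj.tolist()), labels)

    @cached_property
    def _adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n, self.n), dtype=bool)
        for i, j in self.edges:
            adj[i, j] = True
        adj.setflags(write=False)
        return adj

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix; ``adj[i, j]`` iff ``i -> j``."""
        return self._adjacency.copy()

    @cached_property
    def _parents(self) -> tuple[tuple[int, ...], ...]:
        out: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            out[j].append(i)
        return tuple(tuple(sorted(p)) for p in out)

    def parents(self, j: int) -> tuple[int, ...]:
        return self._parents[j]

    def in_degree(self, j: int) -> int:
        return len(self._parents[j])

    def max_in_degree(self) -> int:
        return max((len(p) for p in self._parents), default=0)

    def __len__(self) -> int:
        return self.n


def topological_order(dag: DAG) -> tuple[int, ...]:
    """Topological order with deterministic lowest-index tie-breaking."""
    indeg = [dag.in_degree(j) for j in range(dag.n)]
    children: list[list[int]] = [[] for _ in range(dag.n)]
    for i, j in dag.edges:
        children[i].append(j)
    ready = sorted(v for v in range(dag.n) if indeg[v] == 0)
    order: list[int] = []
    import heapq

    heapq.heapify(ready)
    while ready:
        v = heapq.heappop(ready)
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != dag.n:  # pragma: no cover - DAG invariant guards this
        raise ValueError("graph contains a directed cycle")
    return tuple(order)


def generate_random_dag(
    n: int,
    edge_prob: float = 0.25,
    max_in_degree: int | None = None,
    seed: int | Sequence[int] | np.random.Generator | None = None,
    labels: Sequence[str] | None = None,
) -> DAG:
    """Random DAG: uniform random topological order, then each forward pair
    included independently with probability ``edge_prob``, rejecting additions
    that would exceed the in-degree cap."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    if max_in_degree is not None and max_in_degree < 0:
        raise ValueError("max_in_degree must be >= 0")
    rng = _as_rng(seed)
    order = rng.permutation(n)
    cap = n - 1 if max_in_degree is None else max_in_degree
    edges: set[tuple[int, int]] = set()
    indeg = np.zeros(n, dtype=int)
    for b in range(n):
        tgt = int(order[b])
        for a in range(b):
            src = int(order[a])
            if rng.random() < edge_prob and indeg[tgt] < cap:
                edges.add((src, tgt))
                indeg[tgt] += 1
    return DAG.from_edges(n, edges, labels)


@dataclasses.dataclass
class GBN:
    """A DAG together with its linear-Gaussian parameters Theta."""

    dag: DAG
    base_levels: np.ndarray  # m_j, shape (n,)
    weights: dict[tuple[int, int], float]  # w_ij keyed by dag.edges
    variances: np.ndarray  # sigma_j^2, shape (n,)

    def __post_init__(self) -> None:
        self.base_levels = np.asarray(self.base_levels, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        n = self.dag.n
        if self.base_levels.shape != (n,) or self.variances.shape != (n,):
            raise ValueError("base_levels and variances must have shape (n,)")
        if set(self.weights) != set(self.dag.edges):
            raise ValueError("weights must be keyed exactly by dag.edges")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n(self) -> int:
        return self.dag.n

    def weight_matrix(self) -> np.ndarray:
        """W with W[i, j] = w_ij (zero where no edge)."""
        W = np.zeros((self.n, self.n))
        for (i, j), w in self.weights.items():
            W[i, j] = w
        return W

    def observational_covariance(self) -> np.ndarray:
        """Closed-form joint covariance (I - W)^-T diag(sigma^2) (I - W)^-1."""
        A = np.linalg.inv(np.eye(self.n) - self.weight_matrix())
        return A.T @ np.diag(self.variances) @ A

    def observational_mean(self) -> np.ndarray:
        A = np.linalg.inv(np.eye(self.n) - self.weight_matrix())
        return A.T @ self.base_levels


@dataclasses.dataclass(frozen=True)
class Intervention:
    """A set of (node, clamp value) pairs; the empty set is observational."""

    clamps: frozenset[tuple[int, float]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "clamps", frozenset((int(i), float(c)) for i, c in self.clamps)
        )
        nodes = [i for i, _ in self.clamps]
        if len(nodes) != len(set(nodes)):
            raise ValueError("clamped node indices must be distinct")
        for i, c in self.clamps:
            if i < 0:
                raise ValueError("node indices must be non-negative")
            if not math.isfinite(c):
                raise ValueError("clamp values must be finite")

    @classmethod
    def observational(cls) -> "Intervention":
        return cls()

    @classmethod
    def knockout(cls, node: int, value: float = 0.0) -> "Intervention":
        return cls(frozenset({(node, value)}))

    @property
    def targets(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.clamps)

    def as_dict(self) -> dict[int, float]:
        return dict(self.clamps)

    def is_observational(self) -> bool:
        return not self.clamps

    def __len__(self) -> int:
        return len(self.clamps)


OBSERVATIONAL = Intervention()


@dataclasses.dataclass
class Dataset:
    """A dense m x n instance matrix with per-instance intervention specs.

    Clamped values are stored inside the instance vectors, so a child's
    family regression can read a clamped parent's value directly.
    """

    X: np.ndarray
    interventions: tuple[Intervention, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.interventions = tuple(self.interventions)
        if self.X.shape[0] != len(self.interventions):
            raise ValueError("number of instances must match number of intervention specs")
        for k, iv in enumerate(self.interventions):
            for i, c in iv.clamps:
                if i >= self.n:
                    raise ValueError(f"instance {k}: clamped node {i} out of range")
                if self.X[k, i] != c:
                    raise ValueError(
                        f"instance {k}: value {self.X[k, i]} at node {i} "
                        f"does not equal its clamp {c}"
                    )

    @classmethod
    def empty(cls, n: int, labels: Sequence[str] | None = None) -> "Dataset":
        return cls(np.empty((0, n)), (), tuple(labels) if labels else None)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @cached_property
    def unclamped(self) -> np.ndarray:
        """Boolean (m, n): True where the node is NOT clamped in the instance."""
        mask = np.ones((self.m, self.n), dtype=bool)
        for k, iv in enumerate(self.interventions):
            for i, _ in iv.clamps:
                mask[k, i] = False
        mask.setflags(write=False)
        return mask

    def total_clamped(self) -> int:
        return sum(len(iv) for iv in self.interventions)

    def append(self, x: np.ndarray, intervention: Intervention) -> "Dataset":
        x = np.asarray(x, dtype=float).reshape(1, -1)
        if x.shape[1] != self.n:
            raise ValueError("instance length mismatch")
        return Dataset(
            np.vstack([self.X, x]), self.interventions + (intervention,), self.labels
        )

    def extend(self, other: "Dataset") -> "Dataset":
        return Dataset(
            np.vstack([self.X, other.X]),
            self.interventions + other.interventions,
            self.labels,
        )

    def __len__(self) -> int:
        return self.m


def generate_random_gbn(
    dag: DAG,
    seed: int | Sequence[int] | np.random.Generator | None = None,
    sigma: float = 0.05,
) -> GBN:
    """Ground-truth parameter draw: edge weights uniform on
    (-1, -0.25) U (0.25, 1), base levels standard normal, noise sd ``sigma``
    (0.05 by default) for every node."""
    rng = _as_rng(seed)
    edges = sorted(dag.edges)
    mags = rng.uniform(0.25, 1.0, size=len(edges))
    signs = rng.choice([-1.0, 1.0], size=len(edges))
    weights = {e: float(m * s) for e, m, s in zip(edges, mags, signs)}
    base = rng.standard_normal(dag.n)
    variances = np.full(dag.n, float(sigma) ** 2)
    return GBN(dag=dag, base_levels=base, weights=weights, variances=variances)


def sample_data(
    gbn: GBN,
    intervention: Intervention = OBSERVATIONAL,
    count: int = 1,
    seed: int | Sequence[int] | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``count`` instances under the (possibly mutilated) model.

    Clamped coordinates equal their clamp values exactly; each unclamped node
    j is drawn from N(m_j + sum_i w_ij x_i, sigma_j^2) along a topological
    order of the mutilated graph.
    """
    rng = _as_rng(seed)
    n = gbn.n
    clamps = intervention.as_dict()
    for i in clamps:
        if i >= n:
            raise ValueError(f"clamped node {i} out of range")
    W = gbn.weight_matrix()
    X = np.zeros((count, n))
    # A topological order of the full graph is valid for any mutilation.
    for j in topological_order(gbn.dag):
        if j in clamps:
            X[:, j] = clamps[j]
        else:
            mean = gbn.base_levels[j] + X @ W[:, j]
            X[:, j] = mean + math.sqrt(gbn.variances[j]) * rng.standard_normal(count)
    return X


def log_density(
    gbn: GBN,
    instance: np.ndarray,
    intervention: Intervention = OBSERVATIONAL,
) -> float:
    """Log density of one instance under the mutilated model: the sum over
    unclamped nodes j of log N(x_j; m_j + sum_{i in Pa(j)} w_ij x_i, sigma_j^2).
    All nodes clamped gives 0 (an empty product)."""
    x = np.asarray(instance, dtype=float).ravel()
    if x.shape != (gbn.n,):
        raise ValueError("instance length mismatch")
    clamps = intervention.as_dict()
    for i, c in clamps.items():
        if x[i] != c:
            raise ValueError(f"instance value at node {i} does not match clamp {c}")
    W = gbn.weight_matrix()
    total = 0.0
    for j in range(gbn.n):
        if j in clamps:
            continue
        mean = gbn.base_levels[j] + float(x @ W[:, j])
        var = gbn.variances[j]
        total += -0.5 * (_LOG_2PI + math.log(var)) - 0.5 * (x[j] - mean) ** 2 / var
    return total
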