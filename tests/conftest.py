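import itertools

import numpy as np
import pytest

from gbnlearn.gbn import DAG, GBN, Dataset, OBSERVATIONAL, is_acyclic, sample_data
from gbnlearn.scoring import Priors


@pytest.fixture(scope="session")
def priors() -> Priors:
    return Priors()


@pytest.fixture(scope="session")
def all_3node_dags() -> list[DAG]:
    """Exhaustive enumeration of the 25 labeled DAGs on 3 nodes."""
    pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
    dags = []
    for r in range(len(pairs) + 1):
        for sub in itertools.combinations(pairs, r):
            if is_acyclic(3, sub):
                dags.append(DAG.from_edges(3, sub))
    assert len(dags) == 25
    return dags


@pytest.fixture(scope="session")
def chain_gbn() -> GBN:
    """3-node chain 0 -> 1 -> 2 with moderate noise (spread-out posterior)."""
    dag = DAG.from_edges(3, [(0, 1), (1, 2)])
    return GBN(dag, np.zeros(3), {(0, 1): 0.8, (1, 2): -0.6}, np.full(3, 0.25))


@pytest.fixture(scope="session")
def chain_dataset(chain_gbn) -> Dataset:
    X = sample_data(chain_gbn, count=6, seed=42)
    return Dataset(X, (OBSERVATIONAL,) * 6)


@pytest.fixture(scope="session")
def two_node_gbn() -> GBN:
    """X -> Y with a strong weight; Y <- X is its Markov-equivalent rival."""
    dag = DAG.from_edges(2, [(0, 1)])
    return GBN(dag, np.zeros(2), {(0, 1): 0.9}, np.full(2, 0.25))


def observational(X: np.ndarray) -> Dataset:
    return Dataset(X, (OBSERVATIONAL,) * X.shape[0])
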