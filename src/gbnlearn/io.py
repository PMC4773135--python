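"""Tab-separated file formats and serialization.

Expression matrices are TSV with a mandatory sample-id first column and
variable labels in the header; intervention annotations are TSV with columns
``sample_id  variable  value`` (zero or more rows per sample).  Networks are
edge-list TSVs keyed by labels, with a parameter sidecar for ground-truth
models.  Belief samples and trajectories serialize as JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .active import MiEstimate, Trajectory
from .evaluation import EdgeScoreMatrix
from .gbn import DAG, GBN, Dataset, Intervention
from .mcmc import BeliefSample

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_network",
    "read_network",
    "write_truth",
    "read_truth",
    "write_belief",
    "read_belief",
    "write_trajectory",
    "write_metrics",
]


class ParseError(ValueError):
    pass


def _check_labels(labels: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    for lab in labels:
        if "\t" in lab or "\n" in lab:
            raise ParseError(f"label {lab!r} contains a tab or newline")
    if len(set(labels)) != len(labels):
        raise ParseError("variable labels must be unique")
    return labels


def read_dataset(expression_path: str | Path, intervention_path: str | Path | None) -> Dataset:
    """Load an expression matrix plus intervention annotations.

    Samples absent from the intervention file are observational.  The matrix
    value at every clamped coordinate must equal the annotated clamp value.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    labels = _check_labels(expr.columns)
    sample_ids = [str(s) for s in expr.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError("duplicate sample ids in expression matrix")
    index = {lab: i for i, lab in enumerate(labels)}
    row_of = {sid: k for k, sid in enumerate(sample_ids)}
    clamps: list[set[tuple[int, float]]] = [set() for _ in sample_ids]
    if intervention_path is not None:
        iv = pd.read_csv(intervention_path, sep="\t", dtype={"sample_id": str})
        required = {"sample_id", "variable", "value"}
        if not required.issubset(iv.columns):
            raise ParseError(
                f"intervention file must have columns {sorted(required)}"
            )
        for line, rec in enumerate(iv.itertuples(index=False), start=2):
            sid, var, val = str(rec.sample_id), str(rec.variable), float(rec.value)
            if sid not in row_of:
                raise ParseError(f"line {line}: unknown sample id {sid!r}")
            if var not in index:
                raise ParseError(f"line {line}: unknown variable label {var!r}")
            k, i = row_of[sid], index[var]
            cell = float(expr.iat[k, i])
            if cell != val:
                raise ParseError(
                    f"line {line}: sample {sid!r} clamps {var!r} at {val} "
                    f"but the expression matrix holds {cell}"
                )
            clamps[k].add((i, val))
    interventions = tuple(Intervention(frozenset(c)) for c in clamps)
    return Dataset(expr.to_numpy(dtype=float), interventions, labels)


def write_dataset(
    dataset: Dataset,
    expression_path: str | Path,
    intervention_path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    labels = _check_labels(labels or dataset.labels or [f"X{i}" for i in range(dataset.n)])
    ids = [f"S{k}" for k in range(dataset.m)]
    pd.DataFrame(dataset.X, index=pd.Index(ids, name="sample_id"), columns=labels).to_csv(
        expression_path, sep="\t"
    )
    rows = [
        {"sample_id": ids[k], "variable": labels[i], "value": c}
        for k, iv in enumerate(dataset.interventions)
        for i, c in sorted(iv.clamps)
    ]
    pd.DataFrame(rows, columns=["sample_id", "variable", "value"]).to_csv(
        intervention_path, sep="\t", index=False
    )


def write_network(
    edge_scores: EdgeScoreMatrix,
    labels: Sequence[str],
    path: str | Path,
) -> None:
    """Ranked predictions: ``source target score signed_weight`` sorted by
    descending score with (row, column) order as the stable tie-break."""
    labels = _check_labels(labels)
    n = edge_scores.n
    rows = [
        (labels[i], labels[j], edge_scores.scores[i, j], edge_scores.signed_weights[i, j])
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    rows.sort(key=lambda r: -r[2])
    pd.DataFrame(rows, columns=["source", "target", "score", "signed_weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_network(path: str | Path, labels: Sequence[str]) -> EdgeScoreMatrix:
    labels = _check_labels(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    df = pd.read_csv(path, sep="\t")
    n = len(labels)
    scores = np.zeros((n, n))
    signed = np.zeros((n, n))
    for rec in df.itertuples(index=False):
        i, j = index[str(rec.source)], index[str(rec.target)]
        scores[i, j] = rec.score
        signed[i, j] = rec.signed_weight
    return EdgeScoreMatrix(scores=scores, signed_weights=signed)


def write_truth(
    gbn: GBN,
    edges_path: str | Path,
    params_path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    """Edge-list TSV ``source target weight`` plus a parameter sidecar
    ``node base_level sigma``."""
    labels = _check_labels(
        labels or gbn.dag.labels or [f"X{i}" for i in range(gbn.n)]
    )
    edges = [
        (labels[i], labels[j], gbn.weights[(i, j)]) for i, j in sorted(gbn.dag.edges)
    ]
    pd.DataFrame(edges, columns=["source", "target", "weight"]).to_csv(
        edges_path, sep="\t", index=False, float_format="%.17g"
    )
    params = [
        (labels[j], gbn.base_levels[j], float(np.sqrt(gbn.variances[j])))
        for j in range(gbn.n)
    ]
    pd.DataFrame(params, columns=["node", "base_level", "sigma"]).to_csv(
        params_path, sep="\t", index=False, float_format="%.17g"
    )


def read_truth(edges_path: str | Path, params_path: str | Path) -> GBN:
    params = pd.read_csv(params_path, sep="\t")
    labels = _check_labels(params["node"])
    index = {lab: i for i, lab in enumerate(labels)}
    edges_df = pd.read_csv(edges_path, sep="\t")
    weights: dict[tuple[int, int], float] = {}
    for rec in edges_df.itertuples(index=False):
        src, tgt = str(rec.source), str(rec.target)
        if src not in index or tgt not in index:
            raise ParseError(f"edge {src!r}->{tgt!r} references an unknown node")
        weights[(index[src], index[tgt])] = float(rec.weight)
    dag = DAG.from_edges(len(labels), weights.keys(), labels)
    return GBN(
        dag=dag,
        base_levels=params["base_level"].to_numpy(float),
        weights=weights,
        variances=params["sigma"].to_numpy(float) ** 2,
    )


def _dag_to_json(dag: DAG) -> dict:
    return {"n": dag.n, "edges": sorted(map(list, dag.edges))}


def write_belief(belief: BeliefSample, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in belief.graphs:
            fh.write(json.dumps(_dag_to_json(g)) + "\n")


def read_belief(path: str | Path) -> BeliefSample:
    graphs = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            graphs.append(DAG.from_edges(rec["n"], [tuple(e) for e in rec["edges"]]))
    return BeliefSample(graphs)


def _psi_table(estimates: list[MiEstimate] | None) -> list[dict] | None:
    if estimates is None:
        return None
    return [
        {"clamps": sorted(map(list, e.intervention.clamps)), "psi": e.psi}
        for e in estimates
    ]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """One JSON record per round: the chosen intervention, the psi table, and
    the dataset size after acquisition."""
    with open(path, "w") as fh:
        for rec in trajectory.rounds:
            fh.write(
                json.dumps(
                    {
                        "round": rec.round,
                        "intervention": None
                        if rec.intervention is None
                        else sorted(map(list, rec.intervention.clamps)),
                        "candidate_index": rec.candidate_index,
                        "n_instances": rec.dataset.m,
                        "psi": _psi_table(rec.psi),
                    }
                )
                + "\n"
            )


def write_metrics(rows: list[dict], path: str | Path) -> None:
    """Per-round metric table: ``round kl auroc auprc mse``."""
    pd.DataFrame(rows, columns=["round", "kl", "auroc", "auprc", "mse"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
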