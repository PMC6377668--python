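"""Readers and writers for matrices, edge lists, graphs, and trajectories.

Formats are deliberately plain: square-matrix CSV and ``source,target,weight``
edge-list CSV for signed adjacency, GraphML for mutual-positive graphs,
CSV for trajectories, JSON for configs/manifests/fits.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_edge_list",
    "read_matrix_csv",
    "read_trajectory_csv",
    "write_edge_list",
    "write_graphml",
    "write_json",
    "write_matrix_csv",
]


def write_matrix_csv(S: np.ndarray, path) -> None:
    """Square reputation matrix as headerless CSV."""
    np.savetxt(path, np.asarray(S, dtype=float), delimiter=",", fmt="%.10g")


def read_matrix_csv(path) -> np.ndarray:
    S = np.loadtxt(path, delimiter=",", ndmin=2)
    if S.shape[0] != S.shape[1]:
        raise ValueError(f"{path}: not a square matrix (shape {S.shape})")
    return S


def write_edge_list(S: np.ndarray, path, *, include_zero: bool = False) -> None:
    """Signed adjacency as a directed edge list ``source,target,weight``.

    0-based agent ids; the diagonal is omitted; zero-weight (never-met or
    forgotten) relationships are skipped unless ``include_zero``.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    rows = [
        (x, y, S[x, y])
        for x in range(n)
        for y in range(n)
        if x != y and (include_zero or S[x, y] != 0.0)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def read_edge_list(path, n: int | None = None) -> np.ndarray:
    """Rebuild a reputation matrix from an edge-list CSV.

    ``n`` defaults to one more than the largest agent id seen; unmentioned
    relationships are neutral 0 and the diagonal is set to 1.
    """
    df = pd.read_csv(path)
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if n is None:
        n = int(max(df["source"].max(), df["target"].max())) + 1
    S = np.zeros((n, n))
    S[df["source"].to_numpy(int), df["target"].to_numpy(int)] = df[
        "weight"
    ].to_numpy(float)
    np.fill_diagonal(S, 1.0)
    return S


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "name"):  # enums
        return obj.name
    raise TypeError(f"not JSON serializable: {type(obj)}")
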