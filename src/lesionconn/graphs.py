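"""Percentile-thresholded graph metrics of connectivity matrices.

Connectivity is binarized by retaining the edges above the P-th percentile
of the off-diagonal values — i.e. the strongest (100-P)% of connections —
with a deterministic tie-break so every subject retains the identical edge
count (matching network degree across participants).  On the binary graph:
global clustering C (mean nodal clustering, isolates counting 0), global
efficiency E (mean inverse shortest-path length, disconnected pairs
contributing 0), small-worldness approximated as the product C*E, and the
fraction of isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Adjacency",
    "binarize_at_percentile",
    "global_clustering",
    "global_efficiency",
    "small_world_index",
    "isolate_fraction",
    "metric_sweep",
    "graph_summary",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = tuple(range(85, 100))


@dataclass(frozen=True)
class Adjacency:
    """Binary, symmetric, hollow adjacency matrix at a percentile threshold."""

    matrix: np.ndarray
    percentile: float
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def binarize_at_percentile(conn: np.ndarray, P: float) -> Adjacency:
    """Keep the strongest (100-P)% of unique edges.

    The retained count is round((1 - P/100) * N(N-1)/2), enforced exactly
    by ranking under the total order (z descending, then row index, then
    column index) so ties cannot change the degree across subjects.
    """
    if not 0.0 <= P < 100.0:
        raise ValueError("P must lie in [0, 100)")
    conn = np.asarray(conn, dtype=float)
    N = conn.shape[0]
    ii, jj = np.triu_indices(N, 1)
    zz = conn[ii, jj]
    if np.nanstd(zz) < 1e-15:
        raise ValueError("all edge values equal; percentile ranking undefined")
    M = zz.size
    n_keep = int(round((1.0 - P / 100.0) * M))
    order = np.lexsort((jj, ii, -zz))       # z desc, then (i, j) asc
    sel = order[:n_keep]
    A = np.zeros((N, N), dtype=int)
    A[ii[sel], jj[sel]] = 1
    A |= A.T
    return Adjacency(matrix=A, percentile=float(P), n_edges=n_keep)


def global_clustering(adj: Adjacency | np.ndarray) -> float:
    """Mean nodal clustering coefficient; nodes with degree < 2 count 0."""
    A = adj.matrix if isinstance(adj, Adjacency) else np.asarray(adj)
    k = A.sum(axis=1)
    tri2 = np.diag(A @ A @ A)               # 2 * triangles per node
    denom = k * (k - 1)
    c = np.zeros(A.shape[0], dtype=float)
    ok = denom > 0
    c[ok] = tri2[ok] / denom[ok]
    return float(c.mean())


def global_efficiency(adj: Adjacency | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    A = adj.matrix if isinstance(adj, Adjacency) else np.asarray(adj)
    N = A.shape[0]
    if N < 2:
        return 0.0
    D = shortest_path(csr_matrix(A), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (N * (N - 1)))


def small_world_index(C: float, E: float) -> float:
    """Small-worldness approximated as the product of global clustering and
    global efficiency."""
    return C * E


def isolate_fraction(adj: Adjacency | np.ndarray) -> float:
    A = adj.matrix if isinstance(adj, Adjacency) else np.asarray(adj)
    return float(np.mean(A.sum(axis=1) == 0))


def graph_summary(conn: np.ndarray, P: float) -> dict:
    adj = binarize_at_percentile(conn, P)
    C = global_clustering(adj)
    E = global_efficiency(adj)
    return {
        "P": float(P),
        "clustering": C,
        "efficiency": E,
        "small_worldness": small_world_index(C, E),
        "isolate_fraction": isolate_fraction(adj),
        "n_edges": adj.n_edges,
    }


def metric_sweep(conn: np.ndarray,
                 percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
                 ) -> pd.DataFrame:
    """One row of graph metrics per percentile threshold (default 85-99%)."""
    return pd.DataFrame([graph_summary(conn, P) for P in percentiles])
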