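"""Directed weighted graph characterization of thresholded connectivity.

Conventions shared by every metric here:

* ``A[i, j]`` is the weight of the directed edge i -> j; the diagonal is zero.
* In-strength k_in is the column sum, out-strength k_out the row sum, total
  degree TD = k_in + k_out, and the directionality index DI = k_out - k_in
  (positive: the node behaves as a sender).
* For clustering and local efficiency, weights are first normalized by the
  matrix maximum; denominators use *binary* degrees, so both reduce to the
  classic binary directed forms on 0/1 graphs.
* For path-based metrics, edge length is 1/weight (stronger coupling =
  shorter distance); disconnected ordered pairs are excluded from the
  characteristic path length (their count is reported) and contribute zero
  to global efficiency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _sp

from .connectivity import Adjacency


def _as_matrix(A) -> np.ndarray:
    M = A.matrix if isinstance(A, Adjacency) else np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(M) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if np.any(M < 0):
        raise ValueError("edge weights must be non-negative")
    return M


def node_strengths(A) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(k_in, k_out, TD) per node: column sums, row sums, their sum."""
    M = _as_matrix(A)
    k_in = M.sum(axis=0)
    k_out = M.sum(axis=1)
    return k_in, k_out, k_in + k_out


def directionality_index(A) -> np.ndarray:
    """DI = k_out - k_in per node; sums to zero over the graph."""
    k_in, k_out, _ = node_strengths(A)
    return k_out - k_in


def _normalized(M: np.ndarray) -> np.ndarray:
    mx = M.max()
    return M / mx if mx > 0 else M


def clustering(A) -> tuple[np.ndarray, float]:
    """Directed weighted local clustering (Fagiolo form) and its graph mean.

    t_i = (1/2) [ (W^(1/3) + (W^T)^(1/3))^3 ]_ii  with W normalized by its
    maximum; C_i = t_i / [ d_i (d_i - 1) - 2 d_i_recip ] with binary total
    degree d_i and reciprocal-edge count d_i_recip.  Nodes with binary total
    degree < 2 get C_i = 0.
    """
    M = _as_matrix(A)
    W = _normalized(M)
    B = (M > 0).astype(float)
    d_tot = B.sum(axis=0) + B.sum(axis=1)
    d_recip = (B * B.T).sum(axis=1)
    Wc = np.cbrt(W)
    Sym = Wc + Wc.T
    t = np.einsum("ij,jk,ki->i", Sym, Sym, Sym) / 2.0
    denom = d_tot * (d_tot - 1) - 2 * d_recip
    C = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0), 0.0)
    return C, float(C.mean()) if C.size else 0.0


def _lengths(M: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(M > 0, 1.0 / np.where(M > 0, M, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def _distances(M: np.ndarray) -> np.ndarray:
    """All-pairs directed shortest-path distances on 1/weight lengths,
    weights pre-normalized by the matrix maximum (so distances >= 1)."""
    W = _normalized(M)
    L = _lengths(W)
    if not np.isfinite(L[~np.eye(len(L), dtype=bool)]).any():
        D = np.full_like(L, np.inf)
        np.fill_diagonal(D, 0.0)
        return D
    return _sp(np.where(np.isfinite(L), L, 0.0), method="D", directed=True,
               unweighted=False)


def local_efficiency(A) -> tuple[np.ndarray, float]:
    """Per-node and mean local efficiency (directed weighted form).

    For node i with neighborhood N_i (nodes with any edge to or from i),
    shortest paths d_jh(N_i) are computed on the subgraph induced by N_i;
    the per-node value symmetrizes over ordered neighbor pairs with the 1/2
    factor and is normalized by the same binary-degree denominator as
    clustering.
    """
    M = _as_matrix(A)
    W = _normalized(M)
    n = len(W)
    B = (W > 0)
    d_tot = B.sum(axis=0) + B.sum(axis=1)
    d_recip = (B & B.T).sum(axis=1)
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(B[i] | B[:, i])
        nbrs = nbrs[nbrs != i]
        if nbrs.size < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = _distances(sub)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
        wi = W[i, nbrs] + W[nbrs, i]                 # (A_ij + A_ji) per neighbor
        num = 0.5 * (wi[:, None] * wi[None, :] * (inv + inv.T)).sum()
        denom = d_tot[i] * (d_tot[i] - 1) - 2 * d_recip[i]
        if denom > 0:
            eloc[i] = num / denom
    return eloc, float(eloc.mean()) if n else 0.0


@dataclass
class PathMetrics:
    char_path_length: float        # mean finite off-diagonal distance (NaN if none)
    global_efficiency: float
    nodal_path_length: np.ndarray  # mean finite out-distance per node
    unreachable_pairs: int


def path_metrics(A) -> PathMetrics:
    """Characteristic path length, global efficiency and nodal path lengths."""
    M = _as_matrix(A)
    n = len(M)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    D = _distances(M)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    unreachable = int(off.sum() - finite.sum())
    lam = float(D[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        invD = np.where(finite, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    ge = float(invD[off].sum() / (n * (n - 1)))
    nodal = np.full(n, np.nan)
    for i in range(n):
        fi = finite[i]
        if fi.any():
            nodal[i] = D[i, fi].mean()
    return PathMetrics(lam, ge, nodal, unreachable)


def betweenness(A) -> np.ndarray:
    """Shortest-path betweenness centrality, normalized by (N-1)(N-2).

    Path multiplicities sp_hj(i)/sp_hj are counted; edge lengths are
    1/weight as in the other path metrics.
    """
    M = _as_matrix(A)
    n = len(M)
    if n < 3:
        return np.zeros(n)
    W = _normalized(M)
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(W)):
        G.add_edge(int(i), int(j), length=1.0 / W[i, j])
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(n)])


def _extreme_set(values: np.ndarray, k: int, lowest: bool) -> np.ndarray:
    """Boolean membership of the k most extreme values, ties at the cutoff
    included."""
    v = np.asarray(values, dtype=float)
    order = v if lowest else -v
    cut = np.sort(order)[k - 1]
    return order <= cut + 1e-12


def hub_scores(nodal: pd.DataFrame, quantile: float = 0.2) -> pd.DataFrame:
    """Composite hub score 0-4 and hub flag (HS >= 2).

    One point each for membership in: the lowest ``quantile`` of local
    clustering C_i, the lowest quantile of nodal path length PL_i, the
    highest quantile of total degree TD, and the highest quantile of
    betweenness BC.  The criterion set size is ceil(quantile * N); ties at
    the cutoff are all included.  A criterion whose metric is constant over
    nodes carries no information and is skipped (with a warning).
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    n = len(nodal)
    k = math.ceil(quantile * n)
    hs = np.zeros(n, dtype=int)
    criteria = [("C", True), ("PL", True), ("TD", False), ("BC", False)]
    for col, lowest in criteria:
        v = nodal[col].to_numpy(dtype=float)
        if np.isnan(v).any() and not np.isnan(v).all():
            # a node with no defined value never wins a criterion
            worst = np.nanmax(v) if lowest else np.nanmin(v)
            v = np.where(np.isnan(v), worst, v)
        if np.isnan(v).all() or np.nanmax(v) - np.nanmin(v) < 1e-15:
            warnings.warn(f"hub criterion on {col!r} skipped: constant metric")
            continue
        hs += _extreme_set(v, k, lowest).astype(int)
    out = nodal.copy()
    out["HS"] = hs
    out["is_hub"] = hs >= 2
    return out


def sparsity(A) -> float:
    """Edge count divided by the (N^2 - N)/2 possible directed pairs."""
    M = _as_matrix(A)
    n = len(M)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return float(np.count_nonzero(M) / ((n * n - n) / 2))


def nodal_metrics(A, quantile: float = 0.2,
                  labels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Full per-node table: strengths, DI, clustering, path length,
    betweenness, hub score and hub flag."""
    M = _as_matrix(A)
    if labels is None:
        labels = A.labels if isinstance(A, Adjacency) else tuple(
            str(i) for i in range(len(M)))
    k_in, k_out, td = node_strengths(M)
    C, _ = clustering(M)
    pm = path_metrics(M)
    bc = betweenness(M)
    table = pd.DataFrame({
        "node": list(labels),
        "k_in": k_in, "k_out": k_out, "TD": td, "DI": k_out - k_in,
        "C": C, "PL": pm.nodal_path_length, "BC": bc,
    })
    return hub_scores(table, quantile)


def global_metrics(A, quantile: float = 0.2) -> pd.DataFrame:
    """One-row graph-level table: CC, LE, lambda, GE, sparsity, edges, hubs."""
    M = _as_matrix(A)
    _, cc = clustering(M)
    _, le = local_efficiency(M)
    pm = path_metrics(M)
    nodal = nodal_metrics(A, quantile=quantile)
    return pd.DataFrame([{
        "CC": cc, "LE": le, "lambda": pm.char_path_length,
        "GE": pm.global_efficiency, "sparsity": sparsity(M),
        "edges": int(np.count_nonzero(M)),
        "unreachable_pairs": pm.unreachable_pairs,
        "n_hubs": int(nodal["is_hub"].sum()),
        "hubs": ",".join(nodal.loc[nodal["is_hub"], "node"]),
    }])
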