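"""Independent brute-force oracles for graph metrics.

Everything here is deliberately naive — explicit loops, Floyd-Warshall,
exhaustive simple-path enumeration — and shares no code with the package
implementation.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

INF = float("inf")
TOL = 1e-9


def floyd(lengths: np.ndarray) -> np.ndarray:
    n = len(lengths)
    D = lengths.astype(float).copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def edge_lengths(A: np.ndarray) -> np.ndarray:
    mx = A.max()
    W = A / mx if mx > 0 else A
    n = len(A)
    L = np.full((n, n), INF)
    for i in range(n):
        L[i, i] = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                L[i, j] = 1.0 / W[i, j]
    return L


def bf_clustering(A: np.ndarray) -> np.ndarray:
    n = len(A)
    mx = A.max()
    W = A / mx if mx > 0 else A
    S = np.cbrt(W) + np.cbrt(W.T)
    C = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += S[i, j] * S[j, h] * S[h, i]
        t /= 2.0
        d_in = sum(1 for j in range(n) if A[j, i] > 0)
        d_out = sum(1 for j in range(n) if A[i, j] > 0)
        recip = sum(1 for j in range(n) if A[i, j] > 0 and A[j, i] > 0)
        denom = (d_in + d_out) * (d_in + d_out - 1) - 2 * recip
        C[i] = t / denom if denom > 0 else 0.0
    return C


def bf_local_efficiency(A: np.ndarray) -> np.ndarray:
    n = len(A)
    mx = A.max()
    W = A / mx if mx > 0 else A
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n)
                if j != i and (A[i, j] > 0 or A[j, i] > 0)]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = floyd(edge_lengths(sub))
        num = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if a == b:
                    continue
                inv = 0.0
                if np.isfinite(D[a, b]) and D[a, b] > 0:
                    inv += 1.0 / D[a, b]
                if np.isfinite(D[b, a]) and D[b, a] > 0:
                    inv += 1.0 / D[b, a]
                num += (W[i, j] + W[j, i]) * (W[i, h] + W[h, i]) * inv
        num *= 0.5
        d_in = sum(1 for j in range(n) if A[j, i] > 0)
        d_out = sum(1 for j in range(n) if A[i, j] > 0)
        recip = sum(1 for j in range(n) if A[i, j] > 0 and A[j, i] > 0)
        denom = (d_in + d_out) * (d_in + d_out - 1) - 2 * recip
        if denom > 0:
            eloc[i] = num / denom
    return eloc


def bf_path_metrics(A: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(char path length over finite pairs, global efficiency, nodal PL)."""
    n = len(A)
    D = floyd(edge_lengths(A))
    finite, inv_sum, count = [], 0.0, 0
    nodal = np.full(n, np.nan)
    for i in range(n):
        fi = []
        for j in range(n):
            if i == j:
                continue
            count += 1
            if np.isfinite(D[i, j]):
                finite.append(D[i, j])
                fi.append(D[i, j])
                inv_sum += 1.0 / D[i, j]
        if fi:
            nodal[i] = float(np.mean(fi))
    lam = float(np.mean(finite)) if finite else float("nan")
    ge = inv_sum / count if count else 0.0
    return lam, ge, nodal


def bf_betweenness(A: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration (small n only)."""
    n = len(A)
    L = edge_lengths(A)
    D = floyd(L)
    bc = np.zeros(n)
    for h in range(n):
        for j in range(n):
            if h == j or not np.isfinite(D[h, j]):
                continue
            # enumerate all simple paths h -> j, keep the shortest ones
            shortest = []
            for r in range(n - 2 + 1):
                inner = [x for x in range(n) if x not in (h, j)]
                for mids in permutations(inner, r):
                    nodes = (h, *mids, j)
                    length = 0.0
                    ok = True
                    for a, b in zip(nodes, nodes[1:]):
                        if not np.isfinite(L[a, b]):
                            ok = False
                            break
                        length += L[a, b]
                    if ok and abs(length - D[h, j]) < TOL:
                        shortest.append(nodes)
            sp = len(shortest)
            if sp == 0:
                continue
            for i in range(n):
                if i in (h, j):
                    continue
                through = sum(1 for p in shortest if i in p)
                bc[i] += through / sp
    if n > 2:
        bc /= (n - 1) * (n - 2)
    return bc
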