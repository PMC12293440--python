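"""Independent brute-force oracles for small weighted graphs.

Everything here is deliberately naive — explicit loops, exhaustive path
enumeration, characteristic-polynomial eigenvalues — so it shares no
code path with the implementation it checks.
"""

from itertools import permutations

import numpy as np


def strength_bf(W):
    n = len(W)
    return np.array([sum(W[i][j] for j in range(n) if j != i)
                     for i in range(n)])


def clustering_bf(W):
    """Onnela clustering by explicit triangle loops."""
    n = len(W)
    wmax = max((W[i][j] for i in range(n) for j in range(n) if i != j),
               default=0.0)
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and W[i][j] > 0)
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                s += ((W[i][j] / wmax) * (W[i][h] / wmax)
                      * (W[j][h] / wmax)) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def transitivity_bf(W):
    n = len(W)
    wmax = max((W[i][j] for i in range(n) for j in range(n) if i != j),
               default=0.0)
    if wmax == 0:
        return 0.0
    num = 0.0
    den = 0
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and W[i][j] > 0)
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                num += ((W[i][j] / wmax) * (W[i][h] / wmax)
                        * (W[j][h] / wmax)) ** (1.0 / 3.0)
    return num / den if den else 0.0


def distances_bf(W):
    """All-pairs shortest paths (length 1/w) by exhaustive enumeration
    of simple paths."""
    n = len(W)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    nodes = list(range(n))
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            best = np.inf
            for r in range(0, n - 1):
                for mid in permutations([v for v in nodes
                                         if v not in (a, b)], r):
                    path = (a, *mid, b)
                    length = 0.0
                    ok = True
                    for u, v in zip(path[:-1], path[1:]):
                        if W[u][v] <= 0:
                            ok = False
                            break
                        length += 1.0 / W[u][v]
                    if ok:
                        best = min(best, length)
            D[a][b] = best
    return D


def char_path_length_bf(W):
    D = distances_bf(W)
    vals = [D[a][b] for a in range(len(W)) for b in range(len(W))
            if a != b and np.isfinite(D[a][b])]
    return float(np.mean(vals))


def n_disconnected_bf(W):
    D = distances_bf(W)
    return sum(1 for a in range(len(W)) for b in range(len(W))
               if a != b and not np.isfinite(D[a][b]))


def global_efficiency_bf(W):
    D = distances_bf(W)
    n = len(W)
    vals = [1.0 / D[a][b] if np.isfinite(D[a][b]) and D[a][b] > 0 else 0.0
            for a in range(n) for b in range(n) if a != b]
    return float(np.mean(vals))


def graph_energy_bf(W):
    """Sum of |roots| of the characteristic polynomial."""
    coeffs = np.poly(np.asarray(W, dtype=float))
    roots = np.roots(coeffs)
    return float(np.abs(roots.real).sum() + 0.0 * np.abs(roots.imag).sum())


def random_small_graph(rng, max_nodes=6):
    """Random symmetric weighted graph with random sparsity."""
    n = int(rng.integers(2, max_nodes + 1))
    W = rng.random((n, n))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    mask = rng.random((n, n)) < rng.uniform(0.3, 1.0)
    mask = np.triu(mask, 1)
    mask = mask | mask.T
    W = W * mask
    return W
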