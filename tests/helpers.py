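"""Independent oracles used by the test suite.

Everything here is deliberately written with a different algorithm (and,
where possible, a different library routine) than the implementation it
checks: a pure-Python double loop for the model right-hand side, and a
Floyd-Warshall path-counting betweenness (scipy distances, no networkx).
"""

import math

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

PATH_TOL = 1e-10


def naive_rhs(t, S, I, B, L, params, P, V_idx=frozenset(), t0=0.0, delta_t=0.0):
    """Double-loop reference for the coupled derivative; no vectorization."""
    n = len(S)

    def theta(x):
        return 1.0 / (1.0 + math.exp(-params.k * x))

    def gate(i, j):
        if i in V_idx or j in V_idx:
            x = t - t0
            return 0.0 if 0.0 <= x <= delta_t else 1.0
        return 1.0

    dS, dI, dB, dL, dT = ([0.0] * n for _ in range(5))
    for i in range(n):
        infection = params.A * S[i] * (I[i] + B[i]) * theta(I[i] - params.Ia)
        export = 0.0
        imports = 0.0
        for j in range(n):
            if j == i:
                continue
            export += (
                params.d * gate(i, j) * P[j][i]
                * (1.0 - params.Ce) * (1.0 - L[i]) * I[i]
            )
            imports += (
                params.d * gate(i, j) * P[i][j]
                * (1.0 - params.Ce) * (1.0 - L[j]) * I[j]
            )
        dS[i] = params.r * S[i] * (1.0 - (S[i] + I[i]) / params.K) - infection
        dI[i] = -params.gamma * I[i] + infection - export
        dB[i] = -params.gamma * B[i] + imports
        dL[i] = (
            params.sigma * L[i] * (1.0 - L[i])
            * (params.U + params.s * (2.0 * L[i] - 1.0) + params.f * I[i])
        )
        dT[i] = infection
    return dS, dI, dB, dL, dT


def _shortest_path_counts(source, D, W):
    """Count shortest paths from one source via predecessor DP over distances."""
    n = D.shape[0]
    counts = np.zeros(n)
    counts[source] = 1.0
    for t in np.argsort(D[source]):
        if t == source or np.isinf(D[source, t]):
            continue
        counts[t] = sum(
            counts[p]
            for p in range(n)
            if np.isfinite(W[p, t])
            and abs(D[source, p] + W[p, t] - D[source, t]) < PATH_TOL
        )
    return counts


def brute_betweenness(W):
    """Unnormalized directed betweenness from an edge-distance matrix.

    ``W[u, v]`` is the distance of edge u -> v (np.inf if absent).  Uses the
    identity: the number of shortest s->t paths through i equals
    counts(s->i) * counts(i->t) whenever d(s,i) + d(i,t) = d(s,t).
    """
    n = W.shape[0]
    finite = np.isfinite(W)
    D = floyd_warshall(
        csr_matrix((W[finite], np.nonzero(finite)), shape=(n, n)), directed=True
    )
    C = np.array([_shortest_path_counts(s, D, W) for s in range(n)])
    g = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(n):
                if len({i, s, t}) < 3 or np.isinf(D[s, t]):
                    continue
                if abs(D[s, i] + D[i, t] - D[s, t]) < PATH_TOL and C[s, t] > 0:
                    g[i] += C[s, i] * C[i, t] / C[s, t]
    return g


def brute_quarantine_selection(network, n_nodes):
    """Top-n betweenness selection using the brute-force scores."""
    P = network.trip_fraction
    off = P.copy()
    np.fill_diagonal(off, 0.0)
    pmax = off.max()
    W = np.where(off > 0, pmax + 1.0 - off, np.inf)
    np.fill_diagonal(W, np.inf)
    g = brute_betweenness(W)
    order = sorted(range(network.n), key=lambda i: (-round(g[i], 9), i))
    return [network.node_ids[i] for i in order[:n_nodes]]


def random_stochastic_network(rng, n=None, p_edge=0.5):
    """Random directed column-stochastic travel network for oracle tests."""
    from firewoodnet import TravelNetwork

    if n is None:
        n = int(rng.integers(4, 13))
    counts = np.where(
        rng.random((n, n)) < p_edge, rng.integers(1, 20, size=(n, n)), 0
    ).astype(float)
    np.fill_diagonal(counts, 0.0)
    for j in range(n):
        if counts[:, j].sum() == 0:
            i = (j + 1 + int(rng.integers(0, n - 1))) % n
            counts[i, j] = float(rng.integers(1, 20))
    P = counts / counts.sum(axis=0)
    return TravelNetwork(list(range(n)), P)


def lsq_slope(x, y):
    """Closed-form least-squares slope, independent of np.polyfit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))
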