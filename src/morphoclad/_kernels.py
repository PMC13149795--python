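"""Numba kernels for unit-cost Sankoff scoring.

Trees arrive as flat postorder arrays: ``kidptr``/``kids`` give each
node's children (CSR layout over postorder node indices, root last),
``leaftax[v]`` is the matrix row of leaf ``v`` or -1 for internal nodes.
Leaf costs are 0/INF arrays of shape (chars, taxa, kmax); the unit-cost
dynamic programme is exact for polytomies and leaf ambiguity alike.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.int64(1) << 40


@njit(cache=True)
def score_per_char(kidptr, kids, leaftax, leafcost, out):
    """Minimum steps per character on one tree; writes into ``out``."""
    n_nodes = leaftax.shape[0]
    n_chars, _, kmax = leafcost.shape
    cost = np.empty((n_nodes, kmax), dtype=np.int64)
    for c in range(n_chars):
        for v in range(n_nodes):
            tax = leaftax[v]
            if tax >= 0:
                for a in range(kmax):
                    cost[v, a] = leafcost[c, tax, a]
            else:
                for a in range(kmax):
                    cost[v, a] = 0
            for ci in range(kidptr[v], kidptr[v + 1]):
                w = kids[ci]
                mn = cost[w, 0]
                for b in range(1, kmax):
                    if cost[w, b] < mn:
                        mn = cost[w, b]
                for a in range(kmax):
                    t = cost[w, a]
                    if mn + 1 < t:
                        t = mn + 1
                    cost[v, a] += t
        root = n_nodes - 1
        mn = cost[root, 0]
        for a in range(1, kmax):
            if cost[root, a] < mn:
                mn = cost[root, a]
        out[c] = mn


@njit(cache=True)
def score_total(kidptr, kids, leaftax, leafcost, bound):
    """Total steps over characters; aborts (returning > bound) once the
    running total exceeds ``bound``.  Pass a huge bound for exact totals."""
    n_nodes = leaftax.shape[0]
    n_chars, _, kmax = leafcost.shape
    cost = np.empty((n_nodes, kmax), dtype=np.int64)
    total = np.int64(0)
    for c in range(n_chars):
        for v in range(n_nodes):
            tax = leaftax[v]
            if tax >= 0:
                for a in range(kmax):
                    cost[v, a] = leafcost[c, tax, a]
            else:
                for a in range(kmax):
                    cost[v, a] = 0
            for ci in range(kidptr[v], kidptr[v + 1]):
                w = kids[ci]
                mn = cost[w, 0]
                for b in range(1, kmax):
                    if cost[w, b] < mn:
                        mn = cost[w, b]
                for a in range(kmax):
                    t = cost[w, a]
                    if mn + 1 < t:
                        t = mn + 1
                    cost[v, a] += t
        root = n_nodes - 1
        mn = cost[root, 0]
        for a in range(1, kmax):
            if cost[root, a] < mn:
                mn = cost[root, a]
        total += mn
        if total > bound:
            return total
    return total
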