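"""Independent brute-force oracles, deliberately separate from the package.

These recompute Betti numbers by GF(2) matrix rank, diagram distances by
exhaustive matching enumeration, and BH-FDR by its step-up definition,
so the package's reduction/assignment algorithms are checked against a
different computational route.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gf2_rank(M: np.ndarray) -> int:
    M = (np.asarray(M, dtype=np.int64) % 2).copy()
    rank = 0
    rows, cols = M.shape
    r = 0
    for c in range(cols):
        pivot = None
        for i in range(r, rows):
            if M[i, c]:
                pivot = i
                break
        if pivot is None:
            continue
        M[[r, pivot]] = M[[pivot, r]]
        for i in range(rows):
            if i != r and M[i, c]:
                M[i] ^= M[r]
        r += 1
        rank += 1
        if r == rows:
            break
    return rank


def betti_numbers(D: np.ndarray, eps: float) -> tuple[int, int]:
    """(beta0, beta1) of the Rips complex at scale eps by boundary ranks."""
    n = D.shape[0]
    edges = [e for e in itertools.combinations(range(n), 2) if D[e] <= eps]
    tris = [
        t
        for t in itertools.combinations(range(n), 3)
        if max(D[t[0], t[1]], D[t[0], t[2]], D[t[1], t[2]]) <= eps
    ]
    d1 = np.zeros((n, len(edges)), dtype=np.int64)
    for j, (u, v) in enumerate(edges):
        d1[u, j] = d1[v, j] = 1
    eidx = {e: j for j, e in enumerate(edges)}
    d2 = np.zeros((len(edges), len(tris)), dtype=np.int64)
    for j, (u, v, w) in enumerate(tris):
        for f in ((u, v), (u, w), (v, w)):
            d2[eidx[f], j] = 1
    r1 = gf2_rank(d1) if edges else 0
    r2 = gf2_rank(d2) if tris else 0
    beta0 = n - r1
    beta1 = len(edges) - r1 - r2
    return beta0, beta1


def _matching_cost(a, b, assignment, p):
    """Cost of one complete matching; unmatched points pair to the diagonal."""
    costs = []
    used_b = set()
    for i, j in enumerate(assignment):
        if j is None:
            costs.append((a[i][1] - a[i][0]) / 2.0)
        else:
            used_b.add(j)
            costs.append(
                max(abs(a[i][0] - b[j][0]), abs(a[i][1] - b[j][1]))
            )
    for j in range(len(b)):
        if j not in used_b:
            costs.append((b[j][1] - b[j][0]) / 2.0)
    if not costs:
        return 0.0
    if p is None:
        return max(costs)
    return sum(c ** p for c in costs) ** (1.0 / p)


def brute_force_distance(a, b, kind: str) -> float:
    """Exact diagram distance by enumerating all partial matchings."""
    p = {"wasserstein_1": 1, "wasserstein_2": 2, "bottleneck": None}[kind]
    a, b = list(a), list(b)
    best = math.inf
    targets = list(range(len(b))) + [None] * len(a)
    for perm in set(itertools.permutations(targets, len(a))):
        if any(
            j is not None and perm.count(j) > 1 for j in perm
        ):
            continue
        best = min(best, _matching_cost(a, b, perm, p))
    return best if best < math.inf else 0.0


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH definition: adj_i = min_{j >= rank(i)} (m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = math.inf
    for k in range(m - 1, -1, -1):
        running = min(running, m * p[order[k]] / (k + 1))
        adj[order[k]] = min(running, 1.0)
    return adj
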