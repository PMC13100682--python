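"""Diagram summary statistics: persistent entropy, landscape norms, diagram distances.

Persistent entropy is the Shannon entropy of the normalized bar lengths
e_i = (d_i - b_i) / L with L the total persistence; it is scale
invariant and bounded by log(n) for n bars.  The persistence landscape
lambda_k(t) is the k-th largest of the tent functions
max(0, min(t - b_i, d_i - t)); this package needs k = 1 but the
construction is generic.  Landscapes are kept as exact piecewise-linear
functions and their L^p norms are integrated in closed form per segment,
so the values are deterministic and testable against closed forms.

Diagram distances (1-/2-Wasserstein and bottleneck) use the standard
optimal partial matching with the L-infinity ground metric, where
unmatched points pair with their diagonal projection.  Wasserstein is
solved exactly as an assignment problem; bottleneck by binary search
over candidate costs with a bipartite feasibility check.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .ph import PersistenceDiagram

DISTANCE_KINDS = ("wasserstein_1", "wasserstein_2", "bottleneck")


class EmptySelectionError(ValueError):
    """Raised when a measure is requested on an empty bar selection."""


def persistent_entropy(
    PD: PersistenceDiagram, dims=(0, 1, 2), log_base: str = "e"
) -> float:
    """Shannon entropy of normalized bar lengths, pooled over ``dims``.

    Essential classes are excluded (the formula requires finite deaths),
    as are zero-persistence bars.  Natural log by default; base 2 behind
    the flag — group-difference directions are base invariant.
    """
    bars = PD.finite_pairs(dims)
    if not bars:
        raise EmptySelectionError(
            f"no finite positive-persistence bars in dims {tuple(dims)}"
        )
    lengths = np.array([d - b for b, d in bars])
    e = lengths / lengths.sum()
    log = np.log2 if log_base == "2" or log_base == 2 else np.log
    if log_base not in ("e", "2", 2):
        raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")
    return float(-(e * log(e)).sum())


@dataclasses.dataclass
class PersistenceLandscape:
    """Piecewise-linear landscape lambda_k as ordered (t, value) breakpoints.

    Zero outside the breakpoint range.  An empty breakpoint list is the
    zero function.
    """

    k: int
    breakpoints: list[tuple[float, float]]

    def __call__(self, t: float) -> float:
        bp = self.breakpoints
        if not bp or t <= bp[0][0] or t >= bp[-1][0]:
            # boundary values are 0 by construction
            return bp[0][1] if bp and t == bp[0][0] else 0.0
        ts = [x for x, _ in bp]
        i = int(np.searchsorted(ts, t, side="right")) - 1
        t0, y0 = bp[i]
        t1, y1 = bp[i + 1]
        if t1 == t0:
            return max(y0, y1)
        return y0 + (y1 - y0) * (t - t0) / (t1 - t0)


def landscape(PD: PersistenceDiagram, dim: int = 1, k: int = 1) -> PersistenceLandscape:
    """Exact k-th landscape of the finite dim-``dim`` pairs (no grid)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = PD.finite_pairs(dim)
    if not pairs:
        return PersistenceLandscape(k=k, breakpoints=[])
    births = np.array([b for b, _ in pairs])
    deaths = np.array([d for _, d in pairs])
    # kinks of the k-th largest of tent functions can occur only at tent
    # endpoints and at crossings of an up-slope with a down-slope, i.e.
    # at (b_i + d_j) / 2 for every ordered pair (includes tent peaks)
    cand = set(births) | set(deaths)
    cand.update(((births[:, None] + deaths[None, :]) / 2.0).ravel().tolist())
    lo, hi = births.min(), deaths.max()
    ts = sorted(t for t in cand if lo <= t <= hi)

    def kth(t: float) -> float:
        vals = np.minimum(t - births, deaths - t)
        vals = vals[vals > 0]
        if len(vals) < k:
            return 0.0
        return float(np.partition(vals, len(vals) - k)[len(vals) - k])

    pts = [(t, kth(t)) for t in ts]
    # drop collinear interior points
    out: list[tuple[float, float]] = []
    for p in pts:
        while len(out) >= 2:
            (t0, y0), (t1, y1) = out[-2], out[-1]
            if abs((y1 - y0) * (p[0] - t0) - (p[1] - y0) * (t1 - t0)) <= 1e-12 * max(
                1.0, abs(p[0] - t0)
            ):
                out.pop()
            else:
                break
        out.append(p)
    return PersistenceLandscape(k=k, breakpoints=out)


def landscape_norm(lam: PersistenceLandscape, p: int) -> float:
    """L^p norm by exact closed-form integration over linear segments."""
    if p not in (1, 2):
        raise ValueError(f"unsupported p={p}; use 1 or 2")
    bp = lam.breakpoints
    total = 0.0
    for (t0, y0), (t1, y1) in zip(bp, bp[1:]):
        w = t1 - t0
        if p == 1:
            total += w * (y0 + y1) / 2.0
        else:
            total += w * (y0 * y0 + y0 * y1 + y1 * y1) / 3.0
    return total if p == 1 else math.sqrt(total)


def _finite_points(PD: PersistenceDiagram, dim: int) -> np.ndarray:
    return np.array(PD.finite_pairs(dim), dtype=float).reshape(-1, 2)


def diagram_distance(
    A: PersistenceDiagram, B: PersistenceDiagram, kind: str, dim: int = 1
) -> float:
    """Optimal-matching distance between two diagrams (finite dim pairs).

    Ground metric is L-infinity on the plane; a point's diagonal
    projection costs (d - b) / 2.
    """
    if kind not in DISTANCE_KINDS:
        raise ValueError(f"unknown distance kind {kind!r}")
    a = _finite_points(A, dim)
    b = _finite_points(B, dim)
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0.0
    cross = np.maximum(
        np.abs(a[:, None, 0] - b[None, :, 0]),
        np.abs(a[:, None, 1] - b[None, :, 1]),
    ) if n and m else np.zeros((n, m))
    diag_a = (a[:, 1] - a[:, 0]) / 2.0
    diag_b = (b[:, 1] - b[:, 0]) / 2.0
    if kind == "bottleneck":
        return _bottleneck(cross, diag_a, diag_b)
    p = 1 if kind == "wasserstein_1" else 2
    size = n + m
    cost = np.zeros((size, size))
    cost[:n, :m] = cross ** p
    cost[:n, m:] = np.inf
    cost[:n, m:][np.arange(n), np.arange(n)] = diag_a ** p
    cost[n:, :m] = np.inf
    cost[n:, :m][np.arange(m), np.arange(m)] = diag_b ** p
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() ** (1.0 / p))


def _bottleneck(cross: np.ndarray, diag_a: np.ndarray, diag_b: np.ndarray) -> float:
    n, m = len(diag_a), len(diag_b)
    cand = np.unique(
        np.concatenate([cross.ravel(), diag_a, diag_b, [0.0]])
    )
    lo, hi = 0, len(cand) - 1

    def feasible(c: float) -> bool:
        size = n + m
        rows: list[int] = []
        cols: list[int] = []
        if n and m:
            rr, cc = np.nonzero(cross <= c)
            rows.extend(rr.tolist())
            cols.extend(cc.tolist())
        for i in np.nonzero(diag_a <= c)[0]:
            rows.append(int(i))
            cols.append(m + int(i))
        for j in np.nonzero(diag_b <= c)[0]:
            rows.append(n + int(j))
            cols.append(int(j))
        # diagonal-to-diagonal matches cost 0 and are always allowed
        extra_r, extra_c = np.meshgrid(
            np.arange(n, size), np.arange(m, size), indexing="ij"
        )
        rows.extend(extra_r.ravel().tolist())
        cols.extend(extra_c.ravel().tolist())
        graph = csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(size, size)
        )
        match = maximum_bipartite_matching(graph, perm_type="column")
        return bool((match >= 0).all())

    while lo < hi:
        mid = (lo + hi) // 2
        if feasible(cand[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(cand[lo])
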