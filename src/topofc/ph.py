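"""Vietoris-Rips filtration and persistent homology with representative 1-cycles.

The filtration is built from a finite metric (a distance matrix): a
simplex enters at the maximum pairwise distance among its vertices, so
the set of filtration values is {0} union the unique matrix entries.
Persistence is computed by the standard column reduction of the boundary
matrix over GF(2), in filtration order with deterministic tie-breaking
(value, dimension, lexicographic vertex tuple).  Columns are stored as
Python integers used as bitsets, which keeps the reduction fast enough
for a few thousand simplices without compiled code.

For each finite H1 pair the reduced column of the death triangle is a
1-cycle whose latest edge is the birth edge; that cycle (an edge set,
since coefficients are mod 2) is the representative used by the
node-level measures.  Representatives are not unique — they depend on
the node order — which is why the stats module exposes a node-order
permutation robustness protocol instead of pretending otherwise.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations

import numpy as np

from .data_io import DistanceMatrix


@dataclasses.dataclass
class RipsFiltration:
    """Ordered simplex list; ``simplices[k] = (vertex tuple, value)``."""

    simplices: list[tuple[tuple[int, ...], float]]
    n_vertices: int
    max_dim: int
    node_ids: list[str]

    def __post_init__(self) -> None:
        self._reduction: _Reduction | None = None

    def dims(self) -> list[int]:
        return [len(s[0]) - 1 for s in self.simplices]


@dataclasses.dataclass
class PersistenceDiagram:
    """Multiset of (dimension, birth, death); essential classes have death=inf.

    ``all_pairs`` retains zero-persistence pairs; downstream measures use
    :meth:`finite_pairs`, which drops them along with essential classes.
    """

    all_pairs: list[tuple[int, float, float]]

    def finite_pairs(self, dims) -> list[tuple[float, float]]:
        if isinstance(dims, int):
            dims = (dims,)
        dims = set(dims)
        return [
            (b, d)
            for dim, b, d in self.all_pairs
            if dim in dims and math.isfinite(d) and d > b
        ]

    def essential(self, dim: int) -> list[float]:
        return [b for dm, b, d in self.all_pairs if dm == dim and math.isinf(d)]

    def betti_at(self, dim: int, eps: float) -> int:
        """Features alive at scale eps: born at or before, not yet dead."""
        return sum(
            1
            for dm, b, d in self.all_pairs
            if dm == dim and b <= eps < d and d > b
        )


@dataclasses.dataclass(frozen=True)
class CycleEntry:
    birth: float
    death: float
    edges: frozenset[tuple[int, int]]

    @property
    def vertices(self) -> frozenset[int]:
        return frozenset(v for e in self.edges for v in e)


@dataclasses.dataclass
class RepresentativeCycleSet:
    entries: list[CycleEntry]
    node_ids: list[str]


def build_rips_filtration(D: DistanceMatrix, max_dim: int) -> RipsFiltration:
    """Enumerate all simplices up to ``max_dim`` over the distance matrix.

    Filtration value of a simplex is the maximum pairwise distance among
    its vertices; vertices enter at 0.  Order: (value, dimension,
    lexicographic vertex tuple), which makes diagrams and representative
    cycles deterministic for a fixed node order.
    """
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    dvals = D.values
    if np.any(np.isnan(dvals)):
        raise ValueError("distance matrix contains NaN")
    n = dvals.shape[0]
    simplices: list[tuple[tuple[int, ...], float]] = [((v,), 0.0) for v in range(n)]
    for i, j in combinations(range(n), 2):
        simplices.append(((i, j), float(dvals[i, j])))
    for dim in range(2, max_dim + 1):
        for verts in combinations(range(n), dim + 1):
            val = max(dvals[a, b] for a, b in combinations(verts, 2))
            simplices.append((verts, float(val)))
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    return RipsFiltration(simplices, n, max_dim, list(D.node_ids))


class _Reduction:
    """Mod-2 column reduction of the boundary matrix in filtration order."""

    def __init__(self, F: RipsFiltration) -> None:
        simplices = F.simplices
        pos = {s[0]: k for k, (s) in enumerate(simplices)}
        m = len(simplices)
        reduced: dict[int, int] = {}   # column index -> bitset of row indices
        low_of: dict[int, int] = {}    # low row -> column index holding it
        pairs: list[tuple[int, int]] = []          # (birth col, death col)
        unpaired = [True] * m
        for j, (verts, _val) in enumerate(simplices):
            if len(verts) == 1:
                continue
            col = 0
            for k in range(len(verts)):
                face = verts[:k] + verts[k + 1:]
                col |= 1 << pos[face]
            while col:
                low = col.bit_length() - 1
                other = low_of.get(low)
                if other is None:
                    break
                col ^= reduced[other]
            if col:
                low = col.bit_length() - 1
                low_of[low] = j
                reduced[j] = col
                pairs.append((low, j))
                unpaired[low] = False
                unpaired[j] = False
        self.filtration = F
        self.pos = pos
        self.reduced = reduced
        self.pairs = pairs
        self.unpaired = unpaired


def _reduce(F: RipsFiltration) -> _Reduction:
    if F._reduction is None:
        F._reduction = _Reduction(F)
    return F._reduction


def compute_persistence(F: RipsFiltration, max_hom_dim: int) -> PersistenceDiagram:
    """Persistence diagram up to homology dimension ``max_hom_dim``.

    Requires the filtration to contain simplices of dimension
    ``max_hom_dim + 1`` so that deaths in the top dimension are seen.
    """
    if F.max_dim < max_hom_dim + 1:
        raise ValueError(
            f"filtration built to dim {F.max_dim} cannot resolve "
            f"H{max_hom_dim}; need simplices of dim {max_hom_dim + 1}"
        )
    red = _reduce(F)
    simplices = F.simplices
    out: list[tuple[int, float, float]] = []
    for i, j in red.pairs:
        dim = len(simplices[i][0]) - 1
        if dim <= max_hom_dim:
            out.append((dim, simplices[i][1], simplices[j][1]))
    for k, free in enumerate(red.unpaired):
        if free:
            dim = len(simplices[k][0]) - 1
            if dim <= max_hom_dim:
                out.append((dim, simplices[k][1], math.inf))
    return PersistenceDiagram(all_pairs=out)


def compute_representative_cycles(F: RipsFiltration) -> RepresentativeCycleSet:
    """Representative 1-cycle for every finite positive-persistence H1 pair.

    The cycle is the reduced boundary column of the death triangle: an
    edge set with zero mod-2 boundary whose latest edge is the birth
    edge.  Zero-persistence pairs are dropped — they carry no geometric
    signal and would only inflate the node-frequency counts.
    """
    if F.max_dim < 2:
        raise ValueError("representative cycles need simplices through dim 2")
    red = _reduce(F)
    simplices = F.simplices
    entries: list[CycleEntry] = []
    for i, j in red.pairs:
        if len(simplices[i][0]) != 2:
            continue
        birth, death = simplices[i][1], simplices[j][1]
        if not death > birth:
            continue
        col = red.reduced[j]
        edges = []
        while col:
            low = col.bit_length() - 1
            col ^= 1 << low
            edges.append(simplices[low][0])
        entries.append(
            CycleEntry(birth=birth, death=death, edges=frozenset(edges))
        )
    entries.sort(key=lambda e: (e.birth, e.death, sorted(e.edges)))
    return RepresentativeCycleSet(entries=entries, node_ids=list(F.node_ids))
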