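"""Synthetic correlation-matrix cohorts with planted 1-cycles and group effects.

The generator emulates parcellated functional connectivity at desk
scale with an explicit latent-factor (Gram) construction, so every
template is positive semidefinite by design:

* background node i loads sqrt(a_i) on a global factor and sqrt(b_i) on
  its community factor (per-node variances drawn once per cohort,
  shared by both groups and all subjects), and additionally sits on a
  large latent circle — a closed mesoscale gradient across the
  communities — contributing bg_circle * cos(psi_i - psi_j).  The
  gradient loop guarantees background 1-cycles in every subject, which
  anchor the persistence extent the way the rich loop structure of real
  connectivity does; the heterogeneous loadings keep filtration values
  generic instead of massively tied;
* a planted ring of m nodes forms a tight module on its own latent
  circle: ring nodes i, j get correlation l + q cos(2 pi (p_i - p_j)/m)
  with l = ring_base and q = ring_strength (1 - l), plus
  sqrt(l * a_k) to every outside node k.

Under the correlation-to-distance transform the ring's adjacent edges
are the shortest in the graph, so the loop closes long before anything
else and its representative cycle is pinned to the planted nodes under
any node order (no alternative path exists at the birth scale).  The
hole is filled internally at the ring's chord scale, well below the
deaths of the background holes that anchor the extent.  A group effect
is a delta added to ``ring_strength`` for group B: it moves the planted
birth earlier (stronger adjacent correlations) and its chord-scale
death later (weaker long chords), lengthening the planted bar at both
ends without moving the extent anchors, which raises node persistence
on exactly the planted nodes.

Per-subject noise is symmetric Gaussian on the off-diagonal entries
followed by an eigenvalue-clipping projection back to the correlation
cone (the templates themselves need no repair).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from statsmodels.stats.correlation_tools import corr_clipped

from .data_io import CorrelationMatrix, DistanceMatrix, GroupTable


@dataclasses.dataclass
class SyntheticSpec:
    """Cohort recipe; defaults are the package's reference study conditions.

    ``base_within`` / ``base_between`` are the centers of the uniform
    ranges the per-node community / global loadings are drawn from, so
    realized correlations scatter around them.  ``ring_base`` is the
    ring nodes' shared variance l with the global factor: it sets both
    the ring's internal correlation floor and (with the largest outside
    global loading) the coning scale that kills the planted hole.
    """

    n_nodes: int = 30
    community_sizes: tuple[int, ...] = (8, 6, 6, 5, 5)
    community_labels: tuple[str, ...] = ("ring", "bg1", "bg2", "bg3", "bg4")
    base_within: float = 0.35
    base_between: float = 0.10
    bg_circle: float = 0.22
    ring_base: float = 0.8
    planted_cycles: tuple[tuple[tuple[int, ...], float], ...] = (
        ((0, 1, 2, 3, 4, 5, 6, 7), 0.7),
    )
    effect_nodes: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    effect_delta: float = 0.25
    noise_sd: float = 0.04
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError("community sizes must sum to n_nodes")
        for nodes, strength in self.planted_cycles:
            delta = self.effect_delta if set(nodes) & set(self.effect_nodes) else 0.0
            if not 0.0 < strength <= 1.0 or strength + delta > 1.0:
                raise ValueError(f"ring strength {strength}+{delta} outside (0, 1]")
            if len(nodes) < 4:
                raise ValueError("planted rings need at least 4 nodes")
        if not 0.0 < self.ring_base < 1.0:
            raise ValueError("ring_base must lie in (0, 1)")

    def node_ids(self) -> list[str]:
        return [f"n{i:03d}" for i in range(self.n_nodes)]

    def community_map(self) -> dict[str, str]:
        ids = self.node_ids()
        comm: dict[str, str] = {}
        k = 0
        for size, label in zip(self.community_sizes, self.community_labels):
            for _ in range(size):
                comm[ids[k]] = label
                k += 1
        return comm


def _loadings(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-node global (a) and community (b) variances, fixed per cohort.

    The node's total latent variance (global + circle + community) is
    capped below 1 so the construction stays a valid Gram matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    half_a = min(spec.base_between, 1.0 - spec.base_between) * 0.8
    half_b = min(spec.base_within, 1.0 - spec.base_within) * 0.4
    a = rng.uniform(spec.base_between - half_a, spec.base_between + half_a, spec.n_nodes)
    b = rng.uniform(spec.base_within - half_b, spec.base_within + half_b, spec.n_nodes)
    b = np.minimum(b, 0.98 - spec.bg_circle - a)
    return a, b


def _template(spec: SyntheticSpec, group_b: bool) -> np.ndarray:
    n = spec.n_nodes
    a, b = _loadings(spec)
    sa = np.sqrt(a)
    sb = np.sqrt(b)
    block = np.zeros(n, dtype=int)
    k = 0
    for bi, size in enumerate(spec.community_sizes):
        block[k : k + size] = bi
        k += size
    ring_nodes = {v for nodes, _ in spec.planted_cycles for v in nodes}
    bg = [i for i in range(n) if i not in ring_nodes]
    # background nodes on a large latent circle (a closed mesoscale
    # gradient across the communities): guarantees at least one
    # background 1-cycle in every subject, anchoring the persistence
    # extent the way the rich loop structure of real connectivity does
    psi = np.zeros(n)
    for k_bg, i in enumerate(bg):
        psi[i] = 2.0 * math.pi * k_bg / len(bg)
    circle = spec.bg_circle * np.cos(psi[:, None] - psi[None, :])
    is_bg = np.zeros(n, dtype=bool)
    is_bg[bg] = True
    M = np.outer(sa, sa) + np.where(
        np.outer(is_bg, is_bg), circle, 0.0
    )
    same = block[:, None] == block[None, :]
    M = M + same * np.outer(sb, sb)
    for nodes, strength in spec.planted_cycles:
        if group_b and set(nodes) & set(spec.effect_nodes):
            strength = strength + spec.effect_delta
        nodes = list(nodes)
        m = len(nodes)
        l = spec.ring_base
        q = strength * (1.0 - l)
        # ring nodes sit on the global-factor axis
        out = np.sqrt(l) * sa
        M[nodes, :] = out[None, :]
        M[:, nodes] = out[:, None]
        for i in range(m):
            for j in range(m):
                M[nodes[i], nodes[j]] = l + q * math.cos(2.0 * math.pi * (i - j) / m)
    np.fill_diagonal(M, 1.0)
    return M


def _repair(M: np.ndarray) -> np.ndarray:
    """Project to the nearest valid correlation matrix (eigenvalue clipping)."""
    M = np.clip((M + M.T) / 2.0, -0.999, 0.999)
    np.fill_diagonal(M, 1.0)
    for _ in range(20):
        if np.linalg.eigvalsh(M).min() >= -1e-10:
            break
        M = np.asarray(corr_clipped(M, threshold=1e-10))
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
    return np.clip(M, -1.0, 1.0)


def generate_cohort(spec: SyntheticSpec) -> tuple[list[CorrelationMatrix], GroupTable]:
    """Generate n_per_group subjects per group (A = reference, B = effect).

    Fully reproducible from ``spec.seed``; per-subject noise uses spawned
    substreams so cohort prefixes are stable under size changes.
    """
    ids = spec.node_ids()
    comm = spec.community_map()
    n = spec.n_nodes
    streams = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_group)
    subjects: list[CorrelationMatrix] = []
    membership: dict[str, str] = {}
    templates = {"A": _template(spec, group_b=False), "B": _template(spec, group_b=True)}
    k = 0
    for group in ("A", "B"):
        for s in range(spec.n_per_group):
            rng = np.random.default_rng(streams[k])
            k += 1
            noise = rng.normal(0.0, spec.noise_sd, size=(n, n))
            noise = (noise + noise.T) / 2.0
            np.fill_diagonal(noise, 0.0)
            M = _repair(templates[group] + noise)
            sid = f"{group}{s:02d}"
            subjects.append(CorrelationMatrix(M, ids, comm, sid))
            membership[sid] = group
    return subjects, GroupTable(membership)


def square_fixture() -> DistanceMatrix:
    """4-point unit square: sides 1, diagonals sqrt(2); one H1 pair (1, sqrt 2)."""
    s2 = math.sqrt(2.0)
    d = np.array(
        [
            [0.0, 1.0, s2, 1.0],
            [1.0, 0.0, 1.0, s2],
            [s2, 1.0, 0.0, 1.0],
            [1.0, s2, 1.0, 0.0],
        ]
    )
    return DistanceMatrix(d, [f"n{i}" for i in range(4)], {"fixture": "square"})


def two_ring_fixture() -> DistanceMatrix:
    """Two disjoint 4-node squares (sides .5, diagonals .5*sqrt 2), cross = 2.

    beta_1 = 2 with disjoint vertex sets {0..3} and {4..7}.
    """
    n = 8
    d = np.full((n, n), 2.0)
    s = 0.5
    for off in (0, 4):
        block = np.array(
            [
                [0.0, s, s * math.sqrt(2.0), s],
                [s, 0.0, s, s * math.sqrt(2.0)],
                [s * math.sqrt(2.0), s, 0.0, s],
                [s, s * math.sqrt(2.0), s, 0.0],
            ]
        )
        d[off : off + 4, off : off + 4] = block
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [f"n{i}" for i in range(n)], {"fixture": "two_ring"})
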