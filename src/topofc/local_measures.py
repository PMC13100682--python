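"""Node-level topological measures from representative H1 cycles.

Node persistence NP(v) aggregates the spans (d_i - b_i) of every
representative 1-cycle containing v, normalized by the persistence
extent max{d_i} - min{b_i} over all finite H1 pairs of the subject.
Node frequency NF(v) counts the distinct cycles containing v.  Both are
defined over the vertex set of each representative cycle: a node
contributes when it lies on the chosen cycle, not merely near the hole.

Subjects with beta_1 = 0 are legitimate: all nodes get 0 and the extent
is flagged undefined rather than raising.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .data_io import CorrelationMatrix, to_distance
from .ph import (
    RepresentativeCycleSet,
    build_rips_filtration,
    compute_persistence,
    compute_representative_cycles,
)


@dataclasses.dataclass
class NodeMeasureTable:
    """Per-node NP and NF for one subject, plus extent and beta_1 metadata."""

    subject_id: str
    table: pd.DataFrame  # columns: node_id, node_persistence, node_frequency
    extent: float | None  # None when beta_1 = 0
    beta1: int

    def np_values(self) -> dict[str, float]:
        return dict(zip(self.table.node_id, self.table.node_persistence))

    def nf_values(self) -> dict[str, int]:
        return dict(zip(self.table.node_id, self.table.node_frequency))


def _extent(cycles: RepresentativeCycleSet) -> float | None:
    if not cycles.entries:
        return None
    return max(e.death for e in cycles.entries) - min(e.birth for e in cycles.entries)


def node_persistence(cycles: RepresentativeCycleSet) -> dict[str, float]:
    """NP(v) = sum over cycles containing v of (d_i - b_i), over the extent."""
    out = {nid: 0.0 for nid in cycles.node_ids}
    ext = _extent(cycles)
    if ext is None:
        return out
    for entry in cycles.entries:
        span = entry.death - entry.birth
        for v in entry.vertices:
            out[cycles.node_ids[v]] += span / ext
    return out


def node_frequency(cycles: RepresentativeCycleSet) -> dict[str, int]:
    """NF(v) = number of distinct representative cycles containing v."""
    out = {nid: 0 for nid in cycles.node_ids}
    for entry in cycles.entries:
        for v in entry.vertices:
            out[cycles.node_ids[v]] += 1
    return out


def node_measures_for_subject(
    C: CorrelationMatrix,
    formula_variant: str = "linear",
    negative_policy: str = "max_distance",
) -> NodeMeasureTable:
    """Full pipeline: transform -> Rips (dim 2) -> persistence -> cycles -> NP/NF."""
    D = to_distance(C, formula_variant, negative_policy)
    F = build_rips_filtration(D, max_dim=2)
    compute_persistence(F, max_hom_dim=1)
    cycles = compute_representative_cycles(F)
    np_map = node_persistence(cycles)
    nf_map = node_frequency(cycles)
    df = pd.DataFrame(
        {
            "node_id": C.node_ids,
            "node_persistence": [np_map[n] for n in C.node_ids],
            "node_frequency": [nf_map[n] for n in C.node_ids],
        }
    )
    ext = _extent(cycles)
    return NodeMeasureTable(
        subject_id=C.subject_id,
        table=df,
        extent=ext,
        beta1=len(cycles.entries),
    )


def measure_table_frame(
    tables: list[NodeMeasureTable], community: dict[str, str] | None = None
) -> pd.DataFrame:
    """Stack per-subject tables into one long frame for serialization."""
    frames = []
    for t in tables:
        df = t.table.copy()
        df.insert(0, "subject_id", t.subject_id)
        if community is not None:
            df.insert(2, "community", [community[n] for n in df.node_id])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
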