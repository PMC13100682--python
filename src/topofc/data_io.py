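"""I/O and validation for correlation matrices, label/group tables and result artifacts.

Functional-connectivity inputs are square symmetric Pearson-correlation
matrices, one per subject, stored as delimited text (comma or tab,
autodetected) with an optional header row of node names.  Node labels
(node -> community, e.g. one of the seven resting-state networks) and
group membership (subject -> group) are two-column delimited tables.

The correlation-to-distance transform maps C in [-1, 1] to a filtration
scale in [0, 2].  Two variants are exposed: ``linear`` D = 2(1 - C) and
``sqrt`` D = sqrt(2(1 - C)); non-positive correlations are handled by an
explicit policy because the filtration is built from positive
connectivity only.
"""

from __future__ import annotations

import dataclasses
import io
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SYM_TOL = 1e-9

DEFAULT_COMMUNITY = "all"

FORMULA_VARIANTS = ("linear", "sqrt")
NEGATIVE_POLICIES = ("max_distance", "clamp_zero")


class ValidationError(ValueError):
    """Base class for input-validation failures."""


class NonSquareError(ValidationError):
    pass


class AsymmetryError(ValidationError):
    pass


class RangeError(ValidationError):
    pass


class DiagonalError(ValidationError):
    pass


class LabelMismatchError(ValidationError):
    pass


@dataclasses.dataclass
class CorrelationMatrix:
    """A subject-level correlation matrix with node labels.

    Parameters
    ----------
    values
        n x n symmetric matrix, unit diagonal, entries in [-1, 1].
    node_ids
        Ordered node names; the order is canonical and preserved
        end-to-end (representative cycles depend on it).
    community
        Mapping node_id -> community label covering every node.
    subject_id
        Identifier used to key result tables.
    """

    values: np.ndarray
    node_ids: list[str]
    community: dict[str, str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = list(self.node_ids)
        validate_correlation(self.values, self.node_ids, self.community)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def communities(self) -> list[str]:
        seen: dict[str, None] = {}
        for nid in self.node_ids:
            seen.setdefault(self.community[nid], None)
        return list(seen)


@dataclasses.dataclass
class DistanceMatrix:
    """Filtration-scale distance matrix derived from correlations."""

    values: np.ndarray
    node_ids: list[str]
    transform_tag: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = list(self.node_ids)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise NonSquareError(f"distance matrix has shape {v.shape}")
        if len(self.node_ids) != v.shape[0]:
            raise LabelMismatchError(
                f"{len(self.node_ids)} node ids for {v.shape[0]} rows"
            )
        if not np.allclose(v, v.T, atol=SYM_TOL, rtol=0.0):
            raise AsymmetryError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise DiagonalError("distance matrix diagonal must be 0")
        if v.min() < 0.0 or v.max() > 2.0 + SYM_TOL:
            i, j = np.unravel_index(np.argmax(np.abs(v - 1.0)), v.shape)
            raise RangeError(
                f"distance entry ({self.node_ids[i]},{self.node_ids[j]})="
                f"{v[i, j]} outside [0, 2]"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class GroupTable:
    """Subject -> group label mapping; comparisons expect two groups."""

    membership: dict[str, str]

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.membership.values():
            seen.setdefault(g, None)
        return list(seen)

    def subjects(self, group: str) -> list[str]:
        return [s for s, g in self.membership.items() if g == group]

    def __getitem__(self, subject_id: str) -> str:
        return self.membership[subject_id]


def validate_correlation(
    values: np.ndarray, node_ids: Sequence[str], community: Mapping[str, str]
) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise NonSquareError(f"correlation matrix has shape {values.shape}")
    n = values.shape[0]
    if len(node_ids) != n:
        raise LabelMismatchError(f"{len(node_ids)} node ids for {n} matrix rows")
    if len(set(node_ids)) != n:
        dup = next(x for x in node_ids if list(node_ids).count(x) > 1)
        raise LabelMismatchError(f"duplicate node id {dup!r}")
    asym = np.abs(values - values.T)
    if asym.max(initial=0.0) > SYM_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise AsymmetryError(
            f"asymmetry {asym[i, j]:.3e} at ({node_ids[i]},{node_ids[j]})"
        )
    dd = np.abs(np.diag(values) - 1.0)
    if dd.max(initial=0.0) > SYM_TOL:
        i = int(np.argmax(dd))
        raise DiagonalError(f"diagonal entry for {node_ids[i]} is {values[i, i]}")
    if values.min() < -1.0 - SYM_TOL or values.max() > 1.0 + SYM_TOL:
        flat = np.abs(values)
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        raise RangeError(
            f"correlation ({node_ids[i]},{node_ids[j]})={values[i, j]} "
            "outside [-1, 1]"
        )
    missing = [nid for nid in node_ids if nid not in community]
    if missing:
        raise LabelMismatchError(f"nodes without community label: {missing[:5]}")


def _read_delimited_matrix(path: Path) -> tuple[np.ndarray, list[str] | None]:
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.strip() else ""
    sep = "\t" if "\t" in first else ","
    fields = [f.strip() for f in first.split(sep)]

    def _numeric(f: str) -> bool:
        try:
            float(f)
            return True
        except ValueError:
            return False

    has_header = bool(fields) and not all(_numeric(f) for f in fields if f)
    df = pd.read_csv(
        io.StringIO(text), sep=sep, header=0 if has_header else None,
        float_precision="round_trip",
    )
    node_ids = [str(c) for c in df.columns] if has_header else None
    return df.to_numpy(dtype=float), node_ids


def read_label_table(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"label table {path} needs two columns")
    if str(df.iloc[0, 0]).lower() in ("node_id", "node"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def read_group_table(path: Path) -> GroupTable:
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"group table {path} needs two columns")
    if str(df.iloc[0, 0]).lower() in ("subject_id", "subject"):
        df = df.iloc[1:]
    return GroupTable(dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip())))


def read_correlation_matrix(
    path: Path,
    label_path: Path | None = None,
    subject_id: str | None = None,
    symmetrize: bool = False,
) -> CorrelationMatrix:
    """Read and validate one subject's correlation matrix.

    Row/column order follows file order.  With no label file every node is
    assigned a single default community.  ``symmetrize`` averages
    (M + M.T)/2 before validation, for tolerant ingestion.
    """
    values, node_ids = _read_delimited_matrix(Path(path))
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise NonSquareError(f"{path}: matrix has shape {values.shape}")
    n = values.shape[0]
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(n)]
    if symmetrize:
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 1.0)
    if label_path is not None:
        community = read_label_table(Path(label_path))
        missing = [nid for nid in node_ids if nid not in community]
        if len(missing) == n and len(community) == n:
            # label file in row order, names differ from default ids
            community = dict(zip(node_ids, community.values()))
        elif missing:
            raise LabelMismatchError(
                f"{path}: nodes without community label: {missing[:5]}"
            )
        community = {nid: community[nid] for nid in node_ids}
    else:
        community = {nid: DEFAULT_COMMUNITY for nid in node_ids}
    sid = subject_id if subject_id is not None else Path(path).stem
    return CorrelationMatrix(values, node_ids, community, sid)


def to_distance(
    C: CorrelationMatrix,
    formula_variant: str = "linear",
    negative_policy: str = "max_distance",
) -> DistanceMatrix:
    """Correlation-to-distance transform D = 2(1-C) (or its square root).

    Entries with C <= 0 carry no positive-connectivity signal; under
    ``max_distance`` they enter the filtration last (D = 2), under
    ``clamp_zero`` the correlation is floored at 0 before the formula.
    The diagonal is forced to 0.
    """
    if formula_variant not in FORMULA_VARIANTS:
        raise ValidationError(f"unknown formula variant {formula_variant!r}")
    if negative_policy not in NEGATIVE_POLICIES:
        raise ValidationError(f"unknown negative policy {negative_policy!r}")
    c = C.values.copy()
    nonpos = c <= 0.0
    if negative_policy == "clamp_zero":
        c[nonpos] = 0.0
    c = np.clip(c, -1.0, 1.0)
    d = 2.0 * (1.0 - c)
    if formula_variant == "sqrt":
        d = np.sqrt(d)
    if negative_policy == "max_distance":
        d[nonpos] = 2.0
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    tag = {"formula_variant": formula_variant, "negative_policy": negative_policy}
    return DistanceMatrix(d, C.node_ids, tag)


def extract_community_submatrix(C: CorrelationMatrix, community: str) -> CorrelationMatrix:
    """Principal submatrix restricted to one community, node order preserved."""
    idx = [i for i, nid in enumerate(C.node_ids) if C.community[nid] == community]
    if not idx:
        raise ValidationError(f"unknown community label {community!r}")
    ids = [C.node_ids[i] for i in idx]
    sub = C.values[np.ix_(idx, idx)]
    comm = {nid: C.community[nid] for nid in ids}
    return CorrelationMatrix(sub, ids, comm, C.subject_id)


# --------------------------------------------------------------------------
# result-artifact writers/readers (delimited text, lossless to 15 sig digits)

_FLOAT_FMT = "%.17g"


def write_diagram(diagram, path: Path) -> None:
    """Diagram as TSV with columns dimension, birth, death, essential."""
    rows = [
        {
            "dimension": dim,
            "birth": b,
            "death": d,
            "essential": int(math.isinf(d)),
        }
        for dim, b, d in diagram.all_pairs
    ]
    df = pd.DataFrame(rows, columns=["dimension", "birth", "death", "essential"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_diagram(path: Path):
    from .ph import PersistenceDiagram

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    pairs = [
        (int(r.dimension), float(r.birth), float(r.death))
        for r in df.itertuples(index=False)
    ]
    return PersistenceDiagram(all_pairs=pairs)


def write_cycles(cycles, path: Path) -> None:
    """Cycle set as TSV: one row per edge, grouped by cycle index."""
    rows = []
    for k, entry in enumerate(cycles.entries):
        for u, v in sorted(entry.edges):
            rows.append(
                {
                    "cycle": k,
                    "birth": entry.birth,
                    "death": entry.death,
                    "node_u": cycles.node_ids[u],
                    "node_v": cycles.node_ids[v],
                }
            )
    df = pd.DataFrame(rows, columns=["cycle", "birth", "death", "node_u", "node_v"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_cycles(path: Path):
    from .ph import CycleEntry, RepresentativeCycleSet

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    node_ids: list[str] = []
    index: dict[str, int] = {}
    for nid in pd.concat([df.node_u, df.node_v]).astype(str):
        if nid not in index:
            index[nid] = len(node_ids)
            node_ids.append(nid)
    entries = []
    if len(df):
        for _, grp in df.groupby("cycle", sort=True):
            edges = frozenset(
                (index[str(r.node_u)], index[str(r.node_v)])
                for r in grp.itertuples(index=False)
            )
            entries.append(
                CycleEntry(
                    birth=float(grp.birth.iloc[0]),
                    death=float(grp.death.iloc[0]),
                    edges=edges,
                )
            )
    return RepresentativeCycleSet(entries=entries, node_ids=node_ids)


def write_measure_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_measure_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_matrix(
    values: np.ndarray, node_ids: Sequence[str], path: Path, sep: str = ","
) -> None:
    pd.DataFrame(values, columns=list(node_ids)).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT
    )
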