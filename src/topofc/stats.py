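"""Group comparisons, FDR, robustness-to-cycle-choice protocol, enrichment null.

Two-sample t tests (pooled Student by default, Welch behind a flag) with
Benjamini-Hochberg FDR applied within explicit families: per measure for
global and node-level analyses, optionally per community for the
network-level workflow.  No covariates are modelled.

Representative cycles are deterministic only for a fixed node order, so
the node-level measures inherit a dependence on the ordering.  The
robustness protocol quantifies it the way it should be quantified:
recompute NP/NF under R random node-order permutations, map values back
to original node identity, and summarise per-node dispersion (MAD and
MAD/M) and rank stability (pairwise Spearman of node rankings).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_io import CorrelationMatrix, GroupTable
from .local_measures import node_measures_for_subject

TAILS = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclasses.dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def two_sample_ttest(
    x, y, tail: str = "two_sided", variant: str = "pooled"
) -> TTestResult:
    """Two-sample t test; ``tail='less'`` tests mean(x) < mean(y)."""
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        t = -np.inf if x.mean() < y.mean() else np.inf
        if tail == "two_sided":
            p = 0.0
        elif tail == "less":
            p = 0.0 if t < 0 else 1.0
        else:
            p = 0.0 if t > 0 else 1.0
        return TTestResult(t=float(t), p=p, degenerate=True)
    res = sps.ttest_ind(
        x, y, equal_var=(variant == "pooled"), alternative=TAILS[tail]
    )
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p); rho is nan (flagged undefined) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mad_index(values) -> tuple[float, float]:
    """(MAD, MAD/M): unscaled median absolute deviation and its median ratio.

    MAD/M is nan-flagged when the median is 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return mad, (mad / med if med != 0.0 else float("nan"))


def compare_groups(
    measures: pd.DataFrame,
    groups: GroupTable,
    alpha: float = 0.05,
    fdr_scope: tuple[str, ...] = ("measure",),
    tail: str = "two_sided",
    variant: str = "pooled",
) -> pd.DataFrame:
    """Per-feature two-sample tests with FDR within explicit families.

    ``measures`` is a long frame with columns subject_id, measure,
    feature, value (feature = node_id, community name, or the measure
    name itself for global scalars).  FDR is applied separately within
    each combination of the ``fdr_scope`` columns.
    """
    required = {"subject_id", "measure", "feature", "value"}
    if not required.issubset(measures.columns):
        raise ValueError(f"measures frame needs columns {sorted(required)}")
    labels = groups.labels()
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    ga, gb = labels
    missing = set(measures.subject_id) - set(groups.membership)
    if missing:
        raise ValueError(f"subjects without group label: {sorted(missing)[:5]}")
    rows = []
    for (measure, feature), grp in measures.groupby(["measure", "feature"], sort=True):
        sub = grp.set_index("subject_id").value
        xa = sub[[s for s in sub.index if groups[s] == ga]].to_numpy()
        xb = sub[[s for s in sub.index if groups[s] == gb]].to_numpy()
        res = two_sample_ttest(xa, xb, tail=tail, variant=variant)
        rows.append(
            {
                "measure": measure,
                "feature": feature,
                f"mean_{ga}": float(np.mean(xa)),
                f"mean_{gb}": float(np.mean(xb)),
                "t": res.t,
                "p_raw": res.p,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    scope_cols = [c for c in fdr_scope if c in out.columns]
    if scope_cols:
        out["p_adj"] = (
            out.groupby(scope_cols, sort=False)
            .p_raw.transform(lambda p: bh_fdr(p.to_numpy()))
        )
    else:
        out["p_adj"] = bh_fdr(out.p_raw.to_numpy())
    out["significant"] = out.p_adj < alpha
    out["direction"] = np.where(
        out[f"mean_{ga}"] > out[f"mean_{gb}"], f"{ga}>{gb}", f"{ga}<{gb}"
    )
    return out


@dataclasses.dataclass
class RobustnessSummary:
    """Dispersion and rank stability of node measures across node orders."""

    per_node: pd.DataFrame        # measure, node_id, mad/mad_over_median stats
    spearman: dict[str, np.ndarray]  # measure -> R x R mean Spearman matrix
    sig_counts: pd.DataFrame | None  # permutation, measure, n_significant
    R: int
    seed: int


def _permuted_matrix(C: CorrelationMatrix, perm: np.ndarray) -> CorrelationMatrix:
    ids = [C.node_ids[i] for i in perm]
    vals = C.values[np.ix_(perm, perm)]
    comm = {nid: C.community[nid] for nid in ids}
    return CorrelationMatrix(vals, ids, comm, C.subject_id)


def robustness_protocol(
    subjects: list[CorrelationMatrix],
    R: int,
    seed: int,
    groups: GroupTable | None = None,
    alpha: float = 0.05,
    formula_variant: str = "linear",
    negative_policy: str = "max_distance",
    permutations: list[np.ndarray] | None = None,
) -> RobustnessSummary:
    """Recompute NP/NF under R node-order permutations and summarise stability.

    A master seed spawns one substream per permutation, so adding
    permutations never changes earlier ones.  Values are mapped back to
    original node identity before aggregation.  Explicit ``permutations``
    override the seeded draws (used for degenerate-case checks).
    """
    if R < 2:
        raise ValueError("need at least two permutations")
    if not subjects:
        raise ValueError("no subjects")
    if permutations is not None and len(permutations) != R:
        raise ValueError("need exactly R explicit permutations")
    node_ids = subjects[0].node_ids
    n = len(node_ids)
    streams = np.random.SeedSequence(seed).spawn(R)
    # values[measure][r] = frame subjects x nodes
    values: dict[str, list[pd.DataFrame]] = {"node_persistence": [], "node_frequency": []}
    for r in range(R):
        if permutations is not None:
            perm = np.asarray(permutations[r])
        else:
            rng = np.random.default_rng(streams[r])
            perm = rng.permutation(n)
        rows_np, rows_nf = [], []
        for C in subjects:
            t = node_measures_for_subject(
                _permuted_matrix(C, perm), formula_variant, negative_policy
            )
            npv, nfv = t.np_values(), t.nf_values()
            rows_np.append([npv[nid] for nid in node_ids])
            rows_nf.append([nfv[nid] for nid in node_ids])
        idx = [C.subject_id for C in subjects]
        values["node_persistence"].append(
            pd.DataFrame(rows_np, index=idx, columns=node_ids)
        )
        values["node_frequency"].append(
            pd.DataFrame(rows_nf, index=idx, columns=node_ids)
        )

    per_node_rows = []
    spearman_mats: dict[str, np.ndarray] = {}
    for measure, frames in values.items():
        stack = np.stack([f.to_numpy() for f in frames])  # R x subjects x nodes
        for j, nid in enumerate(node_ids):
            mads = []
            madms = []
            for s in range(stack.shape[1]):
                mad, madm = mad_index(stack[:, s, j])
                mads.append(mad)
                madms.append(madm)
            mads = np.array(mads)
            madms = np.array(madms)
            per_node_rows.append(
                {
                    "measure": measure,
                    "node_id": nid,
                    "mad_mean": float(np.mean(mads)),
                    "mad_q1": float(np.percentile(mads, 25)),
                    "mad_median": float(np.median(mads)),
                    "mad_q3": float(np.percentile(mads, 75)),
                    "madm_mean": float(np.nanmean(madms)) if not np.all(np.isnan(madms)) else float("nan"),
                    "madm_median": float(np.nanmedian(madms)) if not np.all(np.isnan(madms)) else float("nan"),
                }
            )
        mat = np.ones((R, R))
        for a in range(R):
            for b in range(a + 1, R):
                rhos = []
                for s in range(stack.shape[1]):
                    xa, xb = stack[a, s], stack[b, s]
                    if np.all(xa == xa[0]) or np.all(xb == xb[0]):
                        # constant rankings: identical vectors agree
                        # perfectly, otherwise uninformative — skip
                        if np.array_equal(xa, xb):
                            rhos.append(1.0)
                        continue
                    rho, _ = spearman(xa, xb)
                    rhos.append(rho)
                mat[a, b] = mat[b, a] = float(np.mean(rhos)) if rhos else float("nan")
        spearman_mats[measure] = mat

    sig_counts = None
    if groups is not None:
        rows = []
        for measure, frames in values.items():
            for r, frame in enumerate(frames):
                long = frame.reset_index(names="subject_id").melt(
                    id_vars="subject_id", var_name="feature", value_name="value"
                )
                long["measure"] = measure
                res = compare_groups(long, groups, alpha=alpha)
                rows.append(
                    {
                        "permutation": r,
                        "measure": measure,
                        "n_significant": int(res.significant.sum()),
                    }
                )
        sig_counts = pd.DataFrame(rows)

    return RobustnessSummary(
        per_node=pd.DataFrame(per_node_rows),
        spearman=spearman_mats,
        sig_counts=sig_counts,
        R=R,
        seed=seed,
    )


def term_enrichment_null(
    annotations: dict[str, set[str]],
    selected: set[str],
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Resampling null for term frequencies among a selected node set.

    Observed term counts in ``selected`` are compared with counts over B
    uniformly resampled node sets of the same size; Z = (obs - mean)/sd
    with a one-sided upper-tail normal p (enrichment, not depletion).
    Terms with a degenerate null (sd = 0) are nan-flagged.
    """
    universe = sorted(annotations)
    if not selected:
        raise ValueError("selected set is empty")
    if not selected <= set(universe):
        raise ValueError("selected nodes must be annotated")
    if B < 100:
        raise ValueError("need at least 100 resamples")
    k = len(selected)
    terms = sorted({t for ts in annotations.values() for t in ts})
    t_index = {t: i for i, t in enumerate(terms)}
    member = np.zeros((len(universe), len(terms)), dtype=np.int64)
    for i, nid in enumerate(universe):
        for t in annotations[nid]:
            member[i, t_index[t]] = 1
    sel_idx = [universe.index(s) for s in sorted(selected)]
    obs = member[sel_idx].sum(axis=0)
    rng = np.random.default_rng(seed)
    null = np.empty((B, len(terms)))
    for b in range(B):
        pick = rng.choice(len(universe), size=k, replace=False)
        null[b] = member[pick].sum(axis=0)
    mean, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    if k == len(universe):
        # resampling the whole universe is a trivial null: obs == mean
        z = np.where(sd == 0, 0.0, z)
    p = np.where(np.isnan(z), np.nan, sps.norm.sf(z))
    return pd.DataFrame(
        {"term": terms, "count": obs, "null_mean": mean, "null_sd": sd, "Z": z, "p": p}
    )
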