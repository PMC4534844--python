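"""Persistence classification, group t-tests with BH correction, onset
ordering of transcription vs methylation, and sample/DMR clustering.

A DMR is *persistent* when the stress-vs-control difference in its
per-sample weighted CNN level is significant, the recovery-vs-control
difference is also significant, and recovery does not differ from stress —
i.e. the stress-induced state survives removal of the stress.  *Transient*
DMRs are significant under stress but revert on recovery.  Significance is
a two-sided Welch t-test on per-sample corrected levels, with
Benjamini-Hochberg adjustment across DMRs within each group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "GroupComparison",
    "PersistenceCall",
    "OnsetSummary",
    "UntestableError",
    "group_ttest",
    "benjamini_hochberg",
    "compare_groups",
    "classify_persistence",
    "onset_summary",
    "cluster_samples",
]


class UntestableError(ValueError):
    """The t-test is undefined (too few replicates or zero variance)."""


@dataclass(frozen=True)
class GroupComparison:
    dmr_id: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_stat: float
    pvalue: float
    qvalue: float = float("nan")


@dataclass(frozen=True)
class PersistenceCall:
    dmr_id: str
    call: str  # persistent / transient / ambiguous
    q_stress_vs_control: float
    q_recovery_vs_control: float
    q_stress_vs_recovery: float
    alpha: float


@dataclass(frozen=True)
class OnsetSummary:
    timepoint: int
    frac_genes_de: float
    frac_dmrs_dm: float


def group_ttest(
    levels_a: Sequence[float], levels_b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-sample levels (Welch by default).

    NaN entries (missing coverage) are dropped.  Raises
    :class:`UntestableError` with fewer than two values per group or when
    both groups are constant (zero pooled variance).
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise UntestableError("need >= 2 non-missing values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            raise UntestableError("both groups constant and equal; test degenerate")
        # perfectly separated constant groups: infinite statistic
        return float(np.sign(a[0] - b[0]) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def compare_groups(
    level_matrix: pd.DataFrame,
    group_of: Mapping[str, str],
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Welch t-test per DMR between two sample groups, BH across DMRs.

    ``level_matrix`` is indexed by dmr_id with one column per sample.
    Untestable DMRs get NaN statistics and are excluded from the BH family.
    """
    cols_a = [c for c in level_matrix.columns if group_of.get(c) == group_a]
    cols_b = [c for c in level_matrix.columns if group_of.get(c) == group_b]
    rows = []
    for dmr_id, row in level_matrix.iterrows():
        try:
            t, p = group_ttest(row[cols_a].to_numpy(), row[cols_b].to_numpy(), equal_var)
        except UntestableError:
            t, p = float("nan"), float("nan")
        rows.append(
            {
                "dmr_id": dmr_id, "group_a": group_a, "group_b": group_b,
                "mean_a": float(np.nanmean(row[cols_a].to_numpy(dtype=float))),
                "mean_b": float(np.nanmean(row[cols_b].to_numpy(dtype=float))),
                "t_stat": t, "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = np.nan
    testable = out["pvalue"].notna()
    if testable.any():
        out.loc[testable, "qvalue"] = benjamini_hochberg(out.loc[testable, "pvalue"].to_numpy())
    return out


def classify_persistence(
    level_matrix: pd.DataFrame,
    group_of: Mapping[str, str],
    control: str = "plus_pi",
    stress: str = "minus_pi",
    recovery: str = "resupply",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[PersistenceCall]:
    """Persistence call per DMR from the three pairwise group comparisons.

    persistent: q(control, stress) < alpha and q(recovery, control) < alpha
    and q(stress, recovery) >= alpha; transient: first significant, second
    not; everything else (including untestable) ambiguous.
    """
    cs = compare_groups(level_matrix, group_of, control, stress, equal_var).set_index("dmr_id")
    rc = compare_groups(level_matrix, group_of, recovery, control, equal_var).set_index("dmr_id")
    sr = compare_groups(level_matrix, group_of, stress, recovery, equal_var).set_index("dmr_id")
    calls = []
    for dmr_id in level_matrix.index:
        q1 = float(cs.loc[dmr_id, "qvalue"])
        q2 = float(rc.loc[dmr_id, "qvalue"])
        q3 = float(sr.loc[dmr_id, "qvalue"])
        if np.isnan(q1) or q1 >= alpha:
            call = "ambiguous"
        elif not np.isnan(q2) and q2 < alpha:
            call = "persistent" if (np.isnan(q3) or q3 >= alpha) else "ambiguous"
        else:
            call = "transient"
        calls.append(PersistenceCall(str(dmr_id), call, q1, q2, q3, alpha))
    return calls


def onset_summary(
    dmr_level_matrices: Mapping[int, pd.DataFrame],
    group_of_per_tp: Mapping[int, Mapping[str, str]],
    de_tables: Mapping[int, pd.DataFrame],
    dmr_genes: Mapping[str, str],
    control: str = "plus_pi",
    stress: str = "minus_pi",
    alpha: float = 0.05,
) -> list[OnsetSummary]:
    """Per timepoint: fraction of DMR-associated genes differentially
    expressed and fraction of DMRs differentially methylated (vs control).

    ``de_tables`` maps timepoint -> frame with gene_id and qvalue columns;
    ``dmr_genes`` maps dmr_id -> nearest gene id.
    """
    tps = sorted(dmr_level_matrices)
    if sorted(de_tables) != tps:
        raise ValueError("methylation and expression timepoints do not match")
    out = []
    genes = sorted(set(dmr_genes.values()))
    for tp in tps:
        cmp_df = compare_groups(dmr_level_matrices[tp], group_of_per_tp[tp], control, stress)
        ok = cmp_df["qvalue"].notna()
        frac_dm = float((cmp_df.loc[ok, "qvalue"] < alpha).mean()) if ok.any() else float("nan")
        de = de_tables[tp].set_index("gene_id")
        qs = [float(de.loc[g, "qvalue"]) for g in genes if g in de.index]
        frac_de = float(np.mean([q < alpha for q in qs])) if qs else float("nan")
        out.append(OnsetSummary(tp, frac_de, frac_dm))
    return out


def cluster_samples(
    level_matrix: pd.DataFrame, axis: str = "samples"
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering on Euclidean distances.

    ``level_matrix`` is DMRs x samples; ``axis`` selects which side to
    cluster.  Rows with missing values are dropped before computing
    distances.  Returns the scipy linkage matrix and the labels in leaf
    order (ties broken deterministically by input order).
    """
    mat = level_matrix.dropna(axis=0, how="any")
    if axis == "samples":
        data = mat.to_numpy(dtype=float).T
        labels = [str(c) for c in mat.columns]
    elif axis == "dmrs":
        data = mat.to_numpy(dtype=float)
        labels = [str(i) for i in mat.index]
    else:
        raise ValueError("axis must be 'samples' or 'dmrs'")
    if data.shape[0] < 2:
        raise ValueError("need at least two observations to cluster")
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    return link, [labels[i] for i in order]


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = render(node.left), render(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return render(tree) + ";"
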