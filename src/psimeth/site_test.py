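"""Per-cytosine differential-methylation testing.

Each cytosine with read coverage in at least two samples yields an r x 2
contingency table (rows = samples, columns = methylated / unmethylated read
counts).  Heterogeneity of methylation across samples is measured with the
root-mean-square (RMS) deviation of observed cell frequencies from the
independence expectation, and calibrated by Monte-Carlo simulation from the
multinomial independence model with early stopping.  A p-value cutoff is then
chosen as the largest threshold that still satisfies the target false
discovery rate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "SiteTestResult",
    "FdrCalibration",
    "build_table",
    "rms_statistic",
    "permutation_pvalue",
    "exact_pvalue",
    "select_cutoff",
    "run_site_tests",
    "site_seed",
]

_PERM_CHUNK = 256


class SkipSite(Exception):
    """Raised when a site cannot support a test (insufficient coverage)."""


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 grid of (methylated, unmethylated) read counts, one row per sample.

    Rows carry their sample-group labels so that pooled direction and the
    optional 2 x 2 pooled-table mode can be derived without re-reading data.
    """

    counts: np.ndarray  # shape (r, 2), non-negative ints
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError(f"contingency table must be r x 2, got {c.shape}")
        if c.shape[0] < 2:
            raise ValueError("contingency table needs at least 2 rows")
        if (c < 0).any():
            raise ValueError("negative counts in contingency table")
        if c.sum() == 0:
            raise ValueError("contingency table has zero total reads")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SiteTestResult:
    """Permutation-test outcome for one cytosine."""

    chrom: str
    pos: int
    strand: str
    context: str
    stat: float
    pvalue: float
    n_perms_run: int
    n_exceedances: int
    stopped_early: bool
    direction: Literal["hyper", "hypo", "none"]


@dataclass(frozen=True)
class FdrCalibration:
    """Largest p-value cutoff meeting a target FDR, plus bookkeeping."""

    target_fdr: float
    pvalue_cutoff: float
    n_significant: int
    method: Literal["bh", "empirical_null"]


def build_table(
    mc_row: np.ndarray,
    total_row: np.ndarray,
    group_labels: Sequence[str],
) -> ContingencyTable:
    """Assemble the per-site r x 2 table, dropping zero-coverage samples.

    Raises :class:`SkipSite` when fewer than two samples are covered or when
    any group is entirely uncovered (the test would be undefined or
    directionless).
    """
    mc_row = np.asarray(mc_row)
    total_row = np.asarray(total_row)
    covered = total_row > 0
    labels = np.asarray(group_labels)
    if covered.sum() < 2:
        raise SkipSite("fewer than two covered samples")
    for g in np.unique(labels):
        if not covered[labels == g].any():
            raise SkipSite(f"group {g!r} has no coverage at this site")
    mc = mc_row[covered]
    tot = total_row[covered]
    counts = np.stack([mc, tot - mc], axis=1)
    return ContingencyTable(counts, tuple(labels[covered]))


def rms_statistic(table: ContingencyTable | np.ndarray) -> float:
    """Root-mean-square deviation of cell frequencies from independence.

    With f_ij = counts_ij / n and e_ij = (row_i * col_j) / n^2,
    returns sqrt(mean_ij (f_ij - e_ij)^2).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty table")
    f = counts / n
    e = np.outer(f.sum(axis=1), f.sum(axis=0))
    return float(np.sqrt(np.mean((f - e) ** 2)))


def _batch_rms(tables: np.ndarray) -> np.ndarray:
    """RMS statistic for a (B, r, 2) stack of tables, each with its own marginals."""
    n = tables.sum(axis=(1, 2), keepdims=True)
    f = tables / n
    e = f.sum(axis=2, keepdims=True) * f.sum(axis=1, keepdims=True)
    return np.sqrt(np.mean((f - e) ** 2, axis=(1, 2)))


def independence_probs(table: ContingencyTable) -> np.ndarray:
    """Cell probabilities of the fitted independence model (sum to 1)."""
    f = table.counts / table.n
    return np.outer(f.sum(axis=1), f.sum(axis=0))


def permutation_pvalue(
    table: ContingencyTable,
    max_perms: int = 10_000,
    stop_exceedances: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, int, int, bool]:
    """Monte-Carlo p-value of the RMS statistic under the independence model.

    Each simulated table draws ``n`` reads multinomially over the r x 2 cells
    with the independence probabilities estimated from the observed table; its
    statistic is computed from its own marginals.  Simulation stops once
    ``stop_exceedances`` simulated statistics reach the observed one, or after
    ``max_perms`` draws.  Returns ``(stat, pvalue, n_perms_run, n_exceedances,
    stopped_early)`` with ``pvalue = (exceedances + 1) / (perms_run + 1)``.
    """
    if max_perms < 1:
        raise ValueError("max_perms must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    observed = rms_statistic(table)
    probs = independence_probs(table).ravel()
    probs = probs / probs.sum()
    r = table.counts.shape[0]
    n = table.n
    # Numerical guard: a simulated table may tie the observed statistic exactly
    # (e.g. observed stat 0); >= must treat ties as exceedances.
    thresh = observed - 1e-12

    exceed = 0
    run = 0
    while run < max_perms:
        chunk = min(_PERM_CHUNK, max_perms - run)
        draws = rng.multinomial(n, probs, size=chunk).reshape(chunk, r, 2)
        stats = _batch_rms(draws)
        hits = stats >= thresh
        cum = exceed + np.cumsum(hits)
        reached = np.nonzero(cum >= stop_exceedances)[0]
        if reached.size:
            stop_at = int(reached[0])
            exceed = int(cum[stop_at])
            run += stop_at + 1
            pvalue = (exceed + 1) / (run + 1)
            return observed, pvalue, run, exceed, True
        exceed = int(cum[-1]) if chunk else exceed
        run += chunk
    pvalue = (exceed + 1) / (run + 1)
    return observed, pvalue, run, exceed, False


def exact_pvalue(table: ContingencyTable) -> float:
    """Exact tail probability P(stat >= observed) under the independence model.

    Enumerates every multinomial outcome of ``n`` reads over the r x 2 cells
    (feasible for small n; intended for tables with n <= ~12 and r = 2) and
    sums the probabilities of outcomes whose own-marginal RMS statistic
    reaches the observed one.  This is the n -> infinity limit of
    :func:`permutation_pvalue` without the +1/+1 pseudocount.
    """
    observed = rms_statistic(table)
    probs = independence_probs(table).ravel()
    probs = probs / probs.sum()
    n = table.n
    k = probs.size
    if n > 20 or k > 8:
        raise ValueError("exact enumeration is only supported for tiny tables")
    logp = np.log(np.where(probs > 0, probs, 1.0))
    zero = probs == 0

    total = 0.0
    shape = table.counts.shape

    def rec(cell: int, remaining: int, acc: list[int]) -> None:
        nonlocal total
        if cell == k - 1:
            cells = acc + [remaining]
            counts = np.asarray(cells)
            if (counts[zero] > 0).any():
                return
            stat = rms_statistic(counts.reshape(shape))
            if stat >= observed - 1e-12:
                lp = gammaln(n + 1) - gammaln(counts + 1).sum() + (counts * logp).sum()
                total += float(np.exp(lp))
            return
        for c in range(remaining + 1):
            rec(cell + 1, remaining - c, acc + [c])

    rec(0, n, [])
    return total


def _bh_cutoff(pvalues: np.ndarray, target_fdr: float) -> tuple[float, int]:
    """Largest p_(k) with p_(k) <= k*q/m (step-up); (0.0, 0) when none."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = p.size
    k = np.arange(1, m + 1)
    ok = np.nonzero(p <= k * target_fdr / m)[0]
    if ok.size == 0:
        return 0.0, 0
    cutoff = float(p[ok[-1]])
    return cutoff, int(np.sum(pvalues <= cutoff))


def _empirical_null_cutoff(
    pvalues: np.ndarray, null_p: np.ndarray, target_fdr: float
) -> tuple[float, int]:
    """Largest cutoff c with (fraction of null_p <= c) * m / #{p <= c} <= q.

    ``null_p`` holds p-values recomputed after random relabeling of the group
    assignment (possibly several relabelings concatenated); the fraction is
    the mean over those relabelings.
    """
    p = np.asarray(pvalues, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    m = p.size
    candidates = np.unique(p)[::-1]  # largest first
    for c in candidates:
        n_sig = int(np.sum(p <= c))
        est_fdr = np.mean(null_p <= c) * m / n_sig
        if est_fdr <= target_fdr:
            return float(c), n_sig
    return 0.0, 0


def select_cutoff(
    observed_p: Sequence[float],
    target_fdr: float,
    method: Literal["bh", "empirical_null"] = "bh",
    null_p: Sequence[float] | None = None,
) -> FdrCalibration:
    """Choose the largest p-value cutoff that still satisfies the target FDR."""
    p = np.asarray(observed_p, dtype=float)
    if p.size == 0:
        raise ValueError("observed_p is empty")
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must lie in (0, 1)")
    if method == "bh":
        cutoff, n_sig = _bh_cutoff(p, target_fdr)
    elif method == "empirical_null":
        if null_p is None:
            raise ValueError("empirical_null requires null_p")
        cutoff, n_sig = _empirical_null_cutoff(p, np.asarray(null_p), target_fdr)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return FdrCalibration(target_fdr, cutoff, n_sig, method)


def site_seed(master_seed: int, chrom: str, pos: int) -> np.random.SeedSequence:
    """Deterministic per-site seed so parallel/ordered runs agree bit-for-bit."""
    key = zlib.crc32(f"{chrom}:{pos}".encode())
    return np.random.SeedSequence([int(master_seed), key])


def _direction(
    mc_row: np.ndarray,
    total_row: np.ndarray,
    group_labels: np.ndarray,
    control: str,
    stress: str,
) -> Literal["hyper", "hypo", "none"]:
    """Sign of the pooled stress-minus-control weighted level at one site."""
    tc = total_row[group_labels == control].sum()
    ts = total_row[group_labels == stress].sum()
    if tc == 0 or ts == 0:
        return "none"
    lc = mc_row[group_labels == control].sum() / tc
    ls = mc_row[group_labels == stress].sum() / ts
    if ls > lc:
        return "hyper"
    if ls < lc:
        return "hypo"
    return "none"


def run_site_tests(
    sites: pd.DataFrame,
    mc: np.ndarray,
    total: np.ndarray,
    group_labels: Sequence[str],
    control: str,
    stress: str,
    max_perms: int = 10_000,
    stop_exceedances: int = 100,
    master_seed: int = 0,
    min_group_reads: int = 1,
    pool_groups: bool = False,
) -> pd.DataFrame:
    """Run the RMS permutation test at every testable site.

    Parameters
    ----------
    sites
        Frame with columns chrom, pos, strand, context (one row per site,
        aligned with the count matrices).
    mc, total
        (n_sites, n_samples) integer matrices of methylated / total reads.
    group_labels
        Per-sample group assignment; only samples labelled ``control`` or
        ``stress`` enter the table.
    min_group_reads
        Coverage floor: a site is skipped unless each group has at least this
        many pooled reads (default 1, i.e. no extra floor).
    pool_groups
        Collapse replicates into a 2 x 2 condition table instead of the
        default r x 2 sample table.

    Returns a frame with one row per *tested* site (untestable sites are
    dropped): chrom, pos, strand, context, stat, pvalue, perms_run,
    exceedances, stopped_early, direction.
    """
    labels = np.asarray(group_labels)
    keep = np.isin(labels, [control, stress])
    labels = labels[keep]
    mc = np.asarray(mc)[:, keep]
    total = np.asarray(total)[:, keep]

    rows = []
    for i in range(len(sites)):
        mc_row, tot_row = mc[i], total[i]
        for g in (control, stress):
            if tot_row[labels == g].sum() < min_group_reads:
                break
        else:
            try:
                tbl = build_table(mc_row, tot_row, labels)
            except SkipSite:
                continue
            if pool_groups:
                pooled = np.stack(
                    [tbl.counts[np.asarray(tbl.group_labels) == g].sum(axis=0)
                     for g in (control, stress)]
                )
                tbl = ContingencyTable(pooled, (control, stress))
            chrom = sites["chrom"].iat[i]
            pos = int(sites["pos"].iat[i])
            stat, pval, run, exceed, early = permutation_pvalue(
                tbl,
                max_perms=max_perms,
                stop_exceedances=stop_exceedances,
                seed=site_seed(master_seed, chrom, pos),
            )
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": sites["strand"].iat[i],
                    "context": sites["context"].iat[i],
                    "stat": stat,
                    "pvalue": pval,
                    "perms_run": run,
                    "exceedances": exceed,
                    "stopped_early": early,
                    "direction": _direction(mc_row, tot_row, labels, control, stress),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "context", "stat", "pvalue",
            "perms_run", "exceedances", "stopped_early", "direction",
        ],
    )
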