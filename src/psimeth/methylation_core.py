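"""Weighted methylation levels and spike-in non-conversion correction.

The methylation level of a scope (a region, a context, a whole sample) is
the *weighted* level: the fraction of all basecalls at cytosine reference
positions in that scope that read as cytosine, i.e. sum(mc) / sum(total) —
never a mean of per-site fractions.  Bisulfite non-conversion is estimated
from an unmethylated spike-in chromosome and subtracted from raw levels
(clamped at zero); the rescaling alternative (raw - e) / (1 - e) is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io_formats import CONTEXTS, MethylomeSet

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationLevel",
    "NonConversionRate",
    "ZeroCoverageError",
    "weighted_level",
    "estimate_nonconversion",
    "correct_level",
    "region_level_matrix",
    "sample_levels",
]

NC_SANITY_THRESHOLD = 0.05


class ZeroCoverageError(ValueError):
    """No basecalls in the requested scope; the level is undefined."""


@dataclass(frozen=True)
class MethylationLevel:
    raw_level: float
    corrected_level: float
    n_cytosines: int
    n_basecalls: int
    context_scope: str  # CG / CHG / CHH / CNN


@dataclass(frozen=True)
class NonConversionRate:
    rate: float
    n_basecalls: int
    source_chrom: str


def weighted_level(
    mc: Sequence[int] | np.ndarray, total: Sequence[int] | np.ndarray
) -> float:
    """Pooled-count methylation level sum(mc)/sum(total) over a scope."""
    mc = np.asarray(mc, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    n = int(total.sum())
    if n == 0:
        raise ZeroCoverageError("no basecalls in scope")
    return float(mc.sum() / n)


def estimate_nonconversion(spike: MethylomeSet, sample_id: str | None = None) -> NonConversionRate:
    """Non-conversion rate from the unmethylated spike-in chromosome.

    The frequency of cytosine basecalls at reference cytosine positions in
    the control genome, normalized by the total number of basecalls there.
    When ``sample_id`` is None, basecalls are pooled across all samples.
    """
    if spike.n_sites == 0:
        raise ZeroCoverageError("spike-in table is empty")
    chroms = spike.sites["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"spike-in records span several chromosomes: {sorted(chroms)}")
    if sample_id is None:
        mc, total = spike.mc, spike.total
    else:
        j = spike.sample_index(sample_id)
        mc, total = spike.mc[:, j], spike.total[:, j]
    n = int(np.asarray(total).sum())
    if n == 0:
        raise ZeroCoverageError("no spike-in coverage")
    rate = float(np.asarray(mc).sum() / n)
    if rate >= NC_SANITY_THRESHOLD:
        logger.warning(
            "non-conversion rate %.4f exceeds sanity threshold %.2f",
            rate, NC_SANITY_THRESHOLD,
        )
    return NonConversionRate(rate, n, str(chroms[0]))


def correct_level(
    raw: float,
    nc: NonConversionRate | float,
    method: Literal["subtract", "rescale"] = "subtract",
) -> float:
    """Correct a raw level for bisulfite non-conversion.

    Default is literal subtraction clamped at zero: max(0, raw - e).  The
    ``rescale`` variant (raw - e) / (1 - e) additionally accounts for the
    slight compression of the observable range; both are clamped to [0, 1].
    """
    e = nc.rate if isinstance(nc, NonConversionRate) else float(nc)
    if not 0.0 <= raw <= 1.0 or not 0.0 <= e <= 1.0:
        raise ValueError("raw level and non-conversion rate must lie in [0, 1]")
    if method == "subtract":
        return max(0.0, raw - e)
    if method == "rescale":
        if e >= 1.0:
            raise ValueError("cannot rescale with non-conversion rate 1")
        return min(1.0, max(0.0, (raw - e) / (1.0 - e)))
    raise ValueError(f"unknown correction method {method!r}")


def scope_level(
    ms: MethylomeSet,
    sample_index: int,
    scope: str = "CNN",
    nc_rate: float = 0.0,
    correction: Literal["subtract", "rescale"] = "subtract",
) -> MethylationLevel:
    """Weighted level of one sample over a context scope of ``ms``."""
    sub = ms.subset_context(scope)
    mc = sub.mc[:, sample_index]
    total = sub.total[:, sample_index]
    raw = weighted_level(mc, total)
    return MethylationLevel(
        raw_level=raw,
        corrected_level=correct_level(raw, nc_rate, correction),
        n_cytosines=int((total > 0).sum()),
        n_basecalls=int(total.sum()),
        context_scope=scope,
    )


def region_level_matrix(
    ms: MethylomeSet,
    chrom: str,
    start: int,
    end: int,
    scope: str = "CNN",
    nc_rates: Sequence[float] | None = None,
    correction: Literal["subtract", "rescale"] = "subtract",
) -> np.ndarray:
    """Per-sample corrected levels over a region; NaN marks missing coverage.

    Returns an array of length n_samples.  Samples without any basecall in
    the region are flagged NaN (excluded from group means downstream, never
    imputed).  An empty region yields an all-NaN vector with a warning.
    """
    sub = ms.subset_region(chrom, start, end).subset_context(scope)
    n_samples = len(ms.samples)
    if nc_rates is None:
        nc_rates = np.zeros(n_samples)
    nc_rates = np.asarray(nc_rates, dtype=float)
    out = np.full(n_samples, np.nan)
    if sub.n_sites == 0:
        logger.warning("region %s:%d-%d has no cytosines in scope %s", chrom, start, end, scope)
        return out
    totals = sub.total.sum(axis=0)
    mcs = sub.mc.sum(axis=0)
    covered = totals > 0
    raw = np.divide(mcs, totals, out=np.zeros(n_samples), where=covered)
    for j in np.nonzero(covered)[0]:
        out[j] = correct_level(float(raw[j]), float(nc_rates[j]), correction)
    return out


def sample_levels(
    ms: MethylomeSet,
    scope: str = "CNN",
    nc_rates: Sequence[float] | None = None,
    correction: Literal["subtract", "rescale"] = "subtract",
) -> np.ndarray:
    """Genome-wide corrected level per sample (NaN where no coverage)."""
    sub = ms.subset_context(scope)
    n_samples = len(ms.samples)
    if nc_rates is None:
        nc_rates = np.zeros(n_samples)
    totals = sub.total.sum(axis=0)
    mcs = sub.mc.sum(axis=0)
    out = np.full(n_samples, np.nan)
    for j in range(n_samples):
        if totals[j] > 0:
            out[j] = correct_level(float(mcs[j] / totals[j]), float(nc_rates[j]), correction)
    return out


def per_sample_nonconversion(ms: MethylomeSet) -> np.ndarray:
    """Non-conversion rate per sample from the spike-in chromosome.

    Samples with no spike-in coverage fall back to the pooled rate (with a
    warning) so that correction stays defined for every sample.
    """
    _, spike = ms.split_spike_in()
    pooled = estimate_nonconversion(spike).rate
    rates = np.full(len(ms.samples), pooled)
    for j, meta in enumerate(ms.samples):
        total = int(spike.total[:, j].sum())
        if total > 0:
            rates[j] = float(spike.mc[:, j].sum() / total)
        else:
            logger.warning(
                "sample %s has no spike-in coverage; using pooled rate %.4f",
                meta.sample_id, pooled,
            )
    return rates
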