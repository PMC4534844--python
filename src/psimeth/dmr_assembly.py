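"""Assemble differentially methylated regions from significant cytosines.

Significant sites are chained left-to-right into blocks when they lie on
the same chromosome, within 200 bases of the previous member, and change
methylation in the same direction.  Blocks with fewer than the minimum
number of member sites (8 for the rice profiles, 5 for Arabidopsis) are
discarded, and surviving blocks must pass a replicate-consistency rule
(e.g. >= 7 of 9 stressed samples clearly separated from the control group,
tolerating one swapped sample on each side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, MethylomeSet
from .methylation_core import per_sample_nonconversion, region_level_matrix
from .site_test import FdrCalibration, select_cutoff, run_site_tests

logger = logging.getLogger(__name__)

__all__ = ["Dmr", "ConsistencyRule", "DmrConfig", "merge_sites", "consistency_filter", "call_dmrs"]


@dataclass(frozen=True)
class ConsistencyRule:
    """Require k of n samples per group to sit on their own side of the midpoint."""

    k_required: int
    n_per_group: int

    def __post_init__(self) -> None:
        if not 1 <= self.k_required <= self.n_per_group:
            raise ValueError("need 1 <= k_required <= n_per_group")

    @property
    def tolerance(self) -> int:
        return self.n_per_group - self.k_required


@dataclass
class Dmr:
    dmr_id: str
    chrom: str
    start: int  # first member-site position (1-based)
    end: int  # last member-site position (1-based)
    n_sites: int
    direction: Literal["hyper", "hypo"]
    member_positions: tuple[int, ...] = ()
    sample_levels: np.ndarray | None = None  # per-sample corrected CNN levels
    context_levels: dict[str, dict[str, float]] | None = None  # context -> group -> level
    passed_min_sites: bool = True
    passed_consistency: bool | None = None
    consistency_reason: str = ""
    pvalue_cutoff: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DmrConfig:
    """Thresholds of one discovery run (profiles live in the pipeline layer)."""

    target_fdr: float = 0.01
    fdr_method: Literal["bh", "empirical_null"] = "bh"
    max_perms: int = 10_000
    stop_exceedances: int = 100
    max_gap: int = 200
    min_sites: int = 8
    k_required: int = 7
    consistency_margin: float = 0.0
    min_group_reads: int = 1
    pool_groups: bool = False
    correction: Literal["subtract", "rescale"] = "subtract"
    master_seed: int = 0


def merge_sites(
    sig_sites: pd.DataFrame,
    max_gap: int = 200,
    min_sites: int = 8,
) -> list[Dmr]:
    """Greedy left-to-right chaining of significant sites into blocks.

    ``sig_sites`` needs columns chrom, pos, direction; sites with direction
    ``none`` are excluded with a warning.  Every block is emitted;
    ``passed_min_sites`` marks whether it meets the minimum-site rule.
    """
    usable = sig_sites[sig_sites["direction"].isin(["hyper", "hypo"])]
    dropped = len(sig_sites) - len(usable)
    if dropped:
        logger.warning("%d significant sites without direction excluded from merging", dropped)
    usable = usable.sort_values(["chrom", "pos"], kind="mergesort")

    dmrs: list[Dmr] = []
    open_blocks: dict[str, dict] = {}  # direction -> block state on current chrom

    def close(block: dict) -> None:
        positions = tuple(block["positions"])
        dmrs.append(
            Dmr(
                dmr_id="",
                chrom=block["chrom"],
                start=positions[0],
                end=positions[-1],
                n_sites=len(positions),
                direction=block["direction"],
                member_positions=positions,
                passed_min_sites=len(positions) >= min_sites,
            )
        )

    current_chrom = None
    for row in usable.itertuples():
        if row.chrom != current_chrom:
            for b in open_blocks.values():
                close(b)
            open_blocks = {}
            current_chrom = row.chrom
        b = open_blocks.get(row.direction)
        if b is not None and row.pos - b["positions"][-1] <= max_gap:
            b["positions"].append(row.pos)
        else:
            if b is not None:
                close(b)
            open_blocks[row.direction] = {
                "chrom": row.chrom,
                "direction": row.direction,
                "positions": [row.pos],
            }
    for b in open_blocks.values():
        close(b)

    dmrs.sort(key=lambda d: (d.chrom, d.start, d.direction))
    for i, d in enumerate(dmrs, 1):
        d.dmr_id = f"DMR{i:04d}"
    return dmrs


def consistency_filter(
    dmr: Dmr,
    levels: np.ndarray,
    group_labels: Sequence[str],
    control: str,
    stress: str,
    rule: ConsistencyRule,
    margin: float = 0.0,
) -> tuple[bool, dict[str, np.ndarray], str]:
    """Replicate-consistency verdict for one DMR.

    The midpoint between the two group mean levels splits the level axis;
    a sample is *consistent* when its level lies strictly on its own
    group's side of the midpoint in the DMR's direction (optionally by at
    least ``margin``).  The DMR passes when each group has at least
    ``rule.k_required`` consistent samples.  Returns
    ``(passed, per-group verdict vectors, reason)``.
    """
    labels = np.asarray(group_labels)
    lv = np.asarray(levels, dtype=float)
    verdicts: dict[str, np.ndarray] = {}
    for g in (control, stress):
        vals = lv[labels == g]
        n_cov = int(np.isfinite(vals).sum())
        if n_cov < rule.k_required:
            verdicts[g] = np.zeros(len(vals), dtype=bool)
            return False, verdicts, "insufficient coverage"
    ctrl_vals = lv[labels == control]
    strs_vals = lv[labels == stress]
    mean_c = float(np.nanmean(ctrl_vals))
    mean_s = float(np.nanmean(strs_vals))
    mid = (mean_c + mean_s) / 2.0
    # "hyper" means stress above control; strict side-of-midpoint test, so
    # identical group means can never pass (nothing separates).
    sign = 1.0 if dmr.direction == "hyper" else -1.0
    ok_ctrl = sign * (mid - ctrl_vals) > margin
    ok_strs = sign * (strs_vals - mid) > margin
    ok_ctrl &= np.isfinite(ctrl_vals)
    ok_strs &= np.isfinite(strs_vals)
    verdicts[control] = ok_ctrl
    verdicts[stress] = ok_strs
    if ok_ctrl.sum() < rule.k_required or ok_strs.sum() < rule.k_required:
        return False, verdicts, (
            f"{int(ok_strs.sum())}/{len(strs_vals)} stress and "
            f"{int(ok_ctrl.sum())}/{len(ctrl_vals)} control samples consistent, "
            f"need {rule.k_required}"
        )
    return True, verdicts, ""


def _attach_levels(
    dmr: Dmr,
    ms: MethylomeSet,
    nc_rates: np.ndarray,
    group_labels: np.ndarray,
    control: str,
    stress: str,
    correction: str,
) -> None:
    dmr.sample_levels = region_level_matrix(
        ms, dmr.chrom, dmr.start, dmr.end, "CNN", nc_rates, correction
    )
    ctx_levels: dict[str, dict[str, float]] = {}
    region = ms.subset_region(dmr.chrom, dmr.start, dmr.end)
    for ctx in CONTEXTS + ("CNN",):
        sub = region.subset_context(ctx)
        grp: dict[str, float] = {}
        for g in (control, stress):
            cols = np.asarray(group_labels) == g
            total = int(sub.total[:, cols].sum())
            grp[g] = float(sub.mc[:, cols].sum() / total) if total else float("nan")
        ctx_levels[ctx] = grp
    dmr.context_levels = ctx_levels


def call_dmrs(
    ms: MethylomeSet,
    group_of: Mapping[str, str],
    control: str,
    stress: str,
    config: DmrConfig | None = None,
    null_p: Sequence[float] | None = None,
) -> tuple[list[Dmr], pd.DataFrame, FdrCalibration]:
    """Full discovery pipeline: test -> cutoff -> merge -> filters -> levels.

    Parameters
    ----------
    ms
        Methylome set including the spike-in chromosome (used for
        correction); tests run on the genome part in the pooled CNN scope.
    group_of
        sample_id -> group label; samples mapped to other labels are
        ignored by the test but still reported in level matrices.
    null_p
        Optional relabeled-null p-values for the ``empirical_null`` cutoff
        method.

    Returns ``(dmrs, site_results, calibration)``; DMRs failing a filter
    are retained with their flags set so the caller can audit them.
    """
    cfg = config or DmrConfig()
    if ms.n_sites == 0:
        raise ValueError("empty methylome set")
    labels = np.array([group_of.get(s.sample_id, "") for s in ms.samples])
    for g in (control, stress):
        if (labels == g).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {g!r}")

    if ms.spike_in_chrom is not None:
        genome, _ = ms.split_spike_in()
        nc_rates = per_sample_nonconversion(ms)
    else:
        genome = ms
        nc_rates = np.zeros(len(ms.samples))

    results = run_site_tests(
        genome.sites, genome.mc, genome.total, labels, control, stress,
        max_perms=cfg.max_perms, stop_exceedances=cfg.stop_exceedances,
        master_seed=cfg.master_seed, min_group_reads=cfg.min_group_reads,
        pool_groups=cfg.pool_groups,
    )
    if results.empty:
        return [], results, FdrCalibration(cfg.target_fdr, 0.0, 0, cfg.fdr_method)

    calibration = select_cutoff(
        results["pvalue"].to_numpy(), cfg.target_fdr, cfg.fdr_method, null_p
    )
    results = results.assign(significant=results["pvalue"] <= calibration.pvalue_cutoff)
    sig = results[results["significant"]]
    logger.info(
        "tested %d sites, cutoff %.3g (%s, FDR %.3g) -> %d significant",
        len(results), calibration.pvalue_cutoff, cfg.fdr_method,
        cfg.target_fdr, len(sig),
    )

    dmrs = merge_sites(sig, max_gap=cfg.max_gap, min_sites=cfg.min_sites)
    n_group = min(int((labels == control).sum()), int((labels == stress).sum()))
    rule = ConsistencyRule(min(cfg.k_required, n_group), n_group)
    kept: list[Dmr] = []
    for d in dmrs:
        d.pvalue_cutoff = calibration.pvalue_cutoff
        if not d.passed_min_sites:
            kept.append(d)
            continue
        _attach_levels(d, genome, nc_rates, labels, control, stress, cfg.correction)
        passed, _, reason = consistency_filter(
            d, d.sample_levels, labels, control, stress, rule, cfg.consistency_margin
        )
        d.passed_consistency = passed
        d.consistency_reason = reason
        kept.append(d)
    n_pass = sum(1 for d in kept if d.passed_min_sites and d.passed_consistency)
    logger.info("%d blocks merged, %d pass all filters", len(kept), n_pass)
    return kept, results, calibration


def dmrs_to_frame(dmrs: Sequence[Dmr], sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """BED-like summary table (start0 is 0-based for BED compatibility)."""
    rows = []
    for d in dmrs:
        row = {
            "chrom": d.chrom, "start0": d.start - 1, "end": d.end,
            "dmr_id": d.dmr_id, "direction": d.direction, "n_sites": d.n_sites,
            "passed_min_sites": d.passed_min_sites,
            "passed_consistency": d.passed_consistency,
        }
        if sample_ids is not None and d.sample_levels is not None:
            row.update({f"level_{s}": lv for s, lv in zip(sample_ids, d.sample_levels)})
        rows.append(row)
    return pd.DataFrame(rows)
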