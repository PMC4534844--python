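"""Reusable simulation experiments quantifying the pipeline's operating
characteristics: empirical FDR control of the site test, DMR recovery and
false-call behaviour, and persistence-classifier accuracy.

Each experiment regenerates its inputs from a seed, runs the relevant
pipeline stages, and returns plain numbers, so the analysis drivers, the
test suite and the reproduction script all share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmr_assembly import DmrConfig, call_dmrs
from .site_test import select_cutoff, run_site_tests
from .synthetic_data import (
    Implant,
    SimConfig,
    simulate_annotation,
    simulate_dmr_level_matrix,
    simulate_methylomes,
    simulate_site_mixture,
)
from .temporal_expression import classify_persistence

__all__ = [
    "fdp_experiment",
    "dmr_recovery_experiment",
    "null_dmr_experiment",
    "persistence_experiment",
]


@dataclass(frozen=True)
class FdpResult:
    fdps: list[float]
    n_significant: list[int]
    n_sites: int

    @property
    def mean_fdp(self) -> float:
        return float(np.mean(self.fdps))


def fdp_experiment(
    n_per_group: int,
    target_fdr: float,
    n_seeds: int = 20,
    base_seed: int = 0,
    n_sites: int = 2000,
    frac_diff: float = 0.10,
    p_null: float = 0.1,
    p_alt: float = 0.6,
    coverage_mean: float = 20.0,
    dispersion: float = 0.01,
    max_perms: int = 1000,
    stop_exceedances: int = 100,
) -> FdpResult:
    """Empirical false-discovery proportion of the site-test + cutoff
    procedure on the two-group site mixture, per seed.

    For each seed: simulate the mixture, run the RMS permutation test at
    every site, choose the largest p-value cutoff meeting ``target_fdr``
    (BH step-up), and measure the proportion of false discoveries among
    the significant sites (0 when nothing is significant).
    """
    fdps: list[float] = []
    n_sig: list[int] = []
    for i in range(n_seeds):
        seed = int(base_seed + i) % (2**31)
        sites, mc, total, truth, labels = simulate_site_mixture(
            n_sites=n_sites, n_per_group=n_per_group, frac_diff=frac_diff,
            p_null=p_null, p_alt=p_alt, coverage_mean=coverage_mean,
            dispersion=dispersion, seed=seed,
        )
        results = run_site_tests(
            sites, mc, total, labels, "control", "stress",
            max_perms=max_perms, stop_exceedances=stop_exceedances,
            master_seed=seed + 10_000,
        )
        cal = select_cutoff(results["pvalue"].to_numpy(), target_fdr, "bh")
        sig = results[results["pvalue"] <= cal.pvalue_cutoff]
        idx = sig["pos"].to_numpy() - 1  # mixture positions are 1..n_sites
        n_false = int((~truth[idx]).sum())
        fdps.append(n_false / len(sig) if len(sig) else 0.0)
        n_sig.append(len(sig))
    return FdpResult(fdps, n_sig, n_sites)


def _recovery_config(seed: int, delta: float, n_implants: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        implants=[Implant(delta=delta) for _ in range(n_implants)],
    )


def dmr_recovery_experiment(
    n_seeds: int = 3,
    base_seed: int = 0,
    delta: float = 0.3,
    n_implants: int = 8,
    max_perms: int = 10_000,
) -> dict:
    """Fraction of implanted loci recovered by the full discovery pipeline.

    An implant counts as recovered when a filter-passing DMR of the correct
    direction overlaps at least half of its span.  Also reports DMRs that
    match no implant (false calls).
    """
    n_truth = n_recovered = n_false = 0
    for i in range(n_seeds):
        seed = int(base_seed + i) % (2**31)
        cfg = _recovery_config(seed, delta, n_implants)
        genes, tes = simulate_annotation(cfg)
        ms, truth = simulate_methylomes(cfg, genes, tes)
        group_of = {m.sample_id: m.condition for m in ms.samples}
        dmrs, _, _ = call_dmrs(
            ms, group_of, "plus_pi", "minus_pi",
            DmrConfig(max_perms=max_perms, master_seed=seed),
        )
        passing = [d for d in dmrs if d.passed_min_sites and d.passed_consistency]
        matched = set()
        for k, tr in enumerate(truth):
            n_truth += 1
            span = tr.end - tr.start + 1
            for d in passing:
                ov = min(d.end, tr.end) - max(d.start, tr.start) + 1
                if d.chrom == tr.chrom and d.direction == tr.direction and ov >= 0.5 * span:
                    n_recovered += 1
                    matched.add(d.dmr_id)
                    break
        n_false += sum(1 for d in passing if d.dmr_id not in matched)
    return {
        "n_truth": n_truth,
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / n_truth if n_truth else float("nan"),
        "n_false_dmrs": n_false,
    }


def null_dmr_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    max_perms: int = 1000,
) -> dict:
    """Count of seeds on which implant-free data yields zero passing DMRs.

    Uses a reduced-size genome (the false-call mechanism — chained runs of
    same-direction significant sites — does not depend on total site
    count) to keep repeated seeds cheap.
    """
    zero_seeds = 0
    dmr_counts = []
    for i in range(n_seeds):
        seed = int(base_seed + i) % (2**31)
        cfg = SimConfig(
            seed=seed, implants=[],
            genome={"chr1": 120_000}, n_genes=12, n_tes=20,
            n_background_sites=600, sites_per_te=10, n_spike_sites=150,
        )
        genes, tes = simulate_annotation(cfg)
        ms, _ = simulate_methylomes(cfg, genes, tes)
        group_of = {m.sample_id: m.condition for m in ms.samples}
        dmrs, _, _ = call_dmrs(
            ms, group_of, "plus_pi", "minus_pi",
            DmrConfig(max_perms=max_perms, master_seed=seed),
        )
        n = sum(1 for d in dmrs if d.passed_min_sites and d.passed_consistency)
        dmr_counts.append(n)
        zero_seeds += n == 0
    return {
        "n_seeds": n_seeds,
        "zero_dmr_seeds": zero_seeds,
        "zero_fraction": zero_seeds / n_seeds,
        "dmr_counts": dmr_counts,
    }


def persistence_experiment(
    n_persistent: int = 30,
    n_transient: int = 30,
    n_null: int = 15,
    n_reps: int = 3,
    base_seed: int = 0,
) -> dict:
    """Accuracy of the persistence classifier on generator truth."""
    matrix, group_of, truth = simulate_dmr_level_matrix(
        n_persistent=n_persistent, n_transient=n_transient, n_null=n_null,
        n_reps=n_reps, seed=int(base_seed) % (2**31),
    )
    calls = classify_persistence(matrix, group_of)
    labelled = [(c.call, t) for c, t in zip(calls, truth) if t != "none"]
    n_correct = sum(1 for call, t in labelled if call == t)
    return {
        "n_labelled": len(labelled),
        "n_correct": n_correct,
        "accuracy": n_correct / len(labelled) if labelled else float("nan"),
        "calls": [c.call for c in calls],
        "truth": truth,
    }
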