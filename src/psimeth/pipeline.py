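"""Stage orchestration: levels -> site tests -> cutoff -> DMRs ->
annotation -> temporal, behind one run configuration with named profiles.

Profiles encode the published analysis variants: ``rice_root`` (FDR 0.01,
>= 8 sites, 7-of-9 consistency), ``rice_shoot`` and ``panicle`` (FDR 0.05,
3-of-3), ``arabidopsis`` (FDR 0.2, >= 5 sites, 2-of-3).  The panicle
profile relaxes the persistence alpha to 0.1.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dmr_annotation import annotate_dmrs, annotated_to_frame, te_class_summary
from .dmr_assembly import DmrConfig, call_dmrs, dmrs_to_frame
from .io_formats import (
    MethylomeSet,
    build_methylome_set,
    read_allc,
    read_de_table,
    read_features,
    read_sample_sheet,
)
from .methylation_core import per_sample_nonconversion, sample_levels
from .temporal_expression import classify_persistence, cluster_samples, linkage_to_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PROFILES", "load_config", "run_pipeline"]


@dataclass(frozen=True)
class Profile:
    target_fdr: float
    min_sites: int
    k_required: int
    n_per_group: int
    alpha_persistence: float = 0.05


PROFILES: dict[str, Profile] = {
    "rice_root": Profile(0.01, 8, 7, 9),
    "rice_shoot": Profile(0.05, 8, 3, 3),
    "panicle": Profile(0.05, 8, 3, 3, alpha_persistence=0.1),
    "arabidopsis": Profile(0.2, 5, 2, 3),
}


@dataclass
class RunConfig:
    profile: str = "rice_root"
    sample_sheet: str = ""
    genes: str = ""
    tes: str = ""
    de_table: str = ""
    spike_in_chrom: str = "lambda_spike"
    control: str = "plus_pi"
    stress: str = "minus_pi"
    recovery: str = "resupply"
    target_fdr: float | None = None
    min_sites: int | None = None
    k_required: int | None = None
    alpha_persistence: float | None = None
    max_perms: int = 10_000
    stop_exceedances: int = 100
    max_gap: int = 200
    fdr_method: str = "bh"
    master_seed: int = 0

    def resolved(self) -> "RunConfig":
        """Fill unset thresholds from the profile presets."""
        if self.profile not in PROFILES and self.profile != "custom":
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "custom":
            missing = [
                k for k in ("target_fdr", "min_sites", "k_required") if getattr(self, k) is None
            ]
            if missing:
                raise ValueError(f"custom profile needs explicit {missing}")
            return replace(self, alpha_persistence=self.alpha_persistence or 0.05)
        p = PROFILES[self.profile]
        return replace(
            self,
            target_fdr=self.target_fdr if self.target_fdr is not None else p.target_fdr,
            min_sites=self.min_sites if self.min_sites is not None else p.min_sites,
            k_required=self.k_required if self.k_required is not None else p.k_required,
            alpha_persistence=(
                self.alpha_persistence
                if self.alpha_persistence is not None
                else p.alpha_persistence
            ),
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def load_methylomes(cfg: RunConfig) -> MethylomeSet:
    metas, allc_paths = read_sample_sheet(cfg.sample_sheet)
    sheet_dir = Path(cfg.sample_sheet).parent
    tables = {}
    for m in metas:
        p = allc_paths.get(m.sample_id)
        if p and not Path(p).is_absolute():
            p = str(sheet_dir / p)  # sheet-relative paths keep datasets relocatable
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"allc table for sample {m.sample_id} not found: {p}")
        tables[m.sample_id] = read_allc(p)
    return build_methylome_set(tables, metas, cfg.spike_in_chrom)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage, writing TSV outputs plus a JSON summary.

    Reruns with the same inputs and master_seed are byte-identical; every
    output name carries no state, the summary carries the config hash.
    """
    cfg = cfg.resolved()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "profile": cfg.profile,
                     "version": __version__}
    try:
        ms = load_methylomes(cfg)
        summary["n_sites"] = ms.n_sites
        summary["n_samples"] = len(ms.samples)
        logger.info("stage load: %d sites x %d samples", ms.n_sites, len(ms.samples))

        # stage: genome-wide levels
        nc = per_sample_nonconversion(ms)
        genome, _ = ms.split_spike_in()
        level_rows = []
        for scope in ("CG", "CHG", "CHH", "CNN"):
            lv = sample_levels(genome, scope, nc)
            for meta, v, e in zip(ms.samples, lv, nc):
                level_rows.append(
                    {"sample_id": meta.sample_id, "context": scope,
                     "corrected_level": v, "nonconversion_rate": e}
                )
        pd.DataFrame(level_rows).to_csv(outdir / "sample_levels.tsv", sep="\t", index=False)
        logger.info("stage levels: %d rows", len(level_rows))

        group_of = {m.sample_id: m.condition for m in ms.samples}
        dmr_cfg = DmrConfig(
            target_fdr=cfg.target_fdr, fdr_method=cfg.fdr_method,  # type: ignore[arg-type]
            max_perms=cfg.max_perms, stop_exceedances=cfg.stop_exceedances,
            max_gap=cfg.max_gap, min_sites=cfg.min_sites, k_required=cfg.k_required,
            master_seed=cfg.master_seed,
        )
        dmrs, site_results, calibration = call_dmrs(
            ms, group_of, cfg.control, cfg.stress, dmr_cfg
        )
        site_results.to_csv(outdir / "site_tests.tsv", sep="\t", index=False)
        passing = [d for d in dmrs if d.passed_min_sites and d.passed_consistency]
        dmrs_to_frame(dmrs, ms.sample_ids).to_csv(outdir / "dmrs_all.tsv", sep="\t", index=False)
        dmrs_to_frame(passing, ms.sample_ids).to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        summary.update(
            n_sites_tested=len(site_results),
            pvalue_cutoff=calibration.pvalue_cutoff,
            n_significant_sites=int(calibration.n_significant),
            n_blocks=len(dmrs),
            n_dmrs=len(passing),
        )
        logger.info(
            "stage dmr: %d tested / %d significant / %d blocks / %d pass",
            len(site_results), calibration.n_significant, len(dmrs), len(passing),
        )

        # stage: annotation
        if cfg.genes:
            genes = read_features(cfg.genes, "gene")
            tes = read_features(cfg.tes, "te") if cfg.tes else []
            de = read_de_table(cfg.de_table) if cfg.de_table else None
            annotated = annotate_dmrs(passing, genes, tes, de)
            annotated_to_frame(annotated).to_csv(
                outdir / "dmrs_annotated.tsv", sep="\t", index=False
            )
            te_class_summary(annotated).to_csv(
                outdir / "te_class_summary.tsv", sep="\t", index=False
            )
            summary["n_te_overlapping"] = sum(1 for a in annotated if a.overlaps_te)
            logger.info("stage annotate: %d DMRs annotated", len(annotated))

        # stage: temporal (needs a recovery group)
        conditions = {m.condition for m in ms.samples}
        if cfg.recovery in conditions and passing:
            matrix = pd.DataFrame(
                {d.dmr_id: d.sample_levels for d in passing}, index=ms.sample_ids
            ).T
            calls = classify_persistence(
                matrix, group_of, cfg.control, cfg.stress, cfg.recovery,
                alpha=cfg.alpha_persistence,
            )
            pd.DataFrame([c.__dict__ for c in calls]).to_csv(
                outdir / "persistence_calls.tsv", sep="\t", index=False
            )
            summary["n_persistent"] = sum(1 for c in calls if c.call == "persistent")
            logger.info("stage temporal: %d persistent", summary["n_persistent"])
        if passing and len(ms.samples) >= 2:
            matrix = pd.DataFrame(
                {d.dmr_id: d.sample_levels for d in passing}, index=ms.sample_ids
            ).T
            try:
                link, leaves = cluster_samples(matrix)
                (outdir / "sample_dendrogram.nwk").write_text(
                    linkage_to_newick(link, [str(c) for c in matrix.columns]) + "\n"
                )
                summary["leaf_order"] = leaves
            except ValueError:
                pass
    except Exception:
        (outdir / "run.failed").write_text("pipeline failed; partial outputs retained\n")
        raise
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
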