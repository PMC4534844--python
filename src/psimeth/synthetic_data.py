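"""Synthetic inputs emulating a phosphate-starvation methylome study.

The generator produces everything the pipeline consumes — a small
two-chromosome genome annotation, per-sample allc count tables with an
unmethylated spike-in chromosome, a matched differential-expression table,
a sample sheet — plus a machine-readable truth table of the implanted
differentially methylated loci, so that every stage can be tested against
known ground truth without any external download.

Design emulated by default: rice roots, 9 phosphate-sufficient (+Pi) vs 9
phosphate-starved (-Pi) replicates spread over three late timepoints
(21/22/24 days, 3 replicates each), CHH-dominant hypermethylation
implanted at TE-overlapping loci near induced genes, and a 0.5%
non-conversion rate observed on the spike-in control.

Two noise regimes are exposed, matching their two uses:

* ``simulate_methylomes`` draws a beta-distributed methylation proportion
  independently per sample and site (replicate-level biological noise, the
  regime the replicate-consistency filter is designed for).
* ``simulate_site_mixture`` draws the beta-dispersed proportion once per
  site (and per group for truly differential sites), shared by all of that
  group's samples: within a site the samples then share a common
  proportion, the regime in which the multinomial permutation null is
  exact.  This is the generator behind the FDR-calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    ALLC_COLUMNS,
    DeRecord,
    GeneFeature,
    MethylomeSet,
    SampleMeta,
    TeFeature,
    write_allc,
    write_de_table,
    write_features_bed,
    write_features_gff3,
    write_sample_sheet,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_annotation",
    "simulate_methylomes",
    "simulate_de_table",
    "simulate_site_mixture",
    "simulate_dmr_level_matrix",
    "default_root_design",
    "persistence_design",
    "write_dataset",
]

TE_CLASS_MIX_DEFAULT = {"MITE": 0.55, "LTR/Gypsy": 0.2, "LTR/Copia": 0.15, "LINE": 0.1}

# Rice-like baselines: TE bodies carry dense CG/CHG methylation with low
# CHH; background cytosines are mostly unmethylated.
BASELINE_LEVELS_DEFAULT = {
    ("CG", True): 0.80, ("CHG", True): 0.50, ("CHH", True): 0.08,
    ("CG", False): 0.30, ("CHG", False): 0.10, ("CHH", False): 0.02,
}


@dataclass(frozen=True)
class Implant:
    """One ground-truth differential locus to inject."""

    context: str = "CHH"
    delta: float = 0.5
    n_sites: int = 12
    direction: Literal["hyper", "hypo"] = "hyper"
    persistence_class: Literal["persistent", "transient", "none"] = "none"


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    start: int
    end: int
    direction: str
    delta: float
    context: str
    persistence_class: str
    nearest_gene: str
    te_overlap: bool
    te_id: str


@dataclass
class SimConfig:
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 300_000, "chr2": 200_000})
    spike_in_chrom: str = "lambda_spike"
    n_spike_sites: int = 300
    n_genes: int = 40
    n_tes: int = 60
    te_class_mix: dict[str, float] = field(default_factory=lambda: dict(TE_CLASS_MIX_DEFAULT))
    te_near_gene_frac: float = 0.6  # fraction of TEs placed within reach of a gene
    te_near_gene_dist: int = 2000
    gene_len: tuple[int, int] = (1500, 4000)
    te_len: tuple[int, int] = (300, 1200)
    baseline_levels: dict[tuple[str, bool], float] = field(
        default_factory=lambda: dict(BASELINE_LEVELS_DEFAULT)
    )
    n_background_sites: int = 1500
    sites_per_te: int = 16
    coverage_mean: float = 20.0
    dispersion: float = 0.01  # beta-binomial intra-class correlation
    nc_rate: float = 0.005
    implants: list[Implant] = field(default_factory=lambda: [Implant() for _ in range(8)])
    samples: list[SampleMeta] = field(default_factory=lambda: default_root_design())
    de_prob: float = 0.9  # chance an implant's nearest gene is induced
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nc_rate <= 1 or not 0 <= self.dispersion < 1:
            raise ValueError("rates must be proportions")
        if abs(sum(self.te_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("te_class_mix must sum to 1")
        for lv in self.baseline_levels.values():
            if not 0 <= lv <= 1:
                raise ValueError("baseline levels must lie in [0,1]")


def default_root_design() -> list[SampleMeta]:
    """9 +Pi vs 9 -Pi root replicates over 21/22/24-day timepoints."""
    metas = []
    for cond in ("plus_pi", "minus_pi"):
        rep = 0
        for tp in (21, 22, 24):
            for _ in range(3):
                rep += 1
                metas.append(SampleMeta(f"root_{cond}_{tp}d_r{rep}", cond, "root", tp, rep))
    return metas


def persistence_design(n_reps: int = 3, tissue: str = "root", timepoint: int = 52) -> list[SampleMeta]:
    """Triplicate control / stress / resupply groups at one late timepoint."""
    metas = []
    for cond in ("plus_pi", "minus_pi", "resupply"):
        for r in range(1, n_reps + 1):
            metas.append(SampleMeta(f"{tissue}_{cond}_{timepoint}d_r{r}", cond, tissue, timepoint, r))
    return metas


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimConfig) -> tuple[list[GeneFeature], list[TeFeature]]:
    """Non-overlapping genes plus TEs biased to lie near a subset of genes."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    chroms = sorted(cfg.genome)
    sizes = np.array([cfg.genome[c] for c in chroms], dtype=float)
    genes: list[GeneFeature] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(length: int, chrom: str | None = None, near: tuple[str, int] | None = None,
              max_dist: int = 0, allow_overlap: bool = False) -> tuple[str, int] | None:
        for _ in range(200):
            if near is not None:
                c, anchor = near
                lo = max(1, anchor - max_dist - length)
                hi = min(cfg.genome[c] - length, anchor + max_dist)
                if hi <= lo:
                    return None
                start = int(rng.integers(lo, hi + 1))
            else:
                c = chrom or chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
                if cfg.genome[c] <= length + 2:
                    continue
                start = int(rng.integers(1, cfg.genome[c] - length))
            if allow_overlap or all(
                start + length < s or start > e for s, e in occupied[c]
            ):
                return c, start
        return None

    for i in range(cfg.n_genes):
        length = int(rng.integers(*cfg.gene_len))
        spot = place(length)
        if spot is None:
            continue
        c, start = spot
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneFeature(c, start, start + length - 1, strand, f"gene{i + 1:03d}"))
        occupied[c].append((start, start + length - 1))

    te_classes = sorted(cfg.te_class_mix)
    te_probs = np.array([cfg.te_class_mix[c] for c in te_classes])
    tes: list[TeFeature] = []
    for i in range(cfg.n_tes):
        length = int(rng.integers(*cfg.te_len))
        if genes and rng.random() < cfg.te_near_gene_frac:
            g = genes[int(rng.integers(len(genes)))]
            anchor = g.start if g.strand == "+" else g.end
            spot = place(length, near=(g.chrom, anchor), max_dist=cfg.te_near_gene_dist)
        else:
            spot = place(length)
        if spot is None:
            spot = place(length)
        if spot is None:
            continue
        c, start = spot
        cls = te_classes[int(rng.choice(len(te_classes), p=te_probs))]
        strand = "+" if rng.random() < 0.5 else "-"
        tes.append(TeFeature(c, start, start + length - 1, strand, f"TE{i + 1:03d}", cls))
        occupied[c].append((start, start + length - 1))

    genes.sort(key=lambda f: (f.chrom, f.start))
    tes.sort(key=lambda f: (f.chrom, f.start))
    return genes, tes


# ---------------------------------------------------------------------------
# methylomes


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, rho: float) -> np.ndarray:
    """Beta draw with given mean and intra-class correlation rho (0 -> mean)."""
    mean = np.clip(mean, 1e-9, 1 - 1e-9)
    if rho <= 0:
        return mean
    a = mean * (1 - rho) / rho
    b = (1 - mean) * (1 - rho) / rho
    return rng.beta(a, b)


def _nearest_gene_id(chrom: str, start: int, end: int, genes: Sequence[GeneFeature]) -> str:
    best, best_d = "", None
    for g in genes:
        if g.chrom != chrom:
            continue
        if end >= g.start and start <= g.end:
            d = 0
        else:
            d = g.start - end if end < g.start else start - g.end
        if best_d is None or d < best_d or (d == best_d and g.id < best):
            best, best_d = g.id, d
    return best


def simulate_methylomes(
    cfg: SimConfig,
    genes: Sequence[GeneFeature],
    tes: Sequence[TeFeature],
) -> tuple[MethylomeSet, list[TruthRecord]]:
    """Per-sample cytosine counts with implanted DMRs and spike-in control.

    Per site and sample the true methylation proportion is the
    context/feature baseline, shifted by the implant delta for stressed
    (and, for persistent implants, resupplied) samples; totals are
    Poisson(coverage_mean), methylated counts beta-binomial with the
    configured dispersion, and bisulfite non-conversion raises the
    observed proportion to level + (1 - level) * nc_rate.  The spike-in
    chromosome has true level 0 everywhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    contexts = np.array(["CG", "CHG", "CHH"])
    chrom_l, pos_l, strand_l, ctx_l, base_l = [], [], [], [], []
    implant_site_idx: dict[int, list[int]] = {}

    # implant loci: TE-overlapping CHH runs near genes, non-overlapping
    near_tes = [
        t for t in tes
        if any(
            g.chrom == t.chrom
            and not (t.end < g.start - cfg.te_near_gene_dist or t.start > g.end + cfg.te_near_gene_dist)
            for g in genes
        )
    ]
    if len(near_tes) < len(cfg.implants):
        near_tes = list(tes)
    if len(near_tes) < len(cfg.implants):
        raise ValueError("not enough TEs to host the requested implants")
    chosen = [near_tes[int(i)] for i in rng.choice(len(near_tes), len(cfg.implants), replace=False)]

    truth: list[TruthRecord] = []
    for k, (imp, te) in enumerate(zip(cfg.implants, chosen)):
        spacing = max(8, (te.end - te.start) // (imp.n_sites + 1))
        spacing = min(spacing, 190)  # keep members chainable under the 200-bp rule
        start = te.start + 2
        positions = [start + j * spacing for j in range(imp.n_sites)]
        positions = [min(p, cfg.genome[te.chrom]) for p in positions]
        idxs = []
        for p in positions:
            idxs.append(len(pos_l))
            chrom_l.append(te.chrom)
            pos_l.append(p)
            strand_l.append("+" if rng.random() < 0.5 else "-")
            ctx_l.append(imp.context)
            base_l.append(cfg.baseline_levels[(imp.context, True)])
        implant_site_idx[k] = idxs
        truth.append(
            TruthRecord(
                te.chrom, positions[0], positions[-1], imp.direction, imp.delta,
                imp.context, imp.persistence_class,
                _nearest_gene_id(te.chrom, positions[0], positions[-1], genes),
                True, te.id,
            )
        )

    # remaining TE body sites
    implant_te_ids = {t.id for t in chosen}
    for te in tes:
        if te.id in implant_te_ids:
            continue
        n = min(cfg.sites_per_te, te.end - te.start)
        if n <= 0:
            continue
        offs = np.sort(rng.choice(te.end - te.start + 1, n, replace=False))
        ctx_idx = rng.choice(3, n, p=[0.25, 0.3, 0.45])
        for o, ci in zip(offs, ctx_idx):
            chrom_l.append(te.chrom)
            pos_l.append(te.start + int(o))
            strand_l.append("+" if rng.random() < 0.5 else "-")
            ctx = contexts[ci]
            ctx_l.append(ctx)
            base_l.append(cfg.baseline_levels[(ctx, True)])

    # background sites
    chroms = sorted(cfg.genome)
    sizes = np.array([cfg.genome[c] for c in chroms], dtype=float)
    counts = rng.multinomial(cfg.n_background_sites, sizes / sizes.sum())
    for c, n in zip(chroms, counts):
        pos = np.sort(rng.choice(cfg.genome[c], n, replace=False)) + 1
        ctx_idx = rng.choice(3, n, p=[0.3, 0.25, 0.45])
        for p, ci in zip(pos, ctx_idx):
            chrom_l.append(c)
            pos_l.append(int(p))
            strand_l.append("+" if rng.random() < 0.5 else "-")
            ctx = contexts[ci]
            ctx_l.append(ctx)
            base_l.append(cfg.baseline_levels[(ctx, False)])

    # spike-in chromosome, true level 0
    spike_pos = np.arange(1, cfg.n_spike_sites + 1) * 30
    for p in spike_pos:
        chrom_l.append(cfg.spike_in_chrom)
        pos_l.append(int(p))
        strand_l.append("+")
        ctx_l.append("CHH")
        base_l.append(0.0)

    sites = pd.DataFrame(
        {"chrom": chrom_l, "pos": pos_l, "strand": strand_l, "context": ctx_l}
    )
    base = np.asarray(base_l)
    order = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort").index.to_numpy()
    # de-duplicate coincidental position collisions
    sites_sorted = sites.loc[order].reset_index(drop=True)
    keep = ~sites_sorted.duplicated(subset=["chrom", "pos", "strand"]).to_numpy()
    inv = order[keep]
    sites_final = sites_sorted.loc[keep].reset_index(drop=True)
    base = base[inv]
    pos_of = {int(i): j for j, i in enumerate(inv)}

    n_sites = len(sites_final)
    n_samples = len(cfg.samples)
    true_level = np.tile(base[:, None], (1, n_samples))
    for k, imp in enumerate(cfg.implants):
        affected = [
            j for j, s in enumerate(cfg.samples)
            if s.condition == "minus_pi"
            or (s.condition == "resupply" and imp.persistence_class == "persistent")
        ]
        delta = imp.delta if imp.direction == "hyper" else -imp.delta
        for i in implant_site_idx[k]:
            if i in pos_of:
                r = pos_of[i]
                true_level[r, affected] = np.clip(true_level[r, affected] + delta, 0.0, 1.0)

    total = rng.poisson(cfg.coverage_mean, (n_sites, n_samples)).astype(np.int64)
    observed = true_level + (1.0 - true_level) * cfg.nc_rate
    p_draw = _beta_draw(rng, observed, cfg.dispersion)
    mc = rng.binomial(total, p_draw).astype(np.int64)

    ms = MethylomeSet(sites_final, mc, total, list(cfg.samples), cfg.spike_in_chrom)
    return ms, truth


# ---------------------------------------------------------------------------
# expression


def simulate_de_table(
    cfg: SimConfig,
    genes: Sequence[GeneFeature],
    truth: Sequence[TruthRecord],
) -> list[DeRecord]:
    """DE table in which hyper-implant nearest genes are induced with
    probability ``cfg.de_prob`` and all other genes behave as nulls."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    induced = {
        t.nearest_gene for t in truth
        if t.direction == "hyper" and t.nearest_gene and rng.random() < cfg.de_prob
    }
    records = []
    for g in genes:
        if g.id in induced:
            log2fc = float(rng.normal(2.6, 0.4))
            q = float(10.0 ** -rng.uniform(2.5, 6.0))
            base_expr = float(rng.lognormal(2.0, 0.5))
            records.append(DeRecord(g.id, log2fc, q, base_expr, base_expr * 2 ** log2fc))
        else:
            log2fc = float(rng.normal(0.0, 0.3))
            q = float(rng.uniform(0.05, 1.0))
            base_expr = float(rng.lognormal(2.0, 0.5))
            records.append(DeRecord(g.id, log2fc, q, base_expr, base_expr * 2 ** log2fc))
    return records


# ---------------------------------------------------------------------------
# focused generators for calibration / classifier experiments


def simulate_site_mixture(
    n_sites: int = 2000,
    n_per_group: int = 9,
    frac_diff: float = 0.10,
    p_null: float = 0.1,
    p_alt: float = 0.6,
    coverage_mean: float = 20.0,
    dispersion: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Two-group site mixture for FDR-calibration experiments.

    A fraction ``frac_diff`` of sites carries a true group difference
    (control mean ``p_null`` vs stress mean ``p_alt``); the remaining
    sites share one common proportion across all samples.  The
    beta-dispersed proportion is drawn once per site-and-group and shared
    by that group's samples, so null sites are exchangeable and the
    permutation test's null model holds exactly.

    Returns ``(sites, mc, total, truth_mask, group_labels)``.
    """
    rng = np.random.default_rng(seed)
    n_samp = 2 * n_per_group
    n_diff = int(round(frac_diff * n_sites))
    truth = np.zeros(n_sites, dtype=bool)
    truth[:n_diff] = True
    mean = np.full((n_sites, 2), p_null)
    mean[:n_diff, 1] = p_alt
    pg = _beta_draw(rng, mean, dispersion)
    pg[n_diff:, 1] = pg[n_diff:, 0]  # null sites: one shared common proportion
    p = np.repeat(pg, n_per_group, axis=1)
    total = rng.poisson(coverage_mean, (n_sites, n_samp)).astype(np.int64)
    mc = rng.binomial(total, p).astype(np.int64)
    sites = pd.DataFrame(
        {
            "chrom": "chrSim",
            "pos": np.arange(1, n_sites + 1, dtype=np.int64),
            "strand": "+",
            "context": "CHH",
        }
    )
    labels = ["control"] * n_per_group + ["stress"] * n_per_group
    return sites, mc, total, truth, labels


def simulate_dmr_level_matrix(
    n_persistent: int = 20,
    n_transient: int = 20,
    n_null: int = 10,
    n_reps: int = 3,
    base_level: float = 0.1,
    stress_level: float = 0.5,
    n_sites: int = 12,
    coverage_mean: float = 20.0,
    dispersion: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Per-DMR per-sample weighted levels for persistence-classifier tests.

    Each DMR pools ``n_sites`` cytosines at ``coverage_mean`` reads per
    site; per-sample beta noise (intra-class correlation ``dispersion``)
    sits on top of the group mean.  Persistent DMRs keep the stress level
    through recovery; transient DMRs revert to the control level.

    Returns ``(level_matrix, group_of, truth_calls)`` with the matrix
    indexed by dmr_id and one column per sample.
    """
    rng = np.random.default_rng(seed)
    groups = ["plus_pi", "minus_pi", "resupply"]
    sample_ids = [f"{g}_r{r}" for g in groups for r in range(1, n_reps + 1)]
    group_of = {s: g for s, g in zip(sample_ids, np.repeat(groups, n_reps))}
    classes = ["persistent"] * n_persistent + ["transient"] * n_transient + ["none"] * n_null
    n_basecalls = int(n_sites * coverage_mean)
    rows = []
    for cls in classes:
        means = {
            "plus_pi": base_level,
            "minus_pi": stress_level,
            "resupply": stress_level if cls == "persistent" else base_level,
        }
        level_row = []
        for s in sample_ids:
            p = _beta_draw(rng, np.asarray(means[group_of[s]]), dispersion)
            level_row.append(rng.binomial(n_basecalls, float(p)) / n_basecalls)
        rows.append(level_row)
    ids = [f"sim_dmr{i + 1:03d}" for i in range(len(classes))]
    matrix = pd.DataFrame(rows, index=ids, columns=sample_ids)
    return matrix, group_of, classes


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize a full synthetic dataset in the exact on-disk formats
    the readers consume.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, tes = simulate_annotation(cfg)
    ms, truth = simulate_methylomes(cfg, genes, tes)
    de = simulate_de_table(cfg, genes, truth)

    paths: dict[str, Path] = {}
    allc_dir = outdir / "allc"
    allc_dir.mkdir(exist_ok=True)
    allc_paths = {}
    for j, meta in enumerate(ms.samples):
        df = ms.sites.copy()
        df["mc_reads"] = ms.mc[:, j]
        df["total_reads"] = ms.total[:, j]
        df = df[df["total_reads"] > 0][ALLC_COLUMNS]
        p = allc_dir / f"{meta.sample_id}.allc.tsv"
        write_allc(df, p)
        # relative to the dataset root so the tree is relocatable
        allc_paths[meta.sample_id] = p.relative_to(outdir).as_posix()
    paths["allc_dir"] = allc_dir

    paths["genes"] = outdir / "genes.gff3"
    write_features_gff3(genes, paths["genes"])
    paths["tes"] = outdir / "tes.bed"
    write_features_bed(tes, paths["tes"])
    paths["de"] = outdir / "expression_de.tsv"
    write_de_table(de, paths["de"])
    paths["sample_sheet"] = outdir / "samples.tsv"
    write_sample_sheet(ms.samples, paths["sample_sheet"], allc_paths)

    paths["truth"] = outdir / "truth.tsv"
    pd.DataFrame([t.__dict__ for t in truth]).to_csv(paths["truth"], sep="\t", index=False)

    paths["config"] = outdir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "genome": cfg.genome,
                "spike_in_chrom": cfg.spike_in_chrom,
                "coverage_mean": cfg.coverage_mean,
                "dispersion": cfg.dispersion,
                "nc_rate": cfg.nc_rate,
                "seed": cfg.seed,
                "n_implants": len(cfg.implants),
            },
            fh,
        )
    return paths
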