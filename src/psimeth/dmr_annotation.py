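"""Annotate DMRs: nearest genes, distance bins, TE overlap, expression class.

Distances are strand-aware and measured to the gene span (TSS to TES):
zero inside the gene body, negative upstream of the TSS, positive
downstream of the TES.  Distance bins follow the scheme gene_body, 0-1 kb,
1-2 kb, 2-4 kb, 4-6 kb, > 6 kb.  The genome-wide bin normalization tiles
the genome into fixed-size windows, classifies each tile midpoint by the
same nearest-gene rule, and divides per-bin DMR counts by per-bin tile
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .dmr_assembly import Dmr
from .io_formats import DeRecord, GeneFeature, TeFeature

logger = logging.getLogger(__name__)

DISTANCE_BINS = ("gene_body", "0-1kb", "1-2kb", "2-4kb", "4-6kb", ">6kb")
EXPRESSION_CLASSES = ("up>4", "up2-4", "down>2", "ns", "absent")

__all__ = [
    "AnnotatedDmr",
    "BinNormalization",
    "assign_nearest_gene",
    "distance_bin",
    "normalized_distance_distribution",
    "te_overlap",
    "expression_class",
    "annotate_dmrs",
]


@dataclass(frozen=True)
class BinNormalization:
    bin: str
    n_genome_windows: int
    n_dmrs: int

    @property
    def normalized_value(self) -> float:
        return self.n_dmrs / self.n_genome_windows if self.n_genome_windows else float("nan")


@dataclass
class AnnotatedDmr:
    dmr: Dmr
    nearest_gene: str | None
    signed_distance: int | None
    distance_bin: str | None
    te_overlaps: list[tuple[str, str, int]] = field(default_factory=list)  # (id, class, bp)
    expression_class: str = "absent"
    persistence_call: str | None = None

    @property
    def overlaps_te(self) -> bool:
        return bool(self.te_overlaps)

    @property
    def te_classes(self) -> set[str]:
        return {c for _, c, _ in self.te_overlaps}


def distance_bin(signed_distance: int) -> str:
    d = abs(signed_distance)
    if signed_distance == 0:
        return "gene_body"
    if d <= 1000:
        return "0-1kb"
    if d <= 2000:
        return "1-2kb"
    if d <= 4000:
        return "2-4kb"
    if d <= 6000:
        return "4-6kb"
    return ">6kb"


def _signed_distance(start: int, end: int, gene: GeneFeature) -> int:
    """Signed bp distance of interval [start, end] to a gene span.

    0 when overlapping; otherwise the gap to the nearest gene end, signed
    by transcriptional orientation (negative upstream of the TSS, positive
    downstream of the TES).
    """
    if end >= gene.start and start <= gene.end:
        return 0
    if end < gene.start:  # interval left of the gene
        gap = gene.start - end
        return -gap if gene.strand == "+" else gap
    gap = start - gene.end
    return gap if gene.strand == "+" else -gap


def assign_nearest_gene(
    start: int, end: int, chrom: str, genes: Sequence[GeneFeature]
) -> tuple[GeneFeature | None, int | None, str | None]:
    """Nearest gene on the same chromosome, its signed distance, and bin.

    Overlapping genes win with distance 0; among several, the one with the
    largest overlap (tie -> lexicographically smaller id).  Otherwise the
    gene minimizing the unsigned distance (same tie-break).  Returns
    ``(None, None, None)`` when the chromosome has no genes.
    """
    cands = [g for g in genes if g.chrom == chrom]
    if not cands:
        logger.warning("no genes on %s; DMR %d-%d left unassigned", chrom, start, end)
        return None, None, None
    overlapping = [g for g in cands if end >= g.start and start <= g.end]
    if overlapping:
        # largest overlap wins; equal overlaps break to the smaller id
        best = min(
            overlapping,
            key=lambda g: (-(min(end, g.end) - max(start, g.start) + 1), g.id),
        )
        return best, 0, "gene_body"
    best = min(cands, key=lambda g: (abs(_signed_distance(start, end, g)), g.id))
    d = _signed_distance(start, end, best)
    return best, d, distance_bin(d)


def normalized_distance_distribution(
    dmrs: Sequence[Dmr | AnnotatedDmr],
    genes: Sequence[GeneFeature],
    genome_sizes: Mapping[str, int],
    tile_bp: int = 200,
) -> list[BinNormalization]:
    """Per-bin DMR counts normalized by genome-wide tile counts.

    The genome is tiled into non-overlapping ``tile_bp`` windows; each tile
    midpoint is classified by the nearest-gene rule, giving the number of
    genomic regions per bin category.
    """
    if tile_bp <= 0:
        raise ValueError("tile_bp must be positive")
    tile_counts = {b: 0 for b in DISTANCE_BINS}
    for chrom, size in genome_sizes.items():
        chrom_genes = [g for g in genes if g.chrom == chrom]
        starts = np.arange(1, size + 1, tile_bp)
        for s in starts:
            mid = int(min(s + tile_bp // 2, size))
            _, _, b = assign_nearest_gene(mid, mid, chrom, chrom_genes)
            if b is not None:
                tile_counts[b] += 1

    dmr_counts = {b: 0 for b in DISTANCE_BINS}
    for d in dmrs:
        if isinstance(d, AnnotatedDmr):
            b = d.distance_bin
        else:
            _, _, b = assign_nearest_gene(d.start, d.end, d.chrom, genes)
        if b is not None:
            dmr_counts[b] += 1
    return [BinNormalization(b, tile_counts[b], dmr_counts[b]) for b in DISTANCE_BINS]


def build_te_trees(tes: Sequence[TeFeature]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over TE spans (half-open internally)."""
    trees: dict[str, IntervalTree] = {}
    for t in tes:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end + 1, t)
    return trees


def te_overlap(
    start: int, end: int, chrom: str, te_trees: Mapping[str, IntervalTree]
) -> list[tuple[str, str, int]]:
    """All TEs overlapping [start, end] by >= 1 bp, with overlap lengths."""
    tree = te_trees.get(chrom)
    if tree is None:
        return []
    hits = []
    for iv in sorted(tree.overlap(start, end + 1)):
        te: TeFeature = iv.data
        bp = min(end, te.end) - max(start, te.start) + 1
        hits.append((te.id, te.te_class, bp))
    return hits


def expression_class(
    gene_id: str | None,
    de_table: Mapping[str, DeRecord],
    fc_thresholds: tuple[float, float] = (2.0, 4.0),
    alpha: float = 0.05,
) -> str:
    """Fold-change class of a DMR's nearest gene.

    ``up>4`` / ``up2-4`` for significant induction beyond the thresholds,
    ``down>2`` for significant repression, ``ns`` otherwise; ``absent``
    when the gene is missing from the table.
    """
    if gene_id is None or gene_id not in de_table:
        return "absent"
    rec = de_table[gene_id]
    lo, hi = fc_thresholds
    fold = 2.0 ** rec.log2fc
    if rec.qvalue >= alpha:
        return "ns"
    if fold > hi:
        return "up>4"
    if fold > lo:
        return "up2-4"
    if fold < 1.0 / lo:
        return "down>2"
    return "ns"


def annotate_dmrs(
    dmrs: Sequence[Dmr],
    genes: Sequence[GeneFeature],
    tes: Sequence[TeFeature],
    de_records: Sequence[DeRecord] | None = None,
) -> list[AnnotatedDmr]:
    """Attach nearest gene, distance bin, TE overlaps and expression class."""
    trees = build_te_trees(tes)
    de_map = {r.gene_id: r for r in de_records} if de_records else {}
    out = []
    for d in dmrs:
        gene, dist, b = assign_nearest_gene(d.start, d.end, d.chrom, genes)
        out.append(
            AnnotatedDmr(
                dmr=d,
                nearest_gene=gene.id if gene else None,
                signed_distance=dist,
                distance_bin=b,
                te_overlaps=te_overlap(d.start, d.end, d.chrom, trees),
                expression_class=expression_class(gene.id if gene else None, de_map),
            )
        )
    return out


def te_class_summary(annotated: Sequence[AnnotatedDmr]) -> pd.DataFrame:
    """Per-class DMR counts and the overall TE-overlap proportion."""
    n = len(annotated)
    n_te = sum(1 for a in annotated if a.overlaps_te)
    rows = [{"te_class": "any_te", "n_dmrs": n_te, "proportion": n_te / n if n else float("nan")}]
    classes: dict[str, int] = {}
    for a in annotated:
        for c in a.te_classes:
            classes[c] = classes.get(c, 0) + 1
    for c in sorted(classes):
        rows.append({"te_class": c, "n_dmrs": classes[c], "proportion": classes[c] / n})
    return pd.DataFrame(rows)


def annotated_to_frame(annotated: Sequence[AnnotatedDmr]) -> pd.DataFrame:
    rows = []
    for a in annotated:
        d = a.dmr
        rows.append(
            {
                "dmr_id": d.dmr_id, "chrom": d.chrom, "start": d.start, "end": d.end,
                "direction": d.direction, "n_sites": d.n_sites,
                "nearest_gene": a.nearest_gene, "signed_distance": a.signed_distance,
                "distance_bin": a.distance_bin, "overlaps_te": a.overlaps_te,
                "te_classes": ",".join(sorted(a.te_classes)),
                "expression_class": a.expression_class,
                "persistence_call": a.persistence_call,
            }
        )
    return pd.DataFrame(rows)
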