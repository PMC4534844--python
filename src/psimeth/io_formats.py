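"""Readers and writers for every external table the pipeline touches.

Formats
-------
* allc-style per-cytosine TSV: ``chrom  pos  strand  context  mc_reads
  total_reads`` (1-based positions, header optional).
* Gene / TE annotations: GFF3 (1-based inclusive) or BED (0-based
  half-open), dialect inferred from the file extension.  Internally every
  interval is 1-based inclusive.
* Differential-expression TSV with header ``gene_id  log2fc  qvalue
  mean_expr_control  mean_expr_stress``.
* Sample sheet TSV: ``sample_id  condition  tissue  timepoint  replicate
  genotype  allc_path``.

Missing coverage is stored as ``total_reads = 0`` rows, never as absent
rows, so that count matrices stay position-aligned across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc_reads", "total_reads"]
DE_COLUMNS = ["gene_id", "log2fc", "qvalue", "mean_expr_control", "mean_expr_stress"]
SHEET_COLUMNS = ["sample_id", "condition", "tissue", "timepoint", "replicate", "genotype"]


class FormatError(ValueError):
    """Unrecognized or malformed external file."""


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-resolved cytosine with its basecall counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str  # CG / CHG / CHH
    mc_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if not 0 <= self.mc_reads <= self.total_reads:
            raise ValueError(
                f"mc_reads must satisfy 0 <= mc <= total, got "
                f"{self.mc_reads}/{self.total_reads} at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str  # plus_pi / minus_pi / resupply
    tissue: str  # root / shoot / panicle
    timepoint: int  # days
    replicate: int
    genotype: str = "WT"


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class TeFeature:
    chrom: str
    start: int
    end: int
    strand: str
    id: str
    te_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class DeRecord:
    gene_id: str
    log2fc: float
    qvalue: float
    mean_expr_control: float = 0.0
    mean_expr_stress: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValueError(f"qvalue out of [0,1] for {self.gene_id}: {self.qvalue}")


@dataclass
class MethylomeSet:
    """Position-aligned count matrices across samples plus sample metadata.

    ``sites`` is sorted by (chrom, pos, strand); ``mc`` and ``total`` are
    (n_sites, n_samples) integer matrices aligned to it.  The spike-in
    chromosome (unmethylated control DNA) is carried alongside the genome
    and split off via :meth:`split_spike_in`.
    """

    sites: pd.DataFrame  # columns chrom, pos, strand, context
    mc: np.ndarray
    total: np.ndarray
    samples: list[SampleMeta]
    spike_in_chrom: str | None = None

    def __post_init__(self) -> None:
        n_sites, n_samples = self.mc.shape
        if self.total.shape != (n_sites, n_samples):
            raise ValueError("mc/total shape mismatch")
        if len(self.sites) != n_sites:
            raise ValueError("sites/counts length mismatch")
        if len(self.samples) != n_samples:
            raise ValueError("samples/counts width mismatch")
        if (self.mc > self.total).any():
            raise ValueError("mc_reads exceeds total_reads")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def split_spike_in(self) -> tuple["MethylomeSet", "MethylomeSet"]:
        """Return (genome-only, spike-in-only) sets."""
        if self.spike_in_chrom is None:
            raise ValueError("no spike-in chromosome declared")
        mask = (self.sites["chrom"] == self.spike_in_chrom).to_numpy()
        return self._take(~mask), self._take(mask)

    def subset_region(self, chrom: str, start: int, end: int) -> "MethylomeSet":
        s = self.sites
        mask = ((s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] <= end)).to_numpy()
        return self._take(mask)

    def subset_context(self, scope: str) -> "MethylomeSet":
        """Restrict to a context scope; ``CNN`` keeps all three contexts."""
        if scope == "CNN":
            return self
        if scope not in CONTEXTS:
            raise ValueError(f"bad context scope {scope!r}")
        mask = (self.sites["context"] == scope).to_numpy()
        return self._take(mask)

    def _take(self, mask: np.ndarray) -> "MethylomeSet":
        return MethylomeSet(
            self.sites.loc[mask].reset_index(drop=True),
            self.mc[mask],
            self.total[mask],
            list(self.samples),
            self.spike_in_chrom,
        )


# ---------------------------------------------------------------------------
# allc tables


def read_allc(path: str | Path) -> pd.DataFrame:
    """Read one sample's per-cytosine count table, validating every row.

    Returns a frame with :data:`ALLC_COLUMNS`, sorted by (chrom, pos,
    strand).  A header line is accepted but optional.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            first = line
            break
    has_header = first.startswith("chrom")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=None if has_header else ALLC_COLUMNS,
            header=0 if has_header else None,
            dtype={
                "chrom": str, "pos": np.int64, "strand": str,
                "context": str, "mc_reads": np.int64, "total_reads": np.int64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed allc table ({exc})") from exc
    missing = set(ALLC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing allc columns {sorted(missing)}")
    df = df[ALLC_COLUMNS]
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        line = int(df.index[bad][0]) + 1 + has_header
        raise FormatError(f"{path}: line {line}: bad context {df.loc[bad, 'context'].iloc[0]!r}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        line = int(df.index[bad][0]) + 1 + has_header
        raise FormatError(f"{path}: line {line}: bad strand")
    if (df["pos"] < 1).any():
        raise FormatError(f"{path}: non-positive position")
    over = df["mc_reads"] > df["total_reads"]
    if over.any() or (df["mc_reads"] < 0).any():
        row = df[over | (df["mc_reads"] < 0)].iloc[0]
        raise FormatError(
            f"{path}: mc_reads > total_reads at {row['chrom']}:{row['pos']} "
            f"({row['mc_reads']}/{row['total_reads']})"
        )
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def write_allc(df: pd.DataFrame, path: str | Path, header: bool = True) -> None:
    df[ALLC_COLUMNS].to_csv(path, sep="\t", index=False, header=header)


def build_methylome_set(
    tables: Mapping[str, pd.DataFrame],
    samples: Sequence[SampleMeta],
    spike_in_chrom: str | None = None,
) -> MethylomeSet:
    """Align per-sample allc tables onto the union of their sites.

    Sites absent from a sample get ``mc = total = 0`` (missing coverage),
    so every count matrix shares the same row order.
    """
    by_id = {s.sample_id: s for s in samples}
    unknown = set(tables) - set(by_id)
    if unknown:
        raise ValueError(f"samples without metadata: {sorted(unknown)}")
    if set(by_id) - set(tables):
        raise ValueError(f"metadata without data: {sorted(set(by_id) - set(tables))}")

    keys = ["chrom", "pos", "strand", "context"]
    union = (
        pd.concat([t[keys] for t in tables.values()], ignore_index=True)
        .drop_duplicates()
        .sort_values(["chrom", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    dup = union.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    if dup.any():
        row = union[dup].iloc[0]
        raise ValueError(
            f"conflicting context annotations at {row['chrom']}:{row['pos']}{row['strand']}"
        )
    n_sites = len(union)
    order = list(samples)
    mc = np.zeros((n_sites, len(order)), dtype=np.int64)
    total = np.zeros_like(mc)
    index = pd.MultiIndex.from_frame(union[["chrom", "pos", "strand"]])
    for j, meta in enumerate(order):
        t = tables[meta.sample_id]
        t_idx = pd.MultiIndex.from_frame(t[["chrom", "pos", "strand"]])
        loc = index.get_indexer(t_idx)
        mc[loc, j] = t["mc_reads"].to_numpy()
        total[loc, j] = t["total_reads"].to_numpy()
    return MethylomeSet(union, mc, total, order, spike_in_chrom)


# ---------------------------------------------------------------------------
# features


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_features(
    path: str | Path, kind: Literal["gene", "te"]
) -> list[GeneFeature] | list[TeFeature]:
    """Read gene or TE features from GFF3 or BED (by extension).

    BED intervals (0-based half-open) are converted to the internal 1-based
    inclusive convention; the TE class comes from the GFF3 ``class`` (or
    ``te_class``) attribute, or from the BED name field after a ``;``
    separator (``TE1;MITE``).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        rows = _read_gff3_rows(path)
    elif suffix == ".bed":
        rows = _read_bed_rows(path)
    else:
        raise FormatError(f"{path}: unknown annotation extension {suffix!r}")

    feats: list = []
    seen: set[str] = set()
    for chrom, start, end, strand, name, te_class in rows:
        if name in seen:
            raise FormatError(f"{path}: duplicate feature id {name!r}")
        seen.add(name)
        if kind == "gene":
            feats.append(GeneFeature(chrom, start, end, strand, name))
        else:
            feats.append(TeFeature(chrom, start, end, strand, name, te_class or "unknown"))
    if not feats:
        logger.warning("%s: empty %s annotation", path, kind)
    feats.sort(key=lambda f: (f.chrom, f.start, f.end))
    return feats


def _read_gff3_rows(path: Path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _, _, start, end, _, strand, _, attrs = parts
            start, end = int(start), int(end)
            if start > end:
                raise FormatError(f"{path}: line {lineno}: start > end")
            a = _parse_gff3_attributes(attrs)
            name = a.get("ID") or a.get("Name") or f"feat{lineno}"
            te_class = a.get("class") or a.get("te_class")
            rows.append((chrom, start, end, strand if strand in "+-" else "+", name, te_class))
    return rows


def _read_bed_rows(path: Path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            start0, end0 = int(parts[1]), int(parts[2])
            if start0 >= end0:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else f"feat{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            te_class = None
            if ";" in name:
                name, te_class = name.split(";", 1)
            rows.append((chrom, start0 + 1, end0, strand, name, te_class))
    return rows


def write_features_bed(feats: Iterable[GeneFeature | TeFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in feats:
            name = f.id
            if isinstance(f, TeFeature):
                name = f"{f.id};{f.te_class}"
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{name}\t0\t{f.strand}\n")


def write_features_gff3(feats: Iterable[GeneFeature | TeFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            ftype = "gene" if isinstance(f, GeneFeature) else "transposable_element"
            attrs = f"ID={f.id}"
            if isinstance(f, TeFeature):
                attrs += f";class={f.te_class}"
            fh.write(
                f"{f.chrom}\tpsimeth\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# DE table and sample sheet


def read_de_table(path: str | Path) -> list[DeRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing DE columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    return [
        DeRecord(
            str(r.gene_id), float(r.log2fc), float(r.qvalue),
            float(r.mean_expr_control), float(r.mean_expr_stress),
        )
        for r in df.itertuples()
    ]


def write_de_table(records: Iterable[DeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.gene_id, r.log2fc, r.qvalue, r.mean_expr_control, r.mean_expr_stress)
            for r in records
        ],
        columns=DE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> tuple[list[SampleMeta], dict[str, str]]:
    """Read the sample sheet; returns (metadata, sample_id -> allc_path)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    metas = [
        SampleMeta(
            r.sample_id, r.condition, r.tissue, int(r.timepoint), int(r.replicate),
            getattr(r, "genotype", "WT") or "WT",
        )
        for r in df.itertuples()
    ]
    paths = dict(zip(df["sample_id"], df.get("allc_path", pd.Series(dtype=str))))
    return metas, paths


def write_sample_sheet(
    samples: Sequence[SampleMeta], path: str | Path, allc_paths: Mapping[str, str] | None = None
) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id, "condition": s.condition, "tissue": s.tissue,
            "timepoint": s.timepoint, "replicate": s.replicate, "genotype": s.genotype,
        }
        if allc_paths is not None:
            row["allc_path"] = allc_paths.get(s.sample_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
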