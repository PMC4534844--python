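#!/usr/bin/env python
"""Persistence of stress-induced methylation after resupply.

On the triplicate +Pi / -Pi / resupply dataset, re-tests the implanted
loci as regions (Welch t-tests on per-sample corrected CNN levels, BH
within each comparison), classifies each locus as persistent / transient
/ ambiguous, and checks the calls against the generator's truth.  Also
writes the average-linkage sample dendrogram over the locus level matrix.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from psimeth.methylation_core import per_sample_nonconversion, region_level_matrix
from psimeth.pipeline import RunConfig, load_methylomes
from psimeth.temporal_expression import classify_persistence, cluster_samples, linkage_to_newick

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "persistence_3x3"
OUT = ROOT / "results" / "tables"


def main() -> None:
    ms = load_methylomes(RunConfig(sample_sheet=str(DATA / "samples.tsv")))
    nc = per_sample_nonconversion(ms)
    genome, _ = ms.split_spike_in()
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t")

    levels = {}
    for t in truth.itertuples():
        locus_id = f"{t.chrom}:{t.start}-{t.end}"
        levels[locus_id] = region_level_matrix(genome, t.chrom, t.start, t.end, "CNN", nc)
    matrix = pd.DataFrame(levels, index=ms.sample_ids).T
    group_of = {m.sample_id: m.condition for m in ms.samples}

    calls = classify_persistence(matrix, group_of)
    out = pd.DataFrame([c.__dict__ for c in calls])
    out["truth"] = truth["persistence_class"].to_numpy()
    OUT.mkdir(parents=True, exist_ok=True)
    out.to_csv(OUT / "persistence_calls.tsv", sep="\t", index=False)

    correct = int((out["call"] == out["truth"]).sum())
    print(f"persistence calls: {correct}/{len(out)} match the implanted truth")
    print(out[["dmr_id", "call", "truth"]].to_string(index=False))

    link, leaves = cluster_samples(matrix)
    (OUT / "persistence_dendrogram.nwk").write_text(
        linkage_to_newick(link, list(matrix.columns)) + "\n"
    )
    cond = [s.rsplit("_", 2)[0] for s in leaves]
    print(f"dendrogram leaf order groups conditions as: {cond}")


if __name__ == "__main__":
    main()
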