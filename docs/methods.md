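# Methods

## Scope and data model

The pipeline consumes per-cytosine count tables ("allc"-style TSV: chrom,
1-based position, strand, trinucleotide context, methylated and total
read counts), gene/TE annotations (GFF3 or BED; BED intervals are
converted on read so that all internal coordinates are 1-based
inclusive), a differential-expression table, and a sample sheet. Sites
missing from a sample are stored with `total_reads = 0`, never as absent
rows, so count matrices stay position-aligned across samples. Strand is
retained per cytosine, but tests and DMR levels pool both strands;
symmetric CG positions are not strand-collapsed (collapsing would halve
the row count of the site tables without changing pooled levels; the
uncollapsed form keeps the site list identical to the input).

## Methylation levels and non-conversion correction

All levels are *weighted*: Σ methylated basecalls / Σ basecalls over the
scope. Means of per-site fractions would over-weight low-coverage sites
and are not used anywhere. The bisulfite non-conversion rate ε is the
weighted level of the unmethylated spike-in chromosome, estimated per
sample (samples without spike-in coverage fall back to the pooled rate,
with a warning). Correction is literal subtraction clamped at zero,
`max(0, m − ε)`, applied per sample before any group comparison and
consistently thereafter; the rescaling alternative `(m − ε)/(1 − ε)`,
which additionally undoes the compression of the observable range, is
available via `correction="rescale"` but is not the default because the
subtraction form is the simpler estimator of the same quantity at small
ε and keeps corrected levels directly comparable with raw ones.
Subtraction leaves a small multiplicative bias — observed proportions are
`p + (1 − p)ε`, so the corrected expectation is `p(1 − ε)`, i.e. relative
bias ≤ ε ≈ 0.5% — which is far below the effect sizes of interest.

## Site-level test

Each cytosine with coverage in at least two samples (and at least one
read per group; no higher floor by default) yields an r×2 table with one
row per covered sample. Rows are samples: a per-site independence test is
only defined with samples as rows, and the row-exchangeability of the
statistic is what the permutation scheme relies on. The RMS statistic is
the root-mean-square deviation of observed cell frequencies from the
independence expectation computed from the table's own marginals.
Monte-Carlo calibration draws tables from the fitted independence model
(multinomial over the r×2 cells); each simulated table's statistic is
computed from *its own* marginals, i.e. a parametric bootstrap with
re-estimated nuisance parameters. The alternative — scoring simulated
tables against the fixed fitted model — was evaluated and rejected: its
null distribution absorbs the marginal sampling noise and the test loses
essentially all power in the 9-replicate design.

Simulation stops early once 100 simulated statistics reach the observed
one (the p-value estimate is then already accurate to ~10% relative), or
at `max_perms` (default 10,000). The estimator `(exceedances + 1) /
(draws + 1)` is used in both cases; it is never zero, which keeps BH
well-defined, and is conservative. For tables small enough to enumerate,
`exact_pvalue` sums multinomial probabilities over the full outcome
space and is the limit of the Monte-Carlo path.

Per-site seeds are derived deterministically from (master seed, chrom,
pos) via `SeedSequence`, so results are independent of execution order
and safely parallelizable.

Direction (hyper/hypo) is the sign of the pooled stress-minus-control
weighted level at the site; it is bookkeeping for DMR assembly, not part
of the test statistic.

## FDR calibration

The cutoff is the largest p-value threshold that still satisfies the
target FDR. Two selection rules are implemented:

* `bh` (default): the largest `p_(k) ≤ k·q/m` of the step-up procedure.
* `empirical_null`: the largest `c` with
  `(mean fraction of null p ≤ c)·m / #{p ≤ c} ≤ q`, where the null
  p-values come from re-running the test after random relabeling of the
  group assignment. This rule only has content in the pooled 2×2 mode
  (`pool_groups=True`), where relabeling changes the tables; in the
  default r×2 mode the statistic ignores group labels and relabeled
  p-values equal the observed ones, making the rule degenerate by
  construction. It is retained as a cross-check for pooled-mode runs.

Permutation p-values are granular (multiples of ~1/max_perms), so the
number of permutations bounds the achievable BH threshold: detecting k
true sites among m tested needs `1/(max_perms+1) ≲ k·q/m`. The default
10,000 permutations comfortably covers the analysis profiles; the
reduced 1,000-permutation setting used in the calibration experiments is
matched to their 200-of-2,000 mixtures.

## DMR assembly and filters

Significant sites chain greedily left-to-right: a site joins the open
block iff same chromosome, same direction, and gap ≤ 200 bp. Hyper and
hypo runs chain independently, so interleaved directions never mix.
Blocks keep their first/last member positions as the DMR span (no
padding). Blocks under the minimum site count (8 in rice-style profiles,
5 in the Arabidopsis-style profile) are emitted with
`passed_min_sites=False` and excluded downstream.

The replicate-consistency rule operationalizes "k of n samples
differentially methylated": the midpoint between the two group mean
levels splits the level axis, and a sample is consistent when it lies
strictly on its own group's side in the DMR's direction. The criterion
is parameter-free and monotone in effect size; an optional minimum
margin from the midpoint (default 0) is available. With identical group
means nothing separates and the filter fails, by design. Multi-timepoint
discovery (e.g. pooling three late timepoints into a 9v9 comparison) is
expressed purely through the sample sheet's group labels.

## Annotation

Nearest-gene distances are measured to the gene span (TSS–TES), zero
inside the body, negative upstream of the TSS and positive downstream of
the TES, strand-aware; the nearest gene minimizes unsigned distance, with
overlap size and then lexicographic id as tie-breaks. Distance bins are
gene_body, 0–1, 1–2, 2–4, 4–6 and > 6 kb. The genome-normalized bin
distribution divides per-bin DMR counts by the number of fixed-size
genome tiles (default 200 bp, roughly the average DMR size) whose
midpoints fall in that bin; tiling is this package's operationalization
of "regions per bin category", and the tile size is an exposed parameter
because the normalization is mildly sensitive to it. TE overlap uses
interval trees and counts any ≥ 1 bp intersection; a DMR may carry
several TE classes. Expression classes use fold-change thresholds 2 and
4 with an FDR < 0.05 gate (up>4, up2–4, down>2, ns, absent).

## Temporal analysis

Group comparisons are two-sided Welch t-tests on per-sample corrected
CNN levels (the pooled-variance Student variant is available via
`equal_var=True`; Welch is the default because replicate variances need
not match across conditions). BH runs within each comparison family.
Persistence calls follow the three-comparison rule; note that the third
comparison accepts a null ("stress vs recovery not significant"), which
is weak evidence — the call therefore carries its three q-values rather
than hiding them. Panicle-style analyses reuse the machinery at
α = 0.1. Hierarchical clustering is average-linkage on Euclidean
distances with scipy's deterministic tie-handling; trees export to
Newick.

## Synthetic data generator

The generator emulates the study design: a small two-chromosome genome
(defaults 300 kb + 200 kb) with non-overlapping genes and TEs biased to
sit near a subset of genes (MITE-heavy class mix); rice-like baseline
levels (TE bodies CG 0.80 / CHG 0.50 / CHH 0.08, background CG 0.30 /
CHG 0.10 / CHH 0.02); a 9 +Pi vs 9 −Pi root design over three late
timepoints, or triplicate control/stress/resupply groups for persistence
runs; CHH hypermethylation implants (default Δ = 0.5, 12 sites) placed
inside TEs near genes; coverage Poisson(20); a spike-in chromosome with
true level 0; non-conversion injected at the read level (observed
proportion `p + (1 − p)ε`, ε = 0.005), which makes the generator itself
the oracle for the correction step; and a DE table whose hyper-implant
nearest genes are induced with configurable probability.

Two noise regimes are deliberate:

* `simulate_methylomes` draws the beta-distributed proportion
  independently per sample and site (intra-class correlation 0.01). This
  is replicate-level biological noise — it is what gives the consistency
  filter real work and what the DMR-level t-tests see.
* `simulate_site_mixture` (used by the FDR-calibration experiments)
  draws the dispersed proportion once per site-and-group, shared by that
  group's samples, so null sites have a genuinely common proportion
  across all samples. Within-site exchangeability is exactly the null
  the multinomial permutation test calibrates against; with per-sample
  noise instead, *every* site violates the test's homogeneity null and
  site-level false-discovery proportions against group-truth are
  inflated (measured ≈ 3.7% at target 1% in the 9v9 design). The full
  pipeline absorbs that inflation through direction-consistent merging,
  the minimum-site rule and the consistency filter — the null-data
  experiment yields zero DMRs — but the site-level calibration statement
  is made, and tested, in the exchangeable regime where it is
  mathematically meaningful.

What the generator does not emulate: sequence composition, mappability
and coverage biases, correlated neighbouring-site methylation states,
context-dependent conversion efficiency, and chromosome-scale
methylation domains. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the
stated generative model, not performance on real libraries.

## Problem sizes and numerical choices

The calibration experiments use 2,000 sites × 1,000 permutations × 20
seeds per design; DMR recovery uses the default ~2,500-site genome with
10,000 permutations over 3 seeds, and the null-specificity experiment
uses a ~1,200-site genome over 20 seeds — sizes chosen so the entire
suite re-runs on a single CPU in minutes while keeping Monte-Carlo error
well below the margins being tested. Statistic ties in the permutation
test are resolved as exceedances with an absolute guard of 1e-12 (the
zero-statistic table must yield p = 1). Zero-coverage samples are
dropped from tables; regions with no covered cytosines return NaN levels
and are excluded from group means, never imputed. Degenerate t-tests
(constant equal groups, < 2 replicates) mark the DMR untestable instead
of returning a number.

## Known limitations

* The consistency rule interprets "differentially methylated sample" as
  midpoint separation; the original per-sample definition is not
  recoverable from the published description, so this is a documented
  interpretation, monotone and parameter-free.
* Site-level FDR control is guaranteed under within-site exchangeability
  (common proportion); replicate-level overdispersion shifts control to
  the region level via the filters, as described above.
* Accepting the null in the persistence rule limits the strength of
  "persistent" calls at small n; q-values are reported alongside.
* The RMS test detects any cross-sample heterogeneity, not specifically
  the group contrast; direction assignment and consistency filtering
  supply the group specificity.
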