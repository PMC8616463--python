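# Methods

## Model and procedure

The pipeline treats each gene's developmental trajectory as a signal
sampled at eight ages — E10.5 … E16.5 at their literal embryonic-day values
and P0 coded as day 22 — in up to three brain regions with two biological
replicates. Three signals are analyzed per gene: expression (TPM from
RNA-seq quantification), and the promoter intensities of H3K4me3
(activating) and H3K27me3 (repressive) from narrowPeak ChIP-seq calls.

**Expression.** Replicates are averaged on the TPM scale (arithmetic mean).
The expressed-gene filter keeps a gene when TPM ≥ `tpm_min` (default 1) in
at least `ceil(min_fraction · n_columns)` columns (default one third,
ceiling because the rule is "at least") and max TPM ≥ `max_floor`
(default 5). "Columns" are those of the matrix handed in: the pipeline runs
the filter per region on the eight replicate-averaged age columns, so each
region gets its own expressed set. Trajectories are log₂(TPM+1)-transformed
and Z-scored per gene with the sample (n−1) standard deviation;
zero-variance rows cannot be standardized and are dropped with a logged
list. Fold changes (P0 vs E10.5 by default) are plain TPM ratios; a zero
baseline switches to a pseudocount of 1 on both endpoints and flags the
gene, since a zero denominator is otherwise undefined.

**Clustering.** UPGMA = agglomerative clustering with average linkage,
where the distance between clusters is the mean over all inter-item
pairwise distances. The default metric is Euclidean distance on the
Z-scored rows (monotone in correlation for standardized vectors;
correlation distance is available as a config switch). The tree is cut to a
user-chosen k (default 5, one number or one per region) — cut-by-height is
also exposed for dendrogram-style use. The implementation delegates to
scipy's average-linkage routine; its nearest-neighbor-chain algorithm
resolves exactly tied merge distances in its own deterministic order, which
is the one tie-break detail not configurable here. On continuous data ties
have probability zero and the result provably equals the brute-force
definition (the suite checks merge heights and flat partitions against an
exhaustive oracle on hundreds of random instances).

**Trend labels.** Each cluster's mean Z-profile is regressed on age in
days; slope < −τ labels it *down*, > +τ *up*, else *other*, with
τ = 0.01 Z-units/day. The dead-band exists because "overall chronological
trend" is not operational for a near-flat mean profile; 0.01/day over the
11.5-day span corresponds to ~0.1 Z-units of total drift, well under
profile noise. Cross-region overlap takes the union of genes in all
clusters of the requested trend per region and reports exact intersection
cardinalities plus shared fraction (all-region intersection / union).

**Promoter signal.** narrowPeak is BED6+4; intensity defaults to the
signalValue column (configurable to score / pValue / qValue, since peak
callers differ in which column carries the usable enrichment statistic).
All interval logic is 0-based half-open. The promoter window is
`[tss − w, tss + w)` with w = 2000 bp; the window is symmetric, so strand
only decides which coordinate is the TSS. A peak assigned to several
promoters counts for each. Per promoter and age the maximum-intensity peak
is kept; ties go to the leftmost start. The annotation supplies one
representative TSS per gene — multi-transcript genes must be collapsed
upstream. Ages where a promoter has no peak are masked; the regression
default treats them as zero intensity (no peak = no signal), with a
`drop`-age alternative, because either reading of absent calls is
defensible and the choice is therefore surfaced as a config switch and
recorded in provenance.

**Age regressions.** Per gene, closed-form OLS of signal against day:
β is the signal change per day of development. Expression regressions use
log₂(TPM+1) — not Z-scores, which would destroy the per-gene scale that
makes β comparable to the histone slopes. Genes with fewer than two usable
points are skipped (logged). Summaries per (region, signal kind, trend)
report median, quartiles and the fraction of negative slopes; no per-gene
significance machinery, as the object of interest is the coefficient
distribution.

**Pathway analysis.** The any-region rule labels a pathway gene *down* if
it sits in a downregulation cluster of at least one region (likewise *up*);
a gene down in one region and up in another is counted under its first
region's label and flagged `conflict`, since the rule itself does not
resolve that case. Only pro/anti × down/up rows enter the four-group
tabulation; `both` and `unknown` directions are excluded. The fold-change
contrast compares pro vs anti genes of the down cluster with a one-sided
rank test. These are two independent gene groups, so the default is the
unpaired rank-sum (Mann–Whitney) test; the p-value is exact by full
enumeration over all C(n, n_pro) group assignments (midranks, hence
tie-safe) when combined n ≤ 20, and the tie-corrected normal approximation
otherwise. A signed-rank mode that pairs the samples by rank order exists
purely as a labeled compatibility option; pairing independent samples is
not statistically recommended and the report always names the variant used.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study design, not mouse
biology. Defaults: 300 down-genes and 250 up-genes with linear
log₂(TPM+1) trajectories (|slope| uniform in 0.05–0.5 per day), 50 + 50
late-reversal genes with a single breakpoint at the E16.5 coded day, 100
flat genes, 25 non-member decoys; 3 regions × 8 ages × 2 replicates;
replicate noise is additive Gaussian on the log₂ scale (sd 0.1, i.e.
lognormal TPM noise, consistent with the pipeline's log-space analysis).
Histone coupling mirrors the epigenetic model under test: down-genes lose
H3K4me3 (β_K4 ~ N(−0.3, 0.05) intensity units/day, truncated at ±3 sd so
noiseless intensities stay positive) with static H3K27me3
(β ~ N(0, 0.02)); up-genes the mirror image; peak intensities get Gaussian
noise (sd 0.2) and 5% per-cell dropout. One in-window peak per
(gene, mark, region, age) keeps assignment unambiguous; an adversarial
mode adds desert decoys and a multi-promoter spanning peak to exercise the
assignment logic. Intercept ranges are constrained so every monotone gene
passes the expression filter and no noiseless profile clips at zero —
which is what makes the noise-free limit recover true slopes exactly.

The pathway list defaults to the 28/13/8/9 pro-down/pro-up/anti-up/
anti-down composition of the published KEGG apoptosis tabulation, with
pro-down genes drawn from the steepest down slopes and anti-down from the
shallowest, so the pro-vs-anti fold-change contrast has the direction the
real pathway shows.

What passing tests do **not** show about real data: real trajectories are
not linear, promoter peaks shift and split rather than scale, true group
structure is not two clean monotone blocks, regions share genes but not
noise, and GO/KEGG annotations are far messier than the four synthetic term
strings. Recovery rates on this generator are upper bounds, not estimates,
of real-data performance; real-data quantities (cluster sizes, fold-change
medians, region-specific β medians) depend on the actual ENCODE/GO/KEGG
snapshots and are out of the desk-scale test surface.

## Numerical choices and degenerate inputs

- Sample sd (ddof = 1) in Z-scores, switchable; zero-variance rows dropped.
- Filter threshold count uses ceiling ("at least one third").
- fcluster/maxclust flat cuts; cluster ids renumbered 1..k by first gene
  appearance so ids are stable under row permutation.
- Promoter window clipped at coordinate 0 on the left (equivalent to the
  unclipped rule, since peaks have non-negative coordinates).
- OLS via the closed form (scipy linregress); r² clamped to [0, 1] against
  rounding; constant-signal fits return slope 0 with r² = 0.
- Exact rank-sum enumeration compares rank sums with a 1e−9 guard so
  midrank arithmetic cannot flip a boundary case.
- Empty selections (no genes with a trend, empty fold-change group, all
  rows excluded from the tabulation) raise rather than return NaN.

## Problem sizes

The default synthetic dataset (775 genes, 48 TPM files, 48 narrowPeak
files) runs the full pipeline in a few seconds; the test suite's oracle
checks use hundreds of random instances of ≤ 7 items (UPGMA), 1000 random
vectors (OLS), and 200 random peak/gene instances (promoter assignment).
These sizes were chosen to make every guarantee checkable at the desk while
keeping the statistical checks (sign-recovery ≥ 95%, membership recovery
≥ 90%, the β_K4/β_K27 sign patterns) comfortably away from their
thresholds — margins observed across seeds are wide (recovery ~100%,
negative-β fractions ~82–85% against the 75% requirement).

## Known limitations

- One TSS per gene; no multi-transcript promoter logic.
- No peak calling, bigwig signal tracks, or genome-browser output; only
  narrowPeak intensities are used.
- No automatic choice of k; the dendrogram cut is the caller's decision.
- The signed-rank compatibility mode pairs unpaired data and should only be
  used to mirror legacy analyses.
- Stage-level CLI re-entry exists for clustering (`epichron cluster`);
  regression and pathway re-runs are library calls on the emitted TSVs
  rather than subcommands.
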