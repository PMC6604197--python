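# Methods

This note documents the models, numerical choices and limitations behind
`betshift`. All coordinates are 0-based half-open (BED convention);
"upstream" and "downstream" are always in transcription orientation.

## Promoter geometry

Each transcript's TSS is flanked by two abutting 1 Kb windows: the *core
promoter* upstream of the start site and the *Pol II pause site*
downstream, clipped at chromosome edges. Overlap is ≥ 1 shared base for
every membership test (window counting, enhancer filtering, peak
categorization, consensus, blacklist). Duplicate TSS records identical in
(chrom, strand, position) collapse to the lexicographically smallest
transcript id.

## Synthetic-data generator

The generator defines the study conditions and carries full ground truth.

**Design.** Two cell models (sensitive, resistant), doses 0/50/500/5000 nM,
two ChIP replicates per condition plus one uniform input sample. The default
genome is 2 chromosomes × 5 Mb carrying 2000 TSSs (jittered grid, random
strand, gene lengths 3–8 kb, ~10% noncoding) — a scale that runs the full
pipeline in minutes on one CPU while leaving hundreds of TSSs per
sensitivity class.

**Occupancy.** Fragment centres are Gaussian around two strand-oriented
modes: upstream at −300 bp and downstream at +165 bp (the centre of the
observed 150–180 bp range), with `peak_sd` = 40 bp. Expected fragments per
window at vehicle are `amp_up` = 60 (core) and `amp_down` = 90 (pause), so
the downstream mode is the stronger one in the sensitive model. The sd and
amplitudes were fixed once with an eye to class separability: fragments are
300 bp, so downstream fragments whose centre falls within 150 bp of the TSS
unavoidably also overlap the core window; a tight positioned-nucleosome
peak keeps that spill from swamping the core-promoter signal, mimicking the
sharp flanking acetylation peaks seen in real promoter metaprofiles.

**Displacement.** Remaining occupancy follows a Hill law
r(d) = 1/(1 + (d/EC50)^h) with h = 1, applied independently per window.
Five per-TSS sensitivity classes set the two EC50s:

| class                  | EC50 core | EC50 pause | default share |
|------------------------|-----------|------------|---------------|
| sensitive-both         | 2000 nM   | 2000 nM    | 0.06          |
| highly-sensitive-both  | 100 nM    | 100 nM     | 0.04          |
| highly-sensitive-pause | —         | 100 nM     | 0.06          |
| highly-sensitive-core  | 100 nM    | —          | 0.05          |
| unaffected             | —         | —          | 0.79          |

("—" = never displaced.) The shares keep the truly affected fraction near
one fifth of TSSs, comparable to a realistic promoter-displacement screen
and small enough that median-of-ratios size factors stay anchored on
unaffected rows. The resistant model multiplies all finite EC50s by 50 and
flattens the binding amplitudes (60/66), giving globally weaker binding and
far fewer affected TSSs at any dose.

**Noise.** Per-window counts are Gamma-Poisson (NB) with dispersion 0.05
per replicate; a uniform background of 40 000 fragments per ChIP sample and
a 200 000-fragment uniform input are added. Expression counts are NB with
gene means log-uniform on [50, 2000] and mean
μ·2^(−β·(1−r_pause)) with coupling β = 2, so expression falls in proportion
to pause-site displacement. Pol II coverage is deterministic by default
(optional Gaussian noise): promoter density scales with
1 + c·(1−r_pause) and body density with max(r_pause, 0.1), c = 1, making
the true traveling-ratio fold change a closed-form function of the truth.

**What the generator does not emulate:** sequence-level effects
(mappability, GC bias), enhancer looping, inter-gene correlation,
batch effects, and the exact genome-wide occupancy landscape of any real
cell line. Passing recovery tests therefore demonstrates the pipeline's
correctness under its stated noise model, not its performance on any
particular public dataset.

**Seeding.** A single global seed expands through named `SeedSequence`
salts (stable CRC32 of stage names, kept below 2^31) so every stage is
independently reproducible across processes.

## Coverage and metaprofiles

Reads are extended to 300 bp from their 5′ end and accumulated into 50-bp
bins; a bin's value is the mean per-base coverage within the bin, so RPGC
("1×") normalization — scale = effective genome size / (n_fragments ×
extension) — yields a genome-wide mean of exactly 1. Input subtraction is
element-wise on matching grids; negative values are preserved (window
counting uses raw fragments, never subtracted tracks, so no clamping is
required). The effective genome size defaults to the full synthetic genome
and is a configuration constant, not mappability-derived.

Metaprofiles sample anchor-relative offset bins at the genomic bin
containing each offset's midpoint; this mirrors minus-strand anchors
without the half-bin phase bias that flipping genome-grid bins would
introduce. Mode detection smooths with a 3-bin moving average (a reporting
choice only; nothing downstream consumes the smoothed profile) and requires
a strict interior local maximum on each side of the anchor; monotone or
flat flanks are flagged unimodal. Reported mode offsets are bin left edges.

## Peak calling and consensus

The broad-peak caller is a transparent Poisson bin scan, not a port of any
existing tool: per 50-bp bin the treatment count is tested against
λ = max(genome-wide control rate, 10-kb local control rate) with the
control scaled to treatment depth; bins at p ≤ 10⁻³ merge across gaps up to
500 bp (the broad-merge gap is a configuration knob); each peak is scored
by its best bin. No multiple-testing step is applied at this stage —
confidence comes from the pseudo-replicate consensus: the merged-replicate
peak set is intersected (≥ 1 bp, in coordinates of the merged set) with the
peaks of each half of a seeded random equal split, then blacklist-filtered.
An empty control falls back to the genome-wide treatment rate with a
warning.

## Differential binding and expression

Counts are normalized by median-of-ratios size factors computed over rows
with an all-positive geometric mean. Each dose is tested against vehicle
independently. Per row, the dispersion is a pooled within-group moment
estimate shrunk 50% toward a least-squares trend a₀ + a₁/mean fitted across
rows; the raw (unclipped) moment estimate is used through the shrink —
clipping first would bias the dispersion and hence the standard error
upward — and only the final value is floored at 10⁻⁸. The Wald statistic is
LFC/SE with a delta-method SE and a pseudo-count of 0.5 on group means.

Because the shrunk dispersion retains a fraction w of the moment
estimator's sampling noise, its relative variance is w²·2/(n−2) and the
natural reference is a t distribution with effective df (n−2)/w² — 8 at the
default w = 0.5 with 2 + 2 replicates, converging to the normal reference
as replication grows. This moderation is what keeps the empirical type-I
error near the nominal 5% level at two replicates per group (verified by
simulation in the test suite; the simplified estimator is validated by that
calibration property, not by numerical identity to any reference tool).

Rows with total normalized count below 10 are left untested (NaN p). BH
correction is applied within each contrast. A TSS is *affected* at a window
when any dose contrast has adjusted p < 0.05 with LFC < 0; the
displacement-only sign requirement is a documented flag (`two_sided`).
Differential expression reuses the same machinery with the dual rule:
significant ⇔ adjusted p < 0.05 and |LFC| > 1.

## Clustering and naming

Affected TSSs are clustered on their raw 6-column LFC signature (3 doses ×
2 windows) — no row scaling, because the moderate-vs-strong displacement
distinction lives in the signed magnitudes. K-means with k = 4, best of 25
seeded restarts, is the default; Ward-linkage hierarchical clustering cut
at 4 is available behind a flag since either is defensible for this
signature. Untested LFCs are imputed 0 and flagged in companion columns
excluded from the clustering features.

Names are assigned from the 5000 nM centroids (the strongest, least noisy
contrast): among clusters with negative mean pause LFC, the smallest |core
LFC| is *highly-sensitive-pause*; symmetrically for *highly-sensitive-core*;
of the remaining two, the lower core+pause sum is *highly-sensitive-both*
and the other *sensitive-both*. Ties break by cluster index, so naming is
deterministic and invariant to cluster re-indexing.

## Traveling ratio

TR = mean per-base coverage over [TSS−100, TSS+300] (401 bases, half-open
[TSS−100, TSS+301) on the plus strand) divided by mean coverage over
[TSS+301, TES). Region means integrate the binned track exactly by
weighting bins with their overlap. Genes with zero body coverage or a body
shorter than 200 bp are excluded as invalid rather than given infinite TR.
A gene *gains* in TR when TR_treated/TR_vehicle exceeds 2; the alternative
reading (post-treatment TR > 2) is available as `gain_mode="absolute"`, and
the fold interpretation is the default because a "gain" is a change. The
cluster comparison uses a chi-square two-proportion test with Yates
continuity correction (corrected statistic floored, so equal proportions
give p = 1); a plain z-test is available with `correction=False`.

## Pre-ranked GSEA

ES is the maximum deviation of the running sum with hit increments
|metric|^w (w = 1, the weighted scheme) normalized to the set total and
miss decrements 1/(N−n); float accumulation is clipped to [−1, 1]. Ties in
the ranking metric break by stable gene-id order. The null is a gene-label
permutation at the observed set size; NES divides ES by the mean |ES*| of
sign-matched permutations, the permutation p is sign-matched with the +1
correction, and the FDR q follows the standard pooled-null procedure over
sign-matched normalized scores. Degenerate sets (all ranked genes, or
all-zero member metrics) fall back to equal hit steps or are rejected.

## Assay models

Relative qPCR abundance is X = (1+EffR)^CtR / (1+EffX)^CtX with
efficiencies fixed on the (0, 1] scale (1 = perfect doubling), as the
(1+Eff) base implies. Values are conventionally rescaled so the DMSO-group
mean is exactly 1; the paired comparison is a two-sided paired t-test with
the star convention ** p < 0.005, * p < 0.05, and identical vectors flagged
p = 1 rather than undefined. Reference-gene candidates are genes with no
significant expression change at doses ≤ 500 nM and expression above the
0.8 quantile in every model, ranked by largest absolute LFC.

The dose–response area is the trapezoidal integral of (1 − viability) over
log10 concentration divided by the log-range — a normalized response
fraction in [0, 1] validated by its limit cases (0 at full viability, 1 at
none); it is a documented simplification of curve-fitting-based AUC
routines.

## Pipeline

`betshift full` runs simulate → coverage → peaks → differential binding →
clustering → pausing → expression → report. Stage artifacts are plain text
(BED, bedGraph, TSV, JSON) plus a JSONL manifest with content hashes; a
fixed config and seed reproduce every summary table bit-for-bit. A stage
failure aborts with a stage-scoped error and preserves completed artifacts.

## Known limitations

- The NB test implements independent two-group contrasts only; no GLM
  designs, outlier handling, or LFC shrinkage estimators.
- The peak caller is a simplified Poisson scan; absolute peak counts are
  not comparable to any specific external caller's output.
- With strong global signal loss (most rows truly changed in one
  direction), median-of-ratios size factors absorb part of the effect;
  the generator's default affected fraction is chosen so this bias stays
  small, but analyses of saturating global displacement should supply
  spike-in-derived factors.
- The resistant model at default scale often yields too few affected TSSs
  to cluster — expected behaviour for a resistant line, handled by skipping
  the stage with a warning.
- bigWig I/O is not implemented; coverage is exchanged as bedGraph.
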