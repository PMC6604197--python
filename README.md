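# betshift

Spatially resolved analysis of dose-dependent displacement of chromatin-bound
BET proteins (BRD2/3/4) around transcription start sites.

## The problem

BET-bromodomain inhibitors displace BET proteins from acetylated chromatin,
but cell lines differ sharply in how much displacement a given dose causes
and in how displacement translates into transcriptional change. A
dose-titration ChIP-seq design — two cell models (one drug-sensitive, one
resistant), four doses (vehicle, 50, 500, 5000 nM), two replicates each —
lets one ask *where* around each promoter binding is lost, and whether the
position of the loss predicts expression changes.

The package implements the full analysis arc for such a design, for
computational biologists working with promoter-level ChIP-seq, Pol II
occupancy and RNA-seq counts:

- **Promoter windows.** Each TSS is flanked by a 1 Kb *core promoter*
  (upstream, in transcription orientation) and a 1 Kb *Pol II pause site*
  (downstream). BET binding is bimodal around the TSS, with an upstream mode
  near −300 bp and a stronger downstream mode near +150–180 bp.
- **Consensus peak calling.** A Poisson bin-scan broad-peak caller wrapped
  in a pseudo-replicate consensus rule: peaks called on the merged
  replicates are kept only if recovered in both halves of a random
  equal split.
- **Differential binding.** Fragment counts in each window are tested per
  dose against vehicle with a negative-binomial Wald test (median-of-ratios
  size factors; moment dispersion shrunk 50% toward a fitted
  mean–dispersion trend; moderated-t reference), BH-corrected.
- **Sensitivity clustering.** Affected TSSs carry a 6-column log2-fold-change
  signature (3 doses × 2 windows); k-means with k = 4 and a centroid-based
  naming rule yield the four canonical classes *sensitive-both*,
  *highly-sensitive-both*, *highly-sensitive-pause*, *highly-sensitive-core*.
- **Pol II pausing.** Traveling ratio TR = mean coverage over
  [TSS−100, TSS+300] divided by mean coverage over [TSS+301, TES]; TR fold
  changes and a two-proportion test compare pausing gains across clusters.
- **Expression integration.** NB differential expression (FDR < 0.05 and
  |LFC| > 1), overlap of differentially bound and downregulated genes,
  per-cluster paired Wilcoxon comparisons, and a from-scratch pre-ranked
  GSEA (running-sum ES, gene-label permutation NES/FDR).
- **Assay models.** Efficiency-corrected qPCR quantification
  X = (1+EffR)^CtR / (1+EffX)^CtX with DMSO-mean normalization and paired
  t-tests, and the normalized dose–response area of (1 − viability).
- **Synthetic data with ground truth.** A generator that emulates the whole
  design — Hill-law displacement per sensitivity class, Gamma-Poisson
  fragment counts, Pol II coverage coupled to pause-site loss,
  NB expression counts — so every stage can be tested against known truth.

## Worked example

```python
import pandas as pd
from betshift import (SimulationConfig, tss_windows)
from betshift.simulate import make_annotation, assign_classes, simulate_chip
from betshift import diffbind as db, clusters as pc

cfg = SimulationConfig(seed=1)                      # default study conditions
ann = make_annotation(cfg)
classes = assign_classes(cfg, ann)
samples, truth = simulate_chip(cfg, "sensitive", ann, classes)

windows = tss_windows(ann)                          # core/pause 1 Kb windows
cols = {f"dose{s.dose:g}_rep{s.replicate}": s
        for s in samples if not s.is_input}
matrix = db.count_in_windows(cols, windows)
info = pd.DataFrame({"dose": [s.dose for s in samples if not s.is_input]},
                    index=list(cols))
results = db.run_contrasts(matrix, info, cfg.doses)
print(db.affected_tss_table(results, n_total=cfg.n_tss).round(1))

lfc = pc.build_lfc_matrix(results)
assignment = pc.name_clusters(pc.cluster_tss(lfc, seed=1))
print(assignment.labeled().value_counts())
```

Output (seed 1):

```
      core_only  pause_only   both  total_affected  pct_affected
50          0.0         0.0    0.0             0.0           0.0
500        19.0        93.0   62.0           174.0           8.7
5000       68.0       137.0  126.0           331.0          16.6
any        71.0       137.0  126.0           334.0          16.7

highly-sensitive-pause    117
sensitive-both             92
highly-sensitive-both      89
highly-sensitive-core      36
```

The number of affected TSSs rises with dose, with no detectable
displacement yet at 50 nM; of the 334 TSSs affected at any dose, the
clustering recovers the generator's four sensitivity classes with adjusted
Rand index 0.989, and 99% of truly pause-site-sensitive TSSs receive the
*highly-sensitive-pause* label.

The same run from a shell:

```bash
betshift full --seed 1 --outdir run1        # all stages + summary.json
betshift simulate --seed 1 --outdir run1    # synthetic inputs + truth only
```

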