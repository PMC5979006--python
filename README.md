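# lfqde

Differential-expression analysis for label-free quantitative (LFQ)
proteomics, with proteome–transcriptome integration. The package targets
the common design in which a few biological cultures (e.g. polarizing
Th17, iTreg, activated Th0 and naïve Thp T cells) are each measured in a
handful of technical MS runs, intensities are missing not at random
(low-abundance proteins drop out), and the question is which proteins
change between conditions — and whether those changes are mirrored at the
mRNA level.

## What it computes

Starting from a MaxQuant-style `proteinGroups` table and a run design, the
pipeline:

1. **Filters** protein groups flagged as reverse hits, contaminants or
   identified only by site, and records per-run detection (intensity > 0).
2. **Preprocesses**: nondetected intensities are imputed with the minimum
   nonzero intensity of the corresponding run; technical replicates are
   collapsed to per-sample medians; values are log2-transformed and
   quantile-normalized (average-rank tie handling).
3. **Tests** each two-condition contrast with an empirical-Bayes moderated
   t-test. Per-protein variances s²_g with d_g degrees of freedom are
   shrunk toward a prior (d₀, s₀²) fitted by log-moment matching:

       s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),
       t̃_g  = log₂FC_g / sqrt(s̃²_g · c),   t̃_g ~ t(d₀ + d_g) under H₀,

   with c = 1/n for a paired design (one-sample test on per-culture
   differences) and c = 1/n_A + 1/n_B for an unpaired pooled test.
   Proteins detected in every biological sample form the *complete* tier;
   proteins with some missing values but at least one detected value per
   condition form the *partial* tier and are tested on detected values
   only (paired analyses drop cultures whose pair member is undetected).
   The prior fit and Benjamini–Hochberg adjustment run separately per
   tier. Proteins detected in only one condition are reported as
   *selectively expressed*, without a test.
4. **Integrates** with a transcript DE table: matched protein/mRNA pairs
   are classified as concordant (up/down), discordant, protein-only,
   RNA-only or neither, and the Pearson correlation of fold changes is
   reported over any class subset.
5. **Enrichment**: hypergeometric over-representation against the
   detected-protein background, and ranked GSEA with the weighted
   Kolmogorov–Smirnov running sum over scores −log₁₀(q) · sign(log₂FC),
   with gene-label permutation nulls.

A synthetic-data generator (`lfqde.simulate`) emits complete experiments
— run-level intensity tables, designs, matched transcript summaries —
with full ground truth, so every stage is testable without any download.

## Worked example

```sh
lfqde simulate --seed 1 --out sim/
lfqde de --protein-groups sim/proteinGroups.tsv --design sim/design.tsv \
      --contrast Th17:Th0 --paired --out de.tsv
```

which prints, for the default simulated design (4 conditions × 3 cultures
× 3 technical runs, 4,000 proteins):

```
388 DE proteins at q < 0.05 (3471 tested)
```

i.e. 3,471 proteins had at least one detected value in both conditions and
enough usable samples to test, and 388 of them changed significantly at
FDR < 0.05. The written table carries one row per protein with its status
(`tested` / `selective_in_*` / `not_testable`), tier, log₂ fold change,
moderated t, p, BH q and the number of samples or pairs actually used.

The same analysis from Python:

```python
from lfqde import simulate, preprocess, de

cfg = simulate.SimConfig(seed=1)
table, design, rna, truth = simulate.generate_dataset(cfg)
matrix = preprocess.preprocess(table, design)
result = de.run_contrast(matrix, ("Th17", "Th0"), paired=True)
print(result["status"].value_counts())
```

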