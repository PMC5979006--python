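# Methods

## Scope and data model

The package analyses label-free quantitative (LFQ) proteomics experiments
with a nested replicate structure: a small number of biological cultures
per condition, each measured in several technical MS runs. Intensities
are nonnegative, span many orders of magnitude, and a zero means the
protein was not detected in that run. Detection is missing not at random
(MNAR): the probability of nondetection grows as abundance approaches the
instrument's sensitivity limit. The pipeline consumes a MaxQuant-style
protein-group table; database search, raw-spectra processing and
transcript read counting/modelling are out of scope (transcript results
enter as a summary table of gene, log2 fold change, FDR).

## Preprocessing

The stages run in a fixed order; each consumes the previous stage's
output and nothing else.

1. **Row filters.** Protein groups flagged reverse, potential contaminant
   or identified only by site are removed. Absent flag columns are
   tolerated (treated as all-false, with a warning) so that synthetic or
   third-party tables need not carry them.
2. **Minimum imputation.** Every zero in run *r* is replaced by the
   minimum nonzero intensity of run *r*. This is the left-censoring view
   of MNAR missingness: an undetected protein is presumed to sit at or
   below the run's sensitivity floor. The per-run global minimum is used
   (rather than a per-protein minimum across a sample's replicates)
   because it is the only variant that is always defined. Detection is
   recorded *before* imputation and carried through the pipeline as a
   boolean mask.
3. **Median summarization.** Technical replicates collapse to one column
   per biological sample (condition × culture) by the median; a sample
   counts as detected if at least one of its technical replicates was
   nonzero before imputation.
4. **log2 transform.** Imputation guarantees strict positivity.
5. **Quantile normalization.** Each sample's order statistics are
   replaced by the across-sample mean of order statistics. Ties receive
   average ranks and the interpolated (for a tied pair: averaged)
   reference value, which keeps the map deterministic and rank-
   preserving. After this stage every sample's sorted vector is
   identical. Imputed values participate in normalization (they are real
   columns entries by this point); the statistical tests downstream do
   not use them.

## Differential expression

### Effects and variances

For contrast (A, B) with a **paired** design the analysis is a one-sample
test on per-culture differences d_i = A_i − B_i: log2FC = mean(d),
s²_g = var(d) with d_g = n − 1 degrees of freedom, and the variance scale
of the effect is c = 1/n. This is algebraically equivalent to a blocked
two-condition linear model and easier to verify. **Unpaired**: difference
of group means, pooled variance, d_g = n_A + n_B − 2, c = 1/n_A + 1/n_B.

### Empirical-Bayes shrinkage

Per-protein variances are modelled as s²_g | σ²_g ~ σ²_g · χ²_{d_g}/d_g
with a scaled inverse-chi-square prior σ²_g ~ s₀² d₀/χ²_{d₀}. The
hyperparameters are fitted by moment matching on
e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2): the excess variance of e_g beyond
ψ′(d_g/2) identifies ψ′(d₀/2) (solved by Newton iteration on the
trigamma), and the mean identifies s₀². When the observed dispersion of
log-variances is no larger than expected under equal true variances, the
fit returns d₀ = ∞ (complete shrinkage, normal-tail p-values). Exact-zero
sample variances (possible when imputed constants dominate) are floored
at 10⁻³ times the smallest positive variance before taking logs.

The moderated statistic is t̃_g = log2FC_g / sqrt(s̃²_g c) with
s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g), two-sided p from Student t with
d₀ + d_g degrees of freedom. As d₀ → 0 this recovers the ordinary t-test;
as d₀ → ∞ every variance collapses to s₀².

### Tiers, testability and selective expression

Detection drives a per-protein status:

- **tested / complete** — detected in every biological sample of the
  contrast.
- **tested / partial** — at least one detected value in each condition
  and enough usable units for a variance. Only detected values are used:
  paired analyses keep the cultures whose members are detected in both
  conditions (minimum 2 pairs), unpaired analyses keep all detected
  samples (minimum 3, both groups represented). Imputed values never
  enter a test statistic; they exist for normalization and reporting.
- **selective_in_X** — condition-level detection (≥ `min_bio` = 2
  detected biological replicates, configurable) in one condition and zero
  detected values in the other. Reported without a test, with a
  descriptive fold change from the normalized (imputed) values.
- **not_testable** — everything else.

The hyperparameter fit and the Benjamini–Hochberg step-up adjustment run
*separately* within the complete and partial tiers, so noisy
incomplete-data variances cannot contaminate the complete-tier prior, and
each tier forms its own multiple-testing family. With no missingness the
partial tier is empty and the analysis reduces to a single joint fit.
The default significance threshold is q < 0.05.

## Proteome–transcriptome concordance

Proteins without a detected transcript and transcripts without a detected
protein are removed before any percentage is computed, so all shares use
the matched, restricted denominator. Each matched pair is classified
(protein q and RNA FDR thresholds default to 0.05, independently
configurable): concordant_up / concordant_down (both significant, same
sign), discordant (both significant, opposite signs), protein_only /
rna_only (exactly one significant), neither. Agreement requires same sign
and joint significance; no fold-change-magnitude criterion is imposed.
Selectively expressed proteins are treated as significant with the sign
of the expressing condition and flagged in a separate column. The Pearson
correlation of fold changes can be computed over any class subset; note
that selective proteins' descriptive fold changes are dominated by the
imputation floor, so correlation analyses should exclude them (the
bundled acceptance analysis does).

## Enrichment

- **Over-representation**: upper-tail hypergeometric p for the overlap of
  a query (e.g. the DE set) with each gene set, against the background of
  all proteins detected in the samples of the comparison. Sets are
  intersected with the background before sizing and kept if 10–500
  members remain (conventional bounds); BH across retained sets.
- **Ranked GSEA**: features ranked by −log₁₀(q) · sign(log₂FC) (q floored
  at 1e−300, ties broken by id). The enrichment score is the extremum of
  the weighted Kolmogorov–Smirnov running sum (hit steps ∝ |score|^w
  normalized within the set, w = 1 by default; miss steps 1/(N−K)).
  Significance uses gene-label permutations — random same-size member
  sets — because with three cultures per condition phenotype permutation
  is degenerate. perm_p = (1 + #{|ES_null| ≥ |ES|})/(1 + n_perm); NES
  divides ES by the mean |ES_null| of the same sign.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with full ground truth. Latent log2 intensity per protein and run is
baseline + condition effect + culture effect + technical noise; the
observed intensity is 2^latent when detected, else 0.

Defaults (chosen once as a realistic LFQ regime):

| parameter | default | meaning |
| --- | --- | --- |
| n_proteins | 4,000 | protein groups after filtering |
| design | 4 conditions × 3 cultures × 3 tech runs | paired cultures |
| baseline | N(24, 6.6²) log2 units | marginal span well over 6 orders of magnitude |
| de_fraction | 0.10 per non-reference condition | share of proteins with a true effect |
| effect_size | 1.5 log2 units, random sign | true fold change magnitude |
| culture_sd | 1.5 log2 units | biological random effect, shared across conditions within a culture (what makes pairing informative) |
| tech_sd | 0.8 log2 units (× lognormal(0, 0.2) per protein) | technical noise with mild heteroscedasticity |
| dropout_mid / scale | 15.0 / 1.2 | logistic detection curve on latent log2 abundance |
| selective_fraction | 0.01 | proteins expressed in one condition only |
| rna_rho | 0.65 | protein–mRNA fold-change correlation among shared-DE features |

Dropout decisions are made per biological sample (from the sample's
latent mean, shared by its technical replicates) rather than per run:
match-between-runs makes real technical replicates agree on
identification almost always, and per-run-independent dropout would
produce samples whose median is the imputation floor at unrealistic
rates. The marginal detection probability is still logistic in latent
log2 abundance, so detection is monotone in abundance and missingness
concentrates in the low-intensity tail (~11% overall at the defaults).

The dropout curve was calibrated once, jointly with the noise sds,
against three statistics of a well-behaved LFQ experiment:
within-condition replicate Pearson r ≈ 0.9–0.95 after preprocessing,
overall missingness in the 10–25% band, and reasonable power at three
pairs for 1.5-unit effects. A steeper or softer curve degrades all three
at once because quantile normalization amplifies rank noise in the
sparsely populated intensity region between the imputation floor and the
detection boundary — an interaction worth knowing about in real data too.

Transcript tables are emitted as DE summaries (gene, log2 fold change,
FDR, mean expression), matching what the pipeline consumes. Among
protein-DE genes, a configurable share is also transcript-DE; their true
RNA fold changes are drawn so the correlation with the protein fold
changes equals `rna_rho` in expectation, observed fold changes add small
(sd 0.1) estimation noise, and FDRs are drawn below/above the threshold
consistently with the DE labels. A small raw-count emitter supports the
counts-per-million low-expression filter.

What the simulator does **not** model: peptide-level quantification and
razor-peptide ambiguity, retention-time or batch structure beyond the
culture random effect, correlated (co-regulated) protein modules,
transcript-level mean–variance coupling. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every artefact of real MS data.

## Numerical choices and degenerate inputs

- log base 2 everywhere; fold changes are log2 units.
- Trigamma inversion by Newton iteration with asymptotic start values;
  converges in a handful of steps for any positive target.
- BH implemented as the step-up q_(i) = min_{j≥i} p_(j)·m/j, capped at 1.
- Quantile normalization of a single sample is the identity (warned).
- A run with no detected protein, a transcript sample with zero total
  count, and a contrast naming an unknown condition are fatal errors.
- Zero-variance samples make a replicate correlation undefined (NaN).
- GSEA: a set covering the whole ranked list is rejected; a set whose
  member scores are all zero gets ES = 0.
- All simulator randomness flows from one seed through spawned
  substreams; identical configuration and seed give bit-identical tables.

## Problem sizes

The bundled tests and the acceptance script use 2,000–4,000 proteins,
10–20 simulated experiments for null calibration, and 500 matched
features for the concordance correlation — full-scale designs for this
kind of experiment, kept at a size where the whole suite runs in about a
minute on one core.

## Command-line interface

`lfqde` exposes each stage (`simulate`, `preprocess`, `de`, `concord`,
`enrich`) plus `all`, which runs a YAML-configured pipeline end to end
and writes a manifest (version, seed, parameter echo, completed stages).
Exit codes: 0 ok, 1 validation error, 2 runtime failure. All writers emit
deterministic column order, so reruns are byte-identical.
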