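# Methods

This note documents the models, conventions and numerical choices behind
`tntseq`, and what the synthetic benchmarks do and do not establish.

## Quantification

TPM uses the effective gene length supplied in the annotation table; the
bundled GTF reader derives it as the union-exon (merged exon interval)
length, but any transcript-model length can be supplied instead — the choice
is an input, not an assumption of the code. Expression thresholds are strict
(`TPM > t`), with `t = 1` as the conventional detection cutoff for this kind
of data. Sample correlations default to Pearson on `log2(TPM + 1)`; the
pseudocount of 1 keeps zeros finite while leaving the high-expression range
essentially untouched.

## Negative-binomial Wald test

A deliberately minimal two-condition NB test, transparent enough to verify
end to end:

* **Size factors** — median-of-ratios over genes with nonzero counts in all
  samples, normalised to geometric mean 1. Scaling one library rescales its
  factor and leaves fold changes essentially unchanged.
* **Dispersion** — NB variance is μ + αμ². Per-gene α comes from a pooled
  within-condition method-of-moments estimate, then is shrunk toward a trend
  α(μ) = a₀ + a₁/μ fitted by two-pass least squares (second pass trims genes
  deviating from the trend by more than a fixed ratio). Shrinkage combines
  moment and trend values *on the natural scale* with trend weight
  `PRIOR_DF / (PRIOR_DF + residual df)` (PRIOR_DF = 6, so weight 0.6 at
  3 + 3 samples). Averaging on a log scale would bias dispersions downward
  (the moment estimate is noisy but nearly unbiased, and the log of an
  unbiased estimate is not), inflating Wald statistics; the natural-scale
  combination keeps the null type-I error near nominal. Genes with a
  non-positive moment estimate take the trend value. Dispersions are clipped
  to [1e-8, 10]. With fewer than two replicates per condition the two
  conditions are pooled as pseudo-replicates (logged warning).
* **Means and the Wald statistic** — per-condition mean MLE by Newton
  iteration on the NB score (closed form Σk/Σs in the Poisson limit), the
  standard error of log₂μ from the observed Fisher information at the MLE,
  `z = log₂(μ_B/μ_A) / SE`, and a two-sided normal tail. A condition whose
  MLE is zero is floored at a pseudo-mean of 0.5 for the fold change and SE.
* **Calls** — up: p < 0.05 and log₂FC > 1; down: p < 0.05 and log₂FC < −1;
  strict inequalities, raw (unadjusted) p-values. No independent filtering,
  no outlier handling, no FDR control: the classification design downstream
  consumes raw-p calls, and all thresholds are parameters.

The statistic is cross-checked in the tests against an independent numeric
likelihood fit (bounded scalar minimisation of the NB negative
log-likelihood plus a finite-difference Hessian). Note that with a genuinely
global fold change across all genes, median-of-ratios normalisation absorbs
the shift — fold changes are identified relative to the majority-unchanged
gene set, as in any compositional count analysis.

## Translation efficiency and dual-omics classes

TE is the ratio of translatome to transcriptome TPM. It is computed per
matched replicate and averaged on the log₂ scale (the geometric mean of
per-replicate ratios), which is symmetric in the two layers and robust to a
single noisy replicate; TE is only reported where the replicate-mean TPM
exceeds the expression threshold in *both* layers. High-TE gene sets use a
strict `log₂TE > threshold` rule with presets 0, 1, 2 (TE > 1, 2, 4).

Classes cross the transcriptome call with the translatome call
(up/constant/down each, "constant" simply meaning neither call — no
equivalence test). Two cells are fixed by the oocyte analysis that motivated
the design: **Class I** = (constant, up) and **Class IV** = (down, down).
The remaining numbering is this package's own convention:

| transcriptome → / translatome ↓ | up | constant | down |
|---|---|---|---|
| **up**       | II  | VII       | VI  |
| **constant** | I   | unchanged | V   |
| **down**     | III | VIII      | IV  |

chosen so that classes I, III, IV, V are exactly the translationally changed
genes with constant-or-decreased transcription (the biologically privileged
aggregate during oocyte maturation, where transcription is globally
silenced), and so that swapping the condition order maps I↔V, II↔IV, III↔VI,
VII↔VIII. This numbering beyond Classes I and IV is *not* recoverable from
published figure legends and should be treated as local convention.

## Motif scanning and enrichment

Scanning is FIMO-style on the sense strand only (RNA). Window score
= Σᵢ log₂(pᵢ(base)/b(base)) against a zero-order background (uniform by
default; configurable). PWM cells are floored at 1e-4 when forming scores so
log-odds stay finite; the MEME reader additionally floors and renormalises
stored probabilities. The score p-value P(background window ≥ s) is exact up
to discretisation: per-position scores are rounded to integer multiples of
1e-3 log₂ units and the sum distribution is built by position-wise
convolution; window scores are summed in the same integer domain, so DP and
exhaustive enumeration agree to floating-point precision (verified to 1e-6
for motif lengths ≤ 8). Default hit threshold: score p-value < 1e-4;
overlapping hits are kept; windows containing N are skipped.

Hit filtering normalises the raw score over the motif's *attainable* range,
`(s − s_min)/(s_max − s_min)`, and keeps hits ≥ 0.8. Normalising over the
attainable range rather than the observed hit distribution makes the filter
deterministic and dataset-independent. Occurrence is the raw count of
retained hits of any motif of an RBP per gene (per-kilobase optional);
enrichment is a one-sided Welch t-test of per-gene occurrences
(target > background) with log₂FC of means using ε = 0.01, and the
significance rule log₂FC > 1 and p < 10⁻⁵ on unadjusted p-values — a
deliberately conservative raw-p rule in place of multiplicity correction.
If both groups have zero variance, p is 1 when the means are equal
(or lower) and 0 when the target mean is strictly larger. Co-occurrence
reports, for every subset of a chosen RBP list, the number of genes carrying
at least one retained hit of every RBP in the subset (upset-style counts).

The bundled `data/demo_motifs.meme` is a synthetic demonstration compendium
(consensus-style PWMs named after well-known oocyte translational
regulators); it is not a curated database and any MEME minimal file can be
used instead.

## CPE/PAS

Default consensus sets are CPE {UUUUAU, UUUUAAU} and PAS {AAUAAA, AUUAAA} —
standard literature definitions, fully configurable, and not taken from any
single study. Matching is IUPAC-aware, overlapping, case-folded, T ≡ U.
Pairing uses the nearest-end gap between elements (0 when they overlap) and
an inclusive window (gap ≤ 100 nt by default); enlarging the window can
never unpair a gene.

## Spike-in estimator

With spike share f of the transcriptome and true non-specific capture
probability p, the ratio-of-shares estimator converges to
p / ((1 − f) + p·f), i.e. a relative bias of about f(1 − p). At the
simulator default f = 0.02 and p ≈ 0.17 this is ~0.003 — an order below the
estimator's sampling noise at 10⁶ reads. Both a per-sample mean and a
pooled-count estimate are reported, since either convention is defensible;
per-spike capture ratios are returned to diagnose abundance-dependent bias.

## Synthetic data: what it does and does not emulate

The count simulator draws gene abundances log-normal (log₂ mean 5, sd 2 —
arbitrary but spanning the observed dynamic range of TPM data), plants
per-layer fold changes of |log₂FC| = 2 according to a class mix dominated by
unchanged genes with Class I/IV the most common changed classes, multiplies
the translatome baseline by a log-normal per-gene TE (log₂ sd 0.5), jitters
per-sample depth log-normally (log₂ sd 0.1) and draws NB counts at the
specified dispersion (defaults: 2000 genes, 3 + 3 samples, depth 10⁶,
α = 0.05; the null-calibration benchmark uses α = 0.1). `dispersion = 0` is
a deterministic rounding mode used for exactness tests. The UTR simulator
plants Poisson-many motif instances (defaults 5 per target vs 1 per
background UTR, 200 + 1000 genes) sampled from the PWM at non-overlapping
uniform positions in AU-rich (0.3/0.2/0.2/0.3) random sequence; the CPE/PAS
fixture generator uses a G/C-only background so planted pairing is exactly
recoverable.

Not emulated: read-level artifacts (mapping, duplicates, positional bias),
gene–gene correlation, dispersion–mean trends beyond the planted constant,
batch structure, isoform mixtures, real UTR sequence composition and motif
clustering. Passing the planted-recovery benchmarks therefore demonstrates
the correctness and calibration of the statistical machinery under its own
assumptions, not performance on real libraries.

## Numerical conventions

* Coordinates: 0-based, half-open everywhere; T ≡ U and case-folding at
  every sequence ingestion point.
* Strict inequalities at every biological threshold (TPM, p, log₂FC,
  log₂TE); the normalised-score motif filter is inclusive (≥).
* PWM rows must sum to 1 within 1e-6 after loading; rows off by more than
  0.01 in a MEME file are renormalised with a warning.
* Chi-square: Pearson, 1 df, no continuity correction by default (the
  worked 2×2 examples match the uncorrected statistic); Yates available as
  a flag.
* Determinism: all simulators take a single integer seed; identical spec +
  seed gives bit-identical outputs, and the pipeline summary is
  byte-identical across reruns of the same configuration.

## Known limitations

* The NB test is intentionally minimal; it will not numerically match more
  elaborate DE packages (no Cook's-distance outlier handling, no independent
  filtering, simpler dispersion shrinkage), though its calls agree on clear
  effects and its null calibration is verified in the tests.
* Enrichment p-values are unadjusted by design; with thousands of motifs the
  raw p < 10⁻⁵ rule controls the family-wise error only loosely.
* The exact-p-value DP cost grows with motif length × score range / bin
  width; at the 1e-3 bin it is instantaneous for motifs ≤ 30 nt but the bin
  width is the resolution limit of reported p-values.
* One 2×2 worked example in the source literature prints a p-value
  (0.08586) inconsistent with its own statistic (the upper tail at 2.9484
  is 0.08596, confirmed against two independent implementations); this
  package reports the correctly computed tail.
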