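# tntseq

Downstream analysis for **paired transcriptome + translatome sequencing**
("T&T-seq") of low-input samples such as single oocytes. Each sample is split
into a total-RNA library (transcriptome) and a ribosome-affinity-captured
library (translatome), so transcription and translation can be compared gene
by gene across developmental stages or treatments. This package implements
the full downstream pipeline — quantification, differential expression,
translation-efficiency classes, 3′-UTR motif enrichment, CPE/PAS scanning,
spike-in QC and maturation statistics — as a tested Python library with a
`tnt` command line, for computational biologists analysing such paired
count data.

## What it computes

**TPM quantification** (protein-coding genes only, union-exon lengths):

    TPM_g = 10^6 · (c_g / L_g) / Σ_j (c_j / L_j)

**Differential expression** per layer uses a negative-binomial Wald test:
median-of-ratios size factors, per-gene NB model with Var = μ + αμ², a
method-of-moments dispersion shrunk toward an `a₀ + a₁/μ` trend, per-condition
mean MLE, and `z = log2FC / SE` with a two-sided normal tail. DEGs are called
at raw *p* < 0.05 and |log₂FC| > 1 (strict). `log2FC > 0` means higher in the
second condition.

**Translation efficiency** TE = translatome TPM / transcriptome TPM (per
matched replicate, averaged on the log₂ scale; defined where both layers
pass TPM > 1). Crossing the two layers' up/constant/down DE calls assigns
each gene a **dual-omics class**: Class I = translationally up with constant
transcription, Class IV = down in both layers, etc. (full grid in
`docs/methods.md`).

**3′-UTR motif enrichment** scans UTRs with RBP position weight matrices on
the sense strand, scoring windows by the log₂ likelihood ratio against a
background model; score p-values are **exact**, computed by dynamic
programming over the discretised score distribution. Hits are min–max
normalised over each motif's attainable score range and filtered at a strict
cutoff (≥ 0.8); per-gene occurrences are compared between target and
background gene sets with a one-sided Welch t-test (significant at
log₂FC > 1, *p* < 10⁻⁵, unadjusted).

**CPE/PAS scanning** finds cytoplasmic polyadenylation elements and
polyadenylation signals (IUPAC patterns, configurable) and reports genes
with a CPE within 100 nt of a PAS (nearest-end gap, inclusive).

**Spike-in QC** estimates the translatome's non-specific capture as the
ratio of the spike-in read share of the translatome library to its share of
the transcriptome library (spike-ins are not translated, so any capture is
non-specific).

**Maturation statistics**: Pearson chi-square on 2×2 maturation outcome
tables and simple rate percentages.

A **synthetic-data module** generates ground-truth-labelled inputs for every
stage (planted dual-omics classes, planted motif instances, planted CPE/PAS
pairs, known non-specific capture), so the whole pipeline runs and is tested
without any download.

## Worked example

```python
from tntseq import (SimulationSpec, simulate_paired_counts, nb_wald_test,
                    classify_dual_omics, chi_square_2x2)
from tntseq.te_class import class_counts

spec = SimulationSpec(n_genes=2000, dispersion=0.05, seed=1)
tx, tl, truth = simulate_paired_counts(spec)

a, b = ["A_1", "A_2", "A_3"], ["B_1", "B_2", "B_3"]
de_tx = nb_wald_test(tx[a], tx[b])   # transcriptome, condition B over A
de_tl = nb_wald_test(tl[a], tl[b])   # translatome

classes = classify_dual_omics(de_tx, de_tl)
print(class_counts(classes))

recovered = (classes["class_label"].reindex(truth.index) == truth["class_label"])
print(f"label agreement with planted truth: {100 * recovered.mean():.1f}%")

stat, p = chi_square_2x2([[6, 10], [12, 4]])
print(f"chi2 = {stat:.5f}, p = {p:.5f}")
```

prints

```
class_label
I             110
II             38
III            39
IV            107
V              56
VI             21
VII            18
VIII           19
unchanged    1592
Name: count, dtype: int64
label agreement with planted truth: 99.6%
chi2 = 4.57143, p = 0.03251
```

The simulator planted ~20% changed genes (Class I and IV dominating); the
two-layer Wald tests plus the class grid recover 99.6% of the planted
labels at these settings. The 2×2 test reproduces the blocking-antibody
maturation experiment (10/16 treated vs 4/16 control oocytes failing to
mature): χ² = 4.57143, *p* = 0.03251.

The same analyses are available from the shell, e.g.

```bash
tnt chisq --table 6,10,12,4
tnt simulate counts --seed 3 --out-prefix sim
tnt quantify --counts sim_transcriptome.tsv --annotation ann.tsv --out tpm.tsv
tnt run --config pipeline.yaml          # full pipeline + JSON summary
```

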