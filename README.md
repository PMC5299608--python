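# mtcexpr

Transcriptome analysis of medullary thyroid cancer (MTC) by *RET* mutation
status, packaged as a tested, reusable pipeline.

MTC arises from thyroid parafollicular C cells and is driven by *RET*
proto-oncogene mutations — germline in hereditary disease, somatic in a
large fraction of sporadic tumours. Mutations in the cysteine-rich
extracellular region (exons 10–11, "MEN2A-like") and in the kinase domain
(exon 16, "MEN2B-like") produce different clinical phenotypes, which raises
the question of whether they also produce different tumour transcriptomes.
`mtcexpr` implements the complete analysis used to answer that question on
RMA-summarised microarray cohorts, plus the RT-qPCR stage used to validate
candidate genes on an independent sample set, and a synthetic-data generator
that reproduces the cohort structure so the whole pipeline runs and is
testable without access to patient data.

## Pipeline

1. **Probe filtering** (`preprocess`) — remove control probe sets (id
   prefix, e.g. `AFFX`) and low-variability probe sets: a probe is kept only
   if at least 15% of samples deviate from the probe median by ≥ 1.5-fold,
   i.e. |log2 x − log2 med| ≥ log2 1.5.
2. **Unsupervised clustering** (`cluster`) — Ward minimum-variance linkage
   (squared-update convention) on Euclidean distances between samples'
   log2 profiles; Newick export and k-cluster cuts.
3. **Differential expression** (`diffexpr`) — per-probe two-sided Welch
   t-test on log2 values, t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂) with
   Welch–Satterthwaite df, Benjamini–Hochberg FDR across probes, and linear
   fold change FC = mean₁/mean₂ of the linear-scale (2^x) group means.
4. **Signature classifier** (`classify`) — leave-one-out cross-validation of
   a linear SVM (C = 1); inside every fold, genes are reselected with
   Welch p < 0.001 and FC ≥ 4 (or ≤ 0.25), standardised on training-fold
   statistics. The aggregated confusion matrix yields accuracy, sensitivity,
   specificity, PPV and NPV.
5. **qPCR validation** (`qpcr`) — per-amplicon standard curves (efficiency
   E = 10^(−1/slope) − 1), geNorm reference-gene stability M and per-sample
   normalisation factor (geometric mean of reference quantities), and
   per-gene two-sided Mann–Whitney U tests with Bonferroni correction.
6. **Synthetic cohorts** (`simulate`) — 60-sample expression cohorts
   (22 hereditary / 38 sporadic; 21 MEN2A-like vs 9 MEN2B-like) with the
   published 4-gene signature planted by default (NNAT ×6.54, PTPRT ×4.06
   up in MEN2A-like; NTRK3 ×0.21, GABRR1 ×0.18 down), and 25-sample qPCR
   cohorts (16 vs 9) with NNAT ×3.3 and CDC14B ×2.8 planted.

The statistical stages follow a model/results idiom:
`DifferentialExpression(...).fit()`, `SignatureClassifier(...).fit()` and
`QPCRValidation(...).fit()` each return a results object with the estimates,
diagnostics and a `summary()`.

## Worked example

```python
import mtcexpr as m

cfg = m.SimConfig.set_b(n_probes=300, seed=7, noise_log2_sd=0.4)
matrix, ann = m.generate_expression_set(cfg)
filtered = m.filter_probes(matrix)
res = m.SignatureClassifier(filtered, ann, ("MEN2A-like", "MEN2B-like")).fit()
print(res.summary())
```

```text
LOOCV linear-SVM classifier: MEN2A-like (positive) vs MEN2B-like
selection: p < 0.001, >= 4-fold change; C = 1

confusion matrix: 21/21 MEN2A-like and 9/9 MEN2B-like correctly classified

  accuracy      100.0%
  sensitivity   100.0%
  specificity   100.0%
  ppv           100.0%
  npv           100.0%

final signature (all samples):
                 p_value       fdr  mean_group1  mean_group2  fold_change
probe_id
8128087_GABRR1 1.282e-13 1.487e-11        9.292         42.5       0.2186
8062395_NNAT    8.14e-11 4.721e-09        563.2        86.06        6.544
8066347_PTPRT   8.11e-10 3.136e-08        102.1         21.8        4.684
7991186_NTRK3  2.166e-08 6.281e-07        13.61        64.02       0.2127
```

Every fold reselected the four planted signature genes and classified all
30 held-out samples correctly; the all-sample signature recovers the planted
fold changes (e.g. NNAT 6.544 vs the planted 6.54) with BH-adjusted
significance far below the 0.05 threshold. On a null cohort
(`planted_effects=()`) no gene passes selection and every fold degenerates to
the majority-class prediction, giving accuracy 21/30 = 70%.

The same stages are available from a shell:

```sh
mtcexpr simulate --seed 7 --out-dir sim
mtcexpr filter   --matrix sim/expression.tsv --out filtered.tsv
mtcexpr cluster  --matrix filtered.tsv --newick tree.nwk
mtcexpr de       --matrix filtered.tsv --annotation sim/annotation.tsv \
                 --contrast MEN2A-like:MEN2B-like --out de.tsv
mtcexpr classify --matrix filtered.tsv --annotation sim/annotation.tsv \
                 --contrast MEN2A-like:MEN2B-like --out-dir clf
mtcexpr validate-qpcr --qpcr sim/qpcr.tsv --curves sim/standard_curves.tsv \
                 --annotation sim/qpcr_annotation.tsv \
                 --contrast MEN2A-like:MEN2B-like --out val.tsv
```

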