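# Methods

This note records the models, conventions and open design choices behind
each stage of `mtcexpr`, in the order the pipeline runs them.

## Synthetic cohorts

The generator exists so that every downstream stage can be exercised and
calibrated offline; it emulates the *structure* of the study cohorts, not
any real tumour's expression values.

**Expression model.** For probe *p* and sample *s*,

    x_ps = mu_p + delta_p * 1[s in affected class] + eps_ps,
    mu_p ~ Normal(baseline_log2_mean, baseline_log2_sd),
    eps_ps ~ Normal(0, noise_log2_sd),

on the log2 scale, i.e. probe-level baselines plus i.i.d. within-group
noise, the simplest model consistent with RMA-style log2 output. A planted
effect shifts one annotation class by `delta_p = log2(FC)`; because the
log-normal correction factor `E[2^eps]` is common to both groups, the ratio
of linear-scale group means converges to FC exactly, and the DE stage
re-estimates planted log2 effects without bias (checked to <5% at 30 per
group).

**Defaults and what they mean.**

| parameter | default | meaning |
|---|---|---|
| `n_probes` | 10 000 | probe sets after summarisation (order of magnitude of a Gene ST array after filtering) |
| `baseline_log2_mean/sd` | 6.0 / 1.5 | probe-level log2 intensity distribution; places linear means in the tens-to-hundreds range of the published tables |
| `noise_log2_sd` | 0.8 | within-group biological+technical SD. The study reports no within-group variances, so this is an assumption — a mid-range value for bulk tumour microarrays — not a measured quantity |
| `composition` | 60 samples | 22 hereditary (16 MEN2A-like, 2 MEN2B-like, 4 with RET mutations outside exons 10/11/16) and 38 sporadic (5 + 7 + 7 correspondingly, 15 RET-negative, 4 unknown); `SimConfig.set_b()` restricts to the 21-vs-9 mutation-contrast subset |
| `planted_effects` | 4 genes | the published signature fold changes: NNAT 6.54, PTPRT 4.06 up in MEN2A-like; NTRK3 0.21, GABRR1 0.18 down |

The mutation-class vocabulary includes `other` for RET mutations outside
exons 10/11/16 (screened exons 13–15); without it the published cohort
margins (22/38 origin split and 21/9 contrast classes) cannot both hold.
Family membership (two hereditary families of two samples) is annotation
only; no within-family correlation is modelled, as the original analysis
models none.

**qPCR model.** Each sample carries a log-normal loading factor shared by
all genes (SD 1.0 log2). Reference genes track it with 0.05 log2 units of
measurement noise — hence geNorm-stable by construction — while target
genes add 0.8 log2 units of biological noise and, for planted genes
(NNAT ×3.3, CDC14B ×2.8 by default), a class fold change. Cq values follow
the amplicon's standard curve `Cq = intercept + slope*log10(Q)` with
`slope = −1/log10(1+E)` (E = 1 by default, i.e. perfect doubling) plus 0.1
cycles of replicate noise; curves are 8 ten-fold dilutions in duplicate.

**What passing tests do not show.** The generator has no probe-level
effects, no array batch structure, no correlated gene modules, no
heteroscedasticity across the intensity range, and plants effects on single
probes. Calibration and recovery results on it demonstrate that the
*procedures* are implemented correctly and are well calibrated under their
own assumptions — not that the biological findings would replicate on real
tumours.

## Probe filtering

Control probes are matched by id prefix (default `AFFX`); the platform's
control sets are not enumerated anywhere in the source material, so the
prefix list is configurable. The variability rule keeps a probe iff

    #{s : |x_ps − median_p| >= log2(fold_threshold)} / n_samples >= min_fraction

with defaults 1.5-fold and 15%. Conventions chosen where the original is
silent: deviations are measured from the per-probe median of log2 values
(identical to the log2 of the linear median, since log2 is monotone; for
even sample counts the midpoint of the central pair is used), and both
boundaries are inclusive — a sample at exactly 1.5-fold deviates, and a
probe at exactly 15% is kept. The fraction is compared as
`count/n >= min_fraction` rather than `count >= min_fraction*n` so that the
boundary case is exact in floating point (3/20 == 0.15). The filter is
order-independent and monotone in the fold threshold, and is tested against
a literal per-(probe, sample) oracle.

## Clustering

Samples are clustered on unsquared Euclidean distances between log2
profiles with Ward's minimum-variance criterion in the squared-distance
Lance–Williams update (the `ward.D2` convention; scipy's `ward`). The
original description ("Ward on Euclidean distance") does not pin down the
variant; `ward.D2` is the standard pairing for Euclidean input and is
verified against a brute-force Lance–Williams implementation. No per-probe
standardisation is applied before clustering (also unstated in the source;
the filtered log2 matrix is used as-is). Newick branch lengths are parent
minus child merge heights, so root-to-tip distance equals the root height.

## Differential expression

Welch's t on log2 values with Welch–Satterthwaite df and two-sided p from
the t distribution; sidedness is a convention choice (unstated originally;
two-sided is standard for DE screens). Group means and fold changes are
computed on the linear scale (`mean(2^x)`), because the published group
means (e.g. 291.36) are clearly linear-scale while RMA output is log2. The
numerator is the first-listed contrast label. BH adjustment is the step-up
procedure (via statsmodels), tested against the literal definition.
Degenerate probes with zero variance in both groups get t = 0, p = 1 when
means are equal (with a warning) and p = 0 otherwise; p-values of exactly 0
are nudged to the smallest positive float before BH, which requires inputs
in (0, 1].

## Classifier

Linear-kernel SVM, C = 1 (the libsvm default; the original states only
"linear kernel"), features standardised to training-fold mean 0 / SD 1, log2
intensities as inputs. Selection inside each LOOCV fold: Welch p < 0.001
and FC ≥ 4 or ≤ 0.25 ("4-fold up or down"). The held-out sample never
enters its own fold's selection or scaling (property-tested by perturbing
it arbitrarily).

When no gene passes selection in a fold there is no signature to train on;
the fold predicts the training-fold majority class. This degenerate-fold
rule is a deliberate design choice: feeding the top-k smallest-p genes to
the SVM instead (the alternative fallback, available via
`select_features(fallback=True)` and used for the reported all-sample
signature) selects spuriously separating noise genes, whose LOOCV
predictions are nearly independent of the true label and drag null-data
accuracy below the majority rate. With majority prediction, a cohort with
no differential expression yields LOOCV accuracy exactly at the
majority-class rate (21/30 = 70% at the study's class sizes), which is the
behaviour a calibrated procedure should have; with real four-fold effects
the fallback never triggers.

Metrics use the standard definitions: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), with the
first-listed class as positive and NaN (not zero) for undefined ratios.
Note that the published per-class outcome 20/21 and 7/9 gives sensitivity
95.2% and specificity 77.8% under these definitions, whereas the published
table prints 91% and 87.5% — values that coincide with 20/22 and 7/8, i.e.
with PPV/NPV-style column ratios. The package reports the standard
definitions and leaves the discrepancy visible rather than guessing the
intended convention.

## qPCR validation

Replicate Cq values are averaged per sample/gene before quantification
(replicate handling is unstated originally). Quantities come from each
amplicon's own standard curve, `Q = 10^((Cq − intercept)/slope)`; efficiency
is `10^(−1/slope) − 1`, so perfect doubling gives slope −3.3219 and E = 1.
geNorm stability for reference gene j is the mean over other references k
of the sample SD (ddof = 1) of `log2(Q_j/Q_k)`; the per-sample normalisation
factor is the geometric mean of reference quantities, defined up to a
global scale that cancels in group comparisons. The iterative
least-stable-gene exclusion is provided (`genorm_stepwise_ranking`) but the
validation stage uses the fixed a-priori three-gene reference set
(EIF3S10, HADHA, UBE2D2).

Group comparisons are two-sided Mann–Whitney U tests: exact null
distribution when there are no ties and ≤ 20 observations in total (the
study's 16 + 9 cohort exceeds this), otherwise the normal approximation
with tie and continuity corrections. Bonferroni family size defaults to the
number of genes tested in the run (9 in the validation design, after one of
ten assay failures); fold change is the ratio of group means (not medians —
unstated originally, means documented here) of normalised quantities.

## Problem sizes in tests and the acceptance script

Calibration and recovery runs use 300-probe cohorts at the study's 21-vs-9
class sizes (50 seeds for null LOOCV calibration, 11 for planted recovery,
8 replicate qPCR cohorts), sizes at which the Monte-Carlo error of each
reported mean is well below the tolerances being checked while the full
suite runs in seconds. The qPCR fold-change *tolerance* check (±20%) uses
60-per-class cohorts, since at 16-vs-9 the sampling error of a ratio of
means under 0.8 log2-units of noise exceeds 20% by itself; at the study's
own size the planted NNAT effect is instead checked for Bonferroni
significance, which is the study-scale claim.

## Known limitations

- No moderated-variance (empirical Bayes) testing, by design: the original
  analysis uses plain Welch tests.
- One probe set per gene; no probe-to-gene collapsing (an optional
  probe→symbol map is the caller's responsibility).
- No bootstrap support or consensus clustering; no nested hyperparameter
  tuning for the SVM.
- The ΔΔCq method is intentionally absent; quantification is via standard
  curves throughout.
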