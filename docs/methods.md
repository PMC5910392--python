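# Methods

`miratio` implements a biomarker-discovery workflow for circulating
miRNA measured by qPCR panels in blood plasma: quality control, two
reference-free normalizations, multi-group differential testing with
false-discovery-rate control, cross-dataset consistency checks, and
sparse-classifier signature selection with resampling-based stability
assessment. This note records the statistical model behind each stage,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Data model

A qPCR panel yields one quantification cycle Cq(s, i) per sample *s* and
assay *i*; lower Cq means more template (each cycle is a factor of two,
so Cq differences are log2 expression differences). An assay that never
crosses the fluorescence threshold is *undetected*; such entries are
stored as missing with an explicit boolean flag, never as a sentinel Cq,
because sentinel values silently corrupt group means.

Samples carry a group label — SCC (squamous cell carcinoma), AD
(adenocarcinoma), HD (healthy donors), EB (endobronchitis, a
non-cancerous inflammatory control) — and a dataset label (discovery or
verification). SCC and AD are combined into the lung-cancer class for
classification; HD and EB form the non-cancer class.

## Quality control

**Haemolysis gate.** Red-blood-cell lysis floods plasma with
erythrocyte miRNAs and distorts the profile. The per-sample score is
ΔCq = Cq(miR-23a) − Cq(miR-451a); miR-451a is the canonical erythrocyte
marker, so haemolysed samples show a large ΔCq. Samples pass only when
ΔCq < 7.5 cycles (strict inequality; a sample at exactly 7.5 fails).
Samples whose marker assays are undetected are excluded with reason
`qc_marker_missing` rather than passed: an uncomputable gate fails safe.

**Call-rate gate.** Assays detected in fewer than 80% of (retained)
samples are excluded. The boundary is inclusive — exactly 80% is kept —
and configurable; the sample gate runs first so call rates are computed
over the samples that survive.

**Haemolysis blocklist.** Downstream feature lists can additionally be
filtered against a mapping of miRNA → tier (`strong` / `tentative`).
`stringent` mode removes any feature (assay or ratio) touching a
blocklisted miRNA; `semi_stringent` only those touching `strong` ones.
The shipped default list (miR-451a, miR-486-5p, miR-92a-3p strong;
miR-16-5p, miR-25-3p, miR-106b-5p tentative) is literature-derived and
meant to be replaced by a study-specific list.

## Normalization

Plasma has no validated housekeeping miRNA, so two reference-free
transforms are used.

**Global mean.** dCq(s, i) = mean_j Cq(s, j) − Cq(s, i), the mean taken
over assays observed in sample *s*. Higher dCq = more abundant. The sign
convention makes an up-regulated marker show a higher group mean dCq and
a positive fold change. Per sample the observed dCq values average to
zero by construction.

**Pairwise ratios.** For every unordered assay pair {a, b} (canonical
orientation: a before b lexicographically), the feature "a/b" has value
Cq(s, b) − Cq(s, a) = dcq(s, a) − dcq(s, b); positive means a is more
abundant than b. Ratios cancel the per-sample offset *exactly*, making
them invariant to plasma input amount, extraction yield and global batch
shifts — the property that makes them transferable across experiments
without a normalizer. k retained assays give k(k−1)/2 features. A sample
contributes to a ratio only when both members are detected
(pairwise-complete); no imputation is performed, because imputing Cq
values would manufacture signal.

**Fold change.** For group means m1, m2 (dCq units), d = m1 − m2 and
the signed linear fold is +2^d for d ≥ 0 and −2^(−d) for d < 0, so the
magnitude is always ≥ 1 and the sign encodes direction. Tables report
one decimal; full precision is kept internally.

## Differential testing

Two-group comparisons use the two-sided two-sample t-test, Welch by
default (panel data routinely shows unequal group variances; Student is
available by flag), or one-way ANOVA for two or more groups (for two
groups F = t² of the pooled t-test, which the suite verifies). Matched
tumour/normal expression uses the paired Wilcoxon signed-rank test on
log2 values with a 0.5 pseudo-count (RPM tables contain zeros);
zero-difference pairs are uninformative, and fewer than five informative
pairs flags the feature instead of testing it.

Benjamini–Hochberg adjustment is applied within each comparison's
feature family (per group pair, per feature type). Features whose groups
hold fewer than two observations are flagged untested and do not enter
the BH family. p_adj ≥ p_raw and p_adj ≤ 1 always.

Downstream filters:

* **Magnitude**: keep features with |group mean difference| ≥ 1 cycle
  (inclusive), i.e. at least a two-fold expression difference.
* **Consistency**: keep features BH-significant in both discovery and
  verification with the same sign of effect.
* **Pooling gate**: the two datasets may be pooled only if no shared
  feature's two-sample Kolmogorov–Smirnov test rejects at BH-adjusted
  0.05 within the HD group or within the combined LC group. An empty
  feature set pools vacuously but is flagged.
* **Connection degree**: each miRNA's count of significant ratios; the
  degree sum is twice the ratio count (handshake lemma). Hubs suggest
  either strong deregulation or unusually stable expression — the
  summary reports counts and leaves interpretation to the analyst.

## Signature selection

The classifier is L1-penalized (LASSO) logistic regression of cancer
(=1) vs non-cancer on ratio features, fitted by minimizing

    (1/n) Σ log-loss + λ ‖β‖₁

with an unpenalized intercept over features standardized to mean 0 /
SD 1. Coefficients are reported on the standardized scale; the model
serialization stores centers and scales so predictions are reproducible
from raw values.

* **AUC pre-filter.** Only features whose single-feature AUC (oriented,
  so AUC ≥ 0.5) exceeds 0.7 enter the regression. AUC is computed in its
  Mann–Whitney form with half-credit ties.
* **λ selection.** Stratified 5-fold cross-validation minimizes the
  pooled out-of-fold Brier score over a geometric grid of 100 values
  from λ_max (the smallest penalty giving the all-zero model,
  max|X'(y − ȳ)|/n) down to 10⁻⁴·λ_max. Standardization happens inside
  each training fold. Exact ties on the minimum resolve to the largest
  (most parsimonious) λ.
* **Bootstrap enhancement.** 2000 iterations by default. Each iteration
  draws a stratified random 2:1 train/test split of the samples
  (Monte-Carlo cross-validation; `resample_first=True` instead draws a
  bootstrap resample with replacement before splitting — both readings
  of "bootstrap with a 2:1 split" are exposed, the split-only form is
  the default because it keeps test sets free of training duplicates),
  re-optimizes λ by CV on the training part, fits, and records the
  test-set AUC and the set of nonzero coefficients. A per-iteration
  λ re-optimization is the default; a single global λ can be fixed.
* **Aggregation.** Selection frequency = fraction of iterations with a
  nonzero coefficient. Variable importance ranks by selection frequency
  with ties broken by mean |coefficient| (mean over all iterations).
  The 95% CI reported for the AUC is a normal-theory CI *of the mean*
  over iterations — very narrow at 2000 iterations by construction —
  alongside the 1st/3rd quartiles of the AUC distribution.
* **Final model.** Fitted on all data at the CV-optimal λ and evaluated
  by resubstitution ROC/AUC. Resubstitution is optimistic; it is the
  honest option only in the absence of an independent validation
  cohort, and is labelled as such.

### Numerical choices

The penalized fit uses FISTA (accelerated proximal gradient with
adaptive restart) with step size 1/L, L = ‖[1, X]‖₂²/(4n), the Lipschitz
constant of the logistic gradient. Soft-thresholding produces exact
zeros at every iterate, so "selected" is exact, and for λ ≥ λ_max the
solution is exactly the null model with intercept logit(ȳ) (the suite
checks both, plus agreement with an independent solver to 10⁻⁶). An
entire λ path is solved as one batched FISTA run (one column per λ, with
per-column momentum, restart and convergence tracking), which is what
makes per-iteration CV re-optimization affordable. Convergence is
declared at a maximum coefficient change below 10⁻⁷ (10⁻⁸ for final
fits), capped at 2000 iterations per path during CV — on nearly
separable data coefficients at the smallest penalties grow without
bound, and the cap truncates that divergence after the probabilities
have saturated. Constant features are dropped with a warning (detected
with a tolerance of 10⁻¹⁰ relative to the column mean, absorbing
floating-point cancellation).

## Synthetic data

The generator produces Cq cohorts with the structure the analysis
assumes:

    Cq(s, i) = μ(i) − effect(i, group(s)) + offset(s)
               + batch(dataset(s)) + h(s)·susceptibility(i) + ε(s, i)

* μ(i): per-assay baseline, uniform on [22, 33] cycles, drawn from a
  dedicated `baseline_seed` because baselines are properties of the
  assay panel — two cohorts run on the same panel share them, while the
  cohort seed drives everything sample-specific.
* effects are specified in dCq units and applied as Cq *decrements*
  (lower Cq = more template), matching the normalization convention.
* offset(s) ~ N(0, 1.0 cycle) by default: per-sample plasma input and
  extraction-yield variation. It cancels exactly in ratios and in dCq.
* ε ~ N(0, within_sd), default 0.8 cycles, the middle of the 0.5–1.5
  cycle combined assay-error range typical for this measurement type.
* haemolysis: a configurable fraction of samples gets a contamination
  level h ~ U(5, 10) cycles; susceptible assays shift by
  h·susceptibility (miR-451a −1.0, miR-23a −0.1 per cycle of h), so the
  ΔCq of contaminated samples lands in ~[6.5, 11] and the 7.5 gate
  splits them realistically — the QC stage is exercised in both
  directions.
* detection limit: Cq > 37 (configurable) becomes undetected/missing.

The matched-tissue generator draws per-patient log2 baselines with
between-patient SD 1.0 and within-pair SD 0.5, adds planted log2 effects
to the tumour side, and exponentiates to RPM-like values.

What the generator does **not** emulate: amplification-efficiency and
probe-chemistry differences, inter-plate calibrators, correlated miRNA
co-regulation (assays are independent given the sample effects),
heavy-tailed or outlier-prone noise, and missingness that is informative
beyond the detection limit. Passing tests therefore demonstrate that the
*procedures* behave as specified under the assumed model — calibrated
type-I error, FDR control, planted-effect recovery — not that real
plasma cohorts will reproduce any particular published effect.

One known attenuation: global-mean normalization shrinks a planted dCq
effect by the factor (1 − 1/k) for k assays, because the planted assay
moves its own sample mean. Ratio features do not suffer this.

## Problem sizes used in the checks

The calibration study uses 50 null cohorts of 30 + 30 samples × 40
assays; the power study 100 cohorts of 14 + 10; the signature-recovery
study plants 2.0-cycle effects on 5 of 50 disjoint-pair ratio features
(50 cancer / 30 control) and runs 200 bootstrap iterations — the
bootstrap count is scaled down from the 2000-iteration default, which
changes Monte-Carlo precision of the summaries but not the procedure.

## Known limitations

* The pooling gate tests distributional equality feature-by-feature;
  it has no power against dataset differences expressible as per-sample
  offsets (by design — ratios remove those) and limited power at small
  group sizes.
* With strongly separating features the Brier-optimal λ sits at the
  small end of the path and the final model is denser than the
  importance ranking suggests; the selection-frequency ranking, not the
  single final fit, is the stability statement.
* Resubstitution AUC overstates out-of-sample performance; the bootstrap
  test AUC distribution is the better estimate, and an external cohort
  is the only real validation.
* `student`/`welch`/`anova` operate on whatever samples observed each
  feature (pairwise-complete), so effective group sizes vary across
  features in the presence of censoring.
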