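# Methods note

This note records the statistical model, the parameter choices and the
numerical decisions behind `vinomics`, so that every computed quantity
can be traced to an explicit definition.

## Study design model

Two cellar layouts are supported, each with one wine aged in an old and a
new oak barrel and one analytical sample per (barrel, time-point):

- **FB**: barrel samples at months 0, 3, 6 and 9 from both barrels, plus
  month 12 from the new barrel only (the old barrel is emptied before
  month 12). Nine samples.
- **ICVV**: barrel samples at months 0, 3, 9 and 12 from both barrels,
  plus one bottled aliquot per barrel analysed at month 12. Ten samples.

Factor groups (`build_grouping`):

- `barrel_type` — old vs new pooled over months {0, 3, 6, 9} (FB, 4 per
  group) or months {3, 9, 12} (ICVV, 3 per group).
- `time` — months pooled over barrels: {0, 3, 6, 9} for FB and
  {3, 9, month-12 barrel, month-12 bottle} for ICVV, 2 per group.
- `bottled_wine` — month-12 barrel vs month-12 bottle (ICVV, 2 per
  group).

These groupings deliberately treat the two barrels (or the two vessels)
as the replicates within each level; with one analytical sample per
barrel and time-point no other replication exists.

## Differential significance

- **Tests.** Two-group factors use the pooled-variance two-sample
  *t*-test (Welch available via a flag); the multi-level time factor uses
  one-way ANOVA. Both are computed by `scipy.stats`. Degenerate inputs
  (all-constant groups) are assigned p = 1; perfectly separated constant
  groups are assigned the smallest positive float rather than 0.
- **Multiplicity.** Benjamini–Hochberg step-up adjustment per platform
  and factor: with order statistics p(1) ≤ … ≤ p(m),
  q(i) = min over j ≥ i of min(p(j)·m/j, 1). The implementation is
  vectorised (stable argsort + reverse cumulative minimum) and is tested
  for exact agreement against a literal double-loop oracle and against
  `statsmodels.stats.multitest`.
- **FCMM.** Fold change of maximum over minimum: max/min of the values
  pooled across the factor's samples. FCMM is a linear-domain quantity;
  when tests run on variance-stabilised values, FCMM is computed on the
  back-transformed (`2**value`) matrix.
- **Combined call.** significant ⇔ q ≤ α (default 0.05) and FCMM ≥ 2
  (default). Both thresholds are `RunConfig` fields.

## Preprocessing of untargeted intensities

Applied only to peak-area platforms (untargeted GC-MS, LC-MS); targeted
concentrations are analysed as reported (missing cells, if any, are
imputed).

1. **Missingness filter.** Metabolites missing in > 40 % of samples are
   dropped (`max_missing_frac = 0.4`).
2. **kNN imputation** (`k = 10`). Neighbours are metabolite rows;
   distances are root-mean-square differences of log intensities over
   co-observed samples (normalised by the co-observation count so
   profiles with different coverage are comparable). A missing cell takes
   the mean of the k nearest metabolites observed in that sample; if no
   neighbour qualifies, the metabolite's median is used.
3. **Outlier screen.** Samples are projected onto the first two PCoA
   axes of the Euclidean distance matrix (log2 scale for raw-intensity
   input); k-means is run for k = 2…4 and the silhouette-optimal k kept.
   A sample is flagged only if it is a singleton cluster **and** lies
   more than 3× the root-mean-square spread of the remaining samples
   from their leave-one-out centroid. The separation guard exists
   because, on exchangeable data with n = 8, flagging every
   silhouette-optimal singleton produces a ≈ 93 % false-flag rate;
   with the guard the measured false-flag rate is 0.5 % over 200 null
   simulations while a planted 20-SD outlier is still flagged with
   power 1.0. Flagged samples are reported and optionally removed
   (`remove_outliers`, default off given the tiny designs).
4. **VSN.** Sample calibration factors are median quotients against the
   geometric-mean reference profile, followed by the generalised log
   transform glog_a(x) = log2((x + sqrt(x² + a²))/2) with the offset `a`
   set to the 5th percentile of the calibrated values. Variance
   stabilisation is quantified as the slope of per-metabolite SD against
   mean rank (rank/m): on data with multiplicative noise (CV 0.2) plus an
   additive floor at 5 % of the median baseline, the post-glog |slope| is
   ≈ 0.08–0.16× the plain-log2 |slope|. The property holds whenever the
   additive component is comparable to or below a/CV; with a pinned to
   the 5th percentile, a much larger additive floor would require a
   larger offset to stabilise fully.

## Growth-rate kinetics

Growth coefficient between consecutive replicate-mean concentrations C1
(earlier) and C2 (later):

- increase (C2 ≥ C1): k = 1 + (C2 − C1)/C1 = C2/C1
- decrease (C2 < C1): k = 1 + (C1 − C2)/C1 = 2 − C2/C1

Both branches give k ≥ 1, so magnitudes of rises and falls are
comparable; the mapping is not invertible across branches (a 2-fold rise
gives 2.0, a 2-fold fall gives 1.5). A signed variant (k = C2/C1) is
available via `signed=True` where directional ratios are wanted.
Undefined for C1 ≤ 0.

Period schedules: FB {0–3, 3–6, 6–9, 9–12}, ICVV {0–3, 3–9, 9–12},
bottled comparisons {0–12} (barrel series and bottle endpoints against
the month-0 barrel value). Periods whose endpoint is absent for a series
(old FB barrel at month 12) are dropped with a logged warning.

Growth-rate rows (period × series) are clustered with
`scipy.cluster.hierarchy` (average linkage, Euclidean by default). Rows
are pre-sorted lexicographically by label before linkage so that merge
order — and the exported Newick string — is invariant to input row
order even under distance ties.

Replicate-mean trajectories are labelled: **U** if Spearman ρ ≥ +0.5 and
final/initial fold ≥ 1 + tolerance (default 0.2); **D** by the mirror
rule; **S** if the trajectory peaks in the interior or its end fold is
within tolerance of 1 (constant series are S); otherwise the direction
of the larger end fold. The labels are scale-invariant.

## Ordination and PERMANOVA

- **PCoA.** Gower centring B = −½·J·D²·J, symmetric eigendecomposition,
  coordinates = eigenvector·sqrt(λ) for eigenvalues above a relative
  tolerance (1e-12·|λmax|); axis signs are fixed by making the
  largest-magnitude coordinate positive. Explained proportions are
  λ/Σλ⁺. Loadings are Pearson correlations between metabolite values and
  axis scores (zero-variance metabolites get loading 0 and are flagged).
  Cross-checked against scikit-bio.
- **PERMANOVA.** Anderson's pseudo-F =
  (SS_between/(a − 1))/(SS_within/(N − a)), with SS_total the sum of squared
  distances over unordered sample pairs divided by N, SS_within the
  analogous per-group sums divided by each group's size, and
  SS_between = SS_total − SS_within. When the number of distinct
  group assignments is ≤ 10,000 the null is enumerated exactly and
  p = (#assignments with F ≥ F_obs)/(#assignments), observed included;
  the study's own 4-vs-4 design therefore has a discrete null with 35
  outcomes and a minimum p of 1/35 ≈ 0.029. Larger designs fall back to
  a seeded Monte-Carlo null with p = (1 + #extreme)/(1 + n_perm).
  Type-I calibration at α = 0.05 is verified on a two-group design of
  10 + 10 samples (Monte-Carlo branch, 199 permutations), where the
  p-grid is fine enough for a binomial-CI check to be meaningful; on the
  exact 4-vs-4 grid the achievable levels are multiples of 1/35, so the
  test there is conservative at 0.05 by construction.

## Synthetic data generator

`simulate_dataset` draws, per platform:

- log-normal baselines (platform-specific log-mean, `baseline_log_sd`
  default 1.0);
- planted trend exponents w(t) over the time-point index so that the
  trajectory reaches `effect_fold` at its extreme: U rises
  geometrically, D is its reciprocal, S peaks at the middle time-point;
  exact counts round(fraction·m) of metabolites per trend class placed
  by a seeded permutation (so "200 planted among 1,000" means exactly
  200);
- optional barrel and bottling effects multiplying the new-barrel or
  bottle samples of a seeded subset of metabolites;
- multiplicative log-normal noise with σ = sqrt(ln(1 + CV²)), plus an
  optional additive floor (`additive_sd_frac` of the median baseline)
  for untargeted platforms;
- missingness by left-censoring below the intensity quantile matching
  `missing_rate` (MCAR available via a flag), reflecting
  detection-limit dropout.

Realism notes and limits: the generator reproduces the study's sample
layout, platform sizes (39/5/394/502 features by default), intensity
scales, heteroscedastic noise and censored missingness, but it does not
model chromatographic drift, batch effects, correlated metabolite
modules, or chemical identities; trends are monotone/peaked geometric
idealisations. Recovery results on it therefore measure the pipeline's
statistical behaviour, not instrument-specific artefacts.

`recovery_report` compares calls against the planted truth:
sensitivity, specificity, empirical FDR over metabolites with planted
factor effects, and a U/D/S confusion matrix when trend labels are
supplied. At effect fold 4, CV 0.1 and 200 planted among 1,000
metabolites, the documented untargeted path (VSN-stabilised tests, FCMM
on the linear domain) achieves sensitivity 0.905 with empirical FDR 0.0
(seed-fixed test); trend labels are 100 % correct on noiseless
trajectories. Testing raw log-normal intensities instead costs ~2–3 %
sensitivity through ANOVA heteroscedasticity, which is why the pipeline
normalises before testing.

## Determinism

Every stochastic stage receives a child seed derived from the master
seed as (seed·1,000,003 + crc32(stage)) mod 2³¹, so stages are
independent but fully reproducible. JSON outputs are written with sorted
keys; identical configuration and seed produce byte-identical files.
CSV round-trips are bit-exact (`repr`-based float formatting on write,
round-trip float parsing on read).

## Limitations

- With one analytical sample per barrel and time-point, "replicates"
  within factor levels are pooled design cells, not independent
  biological replicates; p-values are descriptive screening statistics
  rather than confirmatory inference.
- The FCMM ≥ 2 threshold and α = 0.05 are screening conventions, not
  optimised decision rules.
- glog with `a` at the 5th percentile stabilises variance only when the
  additive noise floor is modest (see VSN section).
- Exact PERMANOVA p-values on the tiny designs have coarse discrete
  nulls (minimum 1/35 or 1/105); "significant" there can never mean
  p < 0.01 for two-group factors.
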