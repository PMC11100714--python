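# Methods

This document describes the generative model, the analysis estimators, and the
numerical choices behind `adaptscan`. The package simulates and analyses a
visual category study with two event designs (a category localizer and an
fMRI-adaptation paradigm), scales from single-voxel GLMs to group mixed
models, and includes single-case statistics for comparing individual patients
to a control sample.

## 1. Experimental designs

### 1.1 Category localizer

A block design with five stimulus categories (faces, objects, words, houses,
phase-scrambled images). Each run contains 15 stimulation blocks — three per
category — interleaved with 16 fixation rests:

- block: 16 stimuli x (0.8 s image + 0.2 s blank) = 16 s
- rest: 8 s
- run: 16 x 8 + 15 x 16 = 368 s = 6 min 8 s, i.e. 184 volumes at TR = 2.0 s

Each block contains one immediate-repeat probe for a one-back task. The block
order is a fixed pseudo-random sequence shared by all runs and participants
(generated once from a frozen internal seed), so designs are identical across
the cohort, as in a real scanner protocol.

### 1.2 Adaptation paradigm

A mini-block design crossing three categories (faces, objects, words) with
three repetition conditions:

- **different**: 12 distinct exemplars per block (no repetition),
- **alternating**: two exemplars in alternation (ABAB...),
- **same**: one exemplar repeated 12 times; four `same` exemplars rotate
  across a run's four cycles.

Each mini-block shows 12 stimuli x (0.25 s + 0.05 s gap) = 3.55 s. A run has
36 mini-blocks (4 cycles x 9 category-condition block types) separated by
fixation intervals of 6, 7.5, or 9 s, with no two consecutive blocks from the
same category. TR = 1.5 s. Exemplar pools are disjoint across conditions:
12 (different) + 2 (alternating) + 4 (same) = 18 unique exemplars per
category per run. Participants monitor the fixation dot, which changes colour
exactly nine times per run — once during one block of each of the nine block
types (cycle assignments 2/2/2/3 across the four cycles).

## 2. Voxel-level generative model

### 2.1 Neural drive and repetition suppression

Each stimulus event contributes a neural drive `selectivity[category] *
f^k`, where `f <= 1` is a fatigue (repetition-suppression) factor and `k` is
the repetition exponent. In the default `exemplar_memory` mode, `k` counts
prior occurrences of that exact exemplar within the block, giving per-block
mean attenuations with closed forms:

- different: 1
- alternating: (1/n) * sum_{i=0}^{n-1} f^(i div 2)
- same: (1/n) * sum_{k=0}^{n-1} f^k

(`expected_condition_attenuation` implements these.) An `immediate` mode
(`k` = length of the current run of identical exemplars) is also available.
Because the attenuations are strictly ordered for `f < 1`, the generator
guarantees different > alternating > same amplitudes — the classic
fMRI-adaptation signature.

### 2.2 Haemodynamics and noise

Event drives are convolved with a haemodynamic response: the canonical
double-gamma (unit peak at 6 s, undershoot at 16 s, ratio 1/6) for the
localizer, and the single-gamma basis `(t/(p q))^p exp(p - t/q)` with
`p = 8.6`, `q = 0.547` (unit peak at `p*q = 4.7042 s`) for the rapid
adaptation design. Convolution runs on a 0.05-s grid and is then sampled at
the TR. On top of a baseline of 1000 units, the simulator adds AR(1) Gaussian
noise (`noise_sd`, `ar1`) and optional motion regressor leakage.

A deliberate numerical choice: with `within_block="distributed"`, the
per-block summed drive is spread uniformly over the block's events. The
noiseless signal is then *exactly* in the span of the unit-height condition
regressors used by the GLM, so noiseless recovery is an exact oracle (errors
at machine precision) rather than an approximation. The alternative
`per_event` mode keeps event-level heterogeneity but gives only approximate
recovery.

### 2.3 Oracle for recovered betas

Time series are scaled to percent of the run mean before fitting. Because the
task signal itself contributes to the run mean, the noiseless ground truth for
a condition beta is

    beta = selectivity * 100 / mean(raw run signal)

not `selectivity * 100 / baseline`. The unit tests check recovery against
this oracle at 1e-8 (observed errors ~1e-14). Similarly, the fitted
`same`/`different` beta ratio equals `expected_condition_attenuation("same",
12, f)` to machine precision in the noiseless case.

## 3. First-level analysis

- **Scaling and censoring** (`scale_and_censor`): grand-mean scaling to 100,
  censoring of volumes with framewise displacement above 1.0 (plus the next
  volume) and of MAD outliers (k = 5.5); runs with more than 10% censored
  volumes are flagged.
- **Design matrix**: one unit-height boxcar regressor per condition convolved
  with the paradigm's HRF, Legendre drift polynomials (order `1 +
  duration//150`), demeaned motion parameters, and an intercept. Rank is
  checked and deficient columns are named in the error.
- **GLM** (`fit_glm`): OLS, or prewhitened GLS with an AR(1) coefficient that
  is either supplied or pooled from residual lag-1 autocorrelation. Outputs
  per-voxel betas, residual variance, and the task-block parameter covariance
  for t-contrasts.

## 4. ROI definition and held-out amplitudes

Category-selective ROIs are defined from localizer contrasts (target category
vs the mean of the remaining categories) thresholded at voxel p = 0.001 and
cluster-corrected. Cluster extent thresholds come from a Monte-Carlo
simulation in the analysis mask (`estimate_cluster_threshold`): Gaussian
noise smoothed to the target FWHM, restandardized within the mask,
thresholded one-sided, labelled with face connectivity; `k_min` is the
smallest extent whose family-wise false-positive rate across iterations is at
most alpha. This is the same logic as AFNI's 3dClustSim, re-implemented in
scipy so the null is fully reproducible from a seed. At the default settings
(20 x 20 x 10 mask, FWHM 2 voxels, voxel p = 0.001, alpha = 0.05, 2000
iterations) the threshold is 7 voxels and the realized FWE rate is ~0.05.

To avoid selection bias ("double dipping"), ROI definition and amplitude
estimation use disjoint runs: the pipeline defines ROIs on run 0 and computes
category-selectivity amplitudes (`cs_amplitude`, the median held-out contrast
within the ROI) on the remaining runs. `cs_amplitude` refuses run overlap.

## 5. Adaptation and RSA measures

Within each ROI, `responsivity` is the median beta per condition and
`rs_magnitude = beta(different) - beta(same)` for the ROI's preferred
category.

Representational similarity analysis builds 9 x 9 Pearson-correlation
similarity matrices over the nine block types from voxel activation patterns,
and compares them with Spearman rank correlation to three model RDMs with
pinned similarity values {0-step: 1, 1-step: 0.5, 2-step: 0}:

- **CS** (category selectivity): similarity depends only on whether two block
  types share a category.
- **RS** (repetition suppression): similarity depends only on the distance
  between repetition conditions (same/alternating/different).
- **CS_RS**: within-category pairs are graded by condition distance;
  across-category pairs are 0.

Model fits are Fisher-z transformed; group averages use
`tanh(mean(atanh(r)))`. Group RDM comparisons use Kendall tau-b with
min/max permutation envelopes over group-label shuffles.

The measure-level cohort generator samples activation patterns from a
covariance that realizes the CS_RS similarity structure scaled by 1/2 (to
keep the matrix positive definite); with pattern noise the expected model-fit
ordering is CS_RS > CS > RS.

## 6. Cohort generator

`CohortSpec` defaults encode the study conditions: 21 typically developing
(TD) controls scanned in both hemispheres, 12 control patients and 9
occipitotemporal-resection (OTC) patients contributing their structurally
preserved hemisphere; ages ~ N(16, 5) truncated to [7, 38].

Two generator tiers share the same calibration targets:

1. **Time-series tier** (`simulate_cohort` / the pipeline): full voxel grids
   with planted selective clusters, localizer + adaptation runs, noise and
   motion; all downstream measures are *estimated* by the actual analysis
   code. `solve_adaptation_tuning` inverts the closed-form attenuations so a
   hemisphere's planted (fatigue, selectivity) reproduce target responsivity
   and RS magnitude in expectation.
2. **Measure tier** (`simulate_measures`): draws the derived measures
   directly from Gaussians centred on the calibration targets with empirical
   between-/within-participant spreads; used for the statistical calibration
   studies where thousands of cohorts are needed.

Group effects enter as additive `effect_deltas` per group and measure (e.g.
an OTC repetition-suppression deficit of -0.1). Behavioural accuracy is
binomial per task with group-specific probabilities and chance-level
exclusion rules.

**Realism and limits.** The generator reproduces first-order structure
(means, spreads, condition ordering, RSA geometry) but not everything: in the
time-series tier the planted voxel tuning is category x fatigue only, so its
activation patterns follow a geometry in which the pure-CS model can fit as
well as or better than CS_RS; the calibrated CS_RS > CS ordering is a property
of the measure/pattern tier. Spatial noise is i.i.d. plus smoothing, there is
no physiological noise model, and motion couples only linearly.

## 7. Group statistics

### 7.1 Mixed model

`fit_lmem` fits a random-intercept linear mixed model with a custom profiled
likelihood: for `V = sigma^2 (I + lambda Z Z')` with grouped random
intercepts, GLS quantities reduce to blockwise shrinkage weights
`w_i = lambda / (1 + lambda n_i)`, so each candidate `lambda` costs one pass
over the data; the scalar `log lambda` is optimized on [-12, 8] by bounded
minimization. Both ML and REML criteria are implemented (REML adds the
`-1/2 log|X' V^-1 X|` term and uses `n - p` degrees of freedom). The fitter
matches `statsmodels` `MixedLM` to ~1e-6 in parameters, standard errors, and
variance components, but runs in ~1 ms, which is what makes permutation tests
with tens of thousands of refits affordable.

**Estimation policy.** REML is the default for estimation, standard errors,
Wald tests, and estimated marginal means, because ML variance components are
biased low at these sample sizes (ML confidence intervals for an injected
group effect covered at ~90% instead of 95%; REML restores ~94.5%).
ML is required — and enforced — wherever likelihoods are compared across
fixed-effects structures: likelihood-ratio tests, AIC/BIC backward selection,
BIC Bayes factors, and *both* sides of permutation tests (exchangeability
requires the observed and permuted statistics to be computed identically).

### 7.2 Inference

- **Wald tests** (`wald_terms`): Type II by default — the term's block
  chi-square after residualizing its columns against higher-order relatives
  in the whitened model; reduces to the plain block test when no relatives
  exist (then Type II = Type III).
- **Model selection** (`select_model`): backward elimination respecting
  marginality, dropping a term only if its LRT p >= alpha and the reduced
  model's AIC does not increase; all comparisons on ML fits, final model
  refitted with REML.
- **Bayes factors**: BIC approximation `BF01 = exp((BIC_with - BIC_without)/2)`
  on ML fits with identical rows.
- **Permutation tests** (`permute_group_effect`): shuffle group labels at the
  participant level, refit by ML, compare the group block chi-square;
  reported p is `count/n_iter` with the smoothed `(count+1)/(n_iter+1)`
  alongside. Calibration at the defaults (8/6/6 participants, 199
  permutations): rejection rate 0.045 over 200 null cohorts.
- **Estimated marginal means** (`emmeans_contrasts`): model-based cell means
  at covariate means over observed factor combinations, with BH-adjusted
  pairwise contrasts.
- **Demographic matching** (`demographic_matching`): multinomial-logit LR
  test of group ~ covariate against a permutation null; the covariate is
  standardized (the LR statistic is invariant) and perfect-separation fits
  count as +infinity symmetrically in observed and permuted data.
- **Multiple comparisons**: Benjamini-Hochberg step-up (delegating to
  `statsmodels.stats.multitest`).

## 8. Single-case statistics

`crawford_covariate_test` compares one case to a control sample, optionally
adjusting for a covariate (age): the case is predicted from the control
regression and the discrepancy is tested with

    t = (y_case - y_hat) / (s * sqrt(1 + 1/n + (x_case - x_bar)^2 / SS_x))

on `n - 2` degrees of freedom (`n - 1` and no leverage term without a
covariate). This treats the case as a new observation from the control
population, not a z-score against it; without a covariate, a case exactly one
control SD above the mean gives `t = 1/sqrt(1 + 1/n)` (0.97700842... for
n = 21). Null rejection is calibrated at nominal alpha (0.0493 observed over
10^4 draws). `batch_case_control` runs the test per measure with BH
correction across cases.

## 9. Pipeline

`run_pipeline` chains the pieces: simulate the cohort, estimate one cluster
null per configuration, fit per-run GLMs, define ROIs on the definition run,
compute held-out CS amplitudes, responsivity, RS magnitudes and RSA model
fits per hemisphere, score behaviour, then run model selection, Wald tests,
Bayes factor, permutation test, case-control battery, demographic matching,
and the group RDM comparison. Results serialize to TSV/JSON/YAML with a
provenance block (config hash, seed, package version, cluster threshold).
Everything is reproducible from the config: all randomness derives from the
cohort seed through named `SeedSequence` sub-streams.

## 10. Numerical choices, summarized

- Frozen localizer block order; adaptation block order seeded per run.
- HRF convolution on a 0.05-s grid; unit-peak normalization for both HRFs.
- `within_block="distributed"` for exact noiseless oracles (section 2.2).
- Profiled 1-D mixed-model likelihood; bounded search on `log lambda`.
- REML for estimation, ML for any cross-model likelihood comparison.
- Permutation statistics computed identically for observed and permuted data.
- Fisher-z averaging for correlations; values clipped at `1 - 1e-12` before
  `atanh`.
- Named seed streams (`derive_rng(seed, *labels)`) so adding a consumer never
  perturbs existing streams.
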