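# Methods

`periopredict` implements a risk-stratification analysis for major surgery —
the motivating setting is orthotopic liver transplantation (OLT) — that
predicts binary postoperative outcomes (180-day mortality, acute renal
failure) from preoperative clinical features and features mined from
intraoperative hemodynamic monitoring. This note records the model, its
assumptions, the numerical choices, and what the synthetic data generator
does and does not emulate.

## Feature extraction

Sixteen hemodynamic variables are supported (registry in
`periopredict.signals`): ten continuous time series (SBP, CVP, HR, SpO2,
dPmx, PCCI, PPV, SVI, SVRI, SVV) and six intermittently computed
thermodilution indices (CFI, ELWI, GEDI, GEF, ITBI, PVPI). From every signal
the **median** is extracted; from the continuous signals additionally:

- **MAD** — `median(|x − median(x)|)`, deliberately *without* the 1.4826
  normal-consistency factor: the quantity of interest is the raw robust
  spread of the waveform, not a σ estimate.
- **Exposure area** — the time integral of the signal's excursion beyond a
  device "normal" threshold on its harmful side, in signal-unit·minutes:
  SBP below 100 mmHg, CVP above 5 mmHg, HR above 100 bpm, SpO2 below 90%,
  dPmx below 642 mmHg/s, PCCI below 3 L·min⁻¹·m⁻², PPV above 10%, SVI below
  40 mL/m², SVRI below 1700 dyn·s·cm⁻⁵·m², SVV above 10%. The SVI direction
  is configurable (`ThresholdSpec`); the default treats exposure to
  *reduced* stroke volume as harmful.

Integration uses per-sample rectangles (monitors emit step-held values), with
each sample's holding time capped at `max_gap_s` (default 60 s) so recording
dropouts accrue no exposure; the last sample is held for the capped median
inter-sample interval, so a regular series of *n* samples at spacing *d*
covers exactly *n·d*. The extractor is agnostic to the sampling interval.

With the 15 preoperative features (demographics, comorbidities, ASA class,
MELD, INR, bilirubins, albumin, creatinine, donor/technique flags) and the 5
non-hemodynamic intraoperative features (four blood-product volumes in
mL/kg, surgery duration in minutes), the full matrix has 56 columns: 15
preoperative + 36 hemodynamic (16 medians, 10 MADs, 10 areas) + 5
non-hemodynamic.

## Record inclusion

A record enters an analysis only if all preoperative features and all
blood-product volumes (and duration) are present, every continuous signal
carries ≥ 180 minutes of gap-capped coverage (intermittent indices need ≥ 1
sample), and the requested outcome label is present. Coverage is summed
capped inter-sample time, not last-minus-first timestamp, so a long dropout
cannot fake coverage. Nothing is imputed; each exclusion is logged with its
first failing reason. Filtering with `outcome=None` yields the label-blind
set used for subset selection, so both outcomes share feature subsets.

## Subset selection

With ~56 candidate features and ~60 patients, multicollinearity makes
logistic coefficients unstable. Before any model is fit, each task's matrix
is standardized column-wise by `(x − μ)/μ` (fractional deviation from the
cohort mean) and reordered by Householder QR with column pivoting, whose
greedy rule yields non-increasing `|diag(R)|` and places a maximally
linearly independent column set first. The selected subset is the longest
pivot prefix whose 2-norm condition number (extreme-singular-value ratio of
the standardized prefix) stays ≤ `cond_cap`, default 15 — a compromise
within the commonly recommended 10–20 range for collinearity diagnostics.
Scanning k from the full width downward implements "largest satisfying
prefix" literally even when prefix condition numbers are non-monotone.

Notes and choices:

- Condition numbers are computed on the *standardized* prefix (the
  standardization immediately precedes selection in the procedure).
- Mean-ratio standardization is undefined for zero-mean columns; these
  raise an error naming the feature, and a z-score option
  (`standardization="zscore"`) exists for such data. `"none"` is available
  for pre-scaled matrices.
- Pivot ties are resolved by LAPACK's `dgeqp3` (first maximal column),
  which is deterministic.
- Selection never receives labels — enforced by interface
  (`ConditionCappedQRSelector.fit` ignores `y`), and tested by flipping all
  labels.
- Pivoted QR is a greedy heuristic, not the optimum over all k-subsets;
  tests assert the prefix condition number is within 2× of the exhaustive
  best on small matrices.

## Model search

Every nonempty combination of ≤ 5 features from the selected subset
(`max_features=5` caps the feature-to-event ratio at cohort sizes with
~11–13 events) is fit as a maximum-likelihood logistic regression with
intercept, on **raw** feature values — so odds ratios are per physical unit
(e.g. per mmHg·min of CVP exposure). The intercept never counts against the
cap, and the intercept-only model is excluded by default
(`include_empty=True` restores it).

Each patient's predicted probability comes from a model trained on the
other n − 1 records (leave-one-out cross-validation); the pooled score
vector gives the combination's AUC. Feature selection is *not* repeated
inside the CV loop: it is label-blind and global, so running it once outside
the loop leaks no outcome information.

Numerics: Newton/IRLS with step halving, relative log-likelihood tolerance
1e−8, max 100 iterations, linear predictors clipped at ±35. Separation is
flagged by non-convergence or any |coefficient| > 15 and triggers a refit
with an L2 penalty of 1e−6; the penalty is applied to **all** coefficients
(including the intercept) so single-class training folds — possible in
LOOCV with few events — also stay finite. The n leave-one-out fits of one
combination are advanced simultaneously as a batched Newton iteration
warm-started at the full-data solution; this is algebraically identical to
n independent fits (tested against a per-fold reference path and against
statsmodels), and folds that do not converge cleanly are refit
individually. Combinations are independent; any execution order gives
identical output, and results are sorted by AUC descending with ties broken
by fewer features, then lexicographic names.

A property worth knowing: under the null (labels independent of features),
pooled LOOCV scores are *pessimistically* biased — each held-out patient is
scored by a model trained on labels anti-correlated with its own — so the
mean LOOCV AUC over all combinations sits below 0.5 (≈ 0.36–0.44 at
n = 200–600 in our simulations) while the best AUC is inflated above the
mean by selection. The suite asserts this behavior rather than a naive
"mean = 0.5".

## Evaluation

- **AUC** is the normalized Mann-Whitney statistic (concordant case-control
  pairs + half-ties), equivalent to the trapezoidal ROC area over all
  distinct score thresholds (no binning).
- **Confidence intervals** are 95% BCa bootstrap with 1,000 replicates:
  patient-level resampling of the fixed (score, label) pairs, bias
  correction z₀ from the fraction of bootstrap AUCs below the point
  estimate (clipped to [1/2B, 1 − 1/2B] so the normal quantile stays
  finite), acceleration from jackknife skewness. Single-class replicates
  are redrawn and counted. Resampling the fixed LOOCV score vector — rather
  than re-running LOOCV per replicate — is the dominant convention and
  ~1,000× cheaper; it ignores training variability and is therefore mildly
  optimistic about interval width. Re-running the pipeline per replicate can
  be done by hand via `loocv_scores` if needed.
- **DeLong test** compares best-per-task AUCs on the same patients via
  placement-value covariances. The variance estimator is unbiased even at
  11 events (verified by simulation), but the normal approximation of z is
  intrinsically anticonservative at very small case counts (~7% rejection
  at 11/51); calibration checks therefore use cohorts in the asymptotic
  regime (60/90), where the measured type-I error is ~5%.
- **Inclusion frequency** summarizes, over classifiers with AUC > 0.7, how
  often each feature enters with full-data multivariate Wald P < 0.05,
  split by odds-ratio direction. Significance uses the full-data fit
  because that is the fit that defines the reported ORs.
- Randomness: one top-level seed; every stochastic step derives a child
  seed deterministically from (seed, operation, outcome, task).

## Synthetic cohorts

No clinical data ship with the package. `periopredict.simulate` draws:

- **Waveforms**: stationary AR(1) around patient-specific baselines
  (default lag-1 correlation 0.97 at 10 s sampling, marginal SDs per signal),
  clipped to physiological ranges; intermittent indices every 30 min.
  AR(1) (rather than white noise) makes threshold excursions sustained, so
  median, MAD and exposure area are not degenerate functions of one
  another. Every continuous signal's model places nonzero probability on
  its harmful side (the SpO2 model allows transient desaturations below
  90%) so exposure-area columns are not identically zero.
- **Preoperative labs** through a Gaussian copula with hand-set
  correlations (MELD with INR/creatinine/bilirubin positive, with albumin
  negative, …), so subset selection faces realistic multicollinearity.
  Marginals loosely match a liver-transplant population (age ≈ 56,
  MELD ≈ 17, INR ≈ 1.5, albumin ≈ 3.2 g/dL).
- **Blood products**: lognormal mL/kg volumes sharing a per-patient
  severity latent; durations truncated-normal 420 ± 90 min (floor 240).
- **Outcomes**: Bernoulli draws from a logistic link on a sparse set of
  true features (defaults mirror the clinically dominant predictors: CVP
  exposure area and whole-blood volume, plus creatinine for renal failure).
  The intercept is tuned by bisection so the cohort's mean outcome
  probability matches the prevalence target (default 17.7% mortality /
  21% ARF). The bisection targets the simulated cohort's own linear
  predictors — exact in expectation for the cohort at hand, and equivalent
  to a pilot-draw calibration for large n.
- **Missingness** (`inject_missingness`) deletes values completely at
  random; `MissingnessConfig.typical()` reproduces the rough missingness
  profile of retrospective intraoperative archives, leaving ~38% of records
  unusable.
- `population_auc` evaluates the generating model's own AUC exactly from
  the probability vector (the weighted concordance of p against Bernoulli(p)
  labels), providing the reference value for recovery tests.

What the generator does **not** emulate: surgical-phase dynamics
(anhepatic/reperfusion events), measurement artifacts, informative
missingness, or mechanistic coupling between hemodynamic variables beyond
shared baselines. Passing recovery tests therefore demonstrates the
*pipeline's* correctness under its statistical assumptions, not clinical
validity on real monitors.

## Problem sizes used in checks

The reproduction script (`scripts/acceptance.py`) and the test suite use
sizes chosen as a deliberate compute/statistics trade-off: a 62-patient
full-panel cohort for prevalences, subset sizes and a complete four-task
mortality analysis; a 600-patient reduced-panel cohort (CVP, SVI, HR +
non-hemodynamic features, two-feature truth) for end-to-end recovery; 1,000
random instances for the AUC and pivoted-QR contracts; 1,000 null cohorts
(60 cases/90 controls) for DeLong type-I error; 500 binormal cohorts of 62
patients (true AUC 0.8, 1,000 bootstrap replicates each) for BCa coverage.

## Known limitations

- Exact ±5-feature exhaustive search scales combinatorially; pools much
  beyond ~30 features become expensive (the 27-feature pool already means
  101,583 combinations × (n+1) fits).
- The ridge fallback's 1e−6 penalty leaves near-separable coefficients
  large (by design); their Wald intervals are then not trustworthy, and the
  `ridge_fallback` flag should be consulted before interpreting ORs.
- Mean-ratio standardization is scale-free but undefined for zero-mean
  features and ill-behaved for near-zero-mean ones; the z-score option is
  the escape hatch.
- BCa intervals on ~62 patients with ~11 events are themselves noisy; the
  coverage check (90–98%) reflects that.
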