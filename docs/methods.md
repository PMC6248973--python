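# Methods

This note records the models behind `adrsignal`, the assumptions they
make, and the design choices taken where the published descriptions of
the underlying algorithms leave the details open.

## Data model

Four delimited tables in an OMOP-CDM-like layout: `person` (sex, birth
year), `visit` (admission/discharge), `drug_exposure` (one row per
prescribed day), `measurement` (timestamped lab results with per-record
normal ranges). All timestamps are at day resolution; intervals are
closed on both ends. Same-day lab replicates are resolved by keeping the
more extreme value — automatic, because every window statistic is an
extreme. An event direction determines abnormality: "increased" means
value > normal_high, "decreased" means value < normal_low.

The reference dataset pairs a drug universe with a directional lab-event
universe (cartesian product, sorted), labels known ADR pairs positive,
samples twice as many nonpositives, and then drops pairs with fewer than
5 usable records — a record being a patient who contributes a pre/post
extreme pair, the same denominator CERT tests. Because sampling precedes
the filter, the final negative:positive ratio can drift below 2:1. The
70:30 development/test split is stratified by label (stability; the
alternative unstratified split is a one-line change).

## CERT

Pre-exposure window `[admission, first exposure)`, post-exposure window
`[first exposure, discharge]`; only the first exposure episode per visit
defines windows. Descriptive features use min-max-scaled values (per lab,
over the whole dataset) so different tests share one scale; abnormality
flags use raw values against each record's own normal range. The paired
test is Student's t when n > 30 or when Shapiro–Wilk at α = 0.05 does
not reject normality of the differences; otherwise Wilcoxon signed-rank
(zeros dropped; all-zero differences give p = 1). McNemar switches to
the exact binomial test when the discordant total is below 25. Bonferroni
adjustment multiplies by the number of pairs analyzed in the run; the
feature matrix carries the raw p-values (monotone in the adjusted ones
under a fixed factor), the signal criteria use the adjusted ones.
Skewness is the adjusted Fisher–Pearson sample skewness, kurtosis the
bias-corrected sample excess kurtosis; both need enough observations
(3 resp. 4) and nonzero variance, else the feature is missing.

Because window extremes grow with window length, the paired test is only
calibrated when pre and post lengths are exchangeable under the null —
which the synthetic generator guarantees by starting exposure episodes
uniformly within the stay. Measured type-I at α = 0.05 across null
cohorts: 0.048–0.073 per 1,000-pair grid (pairs sharing a cohort are
correlated, which widens the spread).

## CLEAR

Matching keys (sex, age ±5 years, same lab measured, admission year) and
the 1:4 ratio are conventional pharmacoepidemiology choices, exposed as
arguments. The control's pseudo index date is its admission date plus the
case's admission-to-exposure lag (clipped to the stay), aligning
observation time between groups; controls must have a result at/after
that date. A control visit may serve several strata; within a stratum
controls are sampled without replacement.

The outcome is any post-index abnormal value in the event direction —
equivalently, abnormality of the directional post-index extreme. The
exposure effect is estimated by conditional logistic regression
(statsmodels `ConditionalLogit`), polished by a bounded scalar
maximization of the conditional log-likelihood (the default optimizer's
gradient tolerance leaves ~1e-4 slack in the estimate) with the Wald SE
recomputed from the Hessian at the polished optimum. Separation is
declared when |log OR| > 15 or the Wald SE exceeds 20; the estimate is
reported as infinite and the p-value missing. Group descriptive features
use post-index extremes for symmetry with CERT.

## PACE

The event date of a visit is its first abnormal result in the event
direction. Prescription counts of the drug are aggregated over all
events at relative days −3, −2, 0, +1; day −1 is a washout day (the
feature set omits it) and days outside the stay contribute nothing.

PCI = (n₀ + n₊₁ + 0.5) / (n₋₃ + n₋₂ + 0.5). The published account
defines PCI only verbally; this form is the ratio of mean daily
prescribing after vs before the event (equal two-day windows, so the day
counts cancel) with a 0.5 continuity term guarding empty windows, and it
reproduces the printed symmetric cutoff pair (1/1.5, 1.5). Both the
formula and the day windows are config-exposed and should be treated as
provisional. Boundary conventions follow the printed inequalities
exactly: pattern discontinuation at PCI ≤ 0.667, signal at PCI < 0.667,
intervention at PCI > 1.500.

## Disproportionality

Table convention: a = target drug & target event, b/c/d the complements
(in CLEAR usage, exposed/control × abnormal/normal). Zero cells trigger
the Haldane–Anscombe +0.5 correction for PRR/ROR/Yule's Q only; the χ²
test runs on raw counts with Yates continuity correction; the Bayesian
measures need no correction. All printed signal thresholds are strict
inequalities.

**BCPNN.** Independent Beta(1,1) priors on p(x) and p(y), and a
Beta(1, γ−1) prior on p(x,y) with γ = (N+2)²/((a+b+1)(a+c+1)) matching
the prior to independence. The classic closed forms in the literature
approximate E[log₂ p] by log₂ E[p]; this package computes the posterior
mean and SD of IC exactly via digamma/trigamma moments of log-Beta
variables. The two versions differ negligibly except at near-empty
cells, where the exact moments (and any simulation-based posterior)
sit well below the log-of-mean approximation. A Monte-Carlo sampler of
the same posterior serves as the test oracle.

**GPS.** Observed counts a ~ Poisson(λE) with E = (a+b)(a+c)/N and a
two-gamma mixture prior on λ. Hyperparameters maximize the marginal
(negative-binomial mixture) likelihood over all pairs' tables via
L-BFGS-B — boxes [1e-4, 50] on shapes/rates, (1e-3, 1−1e-3) on the
weight — from the canonical DuMouchel start (0.2, 0.1, 2, 4, ⅓) plus 10
seeded random restarts. The posterior per table is again a two-gamma
mixture; EBGM = exp E[ln λ] and EB05 is found by Brent root-finding on
the mixture CDF (xtol 1e-10). The mixture-component labels are not
identifiable (swapping components with the complementary weight leaves
the model unchanged), so only the likelihood and the induced posterior
are order-invariant — tests assert those. Monotonicity in the observed
count holds at fixed expected count; it cannot hold jointly with moving
margins, which is also why the information component is not monotone in
a single cell (its shrinkage strength is margin-matched).

## Feature matrix and models

48 features: CERT f1–f18, CLEAR f19–f43 (f39–f43 are the
disproportionality lower bounds and EB05 on the matched 2×2), PACE
f44–f48, in that canonical order. Columns are z-standardized; by default
the moments come from the entire dataset, replicating the published
preprocessing — a deliberate leakage caveat — with a strict train-fitted
mode (`leakage_mode="strict"`) available. Missing features (no paired
records, no events, empty groups) are imputed to 0 after standardization
(the column mean) with the missingness mask preserved; a complete-case
workflow can filter on the mask.

Model defaults are the published chosen hyperparameters; grid search over
the published spaces (10-fold CV, best mean AUROC, first-in-enumeration
tie-break) is available but not the default path. Implementation choices
where the published account is silent: SVM probabilities come from one
sigmoid fitted on cross-validated decision scores with the SVM refit on
all data (ranking by probability equals ranking by margin; the
calibration fold count adapts to the smallest class); MLP widths are
64-32-16 (by depth: 64 / 64-32 / 64-32-16 / 64-32-16-8) with
loss-plateau stopping (tol 1e-4 over 50 epochs, max 2000) instead of a
held-out validation split, which at reference-dataset sizes (~60–90
pairs) would starve both training and the stopping rule at the published
learning rate of 1e-4.

Evaluation: reps × folds stratified fold-models per family, every model
applied to the held-out test matrix; metrics reported as mean ± SD.
AUROC uses the rank-based (trapezoidal, tie-corrected) estimator.
Model families are compared by one-way ANOVA on the AUROC samples and
Tukey HSD (both orderings of each pair reported, antisymmetric mean
differences). Rule-based comparators (CERT400, CLEAR, PACE, CCP2 =
(CERT ∨ CLEAR) ∧ PCI < 0.667, CCP3 = CERT ∧ CLEAR ∧ PACE, and the six
disproportionality criteria) are evaluated on the whole labeled dataset;
their AUROC is the binary-decision value (sens+spec)/2. The 2×2 feeding
the standalone disproportionality comparators defaults to the CLEAR
matched table and can be switched to whole-cohort exposure × event
counts.

## Synthetic EHR generator

One visit per patient; stay lengths 1 + Geometric(1/(μ−1)) giving mean
μ = 8.6 days with a 2-day minimum, so pre/post windows exist and the
skew resembles real stays. Lab baselines are per-lab Gaussians (SD 10%
of the mean, spread over clinically plausible magnitudes) with normal
ranges at mean ± 2 SD (~2.3% abnormal tail mass per side); values are
clipped to ±5 SD. Labs are measured daily; drugs are prescribed daily
from a start day drawn uniformly in [1, stay−1] — uniform placement
keeps the CERT window lengths exchangeable under the null, which is what
makes the type-I calibration study meaningful.

Planted mechanisms:

- **ADR pairs**: a step shift of `effect_size`·SD in the event direction
  from `onset_lag_days` (default 3) after first exposure — the simplest
  mechanism CERT/CLEAR must detect; the default lag places the PACE
  pre-event window inside the exposure episode. With probability
  `discontinue_prob` the prescription ceases on the day of the first
  abnormal post-exposure result (same-day order cancellation,
  cause-blind). The timing matters: cancelling one day later puts the
  event-day prescription in the PCI numerator and no effect size can
  then produce the discontinuation pattern under 8.6-day stays.
  The default `discontinue_prob` = 0.5 models attendings withdrawing the
  suspect drug about half the time, making the prescribing-pattern
  detector informative but not an oracle for planted pairs; the PACE
  discrimination study raises it to 0.9 to exercise the pattern
  boundaries themselves.
- **Indication pairs**: a forced abnormal result (1.5 SD beyond the
  bound, two days) precedes and triggers the prescription start — the
  adversarial confounding-by-indication fixture that must land in PACE's
  intervention regime.
- All other pairs have no exposure–lab dependence.

Output is byte-identical under a fixed seed. What the generator does
*not* emulate: pharmacokinetic wash-in/out, lab recovery after
withdrawal, multi-visit carry-over, informative (missing-not-at-random)
lab ordering, correlated lab panels, dose changes. Passing the recovery
study therefore shows the pipeline recovers clean step-shift effects at
realistic stay lengths and sampling noise — not that it is robust to the
full confounding structure of real EHR data.

## Standard studies and problem sizes

- **Recovery**: 2,500 stays, 60 drugs × 10 labs, 30 planted 1-SD ADR
  pairs (~125 exposed stays each), 2:1 reference sampling (90 pairs),
  3×5-fold repeated CV. Chosen as the smallest design in which every
  drug has >100 exposed stays and the reference dataset supports the
  published RF/NN hyperparameters.
- **Null calibration**: 1,500 stays, 50 drugs × 10 labs, no effects;
  the 1,000 directional pairs provide test-level replicates for the
  α = 0.05 rejection-rate estimates.
- **PACE discrimination**: 2,000 stays, 15 ADR + 15 indication pairs on
  disjoint drugs, withdrawal propensity 0.9.

## Known limitations

- Whole-dataset standardization and min-max scaling replicate the
  published preprocessing and leak test-set information; use
  `leakage_mode="strict"` for honest generalization estimates.
- CERT's paired test on extremes is slightly liberal at moderate n
  (heavy-tailed difference-of-maxima), visible as null rejection rates a
  shade above 0.05.
- The exact PCI formula, its day windows and the washout day are
  reconstructions consistent with the printed cutoffs, not published
  definitions.
- The GPS fit assumes independent tables; pairs sharing a drug or lab
  violate this mildly.
- Matching ignores stay length; with stays independent of exposure (as
  simulated) this is harmless, in real data it may not be.
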