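# Methods

## Model

`sparsehaz` analyses right-censored survival data under the Lin–Ying
**additive hazards model**

    lambda(t | Z) = lambda0(t) + beta' Z,

where `lambda0` is an unspecified baseline hazard and the p covariates
(typically gene-expression features, possibly with a small clinical block)
shift the hazard *additively* — the natural model when absolute rather than
relative effects are of interest. With observed data (X_i, delta_i, Z_i),
X_i = min(T_i, C_i), the semiparametric estimating function is linear in
beta:

    U(beta) = b − V beta,
    b = (1/n) Σ_i ∫_0^tau (Z_i − Zbar(t)) dN_i(t),
    V = (1/n) Σ_i ∫_0^tau Y_i(t) (Z_i − Zbar(t))(Z_i − Zbar(t))' dt,

with Y_i(t) = I(X_i ≥ t) the at-risk indicator and Zbar(t) the risk-set
covariate mean. Integrating −U gives the least-squares-type loss
L(beta) = beta'V beta / 2 − b'beta, which plays the role of a likelihood.
Both integrals are evaluated *exactly*: risk sets are constant between
consecutive distinct observed times, so each integral is a finite sum.
Censoring is assumed conditionally independent of the event time given Z.

For p ≫ n, V (p × p) is never formed; it is carried in the factored form
V = (Zw'Zw − A'A)/n, where Zw is the covariate matrix row-scaled by the
square root of each subject's at-risk duration min(X_i, tau) and A stacks
duration-weighted risk-set sums. Matrix-vector products, single rows and the
diagonal cost O(np); the dense matrix is materialized only on request, and
the two representations agree to ~1e−15 (tested).

## Penalized estimation

The sparse estimate solves

    betahat = argmin L(beta) + Σ_j p_lambda(|beta_j|)

for three penalty families: the lasso (L1), SCAD (shape a > 2, default 3.7,
defined through its derivative; the closed-form value is its piecewise
integral with p(0) = 0), and SICA (rho(theta) = (a+1)theta/(a+theta),
a > 0), which interpolates between L0-like behaviour (small a) and the L1
penalty (a → ∞).

Optimization is cyclic coordinate descent with **exact** one-dimensional
minimization of each coordinate's penalized quadratic: soft thresholding for
the lasso; for SCAD, enumeration of the stationary points of the three
smooth pieces plus the junctions; for SICA, exploiting that the derivative
of the one-dimensional objective is convex on beta > 0 (so it has at most
two roots, of which only the up-crossing is a local minimum), bracketed and
bisected to machine precision. Ties with the zero candidate resolve to zero.
Exact per-coordinate minimization makes the objective monotonically
nonincreasing, which the tests assert sweep-by-sweep. Sweeps are in fixed
cyclic order for determinism; after two full sweeps the solver iterates on
the current nonzero set and confirms convergence with a full
Karush–Kuhn–Tucker sweep. Convergence is declared when the largest
coefficient change in a full sweep drops below 1e−7 (coefficient-based
because the stability tables consume coefficients); the cap is 10 000 sweeps
for one-off fits and 500 inside cross-validation. Inner loops are
numba-compiled; the Python-level API dispatches to the same jitted scalar
kernels, so there is a single implementation of each update.

### Unboundedness at small lambda (p > n)

When p > n, V is rank-deficient and the penalized objective can be unbounded
below: along a null direction d of V with b'd ≠ 0 the loss decreases
linearly while the lasso penalty grows only linearly (unbounded once
lambda < b'd/|d|_1) and the SCAD/SICA penalties are *bounded*, so the
nonconvex objectives are unbounded at every lambda. Coordinate descent from
the zero start stays in the regularized basin for sufficiently large lambda;
at small lambda it either diverges (detected by an objective collapse below
−1e12) or stalls. Cross-validation scores any non-converged grid point +∞,
never selects it, and abandons the remaining (smaller, strictly harder)
lambdas of that fold.

### Regularization grid

The grid is log-spaced over [0.01·lambda_max, lambda_max] with 50 points by
default (25 in the study pipeline, where the grid is traversed thousands of
times inside resampling loops). For the lasso, lambda_max = max_j |b_j|, the
smallest lambda whose solution is identically zero. For SCAD/SICA that
lasso-style value is *not* an all-zero point when V_jj ≪ 1 (short follow-up
times): the bounded penalties cannot restrain low-curvature coordinates, and
a warm-start path beginning at a divergent fit is useless. The grid top for
the nonconvex penalties is therefore the kind-specific all-zero threshold,
located by bisection on the exact univariate minimizer (whose magnitude is
nonincreasing in lambda). Inside cross-validation the top is the maximum of
this threshold over the full data *and every training fold*, so each fold's
warm path starts from a genuinely zero fit.

## Tuning

lambda is chosen by K-fold cross-validation (K = 10) of the
least-squares-type loss: CV(lambda) = mean over folds of the held-out fold's
own loss evaluated at the fit from the remaining folds. L(0) = 0, so the
empty model scores exactly 0. Folds are stratified by event status (with 35
events in 86 samples, unstratified folds are frequently event-free); fold
assignment is seeded and re-drawn (derived seed, ≤ 10 attempts) if a fold
ends up without events. Ties in the CV minimum break toward the larger
lambda — the sparsest among equals. SCAD's shape is fixed at a = 3.7; SICA's
shape is tuned jointly with lambda over {0.01, 0.1, 1, 10, 100}, with
non-converging (small-a) grid points scored +∞.

## Prediction and evaluation

**Survival prediction.** The baseline cumulative hazard is estimated by the
additive-model analogue of the Breslow estimator,
dLambda0hat = (Σ dN_i − Σ Y_i beta'Z_i dt)/Σ Y_i — a step at each event time
minus a piecewise-linear drift — giving
S(t | z) = exp(−Lambda0hat(t) − (beta'z)·t), clipped to [0, 1] and forced
nonincreasing (the additive model does not constrain the estimated survival
to be monotone in finite samples).

**Time-dependent AUC.** Cumulative-case / dynamic-control: at time t, cases
are subjects with an observed event by t, controls those event-free beyond
t. Concordance of a risk marker is the weighted fraction of correctly
ordered case/control pairs (ties ½), with inverse-probability-of-censoring
weights 1/Ghat(X_i−) for cases and 1/Ghat(t) for controls, where Ghat is the
Kaplan–Meier estimate of the censoring survival (reverse Kaplan–Meier,
events preceding censorings at ties). Because the control weight is constant
at fixed t it cancels, making the estimator equivalent to the Uno form;
tests cross-check both the reverse Kaplan–Meier against lifelines and the
AUC against scikit-survival's `cumulative_dynamic_auc`. Summary statistic:
the median of AUC(t) over the evaluation grid (distinct event times in the
test window), midpoint convention for even lengths.

**Prediction-error (Brier) curves.** At each t, the IPCW-weighted mean
squared difference between the observed event state (1 = event by t,
0 = known event-free) and the predicted event probability 1 − S_i(t);
subjects censored by t contribute through the reweighting of the others. The
event-probability orientation is used so that a perfect model scores 0.

**.632+ estimator.** B replicates each draw floor(0.632·n) training samples
*without replacement* — the subsample size is chosen so the expected holdout
fraction matches the classical bootstrap's out-of-bag fraction — and a
with-replacement flag restores the classical scheme. The training closure
passed in re-runs the *entire* selection pipeline (standardization, CV, fit,
baseline estimation) on each draw, so gene selection never leaks across
replicates. With apparent error err_app, mean out-of-sample error err_oob,
and no-information error gamma (all prediction/outcome pairings, same
weights), the relative overfitting R = (err_oob − err_app)/(gamma −
err_app) is clipped to [0, 1] and the combined curve is
(1 − w)·err_app + w·min(err_oob, gamma) with w = .632/(1 − .368·R).
Replicates whose training draw has fewer than 2 events are redrawn with a
derived seed.

**Stability tables.** R replicates each re-run the full tuning + fit on a
random 80% subsample (without replacement; the scheme mirrors the pipeline's
80/20 split culture and is configurable); the table reports, per feature
ever selected, its selection frequency, the mean coefficient over the
replicates in which it was selected, and SE = SD/√frequency. Failed
replicates are excluded and counted.

## Synthetic data

The generator produces exactly the structure the estimator assumes:

| parameter | default | meaning |
|---|---|---|
| n | 86 | cohort size (motivating study: 86 patients) |
| p | 2000 | features (desk-scale stand-in for a 29 096-probe array) |
| n_signal | 5 | nonzero true coefficients |
| signal range | [0.5, 1], random sign | effect sizes on the hazard scale |
| rho | 0.3 | AR(1) covariate correlation rho^|j−k| |
| lambda0 | 1.0 | constant baseline hazard (time unit⁻¹) |
| target_events | 35 | expected observed events (motivating study: 35) |

Covariates are zero-mean Gaussian with AR(1) covariance (sequential
recursion, O(np)). The subject hazard is h_i = lambda0 + beta'Z_i; subjects
with h_i ≤ 0.01·lambda0 are rejected and redrawn — rejection rather than
clipping, so conditional on acceptance the law is exactly an additive-hazards
law; the count is reported so users can see when beta is too large for
lambda0. Event times are exponential with rate h_i (constant baseline ⇒
closed-form sampling and a closed-form survival truth for prediction tests).
Censoring is uniform(0, c), independent of Z, with c solved by Brent's
method so the expected event count matches `target_events` (the expectation
is written via expm1; the naive form cancels catastrophically for small
hazard·horizon). An optional clinical block mimics an age, a 3-level
baseline histology grade and two continuous protein-expression markers, with
a configurable additive hazard contribution.

What the generator does **not** emulate: probe-level microarray noise, batch
effects, heavy-tailed expression distributions, block correlation beyond
AR(1), or informative censoring. Tests passing on this generator demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to their violation.

A consequence of hazard positivity worth knowing when designing simulations:
since beta'Z must not drive the hazard below zero, usable signal strength is
bounded by lambda0 (rejection truncates the informative tail of the linear
predictor, and the truncation itself distorts marginal associations).
Per-feature selection signal-to-noise grows like (|beta|/lambda0)·√n, with
|beta|/lambda0 capped by the positivity margin — so "strong-signal" test
scenarios scale beta, lambda0 and n together rather than raising beta alone.

## Study pipeline

`run_study` mirrors a complete comparative analysis: an 80/20
event-stratified train/test split; per penalty, CV on the training split
only (standardization statistics computed on the training portion of
whatever resample is in play — never on held-out samples), test-split AUC of
the linear predictor marker; .632+ error curves for a clinical-only model
(unpenalized fit on the 4 clinical covariates) and for each
clinical-plus-genes penalized model; and stability tables. All randomness
derives from one root seed through named SeedSequence derivations; reruns
are byte-identical, and every table is written with the config and package
version embedded. Evaluation time grids are the distinct event times of the
relevant window, thinned to at most 30 points. Each study run uses a single
seeded train/test split; distributions over repeated splits are obtained by
rerunning under different root seeds, since every reported quantity is a
pure function of the root seed.

Problem sizes used by the default study and the acceptance script — n = 86,
p = 2000, B = 25 bootstrap replicates, R = 25 stability replicates, 25-point
CV grids — are the package's desk-scale choices: they preserve the p ≫ n
regime and the resampling design while keeping a full study in the
minutes range. `top_features_by_auc` ranks single features by the median
AUC of the feature itself as a marker, with the association sign from the
univariate additive-hazards coefficient.

A caveat at exactly the motivating cohort's dimensions: with ~35 events
against 2000 candidate features, the per-feature selection signal-to-noise
available to *any* additive-hazards effect respecting hazard positivity sits
below the lasso's selection boundary, so cross-validation frequently — and
correctly — prefers the empty model there. The same generator conditions at
n = 300 are comfortably informative (recovery and discrimination are
demonstrated at that scale in the tests and the reproduction script); on
real cohorts of the small size, discriminative results depend on effect
structure richer than the generator's sparse Gaussian model.

## Numerical choices and edge cases

- Events at exactly tau are included in b; integration truncates at the last
  observed time when tau exceeds it (warning).
- Subjects are removed from the risk set at their own observed time
  (left-continuous risk sets, standard counting-process convention).
- Coordinates with V_jj = 0 (covariate constant within every risk interval)
  are frozen at zero.
- Ties in observed times are handled exactly (no jittering); the estimator
  is tie-safe by construction.
- Zero-event datasets give b = 0 with a warning; zero-event *folds* on the
  evaluation side contribute loss through V only.
- Standardization: covariates are centered and scaled to unit sample SD
  (ddof = 1) before penalized fitting (penalties are scale-sensitive);
  constant columns are centered only. Centers/scales are retained and
  coefficients are reported on both scales.
- Missing values are an error, never imputed.
- G (censoring survival) is floored at 1e−12 in weights; AUC values at times
  with no cases or no controls are dropped with a warning rather than
  imputed.

## Known limitations

- Time-dependent covariates are not supported (covariates are fixed at
  baseline).
- The baseline hazard of the generator is constant by default (a piecewise
  option exists in the model class but is not the default), so calibration
  checks of predicted survival lean on the exponential closed form.
- The SICA shape-selection rule is a joint-CV grid, a deliberate stand-in
  where the literature's exact rule is not fully specified; the grid point
  chosen is always logged.
- With p ≫ n, fits below the practical lambda boundary are not computable
  (the objective is unbounded); the CV machinery treats that region as
  infeasible rather than returning an arbitrary iterate.
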