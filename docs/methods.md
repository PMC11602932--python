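# Methods

## Setting and estimand

`offtreat` supports planning of two-arm parallel-group trials with a
continuous repeated outcome (the motivating case is FEV1 in mL at J = 3
post-baseline visits) in which the intercurrent event *treatment
discontinuation* is handled with a treatment-policy strategy.  The
estimand is

Δ_J = E[Y_J − Y_0 | Z = A] − E[Y_J − Y_0 | Z = C],

the difference in expected change from baseline at the final timepoint,
counting outcomes collected after treatment discontinuation.  Patients
who discontinue treatment (time `disc_time` = t means the outcome at
visit t is the first off-treatment value) remain in follow-up unless
they also *withdraw from the study*, which is the distinct event that
creates missing data.

## Data-generating model

Each patient carries a (2J+1)-dimensional multivariate-normal vector of
potential outcomes: baseline, on-treatment values at visits 1..J and
off-treatment values at the same visits.  Defaults:

- Control on-treatment means (2140, 2470, 2520, 2540) mL; Active adds
  (0, 100, 100, 100) mL.
- Off-treatment means: *return-to-baseline* sets all off-treatment
  means to the baseline mean (both arms); *same-as-active* sets them to
  the Active on-treatment means (both arms).
- Covariance: every component has SD 450 mL; correlation decays as
  0.7^|lag| between visits within a regime (baseline counts as visit 0
  of either regime) and is damped by 0.8 across the on/off regimes.
  The on- and off-treatment blocks are identical by construction, and
  the resulting correlation matrix is positive definite (smallest
  eigenvalue 0.045), so the nearest-PD projection guard is inert for
  the defaults.  The covariance is a package-level design choice and is
  fully configurable; the performance numbers produced by the harness
  should be read as properties of this generative model.

Discontinuation is *fixed by rank*, not drawn Bernoulli: the total
round-half-up(n·rate) per arm is apportioned over visits in the ratio
given by `disc_time_split` (default 5:3:2, largest-remainder rule, ties
to the earliest visit), and at each window the lowest-scoring patients
still on treatment are selected.  The score is the most recent observed
on-treatment value under DAR (baseline for window 1) and the next —
unobserved — potential on-treatment value under DNAR.  Ranking is
deterministic on the raw outcome values; because the outcomes are
continuous, ties occur with probability zero.  An alternative would add
noise to the ranking scores (a stochastic propensity); that would
dilute, but not qualitatively change, the selection effects.

Withdrawal is a single assessment at the moment of discontinuation: an
exact simple random sample of the discontinuers at window t is flagged
withdrawn and contributes no off-treatment data, so missingness is
monotone, confined to discontinuers, and starts exactly at
`disc_time`.  The per-window withdrawal rates (w_1..w_J) satisfy
Σ split_t·w_t = overall rate; the unbalanced schemes move the first
window by ±0.2 and compensate the later windows (for the default split,
"more early" at 50% is (0.7, 0.3, 0.3) and "more late" is
(0.3, 0.7, 0.7); at 70%, (0.9, 0.5, 0.5) and (0.5, 0.9, 0.9)).

What the generator does *not* emulate: intermittent (non-monotone)
missingness, withdrawal among patients still on treatment, gradual
off-treatment decay (mean reversion is immediate at the first
off-treatment visit), different on- vs off-treatment variances, and
rescue-treatment dynamics beyond the two stylised trajectories.
Conclusions from passing tests therefore speak to this idealised
monotone world, not to arbitrary real-trial missingness.

## Truth oracle

The true Δ_J under a scenario depends on the discontinuation mechanism
(rank selection shifts which patients contribute off-treatment values),
so it is evaluated by Monte Carlo: the generative process is run with a
large sample per arm (default 2,000,000) and *no* withdrawal masking.
Because exact-count rank selection couples patients, the naive iid
standard error of the mean is invalid; the oracle therefore runs 20
independent blocks and reports the empirical SE of the block-level
contrasts.  At the default size the oracle SE is a fraction of a mL.

## Imputation models

Missing outcomes are imputed sequentially (j = 1..J), separately per
arm.  At step j the regression is fitted to patients whose outcome at j
is observed (their full history is observed, by monotonicity), and
parameters are drawn from the standard noninformative
normal-inverse-gamma posterior: σ² from a scaled inverse-χ² with n−p
degrees of freedom, β from N(β̂, σ²(X'X)⁻¹) — the usual monotone
proper-imputation draw.  Recipients are imputed as x'β + σz with
observed-or-previously-imputed covariates.  A residual-variance floor of
1e-8 mL² guards exact-fit degeneracies.

The eight structures combine an intercept basis (common; on/off status
D_j; discontinuation pattern P_j; final pattern P_J), a slope basis
(common; D_j interactions; historical D_k interactions; P_J
interactions, which start at Y_1) and the conditioning scale (raw
values or residuals): CICS, OICS, PICS, OIOS, PIOS, PIPS, OICS-R,
PICS-R.  Status covariates are known even for withdrawn patients, so
designs are always constructible; estimability is the binding
constraint.

Degenerate columns (zero variance in the fitting rows — e.g. D_1 when
nobody has discontinued, or an unpopulated pattern level) are dropped
and recorded.  If a patient needing imputation falls in a stratum whose
column was dropped — the "no donors" case — an `InestimableModelError`
is raised carrying the arm, timepoint and model; the harness records it
as non-convergence.  This is exactly the failure mode that makes the
maximal PIPS model fragile at low discontinuation rates.

For the residual models, R_k = Y_k − μ̂_k where μ̂_k is the mean of the
*observed* outcomes at visit k in the patient's arm × status cell
(status D_k for OICS-R, pattern P_k for PICS-R; the arm mean at
baseline).  One-pass cell means were chosen over an iterative
construction: they satisfy the defining zero-mean property exactly
within each cell, and because the cell label is a function of the
pattern, the PICS-R design spans the same column space as PICS at every
step — making the reparameterisation equivalence exact rather than
approximate.  OICS-R is *not* equivalent to OICS: the residual centring
uses the historical status D_k at each earlier visit, which the
raw-value model cannot represent.

## Estimators and pooling

The analysis model is ANCOVA: OLS of Y_J − Y_0 on intercept, arm and
baseline, with LS-means evaluated at the pooled baseline mean (the
effect equals the arm coefficient and the LS-mean difference).  It is
implemented closed-form in numpy because the harness fits it on the
order of 10^6 times; a unit test pins it to statsmodels OLS.

The MMRM uses fixed effects timepoint + arm×timepoint +
baseline×timepoint and one unstructured J×J residual covariance shared
by the arms, maximised by REML over the log-Cholesky parameterisation
(positive-definiteness by construction).  Because the same three
regressors appear at every timepoint, all REML quantities reduce to
per-missingness-pattern cross-products combined with Σ⁻¹ blocks
(Kronecker assembly), so one objective evaluation costs O(J³)
regardless of n.  Optimisation starts from the diagonal of per-visit
OLS residual variances (L-BFGS-B, ftol 1e-8, ≤200 iterations);
non-convergence is flagged, not raised.  SEs are model-based from
(X'V⁻¹X)⁻¹ with t reference on n − 3 degrees of freedom at the final
timepoint; a Kenward-Roger adjustment is out of scope and immaterial at
n = 750.

Rubin's rules: q̄ is the mean effect, W the mean squared SE, B the
between-imputation variance, T = W + (1 + 1/m)B, with the
Barnard-Rubin small-sample degrees of freedom (collapsing to the
complete-data df when B = 0).  Default m = 25 imputations.

## Performance harness

Per replicate the harness simulates a trial, fits the full-data ANCOVA
(the FULL reference), then each requested estimator on the masked data.
Reported per scenario × model: convergence %, bias and its MC SE, mean
95% CI halfwidth and its % change versus FULL, coverage and its change
versus FULL (percentage points), and the two-sided rejection rate at
α = 0.05 (the Type 1 error under a matched null configuration with
equal means and equal discontinuation rates).  "Stable" is
operationalised as pooled SE ≤ 10× the replicate's full-data SE
(configurable); unstable and inestimable fits are excluded from the
summaries and counted against convergence.  Replicate RNG streams are
derived from (master seed, scenario index, replicate, model), making
results independent of the model evaluation order and bit-reproducible.

The shipped factorial (2 mechanisms × 4 discontinuation-rate pairs ×
2 withdrawal rates × 3 balances × 2 trajectories = 96 scenarios)
reproduces the full study design; `scripts/acceptance.py` runs the
headline scenario families at 200-1000 replicates per scenario with
m = 25 — sizes chosen so the whole reproduction runs on a single CPU in
well under half an hour while keeping Monte Carlo SEs of the biases at
roughly 2-4 mL.

## Known limitations

- The generative covariance is a configurable default, not a fitted
  quantity; absolute bias/halfwidth/coverage numbers shift with it
  (the acceptance script's `--sweep` flag quantifies the sensitivity of
  the common-MAR bias to the within-regime correlation over 0.5-0.8).
- Only monotone missingness is supported; non-monotone data require a
  different engine (e.g. FCS) and joint-multivariate imputation is not
  implemented.
- Reference-based (jump-to-reference) imputation is out of scope.
- The MMRM covariance is common to both arms; per-arm covariances and
  sandwich/robust SEs are not provided.
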