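# Methods

## The problem

Longitudinal epidemiological analyses often target the effect of an
*exposure history* — a cumulative average, moving average, or cumulative sum
of repeated exposure measurements — on the trajectory of a continuous
outcome such as a cognitive score. The individual measurements feeding that
history are usually error-prone surrogates (e.g. model-predicted ambient
PM2.5 rather than personal exposure), and plugging the surrogate history
into the outcome model attenuates the exposure effects. `memlong`
implements a regression-calibration correction for this setting under a
main-study / validation-study (MS/VS) design, for both external (EVS,
disjoint subjects, no outcomes) and internal (IVS, a subsample of the main
study) validation.

## Models

**Outcome model (linearly divergent differences).** For subject *i* at
occasion time *t<sub>ij</sub>*,

E[Y(t) | history] = β₀ + β₁ X(t) + β₂ t + β₃ X(t)·t + β₄ᵀ W(t),

where X(t) = g(true exposure history up to t) and g is the chosen history
functional. β₃ — how the outcome's slope over time changes with exposure —
is the parameter of interest.

**Measurement error model (MEM).** In the validation study, where paired
(true c, surrogate C) measurements exist,

E[c | C, t, W] = f(C, t, W; α) = α₀ + α₁ C + α₂ t + α₃ C·t + α₄ᵀ W,

with any subset of these terms. The MEM always uses its own time scale
(`t_mem`, typically age); the outcome model uses `t_outcome` (typically
time on study). The two scales may differ — an external validation study
often has only age — and the code keeps both on every record.

**Induced model.** Under (i) *surrogacy* (given the true history, the
surrogate history is uninformative about Y) and (ii) *localized error*
(the true exposure at an occasion depends only on the current-time
surrogate, time and covariates), the conditional expectation of the history
functional given the observed surrogate history is obtained by calibrating
each pointwise measurement through f and applying the same functional.
All three supported functionals are linear in the pointwise values, so the
calibrated history X̂ is exactly linear in α; the implementation exploits
this through a per-subject calibration matrix G with X̂ = Gα, built by
pushing each MEM design column through the generic functional code.

**Transportability** (the MEM fitted in the VS also governs the MS) is
assumed; under IVS it can be checked with `mem_equality_test`.

## Estimation and inference

The stacked estimating system ψ = (ψ_α, ψ_β) is block triangular: ψ_α only
involves α. The solver is therefore two-stage and exact — fit the MEM
(ordinary least squares when each validation subject has one measurement,
GEE otherwise), then solve the outcome GEE with X̂ in place of X. Under
IVS, validation subjects' outcome rows enter ψ_β with X̂ (not their
observed true exposures); a switch excludes them for sensitivity analyses.

Variance uses the M-estimation sandwich Var(θ̂) = B⁻¹A(B⁻¹)ᵀ with
per-subject stacked scores: A = Σψᵢψᵢᵀ, and B block lower-triangular with
∂ψ_α/∂α and ∂ψ_β/∂β taken from the stage fits and the cross block
∂ψ_β/∂α computed by central differences (step 10⁻⁶(1+|α_k|)) with the
outcome working covariance held fixed. Because ψ_β is linear in α through
Gα, this numeric Jacobian is exact to rounding. Confidence intervals are
Wald z-intervals (±1.96·SE) with no small-sample degrees-of-freedom
correction.

### Working covariance

Structures: independence, AR(1), exchangeable, unstructured (the last
requires a declared common occasion grid; subjects missing occasions
contribute available pairs). Nuisances are moment estimates from the
current residuals — scale φ̂ = Σe²/(N_obs − p) (the denominator convention
is a package choice; the method is invariant to rescaling φ), AR(1)
ρ̂ = Σᵢ Σⱼ e_{ij}e_{i,j+1} / (φ̂ Σᵢ(mᵢ−1)) clamped to (−0.99, 0.99).
The working correlation is treated as known at its estimate inside ψ and
the sandwich; its sampling variation is ignored (standard GEE practice).
Consistency of β̂ does not require the structure to be correct.
Iteration alternates the weighted-least-squares update with the moment
update until the coefficient change is below 10⁻⁸ (at most 50 iterations);
because the mean model is linear, each update is a single solve.

### History functionals

* cumulative average: X(t_j) = Σ_{k<j} c(t_k)(t_{k+1}−t_k)/(t_j−t_1). The
  forward-gap weighting means the value at t_j never uses c(t_j) itself;
  this asymmetry is kept verbatim. With equal spacing it is the plain mean
  of the first j−1 values.
* moving average / cumulative sum over a closed window [t−b, t]; window
  endpoints inclusive.

Occasions with the availability indicator off are dropped before the
functional forms its weights, so results are invariant to inserting absent
records (the assumed missingness mechanism is MCAR; no imputation is
done). The first occasion has no strictly-prior history: `baseline_rule`
either assigns it its own measurement (`single_value`, the continuity
limit — the default, which keeps every outcome row usable) or drops the
row (`exclude`). Both options exist because applied analyses differ in how
they define the baseline history value.

## Diagnostics

* **Localized error** (repeated-measurement VS): the default two-step form
  fits the current-time MEM, then regresses its residuals on the
  cumulative averages of the m lagged surrogates (and lagged covariates)
  and jointly Wald-tests those coefficients with cluster-robust variances.
  The one-step variant adds the lagged averages directly to the MEM; the
  two-step form is the default because past and current surrogates are
  typically collinear and validation samples small. The two-step test
  ignores step-1 estimation error; simulation (in the test suite) shows
  its null rejection rate is nominal at the sample sizes exercised.
* **Surrogacy** (IVS only): outcome model with both the true-history
  functional X and the surrogate-history functional Z (+ Z·t); joint test
  of the Z terms.
* **MEM equality**: Wald comparison of two independently fitted α vectors
  using their sandwich variances.
* **Confounder screen**: refit the outcome model without each candidate
  covariate set; flag sets that move β̂₃ by more than 10% (the
  conventional change-in-estimate threshold; configurable).

## Synthetic-data generator

The generator emulates a 2×3 factorial family of MEM mechanisms — the
interaction factor (NI/IP: whether C·t enters the true MEM) crossed with
the covariate factor (NW/WP/WC: W absent, present-uncorrelated, or
present-correlated with C at Corr(C,W)=0.4). Study conditions:

* five occasions at t = (0, 1, 2, 3, 4) for every subject; both time
  scales coincide in generated data (the two-scale machinery is exercised
  by dedicated tests with an age offset);
* C i.i.d. standard normal; W standard normal, coupled to the same-occasion
  C by a bivariate normal; ε i.i.d. N(0, σ²_ε) independent of everything;
* the true exposure is generated *from* the scenario MEM, so the
  calibration model holds by construction; α = (1.2, 0.7, 0.6, 0.5, 0.4)
  for whichever terms the scenario includes;
* X is the cumulative average of the true exposures (baseline
  `single_value`); outcomes are multivariate normal with the divergence
  mean (β₀ = 0.5, β₂ = 3, β₄ = 1; (β₁, β₃) selectable among (3,3), (3,0.2),
  (0.2,3), (0.2,0.2)) and AR(1) errors with σ²_Y = 1, ρ_Y = 0.1;
* the validation study keeps all five occasions (l=5) or one uniformly
  chosen occasion (l=1); EVS draws fresh subjects with no outcomes, IVS a
  without-replacement subsample of the main study.

σ²_ε is calibrated so the model-implied marginal Corr(c, C), pooling
subjects and occasions, hits the scenario target (0.60 NI-NW, 0.65 NI-WP,
0.57 NI-WC, 0.84 IP-WC): closed-form inversion without the interaction
(e.g. NI-NW: (0.7/0.6)² − 0.49 ≈ 0.871), a bracketed root-find on the grid
moments with it. For IP-NW and IP-WP the targets (0.84, 0.85) exceed the
supremum attainable under this design as σ²_ε → 0 (0.839 and 0.823), so
those two scenarios use a fixed σ²_ε = 0.5 (marginal Corr(c, C) ≈ 0.79 and
0.77). Consequently the uncorrected-bias *magnitudes* in the interaction
scenarios are generator-specific; the qualitative findings (near-zero
corrected bias, bias and under-coverage from omitting a needed MEM term)
are not.

What the generator does **not** emulate: informative missingness (MAR/
MNAR), non-normal exposures or outcomes, nonlinear calibration, subject-
level heterogeneity in measurement error, or distinct MEM/outcome time
scales. Passing tests therefore certify the estimator's behaviour under
the stated mechanism, not robustness to those departures.

Seeding: `SeedSequence(seed).spawn(R)[r]` is the substream for replication
r — part of the public contract, so per-replication datasets are
reproducible independently of which estimators run.

## Monte-Carlo study sizes

Reported operating characteristics (relative bias of β̂₃ in percent, the
empirical SD of the estimates, the mean sandwich SE, and coverage of
nominal 95% intervals, with the two-standard-error acceptance band from
`coverage_bounds`) are computed at desk scale: the packaged acceptance
script uses 1000 replications at (n₁, n₂) = (1000, 100) for the
uncorrected arm and (1000, 500) with l=5 for the corrected arm; the test
suite uses 400–500 replications for the main scenarios and 150 per
misspecification arm. Null calibration of the diagnostic p-values is
checked over 500 simulated validation studies.

## Known limitations

* Identity link and linear-in-parameters models only; no logistic or other
  nonlinear outcome links.
* GEE-based, hence valid under MCAR; MAR/MNAR dropout is out of scope.
* The unstructured working correlation needs a common occasion grid.
* The cross Jacobian is numeric by design; an analytic path, if added,
  must match it to 1e-5 relative (the test suite enforces the numeric
  oracle on an independent code path).
* The two-step localized-error test is approximate (step-1 estimation
  error ignored); its level is verified by simulation rather than theory.
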