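# Methods

## Model and assumptions

`circabp` models the medium-term regulation of blood pressure over one
24-h cycle with four coupled ODEs for systemic vascular resistance
(SVR), systolic blood pressure (SBP), heart rate (HR) and diastolic
blood pressure (DBP), forced by three measured inputs: physical activity
A(t), plasma norepinephrine NE(t) and glycemia glc(t). Direct effects
are first-order; saturating regulatory interactions are Hill terms with
coefficient one wherever possible:

- vasoconstriction drive `k1 · ki1/(ki1+A) · NE/(glc^n + NE)`: activity
  inhibits net vascular resistance (exercise vasodilation dominates the
  visceral compensation), norepinephrine promotes and glycemia (via
  insulin) opposes vasoconstriction, coupled multiplicatively as a
  synergistic term;
- SVR autoregulation `−SVR²/(ki2+SVR)`: metabolic vasodilation when
  perfusion falls;
- pressure drive `k3·(SVR·HR/(ki3+HR) − SBP)`: pressure relaxes toward
  the product of resistance and a saturating function of heart rate
  (cardiac-output surrogate);
- heart-rate balance `k2·A/(ki4+A) − k4·DBP·HR`: activity-driven
  sympathetic input against baroreflex suppression.

The model deliberately omits fluid-volume, renal and pharmacological
sub-systems; it describes cohort-average profiles, not individual
beat-to-beat dynamics.

**DBP equation variant.** As formulated, the DBP equation repeats the
SBP equation (it relaxes toward −SBP, not −DBP), which makes the pulse
pressure DBP − SBP an exact invariant of every trajectory. This is
plausibly a transcription slip in the source formulation, so both forms
are shipped: `dbp_equation="as_printed"` (default, conserved pulse
pressure — asserted by tests) and `"relaxed_to_dbp"` (DBP relaxes to the
same target as SBP, so DBP → SBP asymptotically). Neither is asserted to
be the intended physiology; analyses record which variant produced them.

## Parameters

| name | meaning | units (canonical set) | reference dipper / non-dipper |
|------|---------|----------------------|-------------------------------|
| k1   | basal vasoconstriction rate | SVR·h⁻¹ | 614.7 (shared) |
| n    | glycemia impact exponent | – | 2.472 (shared) |
| ki1  | activity→SVR half-inhibition | activity counts | 801.3 / 544.2 |
| ki2  | SVR self-regulation constant | SVR units | 3861 (shared) |
| ki3  | HR half-saturation in pressure drive | beats·min⁻¹ | 805.3 / 748.4 |
| ki4  | activity→HR half-activation | activity counts | 24.79 / 10.86 |
| k2   | basal HR drive | HR·BP·h⁻¹ | 7654 / 6808 |
| k3, k4 | dimensional homogeneity / baroreflex rate | h⁻¹-scale | fixed at 1 |

k3 and k4 are fixed to one: they are almost perfectly correlated with
ki3 and k2 respectively, and freeing them destroys identifiability. The
source data never carried explicit units for A, NE, glc or the rate
constants, so this package fixes one canonical convention (activity in
device counts, NE in nmol/L, glycemia in mmol/L, time in hours) and
treats the reference magnitudes as meaningful only within it. All
acceptance-style checks are therefore internal-consistency and recovery
experiments, not magnitude matching against external cohorts.

## Synthetic data

The generators emulate the statistical structure of cohort-average
ambulatory recordings (30-min sampling, 48 nodes, midnight start, wake
at 8 a.m.):

- **activity**: night plateau (default 5 counts) during rest
  [0:00, 8:00), raised-cosine rise over 2 h after waking to a 100-count
  plateau with a shallow post-lunch dip, decline from 23:00; optional
  seeded Gaussian noise, clipped to [0, peak].
- **norepinephrine**: day-high (3.0 nmol/L) / night-low (1.5 nmol/L)
  with smooth transitions. The non-dipper profile multiplies every
  rest-window sample by 1.15 and leaves daytime samples untouched.
- **glycemia**: 5.0 mmol/L baseline plus three ~2 mmol/L postprandial
  excursions (meals at 8:30, 13:00, 20:00 — configurable; the peak sits
  1 h post-meal). The non-dipper profile scales the sample 2 h after
  breakfast/lunch/dinner by 4.7, 13.3 and 8.1% respectively, tapered
  with a ±1 h raised cosine so the profile stays smooth; the increase is
  exact at the 2-h node.

Observed datasets are forward simulations of the model on the 48-point
grid with multiplicative Gaussian noise, y = y_model·(1 + cv·z), and
attached dispersions σ = cv·y_model (floored at 1e-6 when cv = 0). The
default cv of 1% mirrors the tight cohort-average profiles the analysis
assumes. Because the data-generating process *is* the model, these
datasets support exact recovery experiments; they do not reproduce
features of real ambulatory data such as inter-subject heterogeneity,
measurement-device quantization, missing readings, autocorrelated
residuals or model misspecification — passing tests demonstrate the
correctness and conditioning of the machinery, not clinical validity.

Observed SVR in real cohorts is a derived quantity:
SVR = (MAP − RAP)·80/(SV·HR), with stroke volume 79.5 ml and right
atrial pressure 5 mmHg (standing in for central venous pressure). The
printed source of this formula is typographically ambiguous about the
MAP numerator; the default is the physiological standard
MAP = (SBP + 2·DBP)/3 with `(2·SBP + DBP)/3` available as
`map_convention="alternate"`. Its standard deviation is propagated from
σ(SBP), σ(DBP), σ(HR) by the first-order delta method under
independence (the original propagation rule is unstated; the delta
method is this package's choice).

## Simulation and calibration

Integration uses LSODA (stiff-capable) at rtol 1e-6 / atol 1e-9
(recorded in trajectory metadata), with inputs lifted to continuous time
by monotone piecewise-cubic interpolation (PCHIP; exact at nodes,
non-undershooting, hence nonnegative). Signals are treated as
24-h-periodic. Simulations of observed datasets start from the first
observed node; generated datasets start from a near-periodic state found
by a 48-h burn-in from the constant-input fixed point with an initial
pulse pressure of 15 model units (the model's pressure scale under the
canonical units is ≈ 50, so a physiologic 40 mmHg would drive DBP toward
zero).

The objective is F = (1/kN)ΣΣ((y_exp − y_model)/y_exp)², k = 4
variables, N nodes; 100·F is the "mean normalized squared error in
percent" quoted throughout. The optimizer is a seeded global search in
log10-parameter space: Latin-hypercube starts (default 24) over bounds
(default [v/100, 100v] around the reference magnitudes), objective
scoring of every start plus the configured reference point, then
bounded trust-region least-squares refinement of the best few (default
3). The Jacobian finite-difference step is fixed at 1e-4 in log10 space:
steps near machine precision fall below the ODE-solver noise floor and
stall the refinement. Failed integrations score as large constant
residuals. The best-so-far trace is recorded and is monotone by
construction; identical seeds give identical results.

Two-stage cohort protocol: stage 1 fits all seven constants per cohort
independently; stage 2 freezes the shared set {k1, n, ki2} at the
arithmetic mean of the stage-1 estimates (alternative rule: the
better-fitting cohort's values) and refits {ki1, ki3, ki4, k2} per
cohort. With the shared set frozen the summed objective separates, so
the stage-2 refits run per cohort; this is mathematically identical to
minimizing the sum.

## Sensitivity analysis

S_ij(t) = ∂y_i/∂p_j is integrated with the variational equations
dS/dt = J_y S + J_p (analytic Jacobians, S(0) = 0 because initial
conditions do not depend on parameters) at rtol 1e-8. A central
finite-difference route (relative step 1e-6, one parameter at a time)
over the plain simulator serves as the independent cross-check; the two
agree to better than 1e-3 after per-variable normalization. Per-variable
normalization matters: the SVR equation is decoupled from ki3, ki4 and
k2, so those sensitivity rows are identically zero and any pointwise
relative comparison there measures only finite-difference noise.

Relative sensitivities Srel = S·p_j/y_i feed the summary index
δ_j = (1/kN)ΣΣ Srel². The mean-of-squares form is the default; the
root-mean-square variant (the convention of the δ^msqr literature) is
selectable, since the aggregation the source used is not decidable from
its text.

## Identifiability

FIM = Σₙ S(tₙ)·W(tₙ)·S(tₙ)ᵀ from the absolute sensitivities. Default
weighting W = diag(1/σ²) (inverse variance, Cramér–Rao-consistent); the
literal variance weighting W = diag(σ²) — under which noisier data would
carry more information — is kept as an explicit option for comparison.
FIM⁻¹ approximates the estimate covariance: standard errors are the
square roots of its diagonal, 95% CIs are p ± 1.96σ, correlations are
κ_jh = σ²_jh/(σ_jj σ_hh), and pairs with |κ| > 0.95 are flagged as
identifiability threats. Inversion goes through a stable solve after an
SVD-based conditioning check; a reciprocal condition number below 1e-12
is declared singular, in which case the report carries the near-null
space instead of CIs. CIs are reported for free parameters only (k3 and
k4, being fixed, have none).

## Residual diagnostics

Residuals R = y_exp − y_model are computed for the directly measured
variables HR, SBP and DBP only; SVR is excluded because it is itself
calculated from them. Residuals are pooled across the three variables
(3·48 = 144 values; units mixed, as a single pooled QQ summary implies)
with a per-variable mode available. Normality is assessed by
Shapiro–Wilk at α = 0.05, QQ coordinates against standard-normal
quantiles with Blom plotting positions (i − 0.375)/(n + 0.25), and a
Sturges-binned histogram. The test's calibration is itself verified:
over 100 seeded standard-normal replicates of n = 144 the rejection rate
stays within Monte-Carlo error of 5%, and a ±5 bimodal mixture is
rejected.

## Problem sizes

All analyses run on the 48-node half-hour grid. Recovery experiments use
10–16 Latin-hypercube starts with 2 refinements (single-cohort refits of
four constants take ~10 s; the full two-cohort, seven-parameter protocol
about 80 s on one core); the Monte-Carlo noise-model check uses 300
replicate draws on an 8-node grid, and the normality calibration 100
replicates. These sizes were chosen as the smallest at which the checks
are statistically meaningful.

## Known limitations

- The as-printed pulse-pressure invariance means DBP carries no
  information beyond its initial offset from SBP; the `relaxed_to_dbp`
  variant changes this but is not the default.
- Parameter magnitudes are unit-convention-bound; comparisons across
  unit conventions are meaningless.
- The FIM approach is local (linearized about the fit); it cannot detect
  non-local non-identifiability, and no profile-likelihood or structural
  algebra is attempted.
- Sensitivity analysis is local by design; no variance-based global
  indices.
- Cohort-average fitting only: no hierarchical/per-subject modelling,
  no multi-day windows.
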