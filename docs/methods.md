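# Methods

## Model structure

The endpoint is plasma LDL-C (mg/dL) at week 12 of treatment. Drug effect
is modelled on dose directly (dose–response, not concentration–response):
each drug contributes a fractional lowering through a (sigmoid) Emax
relationship, and the two drug classes combine through a single bilinear
interaction term,

    E_total = E_BA + E_statin + γ·E_BA·E_statin,     γ = −1.35,

with all effects carried internally as positive fractions of baseline
lowered (published tables report them as negative proportional changes; the
sign is flipped once, on ingestion). A negative γ makes the combination
less than additive, consistent with both drugs inhibiting the same
cholesterol-synthesis pathway. The combination equation is not printed in
the source analysis; this bilinear form is the only single-parameter form
we found that, with the fixed γ, reproduces every published combination
mean within one percentage point, and that numerical validation is frozen
into the test suite (plain additive and plain multiplicative alternatives
each miss at least four cells by more than two points).

LDL-C dynamics follow an indirect-effect turnover model in which effect
inhibits production: `dL/dt = k_in·(1 − E_total) − k_out·L`, `k_in =
baseline·k_out`. `k_out` is fixed at 0.01 h⁻¹ (literature-consistent;
steady-state week-12 data carry no information about it). At week 12
(2016 h) the transient term `exp(−k_out·t)` is ~2×10⁻⁹, so all week-12
predictions use the closed-form steady state `baseline·(1 − E_total)`; the
explicit time course exists for trajectory plots and for visits at other
weeks.

## Fixed parameters

Shipped as a packaged YAML fixture, keyed by drug:

| parameter | value | note |
|---|---|---|
| bempedoic acid Emax | 0.34 (SE 0.01) | fraction lowered |
| bempedoic acid ED50 | 44.0 mg (SE 3.8); 43.96 mg as fixed in combination models | |
| bempedoic acid Hill | 1 | sigmoid variant collapses to simple Emax |
| statin Emax | 0.787, shared | fixed without error |
| statin Hill | 0.451, shared | fixed without error |
| statin ED50 | 13.1 / 30.5 / 4.4 / 97.3 mg | atorva / simva / rosuva / prava |
| γ | −1.35, shared | fixed by sensitivity analysis |
| k_out | 0.01 h⁻¹ | always fixed |

Population parameters per combination model: baseline LDL-C typical values
177.9 / 160.4 / 171.9 / 156.7 mg/dL with baseline IIV CVs 27.1 / 25.5 /
30.4 / 24.2%, residual error (proportional, additive) per statin, and the
monotherapy model (baseline 147.1 mg/dL, IIV 23.0%, emax IIV 36.2%,
residual 8.4% + 11.4 mg/dL). Dose grids are {10, 20, 40, 80} mg, with no
80 mg level for simvastatin or rosuvastatin (not a labelled regimen in the
source analysis).

## Variability conventions

All inter-individual variability is log-normal and multiplicative:
`x_i = x_typ·exp(η)`, `η ~ N(0, σ²)` with `σ² = ln(1 + CV²)` so that the
typical value is the median and the printed CV is the distributional CV.
Under this convention the simulated mean untreated baseline of the shared
comparison population is `177.9·exp(σ²/2) ≈ 184.3 mg/dL`. Residual error is
combined proportional + additive with variance `(σ_prop·f)² + σ_add²`, the
common pharmacometric convention when the order of operations is not
stated.

Individual bempedoic acid maximal effects are `Emax·exp(η)` truncated below
1; total effects are clamped to [0, 1) in all simulation paths so simulated
LDL-C is never negative. The marginal likelihood deliberately does *not*
clamp: clamping puts a kink in the integrand that degrades quadrature,
while the unclamped density remains proper (extreme tail draws predict
unphysical values with negligible probability mass).

## Report simulations

The percent-change and absolute-LDL prediction tables and the
goal-attainment curves follow the published simulation procedure: 1000
patients per dosing condition, one patient per parameter-replicate set,
with the baseline population (typical value and IIV) of the atorvastatin
combination model shared across all statins — the highest-baseline
condition, making cross-statin cells comparable. Parameter uncertainty is a
parametric bootstrap: normal draws for the bempedoic acid Emax and ED50
(the only effect parameters reported with standard errors); statin and
interaction parameters are fixed without error and therefore do not spread.
The multiplicative emax IIV is used when generating observation-level
datasets, not in these prediction summaries, which describe model-predicted
(typical-individual) LDL-C rather than observations.

The shared patient pool is drawn once per table and reused across
conditions, and all normal draws are made in antithetic pairs (z, −z).
Both are pure variance-reduction choices: between-cell contrasts are not
diluted by independent noise, and the mean of the simulated baseline
distribution is pinned near its analytic value (~184.3 mg/dL) instead of
wandering ±1.6 mg/dL between seeds. The sampled distributions are
unchanged. 90% intervals are empirical 5th–95th percentiles of the
per-patient (i.e. per-replicate) values; with every combination-model
effect parameter fixed, statin-monotherapy intervals are degenerate by
construction — the published intervals for those cells additionally carry
non-parametric bootstrap of the original datasets, which cannot be
reproduced without them.

Goal attainment is the strict-inequality proportion of simulated patients
below 100 and 70 mg/dL (2.6 and 1.8 mmol/L).

## Pre-statin baseline imputation

Patients entering combination arms on stable statin therapy have their
entry LDL-C back-calculated to the off-statin scale by inverting the statin
model: `baseline = observed / (1 − E_statin(dose))`. Deterministic
inversion at the point effect is the reference behaviour; stochastic mode
draws the individual response log-normally around the point effect
(default CV 30%, configurable — the exact published uncertainty
parameterization is in supplementary material we treat as unavailable),
truncated so the drawn fraction stays below 0.95, then inverts. Every draw
is recorded in an audit column.

## Estimation

The mixed-effects model has at most two random effects per subject
(baseline, bempedoic emax). NONMEM's FOCE-I is not reimplemented; the
marginal likelihood integrates the random effects on a fixed Gauss–Hermite
grid (default 11 nodes per dimension), fully vectorized over subjects, with
a damped-Newton Laplace approximation implemented as an independent second
route. The tests cross-check the two against each other and against
brute-force adaptive 2-D integration on small datasets; at 41+ nodes the
quadrature agrees with the adaptive integral to ~10⁻⁵ relative, while the
11-node default trades ≲1% objective accuracy for an order-of-magnitude
speedup, which leaves parameter recovery unaffected in the replicate
studies. Degenerate (zero) variabilities collapse the corresponding
dimension exactly.

Free parameters are optimized on unconstrained scales (log; logit for
Emax) by L-BFGS-B from three seeded starts (relative objective tolerance
10⁻⁸); standard errors come from the inverse finite-difference Hessian with
a delta-method map back to the natural scale, and 95% CIs are Wald
intervals on the transformed scale (hence always bracketing the estimate).
Invalid parameter regions return a large penalty rather than raising, so
optimizers can back out. Fitting ED50 requires at least three distinct
bempedoic acid dose levels including 0; fewer raises an identifiability
error. Non-convergence is reported through a flag, not an exception.

γ is profiled on a grid with every other parameter fixed — mirroring the
sensitivity-analysis strategy by which it was originally fixed — rather
than freely estimated.

## Synthetic data

The generator emulates the statistical structure of the pooled trials:
log-normal baselines, log-normal emax IIV, combined residual error,
dose-ranging monotherapy arms and statin-background combination arms whose
week-0 record is the on-statin baseline (statin effect already applied), so
the imputation stage receives realistic input. Study labels are cosmetic
(no study-level random effect, matching the model actually fitted).
Monotherapy preset doses are {0, 60, 120, 180, 240} mg bracketing the
therapeutic 180 mg dose; because the smallest marketed dose sits above the
44 mg ED50, a `rich_design` variant adds a 20 mg arm so ED50 is cleanly
identifiable in recovery studies. It does not emulate dropout, titration,
adherence, covariate effects or study heterogeneity — so passing recovery
tests demonstrate internal consistency of model + estimator under the
model's own assumptions, not robustness to the messiness of real pooled
trial data.

Datasets are long-format CSV (one row per subject-visit) with a fixed
column set; writer/reader round trips are lossless (`%.17g` floats,
round-trip parsing).

## Problem sizes and determinism

Default problem sizes: 1000 patients per condition in report simulations,
1000 bootstrap replicates, 20 replicate trials (~1000 subjects each) in
the parameter-recovery study, 2000 subjects for γ profiling on a −3..0
grid in steps of 0.05. Every stochastic routine takes an explicit seed or
generator and is bit-reproducible under it; emitted artifacts carry
provenance headers (package version, fixture hash, seed).

## Known limitations

- Predictions outside the 180 mg bempedoic acid dose and the labelled
  statin grids inherit extra uncertainty the model does not quantify.
- Published interval widths for statin-monotherapy cells are not
  reproducible without the original datasets (see above); property-based
  checks (monotonicity, dominance, calibration) stand in for them.
- One published absolute-LDL cell (pravastatin 10 mg alone) sits ~2.7 mg/dL
  from our simulated mean — beyond the 2.5 mg/dL band the other 29 cells
  meet. The two published tables are mutually inconsistent for that cell
  (the percent-change table implies ~144.6 mg/dL at the published baseline
  mean, the absolute table prints 143.4), and the published untreated mean
  (183.1) sits ~0.8 Monte-Carlo standard errors below the analytic
  log-normal mean (184.3) that an unbiased simulation centres on.
- No pharmacokinetics, no ezetimibe or PCSK9-inhibitor effects, no
  covariate modelling.
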