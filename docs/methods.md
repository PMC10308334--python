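# Methods

This note records the models implemented in `evsense`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Two-state binding model

The kinetic module realizes the conformational-change binding scheme
A + B ⇌ AB ⇌ AB\* as the mass-action system

    d[AB]/dt  = ka1·C·(Rmax − AB − AB*) − kd1·AB − ka2·AB + kd2·AB*
    d[AB*]/dt = ka2·AB − kd2·AB*

with response R = AB + AB\*, C the molar analyte concentration during
association and C = 0 during dissociation. This is the standard
realization used by commercial SPR evaluation software for a two-state
reaction; mass-transport limitation is deliberately omitted (nothing in
the assay's flow regime requires it, and adding a transport compartment
would make the already-weakly-identified parameters worse). A bulk
refractive-index jump is available as an optional additive constant on
the association phase and defaults to 0, i.e. sensorgrams are treated
as double-referenced.

Equilibrium constants follow the convention KD1 = kd1/ka1 (M),
KD2 = kd2/ka2 (dimensionless), KD_total = KD1·KD2 (M). The package
always reports the product; for one published channel (anti-CD63) the
printed total disagrees with the product of its own printed stepwise
constants by ~7%, which we treat as a typographical inconsistency in
the published values and therefore exclude that single cell from
numerical checks.

### Numerics

Because each phase of the model is a linear 2×2 ODE system, two solvers
coexist deliberately:

* `simulate_two_state` integrates the nonlinear form with LSODA
  (stiff-capable, adaptive), relative tolerance 1e-9. The absolute
  tolerance is 1e-12 **scaled by the steady-state response amplitude**:
  analyte concentrations derived from particle counts are picomolar and
  produce responses ~10⁻⁷ of Rmax, so a fixed absolute tolerance would
  silently dominate the error budget at the low end of the calibration
  range.
* `dissociation_closed_form` and the fitting kernel use the exact
  eigen-decomposition solution x(t) = x_ss + V·e^{Λt}·V⁻¹(x₀ − x_ss).
  For strictly positive rates the dissociation matrix
  [[−(kd1+ka2), kd2], [ka2, −kd2]] always has real, distinct
  eigenvalues; a near-defective system (ka2 → 0 with kd1 ≈ kd2) is
  detected by eigenvector conditioning and handled with the matrix
  exponential, which realizes the limiting form. Tests pin the two
  routes together to 1e-8 relative over randomized rate sets.

### Fitting and identifiability

`fit_two_state` is a global nonlinear least-squares fit over
(ka1, kd1, ka2, kd2, Rmax) in log10-parameter space with bounds
[1e-8, 1e10] in native units. Residuals of each sensorgram are weighted
by the inverse of its RMS response so every concentration contributes
comparably (equivalently: noise proportional to signal). The start
strategy is (i) a data-driven center — ka1 from the initial association
slope R′(0) ≈ ka1·C·Rmax of the highest-concentration curve — and (ii)
a coarse multi-start grid, three points per decade on kd1 and ka2 over
[1e-4, 1e-1] crossed with kd2 ∈ {1e-6, 1e-4, 1e-2}. All starts are
scored by their initial residual, the best twelve are refined by
trust-region-reflective least squares, ties are broken by lowest
residual sum of squares then lowest parameter norm, and the winner is
polished by an unbounded Levenberg–Marquardt pass with a 3-point
finite-difference jacobian. The 3-point polish matters: near the
zero-residual optimum of a refit, 2-point jacobian noise stalls the
optimizer several orders of magnitude above the attainable residual
floor, which biases the sloppiest parameter (kd2) by factors.

One identifiability caveat is intrinsic to the study conditions, not to
the optimizer. At analyte concentrations of 10⁻¹⁶–10⁻¹³ M — far below
KD1 (10⁻⁶–10⁻⁴ M) — occupancy is ~10⁻⁸ and the model is linear in the
product ka1·Rmax; ka1 and Rmax cannot be separated by any amount of
data at those concentrations. Fits of study-condition data therefore
fix Rmax at its independently known value (physically, the saturation
response is set by the antibody-capture level, which the experiment
measures in a separate step). Single-concentration fits are allowed but
flagged `poorly_identified`. The reverse conformational rate kd2 is the
weakest-determined parameter whenever its timescale (1/kd2) exceeds the
390 s observation window; its standard error reflects this.

Parameter standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹·RSS/dof at the optimum, propagated from log10 to native units.

### Dissociation linearity diagnostic

`dissociation_linearity` regresses ln(R₀/R(t)) on t − t₀ over the
dissociation phase, with R₀ the response at the start of the
post-injection phase. The transform is exact for single-exponential
decay (slope = decay rate, r² = 1) and near-linear for two-state decay
over windows short relative to the slow eigenvalue — which is why the
diagnostic looks linear in this assay. Points at or beyond the first
non-positive response are dropped and the fit is flagged truncated; the
window is configurable.

## QCM-D analysis

**Step extraction.** Stages are annotated spans (buffer, csh,
activation, antibody, ev, regeneration). Within each stage the trailing
plateau is the longest end segment over which a moving 30-sample
window's slope stays below 0.01 Hz/s; the stage step is the difference
of consecutive plateau *medians* (robust to spikes), making steps exactly
offset-invariant and summing to the final offset from baseline. A stage
with no qualifying plateau contributes its trailing window and carries a
quality warning instead of failing.

**Sauerbrey conversion.** Γ = |Δf|·C_f/M with C_f = 17.7 ng cm⁻² Hz⁻¹
(5 MHz crystal, configurable). The cysteamine molar mass is 77.15 g/mol
— the free base, because that is the species actually chemisorbed on
gold after the hydrochloride deprotonates; this choice reproduces the
published 2.75 nmol/cm² from a 12 Hz step. The wet→dry correction is
dry = wet/(1 + h) with hydration excess h = 0.30 by default. Δf is
stored overtone-normalized (Δf_n/n) and the default analysis overtone is
n = 3; the source study does not state which overtone its numbers use.

**Antibody packing.** Close-packed 2D densities are Γ = 1/(N_A·A) with
footprints built from IgG dimensions (Fab arms 6.5 × 3.5 nm, Fc stem
5 × 3.5 nm): vertical 6.5 × 3.5 = 22.75 nm², tilted 10.5 × 3.5 nm²,
horizontal 10.5 × 6.5 nm². The effective molecular length of 10.5 nm is
a documented modelling choice: the published tilted and horizontal
densities (4.52 and 2.43 pmol/cm²) are reproduced to <0.5% by exactly
these footprints, whereas no combination of the raw Fab/Fc lengths does
so. The published antibody-layer surface concentrations themselves
(7.75/6.09/8.68 pmol/cm²) are *not* used as checks: they are not
numerically consistent with the quoted antibody-stage frequency shifts
under any stated molar mass and hydration, so the calculator exposes all
inputs and asserts nothing about that intermediate.

**Rigidity.** ΔD-vs-Δf slopes are ordinary least squares of the
dissipation series (1e-6 units) on the frequency series (Hz) over a
stage, both at the same overtone and ordered by time. Small |slope|
indicates a rigid film. The two-segment variant fits a continuous
broken stick by exhaustive breakpoint search over sample abscissae with
at least 10 points per segment; since the single line is nested in every
candidate, the segmented SSE can never exceed the single-line SSE, and a
fit whose two slopes agree within 1e-6 is flagged as having no
breakpoint. This captures the crowding behaviour seen at the highest EV
concentration, where vesicle deformation softens the layer and the
slope steepens beyond a breakpoint.

## Calibration and quantification

Calibration is OLS of signal on log10(C), requiring at least three
distinct positive concentrations. Signal conventions: QCM-D uses the
magnitude of the EV-stage frequency step (the published relations then
have positive slope); SPR uses the EV-response/antibody-capture-response
ratio. The critical signal for detection is blank mean + 3·SD from
(by default five) blank replicates, converted to concentration through
the calibration — the standard IUPAC-style construction; the source
study defines the 3·SD rule but not the conversion, so published LODs
are treated as order-of-magnitude context rather than targets. LOQ is
exactly 3.3 × LOD before rounding; *reported* LOD/LOQ values are rounded
to two significant figures, half-up, which reproduces all six published
LOQ cells from their LODs.

Quantification inverts C = 10^((signal − intercept)/slope) × dilution.
Validity is judged at the measured (post-dilution) concentration, which
must lie strictly inside (10⁴, 10⁷) particles/mL; boundary values are
invalid (a 1e-12 relative guard keeps floating-point boundary hits on
the invalid side). The recommended default dilution is 10⁵-fold.
Replicate rows of a panel are aggregated to mean ± SD; method agreement
against the reference is summarized as per-channel mean relative
difference, overall mean absolute relative difference, and per-sample
flags beyond a 50% default limit. Precision uses RSD = 100·SD/mean, and
regeneration QC passes at ≥ 90% signal retention by default.

## Synthetic-data generator

The generator emulates the study conditions: four EV concentrations
6.1×10⁴…6.1×10⁷ particles/mL; 90 s association / 300 s dissociation
sensorgrams from the published per-channel rate sets; QCM-D staircases
with a −12 Hz cysteamine step, antibody totals of −27/−37.5/−30.3 Hz
(inclusive of the cysteamine offset), and EV steps following the
published log-linear relations; five-replicate blank sets; and
sample panels with reference values.

Choices the source does not pin down, fixed once and documented here:

* **Noise.** No noise figures are published. Defaults: SPR additive SD =
  1% of each sensorgram's maximum response (multiplicative CV also
  available and used for the noisy-refit experiments); QCM-D frequency
  noise SD 0.2 Hz and dissipation noise SD 0.05×10⁻⁶, typical magnitudes
  for a modern dissipation-monitoring instrument; linear drift defaults
  to 0. Blank SDs (0.2 Hz QCM-D, 0.03 ratio units SPR) put LODs on the
  10³–10⁴ particles/mL scale of the assay.
* **Panel noise** is a 10% CV multiplicative factor on the *effective
  captured concentration* per replicate (capture-efficiency
  variability), not on the signal: variability in this assay enters
  before the log-linear transduction, and a signal-domain CV of similar
  size would correspond to implausible order-of-magnitude concentration
  errors. Reference (NTA-style) values carry a 5% CV.
* **Saturation response** Rmax = 100 response units (not published;
  typical antibody-capture level for this chip class).
* **SPR calibration coefficients** are published only graphically, so the
  generator's defaults (slope 0.25 ratio-units/decade, intercept −1.0)
  are synthetic placeholders, labelled as such and never compared to
  published values.
* **Stage timing**: 600 s per QCM-D stage at 1 Hz with a 60 s exponential
  approach to each plateau (the source states only "after at least
  60 min" for antibody saturation); ΔD is co-generated from per-stage
  ΔD/Δf slopes with antibody-stage defaults inside the observed
  [−0.043, −0.029] interval, and an optional two-segment EV-stage mode
  (slopes −0.02/−0.06, breakpoint at 60% of the step) for the
  highest-concentration crowding behaviour.

Determinism: every generator draws from a `SeedSequence` keyed by
(master seed, product stream, stable per-channel key), so equal
configurations are bit-identical, across processes, while different
products are statistically independent.

What the generator does **not** emulate — and hence what passing tests
do and do not show: instrument artifacts beyond Gaussian noise and
linear drift (spikes, air bubbles, baseline steps), mass-transport
limitation, overtone-dependent viscoelastic spreading, non-specific
binding, and matrix effects of real biofluids. Tests demonstrate that
the *analysis* is correct and self-consistent under the stated
statistical model, not that the physical assay behaves ideally.

## Problem sizes

The test suite and the acceptance script use: 391-point sensorgrams at
four concentrations (1564 points per global fit); 100 random rate sets
for the closed-form/ODE equivalence; 50 seeds for the segmented-fit SSE
property; 200 seeded replicates of a 3-sample, 3-channel panel for the
end-to-end recovery experiment. These sizes give stable statistics for
every check while keeping a full run in the tens of seconds on one CPU.

## Known limitations

* The two-state fit cannot separate ka1 from Rmax at study-condition
  concentrations (see above); reported ka1 values under those conditions
  are conditional on the supplied Rmax.
* kd2 values with timescales far beyond the dissociation window carry
  large standard errors; comparing refitted kd2 against a generating
  value is only meaningful through its (small) effect on the trace.
* The LOD depends on the blank-set statistics of the specific run;
  published LODs cannot be reproduced exactly because the underlying
  blank replicates are not available.
* Breakpoint location in the two-segment fit is quantized to sample
  abscissae; its accuracy is bounded by the local Δf sampling density.
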