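# Methods

This note documents the models, numerical choices and open design decisions
behind `mirferm`, and what the simulation results do and do not establish
about real fermentations.

## Spectral model and band-height extraction

Spectra live on an ascending wavenumber grid restricted to 650–3000 cm⁻¹, the
region an ATR probe covers usefully in aqueous media. The synthetic grid uses
1 cm⁻¹ spacing (2351 points) so the nominal band centres (1035 and
1400 cm⁻¹) are exactly on-grid; the real instrument's optical resolution is
coarser (8 cm⁻¹), but its data-point spacing is not a constraint the twin
needs to reproduce.

Quantitation is deliberately univariate. "Peak intensity" is implemented as
**baseline-corrected height at the in-window maximum**, not band area: height
at a nominal single wavenumber is the standard univariate ATR practice and is
what an affine Beer–Lambert template expects. The baseline is the straight
line through the spectrum at the two endpoints of the *baseline window*
(nearest grid points, inclusive), evaluated across the *location window*.
With only a two-bound baseline range specified and no polynomial order, the
two-endpoint chord is the minimal defensible choice; for the glucose band the
baseline window (1058–1004 cm⁻¹) is offset within the wider location window
(1058–978 cm⁻¹), so below 1004 cm⁻¹ the chord is extrapolated. Ties in the
argmax break toward the higher wavenumber.

Two consequences worth knowing:

* Adding any affine function of wavenumber to a spectrum leaves band heights
  unchanged (baseline invariance); constant media backgrounds therefore do
  not need to be known, only stable across a band's windows.
* Because the readout is a *maximum*, a band whose true height is negative
  (concentration below the template intercept, see below) is not recovered:
  the readout saturates near zero and the predicted concentration saturates
  near the intercept. The templates' working range is therefore
  concentrations above their intercepts (≈ 7 g/L for glucose, ≈ 0.7 g/L for
  glutamate); all control scenarios operate far above these.

## Calibration templates

Templates are exactly affine, `c = slope · A + intercept`, with `slope` the
inverted empirical εl term (g/L per AU) and `intercept` the constant
background absorbance of the complex medium expressed in concentration units.
The shipped defaults are the published coefficients (glucose 870.29 / 6.955;
glutamate 526.196 / 0.6888), frozen as package data; fitting always produces
new template objects.

Two estimators are provided because both appear in practice: ordinary least
squares of concentration on absorbance (default), and absorptivity averaging
(slope = mean of `(c − intercept)/A` at a fixed intercept). They agree
exactly on noiseless affine data and differ otherwise; the ratio estimator is
ill-conditioned near zero absorbance and guards against it. R² validation
regresses **reference on predicted** (the off-line analyzer as response);
with both axes noisy the direction is a convention, and this one is
documented rather than configurable. Off-line and in-line MIR measurements
share one noise model; any freeze–thaw effect on off-line samples is not
modelled separately.

Predictions are not clipped to non-negative by default; the control layer
sees raw template output (clipping is available as an option).

## Plant surrogate

No kinetic constants are published for the emulated process, so the plant is
a qualitative surrogate chosen once:

* **Logistic biomass growth**, `dX/dt = mu·X(1 − X/Xmax)`, mu = 0.25 h⁻¹,
  Xmax = 30 g/L, X0 = 0.1 g/L: accelerating-then-saturating growth, which is
  exactly the demand profile that stresses a feed controller.
* **Per-biomass consumption**, q_glc = 0.08 and q_glu = 0.05 g·g⁻¹·h⁻¹, so
  nutrient demand rises from negligible to ≈ 2.4 / 1.5 g/h as biomass
  approaches its ceiling.
* **Starting concentrations** 45 g/L glucose and 30 g/L glutamate (both
  above the 20 g/L trigger), V0 = 1 L in a 2-L vessel; feed stocks 600 g/L
  glucose and 400 g/L MSG, stored as 0.6 / 0.4 g/mL so that pumped-volume ×
  stock is grams and the soft-sensor units come out directly.
* **Explicit Euler at dt = 1 min.** The dynamics are smooth and desk-scale,
  and Euler makes the mass bookkeeping *exact*: final mass = initial +
  pumped − integrated consumption to machine precision, which the test suite
  asserts at 1e-6 g. Volume equals V0 plus pumped volume exactly.
  Working-volume excursions (40–70 % of a 2-L vessel) warn but do not stop a
  run. Antifoam additions and gas stripping are not modelled.

Synthetic spectra are sums of Gaussian bands (FWHM 14 cm⁻¹) whose heights
invert the templates, `h = (c_eff − intercept)/slope`, plus a constant
per-analyte media offset `intercept/slope` (removed again by baseline
correction), a secondary glutamate carbonyl band at 1556 cm⁻¹ (1.2× the
1400 cm⁻¹ height, outside every quantitation window), additive white noise
(sd 1e-4 AU) and an optional linear drift. `c_eff` carries the 2 %
multiplicative probe error; the reference analyzer applies 10 %
multiplicative error, its stated accuracy. (The 5 % figures quoted for
probes refer to temperature/pH probes, which are not modelled.) One run seed
spawns independent substreams (spectral, probe, reference), so switching one
noise source on or off never shifts another's draws; within each tick the
order is probe perturbations (glucose, then glutamate), then the spectral
noise vector, then any reference draws.

## Control regimes

The batch→fed-batch **trigger** latches per analyte the first time an
actionable measurement falls to 20 g/L (inclusive); it never reverts.

* **auto** — every in-line measurement (5-min cadence) updates a discrete
  P(ID) law: rectangle-rule integral, backward-difference derivative, output
  clamped to [0, 200] mL/h with conditional-integration anti-windup (the
  integral is held while the output is clamped — irrelevant at the default
  P-only gains, required for nonzero Ki). Default Kp = 50 mL/h per g/L.
* **manual** — off-line reference draws at 08:00/12:00/16:00 (run clock
  starts at midnight; the schedule is config-exposed, "business hours"
  constrains it to an 8-h daily window). The operator rule pumps the mass
  needed to cover estimated consumption plus the setpoint gap before the
  *next* scheduled sample: `rate = [C·H + (setpoint − measured)·V]/(S·H)`.
  The consumption estimate is the soft sensor on the two most recent
  off-line values (zero until two exist).
* **semi** — the same operator rule applied to in-line values every 4 h
  around the clock (the interval is a choice; only "beyond business hours"
  is specified for remote operation).

Controllers act on measured values only; true state is logged for metrics.
In *all* regimes the in-line probe runs passively at its 5-min cadence and
its readings are logged, mirroring the practice of recording in-process
traces even for manually controlled runs; regime comparisons are made on
this common observable. Pump rates change only at measurement events. Errors
are taken in g/L (not normalized); pump rates are mL/h throughout, with any
rpm display treated as an external linear scale.

**Discrete P-loop dynamics.** The proportional loop's discrete gain is
`g = h·Kp·S/V` (h the measurement interval). For g ≤ 1 the loop settles to
the classic proportional offset `e* = C/(Kp·S)` (C the current consumption
in g/h). At the default Kp = 50, S = 0.6 g/mL, h = 5 min and V ≈ 1 L,
g ≈ 2.1–2.5 — slightly past the oscillatory-stability limit — so the loop
limit-cycles around `e*` with peak tick error ≈ `C·h/V` (≈ 0.2 g/L),
bounded by the no-negative-pumping clamp. The tests assert the tick-wise
offset bound in the stable-gain region (Kp = 20) and the *time-averaged*
bound at the default gain; both hold. The default gain was kept because it
reproduces tight (≈ ±0.2 g/L) setpoint holding rather than textbook
asymptotics.

## Deviation metric and regime comparison

Cumulative deviation is the rectangle-rule sum Σ|value − setpoint|·Δt over a
window (default 48 h), each sample carrying to the next, the last to the
window end — matching a spreadsheet computation from interval samples rather
than trapezoidal integration (config-switchable). It is nonnegative,
nondecreasing, additive over contiguous sub-windows and insensitive to
zero-width duplicate time points.

For **regime comparison** the window opens at the earliest fed-batch trigger
among the compared runs and extends over the controlled span common to them
(`align="feed_start"`, the default; `align="run_start"` integrates from
time zero). Rationale: under the default surrogate kinetics the trigger
fires at ≈ 33 h, and the shared, uncontrolled batch descent from 45 to
20 g/L contributes an identical ≈ 600 g·h/L to every regime; integrating it
would reduce any regime contrast to a ratio near 1 while measuring nothing
about control. Since the plants are bit-identical until feeding starts, the
feed-start alignment scores exactly the part of the run the regimes can
influence. The published comparisons are of runs under active setpoint
control throughout their windows, which this alignment mirrors.

## Soft sensor

`C_t = (G_{t−1}V_{t−1} − G_t V_t + F·S)/I` is an interval mass balance:
consumed mass = mass that disappeared plus mass pumped in. Applied to the
true state of a noiseless run it inverts the Euler bookkeeping exactly
(equality to ~1e-9 when biomass is constant); applied to the in-line
measured values it tracks the plant's true q·X·V interval average within
2 %, the residual being the baseline-anchoring bias of the band readout. No
smoothing is applied by default; a centred moving average is available.

## What the synthetic experiments show — and what they don't

The twin demonstrates *internal consistency*: the quantitation path inverts
the spectral model to 0.1–0.3 %, the controller holds setpoint to the
predicted offset, the automated regime beats remote-operator and manual
control by large factors (≈ 30× and ≈ 20× on the default scenario), and the
calibration-validation surrogate reproduces the R² ≈ 0.95 that a 10 %
reference error implies. None of this validates the *plant*: growth and
consumption defaults are surrogate choices, real MIR spectra contain
overlapping media bands, temperature sensitivity and fouling that the
Gaussian model omits, and real analyzer errors need not be multiplicative
Gaussian. Passing tests certify the method's logic and software, not the
biology. Drug-substance yield is not modelled mechanistically; the yield
t-test summary exists for analysing (synthetic or user-supplied) per-run
yields only.

Two stochastic checks sit exactly at their nominal thresholds by
construction and can land on either side of them: with c ~ U[5, 60] g/L,
10 % reference and 2 % probe error, the population R² between reference and
prediction is
`var(c)² / [(var(c)+0.01·E[c²])(var(c)+0.0004·E[c²])] ≈ 0.949`, so a
median-R² ≥ 0.95 criterion is a coin flip at n = 30 × 100 replicates; and
the OLS slope's sampling sd under the same reference noise is ≈ 4.5 % of
truth, so "within 5 % of truth" holds for ≈ 75 % of replicates, not 95 %.
Both are properties of the stated noise conditions, not implementation
defects, and the corresponding tests are left asserting the nominal values.

## Problem sizes

Default runs simulate 48 h at 1-min steps (2 881 ticks, 577 in-line
spectra per regime); the validation surrogate uses 100 replicates of 30
samples; slope recovery uses 500 replicates. The full test suite runs in
well under a minute on one core.
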