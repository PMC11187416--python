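# mirferm

A digital twin for **in-line mid-infrared (MIR) metabolite monitoring and
automated fed-batch feed control** in stirred-tank fermentation.

In pharmaceutical process development, glucose and glutamate (MSG) levels in a
fermenter are traditionally controlled by hand: operators draw samples during
business hours, assay them off-line, recalculate feed-pump speeds in a
spreadsheet, and adjust pumps manually — with predictable overnight over- and
under-shooting. An in-line MIR spectrometer with an ATR probe changes that: the
absorbance of a metabolite band, read every few minutes directly in the broth,
is converted to concentration by a simple Beer–Lambert template and fed to a
proportional controller that drives the feed pumps continuously.

`mirferm` implements that entire loop as simulation-backed, testable code, for
process-development scientists and control engineers who want to study, tune
or regression-test such a system at their desk:

* **spectra** — spectrum container, water-background subtraction, univariate
  baseline-corrected band-height extraction (glucose 1058–978 cm⁻¹, nominal
  1035 cm⁻¹; glutamate 1413–1393 cm⁻¹, nominal 1400 cm⁻¹).
* **calibration** — affine Beer–Lambert templates
  `c (g/L) = slope · A + intercept`, shipped with the published coefficients
  (glucose `870.29 · A + 6.955`, glutamate `526.196 · A + 0.6888`), plus OLS
  and absorptivity-averaging estimators and R² validation.
* **plant_sim** — synthetic fed-batch plant (logistic biomass, per-biomass
  consumption, two feed pumps with 600 g/L glucose / 400 g/L MSG stocks,
  explicit-Euler mass bookkeeping) and synthetic spectra with a 10 %
  reference-analyzer and 2 % probe noise model.
* **control** — batch→fed-batch trigger at 20 g/L, discrete P(ID) law with
  anti-windup, the manual operator rule, and closed-loop runners for the
  manual / semi-automated / fully automated regimes.
* **analytics** — cumulative deviation-from-setpoint integral (g·h/L over a
  48-h window), fold-reduction comparison, the consumption-rate soft sensor
  `C_t = (G_{t−1}V_{t−1} − G_t V_t + F·S)/I`, and yield t-test summaries.
* **cli / io / config** — `mirferm simulate|calibrate|quantify|compare-regimes|metrics`,
  plain-text CSV/YAML/JCAMP-DX I/O, schema-validated run configs with frozen,
  hash-stamped copies for bit-identical replay.

## Worked example

Quantify a spectrum (here a synthetic 30 g/L glucose broth spectrum):

```bash
$ mirferm quantify demo_spectrum.csv
glucose: absorbance=0.02647 AU at 1035 cm^-1 -> 29.993 g/L
glutamate: absorbance=0.00000 AU at 1413 cm^-1 -> 0.689 g/L
```

The glucose band height (0.02647 AU above its anchored baseline, peaking at
the nominal 1035 cm⁻¹) maps through the default template to 29.99 g/L — the
true 30 g/L within the 0.1 % baseline-anchoring error. With no glutamate band
present, that template returns its intercept, i.e. the constant background of
the medium.

Compare control regimes on one identical simulated fermentation:

```python
import mirferm as mf

controllers = {a: mf.ControllerConfig(setpoint=20.0, Kp=50.0) for a in mf.ANALYTES}
runlogs, summary = mf.compare_regimes(
    mf.PlantParams(), mf.NOISELESS, controllers, seed=1)
print(summary[summary.analyte == "glucose"].to_string(index=False))
```

```
 regime analyte  window_start_h  window_h  cumulative_deviation_g_h_per_L  fold_vs_best
 manual glucose       32.833333 15.166667                       46.201345     30.052723
   semi glucose       32.833333 15.166667                       37.811789     24.595543
   auto glucose       32.833333 15.166667                        1.537343      1.000000
```

Reading the table: glucose falls to the 20 g/L trigger at t ≈ 32.8 h. From
there, thrice-daily manual sampling accumulates 46.2 g·h/L of absolute
deviation from setpoint, a 4-hourly remote operator 37.8 g·h/L, and the 5-min
proportional loop only 1.54 g·h/L — a **30-fold** reduction for full
automation over manual control on this run.

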