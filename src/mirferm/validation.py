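"""Calibration-validation surrogates.

Desk-scale replacements for the wet-lab calibration checks: paired in-line /
reference measurements are simulated at known true concentrations, pushed
through the full synthetic-spectrum quantitation path, and scored with the
same statistics used on real runs (R² of reference vs predicted; fitted-slope
recovery).
"""

from __future__ import annotations

import numpy as np

from .calibration import (
    PairedObservation,
    default_template,
    fit_template_ols,
    predict_concentration,
    validate_r2,
)
from .plant_sim import NoiseModel, NoiseStreams, ReactorState, synth_spectrum
from .spectra import band_absorbance


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_inline_validation(
    n: int = 30,
    n_replicates: int = 100,
    conc_range: tuple[float, float] = (5.0, 60.0),
    noise: NoiseModel = NoiseModel(),
    analyte: str = "glucose",
    seed: int = 0,
) -> dict:
    """Replicated R² between in-line predictions and reference measurements.

    Per replicate: ``n`` true concentrations uniform on ``conc_range``; the
    in-line value goes through synthetic spectrum → band height → template
    (2% probe error by default), the reference value through the analyzer's
    10% multiplicative error; R² is the coefficient of determination of
    reference on predicted. Returns per-replicate R² values and their median.
    """
    tmpl = default_template(analyte)
    r2 = np.empty(n_replicates)
    for rep, s in enumerate(_child_seeds(seed, n_replicates)):
        streams = NoiseStreams.from_seed(s)
        rng = np.random.default_rng(np.random.SeedSequence([s, 1]))  # truth draws
        truth = rng.uniform(*conc_range, size=n)
        predicted = np.empty(n)
        reference = np.empty(n)
        for i, c in enumerate(truth):
            state = ReactorState(t=0.0, V=1.0, X=1.0, conc={analyte: c},
                                 phase={analyte: "batch"})
            spec = synth_spectrum(state, {analyte: tmpl}, noise, streams)
            predicted[i] = predict_concentration(
                tmpl, band_absorbance(spec, tmpl.band))
            reference[i] = max(
                c * (1.0 + noise.ref_cv * streams.reference.standard_normal()), 0.0)
        r2[rep] = validate_r2(predicted, reference)
    return {"r2": r2, "median_r2": float(np.median(r2)),
            "n": n, "n_replicates": n_replicates}


def slope_recovery_experiment(
    n: int = 30,
    n_replicates: int = 500,
    conc_range: tuple[float, float] = (5.0, 60.0),
    ref_cv: float = 0.10,
    analyte: str = "glucose",
    rel_tol: float = 0.05,
    seed: int = 0,
) -> dict:
    """OLS slope recovery under reference noise.

    Per replicate: ``n`` true concentrations uniform on ``conc_range``; exact
    band absorbances from the default template; reference concentrations with
    multiplicative CV ``ref_cv``; refit by OLS and compare the slope to truth.
    Returns the per-replicate relative slope errors and the fraction within
    ``rel_tol``.
    """
    tmpl = default_template(analyte)
    errors = np.empty(n_replicates)
    for rep, s in enumerate(_child_seeds(seed, n_replicates)):
        rng = np.random.default_rng(s)
        truth = rng.uniform(*conc_range, size=n)
        absorb = (truth - tmpl.intercept) / tmpl.slope
        ref = truth * (1.0 + ref_cv * rng.standard_normal(n))
        pairs = [PairedObservation(absorbance=float(a),
                                   reference_concentration=float(max(c, 0.0)))
                 for a, c in zip(absorb, ref)]
        fitted = fit_template_ols(pairs, tmpl.band)
        errors[rep] = (fitted.slope - tmpl.slope) / tmpl.slope
    frac = float(np.mean(np.abs(errors) <= rel_tol))
    return {"relative_errors": errors, "fraction_within_tol": frac,
            "rel_tol": rel_tol, "n": n, "n_replicates": n_replicates}
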