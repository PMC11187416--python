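"""Synthetic fed-batch fermentation plant and in-line MIR probe.

This module is the digital stand-in for the 2-L stirred-tank fermenter, its
two feed pumps, the in-line ATR probe and the off-line reference analyzer.

Growth model
------------
No kinetic constants are published for the process this package emulates, so
the plant uses the simplest model with the right qualitative shape: logistic
biomass growth (accelerating early, saturating at a ceiling ``Xmax``) with
per-biomass metabolite consumption,

    dX/dt = mu·X·(1 − X/Xmax)
    d(G·V)/dt = −q·X·V + F·S          (per analyte, mass units g/h)
    dV/dt = Σ F / 1000                (pump rates F in mL/h)

integrated by explicit Euler at ``dt`` (default 1 min). Under Euler the mass
bookkeeping is exact, which the tests exploit: final mass equals initial mass
plus pumped mass minus integrated consumption to machine precision. The
accelerating-then-saturating nutrient demand is what stresses a feed
controller, which is the point of the surrogate. All kinetic defaults are
surrogate choices, not measured values.

Measurement model
-----------------
Synthetic spectra are sums of Gaussian bands on the 650–3000 cm⁻¹ grid whose
heights invert the calibration templates, so that the full quantitation path
(band height → affine template) recovers the true concentration up to noise
and the small baseline-anchoring error. The reference analyzer applies 10%
multiplicative Gaussian error (its stated accuracy); the in-line probe path
applies 2% plus additive spectral white noise. Noise streams are independent
(spawned from one seed) so disabling one source never shifts another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import CalibrationTemplate
from .spectra import DEFAULT_GRID, GLUTAMATE_SECONDARY_CENTER, Spectrum, gaussian_band

#: Analyte processing order; fixes the RNG draw order (glucose, then glutamate).
ANALYTES = ("glucose", "glutamate")

#: Feed stock concentrations, g/mL (600 g/L glucose, 400 g/L MSG).
FEED_STOCKS = {"glucose": 0.600, "glutamate": 0.400}

#: Gaussian band full width at half maximum for synthetic spectra, cm⁻¹.
BAND_FWHM = 14.0

#: Working-volume warning band for the default 2-L vessel, litres.
WORKING_VOLUME_L = (0.8, 1.4)


@dataclass(frozen=True)
class PlantParams:
    """Plant kinetics and initial conditions (all surrogate defaults).

    mu : specific growth rate, 1/h.
    Xmax, X0 : biomass ceiling and inoculum, g/L wet weight.
    q : per-biomass consumption rates, g analyte / g biomass / h.
    G0 : starting concentrations, g/L (both above the 20 g/L feed trigger).
    V0 : starting volume, L. dt : Euler step, h.
    """

    mu: float = 0.25
    Xmax: float = 30.0
    X0: float = 0.1
    q: dict = field(default_factory=lambda: {"glucose": 0.08, "glutamate": 0.05})
    G0: dict = field(default_factory=lambda: {"glucose": 45.0, "glutamate": 30.0})
    V0: float = 1.0
    dt: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        scalars = {"Xmax": self.Xmax, "X0": self.X0, "V0": self.V0, "dt": self.dt}
        for name, v in scalars.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")  # 0 = null plant
        for a in ANALYTES:
            if self.q.get(a, -1) < 0:
                raise ValueError(f"q[{a!r}] must be >= 0 and present")
            if self.G0.get(a, -1) <= 0:
                raise ValueError(f"G0[{a!r}] must be > 0 and present")

    def initial_state(self) -> "ReactorState":
        return ReactorState(
            t=0.0,
            V=self.V0,
            X=self.X0,
            conc=dict(self.G0),
            phase={a: "batch" for a in ANALYTES},
        )


@dataclass
class ReactorState:
    """Plant state vector: time, volume, biomass, concentrations, phases."""

    t: float  # h
    V: float  # L
    X: float  # g/L
    conc: dict  # analyte -> g/L
    phase: dict  # analyte -> "batch" | "fedbatch"

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        for a, c in self.conc.items():
            if c < 0:
                raise ValueError(f"concentration of {a} must be >= 0, got {c}")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise configuration.

    ref_cv : reference-analyzer multiplicative CV (stated 10%).
    probe_cv : in-line probe multiplicative CV on concentration (2%).
    spectral_sd : additive white noise per spectral point, AU.
    drift_AU_per_h : constant spectral offset growing with run time.
    seed : default seed when no external RNG streams are supplied.
    """

    ref_cv: float = 0.10
    probe_cv: float = 0.02
    spectral_sd: float = 1e-4
    drift_AU_per_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ref_cv", "probe_cv", "spectral_sd", "drift_AU_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def silent(self) -> "NoiseModel":
        """Copy with every noise source switched off."""
        return replace(self, ref_cv=0.0, probe_cv=0.0, spectral_sd=0.0,
                       drift_AU_per_h=0.0)


NOISELESS = NoiseModel(ref_cv=0.0, probe_cv=0.0, spectral_sd=0.0)


@dataclass
class NoiseStreams:
    """Named independent RNG substreams spawned from one seed.

    Keeping the spectral, probe and reference draws on separate generators
    means toggling one noise source cannot shift the draws of another.
    """

    spectral: np.random.Generator
    probe: np.random.Generator
    reference: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "NoiseStreams":
        children = np.random.SeedSequence(seed).spawn(3)
        return cls(
            spectral=np.random.default_rng(children[0]),
            probe=np.random.default_rng(children[1]),
            reference=np.random.default_rng(children[2]),
        )


def step_state(
    state: ReactorState,
    params: PlantParams,
    feed_rates: dict | None = None,
    feed_stocks: dict | None = None,
) -> ReactorState:
    """Advance the plant one explicit-Euler step of ``params.dt``.

    feed_rates : analyte -> pump rate, mL/h (missing analytes = pump off).
    feed_stocks : analyte -> stock concentration, g/mL (default 0.6 / 0.4).

    Concentrations are floored at zero after the update; volume increases by
    exactly the pumped volume.
    """
    feed_rates = feed_rates or {}
    feed_stocks = feed_stocks if feed_stocks is not None else FEED_STOCKS
    for a, r in feed_rates.items():
        if r < 0:
            raise ValueError(f"negative feed rate for {a}: {r}")
    dt = params.dt
    total_rate = sum(feed_rates.values())  # mL/h
    V_new = state.V + total_rate * dt / 1000.0
    conc_new = {}
    for a, c in state.conc.items():
        mass = c * state.V
        consumption = params.q.get(a, 0.0) * state.X * state.V  # g/h
        feed_mass = feed_rates.get(a, 0.0) * feed_stocks.get(a, 0.0)  # mL/h*g/mL
        mass = max(mass + dt * (feed_mass - consumption), 0.0)
        conc_new[a] = mass / V_new
    X_new = state.X + dt * params.mu * state.X * (1.0 - state.X / params.Xmax)
    lo, hi = WORKING_VOLUME_L
    if not lo <= V_new <= hi:
        warnings.warn(
            f"volume {V_new:.3f} L outside working-volume band [{lo}, {hi}] L",
            stacklevel=2,
        )
    return ReactorState(
        t=state.t + dt, V=V_new, X=X_new, conc=conc_new, phase=dict(state.phase)
    )


def synth_spectrum(
    state: ReactorState,
    templates: dict[str, CalibrationTemplate],
    noise: NoiseModel = NOISELESS,
    streams: NoiseStreams | None = None,
) -> Spectrum:
    """Background-subtracted synthetic spectrum of the current broth.

    For each analyte with a template, a Gaussian band at the template's
    nominal centre carries height ``(c_eff − intercept)/slope`` where
    ``c_eff`` is the true concentration with the multiplicative probe error
    applied, plus a constant media offset of ``intercept/slope`` AU (removed
    again by baseline correction, as in the real background medium).
    Glutamate additionally contributes its stronger 1556 cm⁻¹ carbonyl band
    (1.2× the 1400 cm⁻¹ height), which lies outside every quantitation
    window. White noise and a linear-in-time drift offset complete the model.
    Band heights go negative when concentration falls below the template
    intercept; this is the honest behaviour of an affine template.

    Draw order per call: one probe normal per templated analyte (glucose
    first), then the spectral white-noise vector.
    """
    if streams is None:
        streams = NoiseStreams.from_seed(noise.seed)
    grid = DEFAULT_GRID
    absorbance = np.zeros_like(grid)
    for a in ANALYTES:
        if a not in templates:
            continue
        tmpl = templates[a]
        c = state.conc.get(a, 0.0)
        z = streams.probe.standard_normal()
        c_eff = c * (1.0 + noise.probe_cv * z)
        h = (c_eff - tmpl.intercept) / tmpl.slope
        absorbance += gaussian_band(grid, tmpl.band.nominal_center, h, BAND_FWHM)
        if a == "glutamate":
            absorbance += gaussian_band(grid, GLUTAMATE_SECONDARY_CENTER, 1.2 * h,
                                        BAND_FWHM)
        absorbance += tmpl.intercept / tmpl.slope  # constant media background
    absorbance += noise.drift_AU_per_h * state.t
    if noise.spectral_sd > 0.0:
        absorbance += streams.spectral.normal(0.0, noise.spectral_sd, size=grid.shape)
    return Spectrum(grid, absorbance, label=f"synthetic t={state.t:.3f}h")


def measure_reference(
    state: ReactorState,
    noise: NoiseModel = NOISELESS,
    streams: NoiseStreams | None = None,
) -> dict[str, float]:
    """Off-line reference-analyzer draw: true value × (1 + N(0, ref_cv)).

    Values are floored at zero. The seeded stream is consumed in documented
    order (glucose, then glutamate) so replays are bit-identical.
    """
    if streams is None:
        streams = NoiseStreams.from_seed(noise.seed)
    out = {}
    for a in ANALYTES:
        z = streams.reference.standard_normal()
        out[a] = max(state.conc.get(a, 0.0) * (1.0 + noise.ref_cv * z), 0.0)
    return out
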