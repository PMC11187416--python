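"""Beer–Lambert univariate calibration.

Absorbance A at a fixed ATR pathlength is linear in concentration c
(A = εl·c), so concentration is recovered from a band height by an affine
template::

    concentration (g/L) = slope × absorbance + intercept

where ``slope`` is the inverted empirical εl term and ``intercept`` absorbs the
constant background absorbance of the medium. Two estimators are provided:
ordinary least squares of concentration on absorbance (the default), and the
absorptivity-averaging ratio estimator in which the slope is the mean of
(c − intercept)/A over the paired observations with a fixed intercept. The
two agree exactly on noiseless affine data and differ otherwise.

Default templates with the published glucose and glutamate coefficients ship
as a frozen package fixture; :func:`default_template` returns fresh copies.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from math import isfinite

import numpy as np
import yaml
from scipy import stats

from .errors import (
    DivisionGuardError,
    InsufficientDataError,
    SingularDesignError,
    UndefinedR2Error,
)
from .spectra import BandDefinition


@dataclass(frozen=True)
class FitStats:
    n: int
    r_squared: float
    residual_sd: float


@dataclass(frozen=True)
class CalibrationTemplate:
    """Affine Beer–Lambert map for one analyte.

    ``predict(A) = slope·A + intercept`` exactly; slope must be positive
    (absorbance increases with concentration).
    """

    analyte: str
    band: BandDefinition
    slope: float  # g/L per AU
    intercept: float  # g/L
    fit_stats: FitStats | None = None

    def __post_init__(self) -> None:
        if not (isfinite(self.slope) and self.slope > 0):
            raise ValueError(f"slope must be positive and finite, got {self.slope}")
        if not isfinite(self.intercept):
            raise ValueError("intercept must be finite")

    def predict(self, absorbance: float, clip_nonneg: bool = False) -> float:
        return predict_concentration(self, absorbance, clip_nonneg=clip_nonneg)


@dataclass(frozen=True)
class PairedObservation:
    """One (band absorbance, reference concentration) calibration point."""

    absorbance: float  # AU
    reference_concentration: float  # g/L
    time: float = 0.0  # h
    run_id: str = ""

    def __post_init__(self) -> None:
        if not isfinite(self.absorbance):
            raise ValueError("absorbance must be finite")
        if self.reference_concentration < 0:
            raise ValueError("reference concentration must be >= 0")


def _load_default_coefficients() -> dict:
    res = importlib.resources.files("mirferm").joinpath("data/default_templates.yaml")
    return yaml.safe_load(res.read_text())


_DEFAULTS = None


def default_template(analyte: str) -> CalibrationTemplate:
    """Return the frozen published template for ``analyte``.

    Glucose: c = 870.29·A + 6.955. Glutamate: c = 526.196·A + 0.6888.
    """
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _load_default_coefficients()
    try:
        spec = _DEFAULTS[analyte]
    except KeyError:
        raise KeyError(f"no default template for analyte {analyte!r}") from None
    band = BandDefinition(
        analyte=analyte,
        location_window=tuple(spec["band"]["location_window"]),
        baseline_window=tuple(spec["band"]["baseline_window"]),
        nominal_center=spec["band"]["nominal_center"],
    )
    return CalibrationTemplate(
        analyte=analyte, band=band, slope=spec["slope"], intercept=spec["intercept"]
    )


def default_templates() -> dict[str, CalibrationTemplate]:
    """Both default analyte templates, keyed by analyte name."""
    return {a: default_template(a) for a in ("glucose", "glutamate")}


def predict_concentration(
    template: CalibrationTemplate, absorbance: float, clip_nonneg: bool = False
) -> float:
    """Concentration (g/L) from a background-subtracted band absorbance."""
    if not isfinite(absorbance):
        raise ValueError(f"absorbance must be finite, got {absorbance}")
    c = template.slope * absorbance + template.intercept
    if clip_nonneg and c < 0.0:
        return 0.0
    return c


def fit_template_ols(
    pairs: list[PairedObservation], band: BandDefinition
) -> CalibrationTemplate:
    """Ordinary least-squares template: regress concentration on absorbance."""
    if len(pairs) < 2:
        raise InsufficientDataError(f"need >= 2 paired observations, got {len(pairs)}")
    a = np.array([p.absorbance for p in pairs])
    c = np.array([p.reference_concentration for p in pairs])
    if np.ptp(a) == 0.0:
        raise SingularDesignError("all absorbances identical; slope is unidentifiable")
    res = stats.linregress(a, c)
    resid = c - (res.slope * a + res.intercept)
    dof = max(len(pairs) - 2, 1)
    stats_ = FitStats(
        n=len(pairs),
        r_squared=float(res.rvalue**2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )
    return CalibrationTemplate(
        analyte=band.analyte,
        band=band,
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_stats=stats_,
    )


def fit_template_ratio(
    pairs: list[PairedObservation], band: BandDefinition, fixed_intercept: float
) -> CalibrationTemplate:
    """Absorptivity-averaging template: slope = mean[(c − intercept)/A].

    The intercept is fixed (e.g. from a blank medium measurement); each paired
    observation contributes one apparent inverse-absorptivity which is averaged
    over the observations.
    """
    if len(pairs) < 1:
        raise InsufficientDataError("need >= 1 paired observation")
    zero = [i for i, p in enumerate(pairs) if p.absorbance == 0.0]
    if zero:
        raise DivisionGuardError(
            f"zero absorbance in pairs at indices {zero}; cannot form ratio"
        )
    slopes = [
        (p.reference_concentration - fixed_intercept) / p.absorbance for p in pairs
    ]
    return CalibrationTemplate(
        analyte=band.analyte,
        band=band,
        slope=float(np.mean(slopes)),
        intercept=float(fixed_intercept),
        fit_stats=FitStats(n=len(pairs), r_squared=float("nan"), residual_sd=float("nan")),
    )


def validate_r2(predicted, reference) -> float:
    """R² of the OLS regression of reference on predicted concentrations.

    Reference (the off-line analyzer value) is treated as the response, so the
    statistic answers "how much of the reference variance does the in-line
    prediction explain".
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.ndim != 1:
        raise ValueError("predicted and reference must be 1-D of equal length")
    if len(predicted) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(predicted)}")
    if np.ptp(reference) == 0.0:
        raise UndefinedR2Error("reference series is constant; R^2 undefined")
    res = stats.linregress(predicted, reference)
    return float(res.rvalue**2)
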