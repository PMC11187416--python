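"""Spectrum container and univariate band-height extraction.

A :class:`Spectrum` is a wavenumber/absorbance pair on an ascending grid in the
mid-infrared fingerprint region (650–3000 cm⁻¹, the range an ATR probe in
aqueous culture media can usefully cover). Quantitation is univariate: a band
is summarised by its baseline-corrected peak height inside a *location window*,
with the straight baseline anchored at the two endpoints of a *baseline
window*. This is the standard single-wavenumber ATR practice for Beer–Lambert
calibration and deliberately avoids any multivariate chemometrics.

Band definitions for glucose (nominal 1035 cm⁻¹, C–O ether/alcohol stretches)
and glutamate (nominal 1400 cm⁻¹, carboxylate symmetric stretch) ship as
module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, WindowRangeError

WAVENUMBER_MIN = 650.0
WAVENUMBER_MAX = 3000.0

#: Default synthetic grid: 1 cm⁻¹ spacing so the nominal band centres are
#: on-grid (the instrument's optical resolution is coarser, but its data-point
#: spacing is a free choice for the synthetic twin).
DEFAULT_GRID = np.arange(WAVENUMBER_MIN, WAVENUMBER_MAX + 1.0, 1.0)


@dataclass
class Spectrum:
    """Single spectrum: ascending wavenumber grid + absorbance values.

    Parameters
    ----------
    wavenumbers : array-like of float, cm⁻¹
        Strictly increasing, finite, inside [650, 3000].
    absorbance : array-like of float, AU
        Same length; may be negative after background subtraction.
    label : str
        Free-text provenance label.
    meta : dict
        Reader metadata (e.g. whether the source file was re-sorted).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if len(self.wavenumbers) != len(self.absorbance):
            raise ValueError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.absorbance)} absorbance values"
            )
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("non-finite wavenumber")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite absorbance")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        lo, hi = self.wavenumbers[0], self.wavenumbers[-1]
        if lo < WAVENUMBER_MIN or hi > WAVENUMBER_MAX:
            raise ValueError(
                f"wavenumbers [{lo}, {hi}] outside supported range "
                f"[{WAVENUMBER_MIN}, {WAVENUMBER_MAX}]"
            )

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))


@dataclass(frozen=True)
class BandDefinition:
    """Quantitation band: location window, baseline window, nominal centre.

    Windows are given high-to-low in cm⁻¹ (spectroscopy convention); bounds are
    snapped to the nearest grid points, inclusive on both ends.
    """

    analyte: str
    location_window: tuple[float, float]
    baseline_window: tuple[float, float]
    nominal_center: float

    def __post_init__(self) -> None:
        for name, (hi, lo) in (
            ("location_window", self.location_window),
            ("baseline_window", self.baseline_window),
        ):
            if not hi > lo:
                raise ValueError(f"{name}: high bound {hi} must exceed low bound {lo}")
        hi, lo = self.location_window
        if not lo <= self.nominal_center <= hi:
            raise ValueError(
                f"nominal_center {self.nominal_center} outside location window "
                f"{self.location_window}"
            )


#: Glucose band: strongest C–O absorbance, nominal 1035 cm⁻¹.
GLUCOSE_BAND = BandDefinition(
    analyte="glucose",
    location_window=(1058.0, 978.0),
    baseline_window=(1058.0, 1004.0),
    nominal_center=1035.0,
)

#: Glutamate band: carboxylate stretch, nominal 1400 cm⁻¹ (sharper and less
#: media-overlapped than the alternative 1556 cm⁻¹ region).
GLUTAMATE_BAND = BandDefinition(
    analyte="glutamate",
    location_window=(1413.0, 1393.0),
    baseline_window=(1436.0, 1379.0),
    nominal_center=1400.0,
)

DEFAULT_BANDS = {"glucose": GLUCOSE_BAND, "glutamate": GLUTAMATE_BAND}

#: Secondary glutamate carbonyl band; present in synthetic spectra but kept
#: outside every quantitation window.
GLUTAMATE_SECONDARY_CENTER = 1556.0


def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise ``sample − background`` (e.g. remove the water absorbance).

    Both spectra must be on the identical grid; anything else raises
    :class:`~mirferm.errors.GridMismatchError`.
    """
    if len(sample) != len(background) or not np.array_equal(
        sample.wavenumbers, background.wavenumbers
    ):
        raise GridMismatchError(
            f"grids differ (lengths {len(sample)} vs {len(background)})"
        )
    return Spectrum(
        wavenumbers=sample.wavenumbers.copy(),
        absorbance=sample.absorbance - background.absorbance,
        label=f"{sample.label} - {background.label}".strip(" -"),
    )


def _window_slice(s: Spectrum, hi: float, lo: float) -> tuple[int, int]:
    """Indices (i_lo, i_hi) of the grid points nearest the window bounds.

    Raises WindowRangeError when the window extends beyond the grid.
    """
    if lo < s.wavenumbers[0] or hi > s.wavenumbers[-1]:
        raise WindowRangeError(
            f"window ({hi}, {lo}) outside spectrum range "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    i_lo = s.index_of(lo)
    i_hi = s.index_of(hi)
    return i_lo, i_hi


def _baseline_corrected(s: Spectrum, band: BandDefinition) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected absorbance over the location window.

    The baseline is the straight line through the spectrum at the two
    endpoints of the baseline window (nearest grid points), evaluated across
    the location window. Returns (wavenumbers, corrected absorbance).
    """
    b_lo, b_hi = _window_slice(s, *band.baseline_window)
    l_lo, l_hi = _window_slice(s, *band.location_window)
    w1, a1 = s.wavenumbers[b_hi], s.absorbance[b_hi]
    w0, a0 = s.wavenumbers[b_lo], s.absorbance[b_lo]
    w = s.wavenumbers[l_lo : l_hi + 1]
    if w1 == w0:
        baseline = np.full_like(w, a0)
    else:
        baseline = a0 + (a1 - a0) * (w - w0) / (w1 - w0)
    return w, s.absorbance[l_lo : l_hi + 1] - baseline


def band_absorbance(s: Spectrum, band: BandDefinition) -> float:
    """Peak height above the straight baseline, in AU.

    Height is the maximum baseline-corrected absorbance over the location
    window; it may be negative when the band is absent and noise dips below
    the baseline. Adding any affine function of wavenumber to the spectrum
    leaves the result unchanged.
    """
    _, corrected = _baseline_corrected(s, band)
    return float(np.max(corrected))


def band_argmax(s: Spectrum, band: BandDefinition) -> float:
    """Wavenumber (cm⁻¹) of the maximum baseline-corrected absorbance.

    Ties are broken toward the higher wavenumber.
    """
    w, corrected = _baseline_corrected(s, band)
    best = np.flatnonzero(corrected == corrected.max())
    return float(w[best[-1]])


def gaussian_band(
    grid: np.ndarray, center: float, height: float, fwhm: float = 14.0
) -> np.ndarray:
    """Gaussian absorption band evaluated on ``grid``."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return height * np.exp(-0.5 * ((np.asarray(grid, float) - center) / sigma) ** 2)
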