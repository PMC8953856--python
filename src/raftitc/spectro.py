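"""Spectral utilities: tryptophan emission maxima, blue shift, CD differences.

Tryptophan emission maxima report on the polarity of the indole
environment: transfer from water into a membrane blue-shifts the
maximum.  Peaks are located by moving-average smoothing followed by
three-point parabolic interpolation around the discrete argmax, giving
sub-grid resolution on the typical 1 nm sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def _validate_axes(wavelength: np.ndarray, values: np.ndarray) -> None:
    if wavelength.shape != values.shape:
        raise ValueError("wavelength and intensity vectors must have equal length")
    if wavelength.size < 2 or np.any(np.diff(wavelength) <= 0):
        raise ValueError("wavelengths must be strictly increasing")


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum (nm vs arbitrary intensity units)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _validate_axes(self.wavelength_nm, self.intensity)


@dataclass
class CDSpectrum:
    """Circular dichroism spectrum (nm vs ellipticity in mdeg)."""

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        _validate_axes(self.wavelength_nm, self.ellipticity_mdeg)


@dataclass(frozen=True)
class PeakEstimate:
    """A located emission maximum.

    ``at_boundary`` flags a discrete argmax at the edge of the recorded
    range, where parabolic interpolation is undefined and the reported
    wavelength is the raw grid point.
    """

    wavelength_nm: float
    at_boundary: bool
    index: int

    def __float__(self) -> float:
        return self.wavelength_nm


def emission_max(spectrum: EmissionSpectrum, smoothing_window: int = 5) -> PeakEstimate:
    """Locate the emission maximum with sub-grid resolution.

    The intensity is smoothed with a centered moving average
    (reflect-padded, odd window), then a parabola through the three
    points around the discrete argmax refines the peak position.
    """
    wl, y = spectrum.wavelength_nm, spectrum.intensity
    if y.size < 7:
        raise ValueError("need at least 7 points to locate an emission maximum")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    if smoothing_window > 1:
        pad = smoothing_window // 2
        ypad = np.pad(y, pad, mode="reflect")
        ys = np.convolve(ypad, np.ones(smoothing_window) / smoothing_window, mode="valid")
    else:
        ys = y
    j = int(np.argmax(ys))
    if j == 0 or j == ys.size - 1:
        return PeakEstimate(float(wl[j]), True, j)
    denom = ys[j - 1] - 2.0 * ys[j] + ys[j + 1]
    delta = 0.0 if denom == 0 else 0.5 * (ys[j - 1] - ys[j + 1]) / denom
    h = (wl[j + 1] - wl[j - 1]) / 2.0
    return PeakEstimate(float(wl[j] + delta * h), False, j)


def blue_shift(
    free: EmissionSpectrum, bound: EmissionSpectrum, smoothing_window: int = 5
) -> float:
    """Blue shift in nm: peak(free) - peak(bound); positive = blue shift."""
    pf = emission_max(free, smoothing_window)
    pb = emission_max(bound, smoothing_window)
    if pf.at_boundary or pb.at_boundary:
        warnings.warn("emission maximum at range boundary; blue shift unreliable")
    return float(pf) - float(pb)


def cd_difference(
    a: CDSpectrum, b: CDSpectrum, at_nm: float
) -> tuple[float, CDSpectrum]:
    """Ellipticity change b - a at ``at_nm`` plus the full difference spectrum.

    Both spectra are linearly interpolated; the difference spectrum is
    returned on the part of ``a``'s grid covered by both records.
    """
    lo = max(a.wavelength_nm[0], b.wavelength_nm[0])
    hi = min(a.wavelength_nm[-1], b.wavelength_nm[-1])
    if lo > hi:
        raise ValueError("spectra have no overlapping wavelength range")
    if not lo <= at_nm <= hi:
        raise ValueError(
            f"wavelength {at_nm} nm outside the overlap [{lo}, {hi}] nm"
        )
    grid = a.wavelength_nm[(a.wavelength_nm >= lo) & (a.wavelength_nm <= hi)]
    ya = np.interp(grid, a.wavelength_nm, a.ellipticity_mdeg)
    yb = np.interp(grid, b.wavelength_nm, b.ellipticity_mdeg)
    delta = float(
        np.interp(at_nm, b.wavelength_nm, b.ellipticity_mdeg)
        - np.interp(at_nm, a.wavelength_nm, a.ellipticity_mdeg)
    )
    return delta, CDSpectrum(grid, yb - ya, label=f"{b.label} - {a.label}")
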