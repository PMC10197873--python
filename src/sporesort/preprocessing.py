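"""Primitive spectral operations: normalization, windowing, window statistics.

All scoring in :mod:`sporesort.sort_gate` is built from these. Two conventions
are fixed here and relied on everywhere:

* window bounds are a closed interval ``[lo, hi]``; boundary samples included;
* no smoothing, despiking or baseline subtraction is ever applied — raw
  detector intensities go straight into the window statistics.

Min-max normalization, ``(I - I_min) / (I_max - I_min)``, is provided for
display and export only; the sorting ratios are computed on raw intensities
because independently rescaling a cell and its medium to [0, 1] would destroy
the meaning of their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateSpectrumError,
    EmptyWindowError,
    InsufficientSamplesError,
    OutOfSpanError,
)
from .spectra_io import Spectrum


@dataclass(frozen=True)
class SpectralWindow:
    """A closed Raman-shift interval [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi < 4000.0):
            raise ValueError(
                f"window [{self.lo}, {self.hi}] must satisfy 0 < lo < hi < 4000 cm^-1"
            )

    @property
    def breadth(self) -> float:
        return self.hi - self.lo

    def __str__(self) -> str:  # used in CLI logs
        return f"{self.lo:g}:{self.hi:g}"


def minmax_normalize(spectrum: Spectrum) -> Spectrum:
    """Rescale intensities to [0, 1] via (I - I_min) / (I_max - I_min)."""
    y = spectrum.intensities
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise DegenerateSpectrumError(
            "constant spectrum: max == min, min-max normalization undefined"
        )
    return spectrum.with_intensities((y - lo) / (hi - lo), normalized=True)


def _window_mask(spectrum: Spectrum, window: SpectralWindow) -> np.ndarray:
    w = spectrum.wavenumbers
    return (w >= window.lo) & (w <= window.hi)


def crop_window(spectrum: Spectrum, window: SpectralWindow) -> Spectrum:
    """Sub-spectrum of samples with lo <= wavenumber <= hi (bounds included)."""
    mask = _window_mask(spectrum, window)
    n = int(mask.sum())
    if n == 0:
        raise EmptyWindowError(
            f"window {window} contains no samples of axis "
            f"[{spectrum.wavenumbers[0]:g}, {spectrum.wavenumbers[-1]:g}]"
        )
    if n < 2:
        # a 1-sample Spectrum is not representable; callers needing single
        # samples use max_in_window which works on the mask directly
        raise InsufficientSamplesError(
            f"window {window} holds a single sample; cannot form a sub-spectrum"
        )
    return Spectrum(
        spectrum.wavenumbers[mask].copy(), spectrum.intensities[mask].copy(), spectrum.meta
    )


def integrate_window(spectrum: Spectrum, window: SpectralWindow) -> float:
    """Trapezoidal integral of intensity over the in-window samples (a.u. cm^-1).

    The trapezoid rule on the native (possibly non-uniform) axis is exact for
    the piecewise-linear representation the samples define, and is linear in
    any rescaling of the intensities.
    """
    mask = _window_mask(spectrum, window)
    if int(mask.sum()) < 2:
        raise InsufficientSamplesError(
            f"integration over {window} needs >= 2 in-window samples, "
            f"found {int(mask.sum())}"
        )
    return float(np.trapezoid(spectrum.intensities[mask], spectrum.wavenumbers[mask]))


def max_in_window(spectrum: Spectrum, window: SpectralWindow) -> float:
    """Maximum sampled intensity inside the window (no interpolation)."""
    mask = _window_mask(spectrum, window)
    if not mask.any():
        raise EmptyWindowError(f"window {window} contains no samples")
    return float(spectrum.intensities[mask].max())


def resample_to_axis(spectrum: Spectrum, axis: np.ndarray) -> Spectrum:
    """Linearly interpolate the spectrum onto a new wavenumber axis.

    The target axis must lie within the source span; extrapolation is refused.
    """
    axis = np.asarray(axis, dtype=float)
    w = spectrum.wavenumbers
    if axis.size and (axis.min() < w[0] or axis.max() > w[-1]):
        raise OutOfSpanError(
            f"target axis [{axis.min():g}, {axis.max():g}] exceeds source span "
            f"[{w[0]:g}, {w[-1]:g}]"
        )
    y = np.interp(axis, w, spectrum.intensities)
    return Spectrum(axis, y, spectrum.meta)
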