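"""Cell-envelope morphometry on electron micrographs.

Reproduces the classic Fiji workflow: draw a line perpendicular to the cell
envelope, average the grey values over a wide band (default 23 pixels) to
suppress noise, plot grey value against distance, and read the envelope
width off the resulting density profile. Here the width is measured as the
half-depth (FWHM-style) breadth of the envelope's dip or rise relative to a
user-designated baseline region — affine-invariant in grey value and equal to
the edge-to-edge distance for step-like envelopes.

Coordinates are continuous with pixel centers at integer positions, x along
columns and y along rows; grey values between centers come from bilinear
interpolation. Distances are converted to nanometres via the image's pixel
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    AmbiguousFeatureError,
    EmptyInputError,
    FeatureNotFoundError,
    OutOfBoundsError,
)

#: Runs above the half-depth level must also reach this fraction of the
#: extreme deviation to count as a separate candidate feature; smaller
#: excursions are treated as noise blips rather than ambiguity.
_CANDIDATE_FRACTION = 0.75


@dataclass
class GreyImage:
    """A greyscale micrograph with a physical pixel size (nm per pixel)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must form a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("grey values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (nm per pixel)")


@dataclass(frozen=True)
class ProfileLine:
    """A line across the envelope with a perpendicular averaging width."""

    start: tuple[float, float]  # (x, y), pixels
    end: tuple[float, float]
    averaging_width: int = 23

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise ValueError("profile line start and end coincide")
        w = self.averaging_width
        if w < 1 or w % 2 == 0:
            raise ValueError("averaging_width must be an odd integer >= 1")


@dataclass
class DensityProfile:
    """Mean grey value versus distance (nm) along a profile line."""

    distances: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances.size != self.values.size or self.distances.size < 2:
            raise ValueError("distances and values must be equal-length, size >= 2")
        if self.distances[0] != 0 or np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must increase strictly from 0")


def extract_profile(image: GreyImage, line: ProfileLine) -> DensityProfile:
    """Width-averaged density profile along a line.

    Samples are taken at 1-pixel spacing along the line; each sample is the
    mean of ``averaging_width`` bilinear interpolations at integer offsets
    -(w-1)/2 ... +(w-1)/2 along the unit perpendicular. Any sample falling
    outside the pixel-center grid is an error, never padded.
    """
    (x0, y0), (x1, y1) = line.start, line.end
    dx, dy = x1 - x0, y1 - y0
    length = float(np.hypot(dx, dy))
    ux, uy = dx / length, dy / length
    nx, ny = -uy, ux  # unit perpendicular
    ts = np.arange(0.0, np.floor(length) + 1.0)  # 1-pixel spacing along the line
    half = (line.averaging_width - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    # sample grid: (n_offsets, n_samples)
    xs = x0 + np.outer(np.ones_like(offsets), ts * ux) + np.outer(offsets * nx, np.ones_like(ts))
    ys = y0 + np.outer(np.ones_like(offsets), ts * uy) + np.outer(offsets * ny, np.ones_like(ts))
    nrows, ncols = image.pixels.shape
    if (
        xs.min() < 0
        or ys.min() < 0
        or xs.max() > ncols - 1
        or ys.max() > nrows - 1
    ):
        raise OutOfBoundsError(
            "profile line or its averaging band leaves the image "
            f"(x range [{xs.min():.1f}, {xs.max():.1f}], "
            f"y range [{ys.min():.1f}, {ys.max():.1f}], "
            f"image {ncols}x{nrows})"
        )
    taps = map_coordinates(image.pixels, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    values = taps.reshape(xs.shape).mean(axis=0)
    return DensityProfile(ts * image.pixel_size, values)


def measure_envelope_width(
    profile: DensityProfile,
    baseline_region: tuple[float, float],
    method: str = "half_depth",
) -> float:
    """Envelope width (nm) from a density profile.

    The baseline grey is the mean over ``baseline_region`` (a distance
    interval, nm, chosen outside the envelope feature). The feature is the
    extreme excursion from the baseline (a dip for envelopes darker than the
    surroundings, a rise otherwise); the width is the distance between the two
    crossings of the level halfway between baseline and extreme, each crossing
    located by linear interpolation between samples.
    """
    if method != "half_depth":
        raise ValueError(f"unknown method {method!r}")
    d, v = profile.distances, profile.values
    lo, hi = baseline_region
    base_mask = (d >= lo) & (d <= hi)
    if not base_mask.any():
        raise ValueError(f"baseline region [{lo}, {hi}] nm contains no samples")
    baseline = float(v[base_mask].mean())
    dev = v - baseline
    extreme_idx = int(np.argmax(np.abs(dev)))
    extreme = dev[extreme_idx]
    if extreme == 0:
        raise FeatureNotFoundError("profile is flat relative to the baseline")
    scaled = dev / extreme  # 1 at the extreme, ~0 at baseline level
    above = scaled >= 0.5

    # contiguous runs above the half-depth level
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [i + 1 for i in edges if not above[i]]
    stops = [i + 1 for i in edges if above[i]]
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        stops = stops + [above.size]
    runs = list(zip(starts, stops))
    candidates = [r for r in runs if scaled[r[0]: r[1]].max() >= _CANDIDATE_FRACTION]
    if len(candidates) > 1:
        positions = [float(d[r[0] + int(np.argmax(scaled[r[0]: r[1]]))]) for r in candidates]
        raise AmbiguousFeatureError(
            f"{len(candidates)} candidate features cross the half-depth level "
            f"at distances {positions} nm",
            candidates=positions,
        )
    main = next((r for r in runs if r[0] <= extreme_idx < r[1]), None)
    if main is None:  # cannot happen for a finite extreme, defensive
        raise FeatureNotFoundError("no half-depth run contains the extreme")
    i0, i1 = main
    if i0 == 0 or i1 == above.size:
        raise FeatureNotFoundError(
            "feature is not bracketed by the profile: half-depth crossing "
            "lies outside the sampled range"
        )

    def cross(ia: int, ib: int) -> float:
        # linear interpolation of the 0.5 crossing between samples ia and ib
        fa, fb = scaled[ia], scaled[ib]
        t = (0.5 - fa) / (fb - fa)
        return float(d[ia] + t * (d[ib] - d[ia]))

    left = cross(i0 - 1, i0)
    right = cross(i1, i1 - 1)
    return right - left


@dataclass
class EnvelopeWidthSet:
    """Repeated per-cell width measurements and their hierarchical means.

    ``cell_means`` averages each cell's repeats; ``overall_mean`` averages the
    cell means (mean of means, the convention of the source workflow). Values
    are kept unrounded; round only for display.
    """

    per_cell: list[list[float]]
    cell_means: list[float] = field(init=False)
    overall_mean: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_cell or any(len(c) == 0 for c in self.per_cell):
            raise EmptyInputError("need at least one cell with at least one measurement")
        self.per_cell = [[float(x) for x in cell] for cell in self.per_cell]
        self.cell_means = [float(np.mean(cell)) for cell in self.per_cell]
        self.overall_mean = float(np.mean(self.cell_means))

    def display(self, decimals: int = 2) -> dict:
        """Rounded summary for reporting."""
        return {
            "cell_means": [round(m, decimals) for m in self.cell_means],
            "overall_mean": round(self.overall_mean, decimals),
        }


def summarize_widths(measurements: Sequence[Sequence[float]]) -> EnvelopeWidthSet:
    """Per-cell means and their overall mean from repeated width measurements."""
    return EnvelopeWidthSet([list(cell) for cell in measurements])
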