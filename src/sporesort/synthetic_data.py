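"""Synthetic Raman spectra and envelope images with known ground truth.

Spectra are sums of Gaussian/Lorentzian bands on a low-order polynomial
baseline plus seeded Gaussian noise, sampled on the acquisition axis used for
in-liquid single-cell measurements (400-3300 cm^-1 at 3.5 cm^-1 steps).
Phenotype presets place the marker bands of each resting-cell type at the
catalog positions, with amplitudes fixed once so that the populations are
separable by the sorting gate:

* every cell preset integrates to at least 1.5x the medium over the cell
  window (Pc >= 1.5) while debris stays at Pc <= 0.5;
* the endospore preset's CaDPA band puts P_CaDPA >= 1.3, every other cell
  preset stays at P_CaDPA <= 0.9 (the gate threshold is 1.1).

Band images emulate an envelope cross-section: a straight dark strip of known
width on a brighter background, rendered with the analytic Gaussian-blurred
strip profile (error functions of the signed distance to the centerline) and
seeded per-pixel noise. All generators are pure functions of (model, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .envelope_profile import GreyImage
from .errors import GeometryError, PresetMissError
from .spectra_io import Spectrum, SpectrumCollection, SpectrumMeta

#: In-liquid acquisition axis: (lo, hi, step) in cm^-1.
DEFAULT_AXIS = (400.0, 3300.0, 3.5)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PeakSpec:
    """One synthetic band."""

    center: float
    amplitude: float
    fwhm: float = 15.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"shape must be gaussian|lorentzian, got {self.shape!r}")

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            sigma = self.fwhm * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * ((w - self.center) / sigma) ** 2)
        x = 2.0 * (w - self.center) / self.fwhm
        return self.amplitude / (1.0 + x * x)


@dataclass
class SpectrumModel:
    """A generative spectrum: bands + polynomial baseline + Gaussian noise."""

    peaks: list[PeakSpec] = field(default_factory=list)
    baseline: tuple[float, ...] = (0.0,)  # polynomial coefficients, ascending powers
    noise_sd: float = 0.0
    axis: tuple[float, float, float] = DEFAULT_AXIS
    phenotype: str = "unknown"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.axis
        if step <= 0 or hi <= lo:
            raise ValueError("axis must be (lo, hi, step) with lo < hi, step > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.baseline) > 3:
            raise ValueError("baseline polynomial degree is at most 2")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.axis
        n = int(math.floor((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def evaluate(self) -> np.ndarray:
        """Noiseless model intensities on the axis."""
        w = self.wavenumbers()
        y = np.polynomial.polynomial.polyval(w, self.baseline)
        y = np.broadcast_to(y, w.shape).astype(float).copy()
        for p in self.peaks:
            y += p.evaluate(w)
        return y


# ---------------------------------------------------------------------------
# presets

_BASELINE = 10.0  # flat medium/cell background level, a.u.
_CELL_BAND = PeakSpec(1650.0, 10.0, fwhm=30.0)  # "cell peak", no molecular identity
_CH_BAND = PeakSpec(2900.0, 12.0, fwhm=60.0)  # CH2/CH3 stretch
_NOISE_SD = 0.6  # 2% of the largest preset amplitude (CaDPA 1395 at 30)

PRESET_TAGS = (
    "endospore",
    "vegetative_firmicute",
    "exospore",
    "myxospore",
    "cyst",
    "akinete",
    "akinete_vegetative",
    "medium",
    "debris",
)


def _preset_peaks(tag: str) -> tuple[list[PeakSpec], tuple[float, ...]]:
    f = PeakSpec  # fingerprint bands default to fwhm 15
    if tag == "endospore":
        return (
            [f(1017, 25.0), f(1395, 30.0), f(1446, 25.0), _CELL_BAND, _CH_BAND],
            (_BASELINE,),
        )
    if tag == "vegetative_firmicute":
        return [f(1004, 4.0), _CELL_BAND, _CH_BAND], (_BASELINE,)
    if tag == "exospore":
        # the CH ~2900 band is absent from exospore spectra
        return [f(1342, 15.0), f(1586, 15.0), _CELL_BAND], (_BASELINE,)
    if tag == "myxospore":
        return [f(1120, 15.0), f(1149, 15.0), f(1550, 15.0), _CELL_BAND, _CH_BAND], (
            _BASELINE,
        )
    if tag == "cyst":
        return [f(830, 15.0), f(1150, 15.0), f(1350, 15.0), _CELL_BAND, _CH_BAND], (
            _BASELINE,
        )
    if tag == "akinete":
        # carotenoid-dominated resonance spectrum; no CH band
        return [f(1005, 20.0), f(1157, 22.0), f(1520, 28.0), _CELL_BAND], (_BASELINE,)
    if tag == "akinete_vegetative":
        peaks, base = _preset_peaks("akinete")
        return peaks + [f(2295, 8.0)], base
    if tag == "medium":
        # 0.2 M glycerol background: weak broad bands away from both gate windows
        return (
            [f(850, 3.0, fwhm=20), f(925, 2.5, fwhm=20), f(1060, 3.0, fwhm=25), f(1465, 3.5, fwhm=20)],
            (_BASELINE,),
        )
    if tag == "debris":
        # low-scattering particle displacing the medium: below-medium background
        return [f(1450, 2.0, fwhm=50)], (4.0,)
    raise PresetMissError(f"unknown phenotype preset {tag!r}; known: {PRESET_TAGS}")


def phenotype_preset(tag: str) -> SpectrumModel:
    """Generative model for one phenotype at the default study conditions."""
    peaks, baseline = _preset_peaks(tag)
    phenotype = {
        "vegetative_firmicute": "vegetative_firmicute",
        "akinete_vegetative": "akinete_vegetative",
    }.get(tag, tag)
    return SpectrumModel(
        peaks=peaks, baseline=baseline, noise_sd=_NOISE_SD, phenotype=phenotype
    )


def generate_spectrum(model: SpectrumModel, seed=None) -> Spectrum:
    """Draw one spectrum from the model; deterministic for a fixed seed."""
    w = model.wavenumbers()
    y = model.evaluate()
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed if seed is None else seed)
        y = y + rng.normal(0.0, model.noise_sd, size=w.size)
    meta = SpectrumMeta(label=f"{model.phenotype}", phenotype=model.phenotype)
    return Spectrum(w, y, meta)


def generate_population(
    counts: dict[str, int], jitter: float = 0.1, seed: int = 0
) -> SpectrumCollection:
    """Labelled population with per-spectrum lognormal amplitude jitter.

    ``jitter`` is the relative standard deviation of a per-spectrum multiplier
    applied to all band amplitudes (unit mean), emulating the cell-to-cell
    intensity variation seen between individual spores. Each spectrum draws
    from its own random stream ``(seed, index)``, so membership order of other
    phenotypes does not alter any individual spectrum.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    spectra: list[Spectrum] = []
    index = 0
    for tag in sorted(counts):
        n = counts[tag]
        if n < 0:
            raise ValueError("counts must be >= 0")
        preset = phenotype_preset(tag)
        for i in range(n):
            rng = np.random.default_rng([seed, index])
            mult = 1.0
            if jitter > 0:
                sigma = math.sqrt(math.log(1.0 + jitter**2))
                mult = float(rng.lognormal(-0.5 * sigma * sigma, sigma))
            model = replace(
                preset,
                peaks=[replace(p, amplitude=p.amplitude * mult) for p in preset.peaks],
            )
            s = generate_spectrum(model, seed=rng)
            s.meta.label = f"{tag}_{i:03d}"
            spectra.append(s)
            index += 1
    return SpectrumCollection(spectra)


# ---------------------------------------------------------------------------
# band images


@dataclass
class BandImageModel:
    """A straight dark band of known physical width on a brighter background."""

    width_nm: float
    shape: tuple[int, int] = (256, 256)  # rows, cols
    pixel_size: float = 2.0  # nm per pixel
    angle_deg: float = 0.0  # centerline direction, degrees from the y (row) axis
    band_grey: float = 60.0
    background_grey: float = 160.0
    blur_sigma_nm: float = 8.0
    noise_sd: float = 5.0  # grey units; 5% of the default contrast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if self.band_grey == self.background_grey:
            raise ValueError("band and background grey must differ")
        if self.blur_sigma_nm < 0 or self.noise_sd < 0:
            raise ValueError("blur and noise must be >= 0")


def generate_band_image(model: BandImageModel) -> tuple[GreyImage, dict]:
    """Render the band image; returns (image, ground-truth record).

    The centerline passes through the image center at ``angle_deg``. With
    blur, grey values follow the exact blurred-strip profile
    ``bg + (band - bg) * (Phi((s + W/2)/sigma) - Phi((s - W/2)/sigma))`` of
    the signed perpendicular distance s; with blur 0 the strip membership is
    the half-open interval [-W/2, W/2), so an axis-aligned band of width
    k pixels covers exactly k pixel columns.
    """
    nrows, ncols = model.shape
    half_extent = model.width_nm / 2.0 + 3.0 * model.blur_sigma_nm
    max_half = (min(nrows, ncols) / 2.0 - 1.0) * model.pixel_size
    if half_extent > max_half:
        raise GeometryError(
            f"band (half extent {half_extent:g} nm incl. blur support) does not "
            f"fit in a {ncols}x{nrows} image at {model.pixel_size:g} nm/px"
        )
    cx, cy = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    theta = math.radians(model.angle_deg)
    # centerline direction (sin t, cos t); normal (cos t, -sin t)
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    s = ((xx - cx) * math.cos(theta) - (yy - cy) * math.sin(theta)) * model.pixel_size
    w2 = model.width_nm / 2.0
    contrast = model.band_grey - model.background_grey
    if model.blur_sigma_nm > 0:
        frac = ndtr((s + w2) / model.blur_sigma_nm) - ndtr((s - w2) / model.blur_sigma_nm)
    else:
        frac = ((s >= -w2) & (s < w2)).astype(float)
    pixels = model.background_grey + contrast * frac
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        pixels = pixels + rng.normal(0.0, model.noise_sd, size=pixels.shape)
    truth = {
        "width_nm": model.width_nm,
        "angle_deg": model.angle_deg,
        "center_px": (cx, cy),
        "pixel_size_nm": model.pixel_size,
        "band_grey": model.band_grey,
        "background_grey": model.background_grey,
        "blur_sigma_nm": model.blur_sigma_nm,
        "noise_sd": model.noise_sd,
        "seed": model.seed,
    }
    return GreyImage(pixels, model.pixel_size), truth
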