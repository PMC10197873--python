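"""Plain-text IO for single-cell Raman spectra.

A spectrum is a strictly increasing Raman-shift axis (cm^-1) with paired
intensities (arbitrary detector units) and acquisition metadata. Files are
comma-separated text with an optional ``# key: value`` metadata header block:

    # label: SPO91_cell03
    # phenotype: endospore
    # laser_power_mw: 100
    # exposure_s: 1
    wavenumber_cm-1,intensity
    400.0,12.5
    ...

The wide-table dialect stores one shared axis column plus one intensity column
per cell; column names become spectrum labels.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import SpectrumParseError, SpectrumValidationError

#: Phenotype tags understood by the pipeline. ``vegetative_firmicute`` and
#: ``akinete_vegetative`` are refinements used by the synthetic presets.
PHENOTYPES = frozenset(
    {
        "vegetative",
        "endospore",
        "exospore",
        "myxospore",
        "cyst",
        "akinete",
        "medium",
        "debris",
        "unknown",
        "vegetative_firmicute",
        "akinete_vegetative",
    }
)

_META_FIELDS = ("label", "phenotype", "laser_power_mw", "exposure_s", "strain")


@dataclass
class SpectrumMeta:
    """Acquisition metadata carried alongside a spectrum.

    ``extra`` preserves unknown header keys verbatim; ``has_negative`` is set
    automatically when raw intensities dip below zero (detector offsets),
    ``normalized`` when the intensities have been min-max rescaled.
    """

    label: str = ""
    phenotype: str = "unknown"
    laser_power_mw: float | None = None
    exposure_s: float | None = None
    strain: str | None = None
    normalized: bool = False
    has_negative: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise SpectrumValidationError(
                f"unknown phenotype tag {self.phenotype!r}; expected one of "
                f"{sorted(PHENOTYPES)}"
            )


@dataclass
class Spectrum:
    """A single Raman spectrum: paired (wavenumber, intensity) samples.

    The axis is canonicalized to strictly increasing order on construction
    (a strictly descending axis, as exported by some spectrometers, is
    silently reversed together with its intensities). Duplicate wavenumbers
    and length mismatches are validation errors.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise SpectrumValidationError("wavenumbers and intensities must be 1-D")
        if w.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 samples")
        if w.size != y.size:
            raise SpectrumValidationError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise SpectrumValidationError("non-finite wavenumber or intensity")
        order = np.argsort(w, kind="stable")
        w, y = w[order], y[order]
        if np.any(np.diff(w) == 0):
            dup = w[np.nonzero(np.diff(w) == 0)[0][0]]
            raise SpectrumValidationError(f"duplicate wavenumber {dup!r}")
        self.wavenumbers = w
        self.intensities = y
        if np.any(y < 0):
            self.meta.has_negative = True

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        """Return a copy with new intensities (same axis) and meta updates."""
        meta = dataclasses.replace(self.meta, **meta_updates)
        meta.has_negative = False
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), meta)


@dataclass
class SpectrumCollection:
    """An ordered list of spectra, e.g. the 15-20 cells measured per sample."""

    spectra: list[Spectrum]

    @property
    def shared_axis(self) -> bool:
        if not self.spectra:
            return True
        first = self.spectra[0].wavenumbers
        return all(
            len(s) == len(self.spectra[0]) and np.array_equal(s.wavenumbers, first)
            for s in self.spectra
        )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]


# ---------------------------------------------------------------------------
# parsing


def _meta_from_header(pairs: dict[str, str]) -> SpectrumMeta:
    meta = SpectrumMeta()
    for key, value in pairs.items():
        if key == "label":
            meta.label = value
        elif key == "phenotype":
            meta.phenotype = value
            meta.__post_init__()
        elif key == "laser_power_mw":
            meta.laser_power_mw = float(value)
        elif key == "exposure_s":
            meta.exposure_s = float(value)
        elif key == "strain":
            meta.strain = value
        elif key == "normalized":
            meta.normalized = value.lower() in ("true", "1", "yes")
        elif key == "has_negative":
            pass  # recomputed from the data
        else:
            meta.extra[key] = value
    return meta


def _parse_float(token: str, path: str, row: int, col: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise SpectrumParseError(
            f"{path}: non-numeric value {token!r} in column {col!r} at data row {row}"
        ) from None


def read_spectrum(path: str | os.PathLike, dialect: str = "two_column"):
    """Read a spectrum file.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"two_column"`` (header ``wavenumber_cm-1,intensity``) returns a
        :class:`Spectrum`; ``"wide_table"`` (one intensity column per cell)
        returns a :class:`SpectrumCollection` with ``shared_axis`` true.
    """
    if dialect not in ("two_column", "wide_table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = os.fspath(path)
    header_pairs: dict[str, str] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    header_pairs[key.strip()] = value.strip()
                continue
            data_lines.append(line)
    if not data_lines:
        raise SpectrumParseError(f"{path}: no data rows")
    columns = [c.strip() for c in data_lines[0].split(",")]
    rows = data_lines[1:]
    if dialect == "two_column" and len(columns) != 2:
        raise SpectrumParseError(
            f"{path}: two_column dialect expects 2 columns, found {len(columns)}"
        )
    ncol = len(columns)
    table = np.empty((len(rows), ncol), dtype=float)
    for i, line in enumerate(rows, start=1):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != ncol:
            raise SpectrumParseError(
                f"{path}: row {i} has {len(cells)} fields, expected {ncol}"
            )
        for j, tok in enumerate(cells):
            table[i - 1, j] = _parse_float(tok, path, i, columns[j])

    meta = _meta_from_header(header_pairs)
    w = table[:, 0]
    if dialect == "two_column":
        return Spectrum(w, table[:, 1], meta)
    spectra = []
    for j in range(1, ncol):
        m = dataclasses.replace(meta, label=columns[j], extra=dict(meta.extra))
        m.has_negative = False
        spectra.append(Spectrum(w, table[:, j], m))
    return SpectrumCollection(spectra)


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column CSV with a metadata header.

    Numbers are stored with 12 significant digits, so a write/read round trip
    reproduces axis and intensities to that precision.
    """
    buf = io.StringIO()
    meta = spectrum.meta
    for key in _META_FIELDS:
        value = getattr(meta, key)
        if value not in (None, ""):
            buf.write(f"# {key}: {value}\n")
    if meta.normalized:
        buf.write("# normalized: true\n")
    if meta.has_negative:
        buf.write("# has_negative: true\n")
    for key, value in meta.extra.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("wavenumber_cm-1,intensity\n")
    for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
        buf.write(f"{w:.12g},{y:.12g}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
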