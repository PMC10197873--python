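"""Phenotype-specific Raman marker catalog and signature scoring.

The catalog encodes the bands that distinguish the five bacterial resting-cell
types at the single-cell level:

* endospores (Firmicutes): calcium dipicolinate (CaDPA) at 1017, 1395 and
  1446 cm^-1 — the marker the sorting gate exploits;
* exospores (Actinobacteria): amino-acid bands at 1342 and 1586 cm^-1;
* myxospores (Myxococcales): 1120, 1149 and 1550 cm^-1 (the last band is
  also reported at 1505 cm^-1 in parts of the literature; both positions are
  stored, aliased to one marker);
* cysts (Azotobacteraceae): 830, 1150 and 1350 cm^-1;
* akinete-forming cyanobacteria: a 2295 cm^-1 band present only in the
  vegetative cells (akinete spectra are carotenoid-dominated and lack it);
* the CH2/CH3 stretch near 2900 cm^-1, shared by most cell types and hence
  useless for discrimination.

Two bands are shared chemistry rather than phenotype fingerprints: the
trehalose bands at 1149/1150 cm^-1 mark both myxospores and cysts (they are
1 cm^-1 apart, far below the 3.5 cm^-1 spectral resolution), and the ~2900
CH band marks almost everything. Such peaks carry ``discriminative=False``
and are excluded from a phenotype's signature whenever that phenotype has
exclusive markers of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import CatalogMissError
from .spectra_io import Spectrum

DEFAULT_HALF_WINDOW = 10.0  # cm^-1; ~3x the 3.5 cm^-1 spectral resolution
DEFAULT_MIN_PROMINENCE = 0.05  # fraction of the spectrum's intensity range
DEFAULT_MIN_SEPARATION = 8.0  # cm^-1


@dataclass(frozen=True)
class MarkerPeak:
    """One catalog band: a center, a matching half-window, and its phenotypes.

    ``alias_of`` links alternative printed positions of the same physical band
    to a canonical center; aliased peaks count as a single marker when scoring.
    ``discriminative`` is False for bands whose chemistry is shared across
    phenotypes.
    """

    center: float
    phenotypes: frozenset
    half_window: float = DEFAULT_HALF_WINDOW
    assignment: str = ""
    discriminative: bool = True
    alias_of: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.center < 4000.0):
            raise ValueError(f"marker center {self.center} outside (0, 4000) cm^-1")
        if self.half_window <= 0:
            raise ValueError("half_window must be positive")
        if not self.phenotypes:
            raise ValueError("a marker needs at least one phenotype")

    @property
    def group(self) -> float:
        """Canonical center of this marker's alias group."""
        return self.alias_of if self.alias_of is not None else self.center


@dataclass
class MarkerCatalog:
    """An extensible list of marker peaks."""

    peaks: list[MarkerPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.peaks:
            key = (p.center, p.phenotypes)
            if key in seen:
                raise ValueError(f"duplicate marker (center={p.center}, phenotypes)")
            seen.add(key)

    def phenotypes(self) -> frozenset:
        out: set = set()
        for p in self.peaks:
            out |= set(p.phenotypes)
        return frozenset(out)

    def markers_for(self, phenotype: str) -> list[MarkerPeak]:
        """Signature markers of a phenotype.

        Exclusive (discriminative) markers when the phenotype has any;
        otherwise its shared markers, so phenotypes defined only by shared
        chemistry (e.g. the CH band of vegetative cells) still score.
        """
        if phenotype not in self.phenotypes():
            raise CatalogMissError(f"no catalog marker carries phenotype {phenotype!r}")
        mine = [p for p in self.peaks if phenotype in p.phenotypes]
        exclusive = [p for p in mine if p.discriminative]
        return exclusive if exclusive else mine

    # -- plain-text (de)serialization: one "center,half_window,assignment,
    #    phenotypes(;-joined)[,flags]" record per line -----------------------

    def dumps(self) -> str:
        lines = ["center_cm-1,half_window_cm-1,assignment,phenotypes,discriminative,alias_of"]
        for p in self.peaks:
            alias = "" if p.alias_of is None else f"{p.alias_of:g}"
            lines.append(
                f"{p.center:g},{p.half_window:g},{p.assignment},"
                f"{';'.join(sorted(p.phenotypes))},{p.discriminative},{alias}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "MarkerCatalog":
        peaks = []
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        for ln in lines[1:]:
            center, hw, assignment, phen, disc, alias = ln.split(",")
            peaks.append(
                MarkerPeak(
                    center=float(center),
                    half_window=float(hw),
                    assignment=assignment,
                    phenotypes=frozenset(phen.split(";")),
                    discriminative=disc.strip().lower() == "true",
                    alias_of=float(alias) if alias.strip() else None,
                )
            )
        return cls(peaks)


def default_catalog() -> MarkerCatalog:
    """The built-in marker catalog (centers in cm^-1)."""
    E = frozenset({"endospore"})
    X = frozenset({"exospore"})
    M = frozenset({"myxospore"})
    C = frozenset({"cyst"})
    MC = frozenset({"myxospore", "cyst"})
    return MarkerCatalog(
        [
            MarkerPeak(1017, E, assignment="CaDPA"),
            MarkerPeak(1395, E, assignment="CaDPA"),
            MarkerPeak(1446, E, assignment="CaDPA"),
            MarkerPeak(1342, X, assignment="amino acid (L-glutamate)"),
            MarkerPeak(1586, X, assignment="amino acid (L-phenylalanine)"),
            MarkerPeak(1120, M, assignment="trehalose"),
            MarkerPeak(1149, MC, assignment="trehalose", discriminative=False),
            MarkerPeak(1550, M, assignment="myxospore band"),
            MarkerPeak(
                1505,
                M,
                assignment="myxospore band (alternative reported position)",
                alias_of=1550,
            ),
            MarkerPeak(830, C, assignment="trehalose"),
            MarkerPeak(1150, MC, assignment="trehalose", discriminative=False),
            MarkerPeak(1350, C, assignment="cyst band"),
            MarkerPeak(
                2295,
                frozenset({"akinete_vegetative"}),
                assignment="unassigned; vegetative-only in akinete formers",
            ),
            MarkerPeak(
                2900,
                frozenset(
                    {"vegetative", "vegetative_firmicute", "endospore", "myxospore", "cyst"}
                ),
                half_window=30.0,
                assignment="CH2/CH3 stretch",
                discriminative=False,
            ),
        ]
    )


@dataclass(frozen=True)
class DetectedPeak:
    """A local maximum found in a spectrum."""

    position: float  # cm^-1 (sample position, no sub-sample interpolation)
    height: float  # a.u.
    prominence: float  # a.u.


def detect_peaks(
    spectrum: Spectrum,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> list[DetectedPeak]:
    """Find local maxima, thinned so no two retained peaks are too close.

    ``min_prominence`` is a fraction of the spectrum's intensity range, which
    makes detection invariant under positive rescaling of the intensities.
    Thinning is greedy from the tallest peak down: a peak is dropped when a
    taller retained peak lies within ``min_separation`` cm^-1.
    """
    if len(spectrum) < 3:
        raise ValueError("peak detection needs at least 3 samples")
    y = spectrum.intensities
    span = float(np.ptp(y))
    if span == 0.0:
        return []
    idx, props = find_peaks(y, prominence=min_prominence * span)
    if idx.size == 0:
        return []
    positions = spectrum.wavenumbers[idx]
    heights = y[idx]
    prominences = props["prominences"]
    keep: list[int] = []
    for i in np.argsort(-heights, kind="stable"):
        if all(abs(positions[i] - positions[j]) >= min_separation for j in keep):
            keep.append(int(i))
    keep.sort(key=lambda i: positions[i])
    return [
        DetectedPeak(float(positions[i]), float(heights[i]), float(prominences[i]))
        for i in keep
    ]


def _nearest_center(position: float, catalog: MarkerCatalog) -> float:
    centers = np.array([p.center for p in catalog.peaks])
    return float(centers[np.argmin(np.abs(centers - position))])


def signature_score(
    spectrum: Spectrum,
    phenotype: str,
    catalog: MarkerCatalog | None = None,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> float:
    """Fraction of a phenotype's signature markers present in the spectrum.

    A marker is matched when a detected peak lies within the marker's
    half-window *and* the marker is the nearest catalog center to that peak —
    the standard annotation rule, which prevents a band from being claimed by
    a neighbouring phenotype's marker a few cm^-1 away. Alias groups
    (alternative printed positions of one band) count as a single marker.
    Returns a value in [0, 1]; 1.0 means every signature marker was found.
    """
    catalog = catalog if catalog is not None else default_catalog()
    markers = catalog.markers_for(phenotype)
    detected = detect_peaks(spectrum, min_prominence, min_separation)

    def matched(marker: MarkerPeak) -> bool:
        for d in detected:
            if abs(d.position - marker.center) <= marker.half_window and (
                _nearest_center(d.position, catalog) == marker.center
            ):
                return True
        return False

    groups: dict[float, bool] = {}
    for m in markers:
        groups[m.group] = groups.get(m.group, False) or matched(m)
    return sum(groups.values()) / len(groups)
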