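"""The two-threshold Raman sorting gate for endospore isolation.

Stage 1 (is it a cell?) computes

    Pc = integral of cell intensity over 1620-1670 cm^-1
         --------------------------------------------------
         integral of medium intensity over 1620-1670 cm^-1

against a medium spectrum acquired under identical settings. The 1620-1670
region ("cell peak", ~1650 cm^-1) is not a specific molecular bond but is
consistently elevated in cells relative to the surrounding fluid. Particles
with Pc below the cell threshold (default 1.0) are routed to waste.

Stage 2 (is the cell an endospore?) computes, on the same single spectrum,

    P_CaDPA = statistic over 1370-1420 cm^-1 (CaDPA band at 1395)
              ------------------------------------------------------
              statistic over 1620-1670 cm^-1 (cell peak)

where the statistic is the window maximum (default) or the window integral.
Cells at or above the endospore threshold (default 1.1, a deliberately
conservative margin above parity) are routed to the endospore compartment,
the rest to the vegetative compartment.

Both ratios are computed on raw intensities. Threshold comparisons treat the
boundary as passing (>=), so a particle indistinguishable from the medium
(Pc exactly 1) is not discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDenominatorError, InvalidReferenceError, SporesortError
from .preprocessing import (
    SpectralWindow,
    integrate_window,
    max_in_window,
    resample_to_axis,
)
from .spectra_io import Spectrum, SpectrumCollection

DECISIONS = ("waste", "vegetative", "endospore")


@dataclass(frozen=True)
class GateThresholds:
    """Gate thresholds; both boundaries pass (>=)."""

    pc_threshold: float = 1.0
    pcadpa_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.pc_threshold <= 0 or self.pcadpa_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class GateWindows:
    """The two scoring windows; the CaDPA window must lie below the cell window."""

    cell_window: SpectralWindow = SpectralWindow(1620.0, 1670.0)
    cadpa_window: SpectralWindow = SpectralWindow(1370.0, 1420.0)

    def __post_init__(self) -> None:
        if not self.cadpa_window.hi < self.cell_window.lo:
            raise ValueError(
                "cadpa_window must lie entirely below cell_window "
                f"(got {self.cadpa_window} vs {self.cell_window})"
            )


@dataclass
class SortResult:
    """Gate output for one particle. ``pcadpa`` is None when stage 1 already
    routed the particle to waste."""

    label: str
    pc: float
    pcadpa: float | None
    decision: str


def _aligned_medium(cell: Spectrum, medium: Spectrum, window: SpectralWindow) -> Spectrum:
    """Medium spectrum on the cell's axis (resampled only when axes differ).

    Alignment happens over the scoring window only, so cell and medium need
    not share a full acquisition span — both must merely cover the window.
    """
    if len(cell) == len(medium) and np.array_equal(cell.wavenumbers, medium.wavenumbers):
        return medium
    w = cell.wavenumbers
    in_window = w[(w >= window.lo) & (w <= window.hi)]
    return resample_to_axis(medium, in_window)


def compute_pc(
    cell: Spectrum, medium: Spectrum, windows: GateWindows = GateWindows()
) -> float:
    """Cell statistic: ratio of cell to medium integrals over the cell window."""
    medium = _aligned_medium(cell, medium, windows.cell_window)
    denom = integrate_window(medium, windows.cell_window)
    if denom <= 0:
        raise InvalidReferenceError(
            f"medium integral over {windows.cell_window} is {denom:g}; "
            "need a positive reference"
        )
    return integrate_window(cell, windows.cell_window) / denom


def compute_pcadpa(
    cell: Spectrum, windows: GateWindows = GateWindows(), mode: str = "max"
) -> float:
    """Endospore statistic: CaDPA-window over cell-window statistic of one spectrum."""
    if mode not in ("max", "integrated"):
        raise ValueError(f"mode must be 'max' or 'integrated', got {mode!r}")
    stat = max_in_window if mode == "max" else integrate_window
    denom = stat(cell, windows.cell_window)
    if denom <= 0:
        raise InvalidDenominatorError(
            f"cell-window statistic is {denom:g}; P_CaDPA undefined"
        )
    return stat(cell, windows.cadpa_window) / denom


def classify(
    cell: Spectrum,
    medium: Spectrum,
    thresholds: GateThresholds = GateThresholds(),
    windows: GateWindows = GateWindows(),
    mode: str = "max",
) -> SortResult:
    """Run both gate stages on one spectrum."""
    pc = compute_pc(cell, medium, windows)
    if pc < thresholds.pc_threshold:
        return SortResult(cell.meta.label, pc, None, "waste")
    pcadpa = compute_pcadpa(cell, windows, mode)
    decision = "endospore" if pcadpa >= thresholds.pcadpa_threshold else "vegetative"
    return SortResult(cell.meta.label, pc, pcadpa, decision)


def batch_classify(
    cells: SpectrumCollection,
    medium: Spectrum,
    thresholds: GateThresholds = GateThresholds(),
    windows: GateWindows = GateWindows(),
    mode: str = "max",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every spectrum of a collection, tolerating per-spectrum failures.

    Returns an order-preserving table (label, phenotype, pc, pcadpa, decision)
    and the decision counts. A spectrum whose statistics cannot be computed is
    recorded with decision ``"error"`` instead of aborting the batch.
    """
    rows = []
    counts = {d: 0 for d in DECISIONS} | {"error": 0}
    for s in cells:
        try:
            r = classify(s, medium, thresholds, windows, mode)
            rows.append(
                {
                    "label": r.label,
                    "phenotype": s.meta.phenotype,
                    "pc": r.pc,
                    "pcadpa": np.nan if r.pcadpa is None else r.pcadpa,
                    "decision": r.decision,
                }
            )
            counts[r.decision] += 1
        except SporesortError:
            rows.append(
                {
                    "label": s.meta.label,
                    "phenotype": s.meta.phenotype,
                    "pc": np.nan,
                    "pcadpa": np.nan,
                    "decision": "error",
                }
            )
            counts["error"] += 1
    table = pd.DataFrame(
        rows, columns=["label", "phenotype", "pc", "pcadpa", "decision"]
    )
    return table, counts
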