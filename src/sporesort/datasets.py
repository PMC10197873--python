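"""Bundled example measurements.

Published manual cell-envelope width measurements (nm) from cryo-electron
micrographs of vitreous sections: for each species and cell form, the
per-cell values are the average of five measurements on one image of that
cell, for five different cells. For the akinete-forming cyanobacterium only a
single image was of sufficient quality, so its five values are repeated
measurements of one image. These serve as the worked input for
:func:`sporesort.envelope_profile.summarize_widths`.
"""

from __future__ import annotations

#: species -> form ("VEG" vegetative, "SPO" spore) -> per-cell widths (nm)
ENVELOPE_WIDTHS_NM: dict[str, dict[str, list[float]]] = {
    "B. subtilis": {
        "VEG": [63.2, 41.6, 29.4, 39.8, 49.6],
        "SPO": [237.0, 180.6, 225.5, 209.2, 216.2],
    },
    "S. violaceoruber": {
        "VEG": [40.0, 50.0, 31.0, 27.4, 33.0],
        "SPO": [97.4, 67.8, 92.2, 107.0, 119.4],
    },
    "M. xanthus": {
        "VEG": [26.6, 30.0, 34.8, 33.0, 30.8],
        "SPO": [249.6, 246.6, 272.8, 177.4, 269.8],
    },
    "A. cylindrica": {
        "VEG": [63.0, 50.0, 70.6, 51.6, 58.4],
        "SPO": [199.0, 230.0, 210.0, 207.0, 238.0],
    },
}


def envelope_width_measurements() -> dict[str, dict[str, list[float]]]:
    """Deep copy of the bundled envelope-width measurements (nm)."""
    return {
        species: {form: list(values) for form, values in forms.items()}
        for species, forms in ENVELOPE_WIDTHS_NM.items()
    }
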