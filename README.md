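# sporesort

Tools for two single-cell measurements of bacterial specialized resting cells
(endospores, exospores, myxospores, cysts, akinetes):

1. **Raman spore sorting.** Endospores accumulate calcium dipicolinate
   (CaDPA), with Raman bands at 1017, 1395 and 1446 cm⁻¹ that no other cell
   type shows. A Raman-activated cell sorter can exploit this with two scalar
   statistics per measured particle:

   * the **cell statistic** `Pc = ∫₁₆₂₀¹⁶⁷⁰ I_cell dν̃ / ∫₁₆₂₀¹⁶⁷⁰ I_medium dν̃`,
     which separates cells (Pc ≥ 1) from debris (→ waste);
   * the **endospore statistic**
     `P_CaDPA = max_{1370–1420} I_cell / max_{1620–1670} I_cell`
     (window integrals available as an alternative mode), which routes cells
     with P_CaDPA ≥ 1.1 to the endospore compartment and the rest to the
     vegetative compartment.

   The package provides the window statistics, the two-threshold gate, batch
   classification with CSV export, a phenotype marker-peak catalog with
   signature scoring, and plain-text spectrum IO.

2. **Envelope morphometry.** The one morphological feature all resting-cell
   types share is a thickened cell envelope. From cryo-electron micrographs,
   the package extracts width-averaged grey-value profiles along
   user-supplied lines (23-pixel perpendicular averaging, bilinear
   interpolation) and measures envelope widths as the half-depth breadth of
   the profile's dip or rise, plus hierarchical per-cell/overall width
   summaries.

A synthetic-data module generates labelled spectra (per-phenotype marker-band
presets, amplitude jitter, seeded noise) and envelope band images with known
ground truth, so the full pipeline is testable without instrument data.

Intended users: microbiologists and spectroscopists prototyping
Raman-activated sorting thresholds, and microscopists who want a scripted,
reproducible replacement for hand-measured envelope widths.

## Worked example

```python
import numpy as np
from sporesort import batch_classify, summarize_widths
from sporesort.datasets import envelope_width_measurements
from sporesort.synthetic_data import (
    generate_population, generate_spectrum, phenotype_preset,
)

# a medium reference and a labelled mixed population
medium = generate_spectrum(phenotype_preset("medium"), seed=0)
population = generate_population(
    {"endospore": 20, "vegetative_firmicute": 20, "debris": 10},
    jitter=0.1, seed=1,
)
table, counts = batch_classify(population, medium)
print(table.head(3).to_string(index=False))
print("counts:", counts)

# envelope widths: per-cell means, then the mean of cell means
widths = envelope_width_measurements()["B. subtilis"]
veg = summarize_widths([[v] for v in widths["VEG"]])
spo = summarize_widths([[v] for v in widths["SPO"]])
print(f"B. subtilis envelope: {veg.overall_mean:.2f} nm (vegetative) "
      f"-> {spo.overall_mean:.2f} nm (endospore)")
```

prints

```
     label phenotype       pc  pcadpa decision
debris_000    debris 0.397173     NaN    waste
debris_001    debris 0.384437     NaN    waste
debris_002    debris 0.421299     NaN    waste
counts: {'waste': 10, 'vegetative': 20, 'endospore': 20, 'error': 0}
B. subtilis envelope: 44.72 nm (vegetative) -> 213.70 nm (endospore)
```

Each debris particle fails the Pc gate (Pc ≈ 0.4 < 1) and is discarded
before the CaDPA stage (`pcadpa` empty); all 20 endospores and none of the
vegetative cells clear the P_CaDPA ≥ 1.1 threshold. The width summary shows
the roughly five-fold envelope thickening of the endospore.

The same stages are available from a CLI:

```sh
sporesort simulate --counts endospore=20,debris=10 --seed 1 --out-dir pop/
sporesort sort --medium medium.csv --cells pop/ --out decisions.csv
sporesort profile --image section.tif --line 10,128:245,128 \
    --pixel-size 2.0 --out profile.csv
sporesort summarize-widths --measurements widths.csv --out summary.csv
```

All options can be pre-set in a YAML config (`sporesort --config run.yaml …`,
one section per subcommand); explicit flags win.

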