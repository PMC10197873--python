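# Methods

## The sorting gate

Bacterial endospores accumulate calcium dipicolinate (CaDPA), whose Raman
bands at 1017, 1395 and 1446 cm⁻¹ are absent from vegetative cells and from
the other specialized resting-cell types (exospores, myxospores, cysts,
akinetes). A Raman-activated cell-sorting platform can therefore isolate
endospores from a mixed sample with two scalar statistics per measured
particle:

* **Pc (cell statistic).** The 1620–1670 cm⁻¹ region — a "cell peak" near
  1650 cm⁻¹ with no single molecular assignment — is consistently elevated in
  cells relative to the surrounding fluid. Pc is the ratio of the trapezoidal
  integral of the particle's raw intensity over that window to the same
  integral of a medium spectrum acquired under identical settings. Particles
  with Pc below the cell threshold (default 1.0) are debris and go to waste.
* **P_CaDPA (endospore statistic).** The ratio of a window statistic over the
  CaDPA band window (1370–1420 cm⁻¹, containing the 1395 cm⁻¹ band) to the
  same statistic over the cell window, on the one particle spectrum. The
  default statistic is the window maximum; the window integral is available
  as `mode="integrated"` because both phrasings are in circulation for this
  gate. Cells at or above the endospore threshold (default 1.1 — a
  deliberately conservative margin above parity, favouring purity of the
  endospore compartment over recall) are routed to the endospore compartment,
  the rest to the vegetative compartment.

Numerical conventions, fixed once:

* window bounds are closed; in-window samples only, no boundary
  interpolation; integration is the trapezoid rule on the native axis (exact
  for the piecewise-linear representation the samples define);
* threshold comparisons pass on equality (`>=`), so a particle exactly at
  parity with the medium is analysed rather than discarded; both thresholds
  and both windows are configurable;
* both ratios are computed on **raw** intensities. Min–max normalization
  `(I − I_min)/(I_max − I_min)` is provided for display and export only:
  rescaling cell and medium independently to [0, 1] would destroy the meaning
  of their ratio;
* no smoothing, despiking or baseline subtraction anywhere in the scoring
  path;
* when cell and medium axes differ, the medium is linearly resampled onto the
  cell's in-window axis; extrapolation is refused.

## Marker catalog and signature scoring

The catalog stores each phenotype's fingerprint bands (cm⁻¹): endospore
1017/1395/1446 (CaDPA); exospore 1342/1586 (amino-acid bands); myxospore
1120/1149/1550; cyst 830/1150/1350; a 2295 band present only in the
vegetative cells of akinete formers; and the CH₂/CH₃ stretch near 2900
shared by most cell types. The myxospore band reported at both 1550 and
1505 cm⁻¹ is stored as one marker with an alias entry (`alias_of=1550`);
alias groups count as a single marker.

Two scoring decisions deal with bands that are chemically shared between
phenotypes:

1. The trehalose bands at 1149 (myxospore) and 1150 cm⁻¹ (cyst) are the same
   physical signal — they are 1 cm⁻¹ apart against a 3.5 cm⁻¹ spectral
   resolution — and the ~2900 CH band is near-universal. Such peaks carry
   `discriminative=False`: a phenotype's signature uses its exclusive markers
   whenever it has any, falling back to shared markers only for phenotypes
   (like generic vegetative cells) that have nothing else.
2. A detected peak matches a marker only if it lies within the marker's
   half-window (default 10 cm⁻¹, ≈3× the spectral resolution) **and** the
   marker is the nearest catalog center to the peak — the standard annotation
   rule. Without it, the cyst band at 1350 cm⁻¹ would also "match" the
   exospore marker at 1342 cm⁻¹.

With both rules, each noiseless synthetic fingerprint preset scores 1.0
against its own phenotype and 0.0 against every other fingerprint phenotype.
Peak detection is scipy's prominence-based local-maximum search with the
prominence threshold expressed as a fraction of the intensity range (making
detection scale-invariant; default 0.05) and greedy thinning so no two
retained peaks are closer than 8 cm⁻¹.

## Envelope morphometry

The one morphological feature shared by all five resting-cell types is a
thickened cell envelope, measured on cryo-electron micrographs of vitreous
sections. The implemented workflow mirrors the classic Fiji procedure: a
profile line is drawn perpendicular to the envelope and grey values are
averaged over a wide band (default 23 pixels, taken as 23 bilinear
interpolations at integer offsets along the unit perpendicular) to suppress
noise, giving a density profile of mean grey value versus distance in nm.

The original width measurements were made by hand; this package implements an
explicit, reproducible criterion instead: **half-depth width**. The baseline
grey is the mean over a user-designated region outside the feature; the
feature is the extreme excursion from that baseline (dark dip or bright
rise); the width is the distance between the two crossings of the level
halfway between baseline and extreme, each crossing located by linear
interpolation between samples. The criterion is invariant under affine grey
rescaling, scales linearly with pixel size, and reduces to the edge-to-edge
distance for step-like envelopes. Runs above the half-depth level only count
as separate candidate features (an `AmbiguousFeatureError`) when they also
reach 75% of the extreme deviation; smaller excursions are treated as noise
blips. A feature whose crossings are not bracketed by the profile raises
`FeatureNotFoundError` rather than returning a truncated width.

The published per-cell width table (four species × vegetative/spore, five
cells each, bundled in `sporesort.datasets`) is reproduced at the
summary-statistics level — per-cell means, then the mean of cell means,
rounded to 2 decimals only for display — because the original micrographs are
not available for re-measurement, and the manual start/end criterion for
"envelope" is not recoverable from the summaries.

## Synthetic data

The generators define the conditions every test and the acceptance script
run under.

**Spectra** are sums of Gaussian bands (fwhm 15 cm⁻¹ for fingerprint bands,
30 cm⁻¹ for the 1650 cell band, 60 cm⁻¹ for the broad CH stretch; Lorentzian
shapes are available) on a flat baseline of 10 a.u., sampled on the in-liquid
acquisition axis 400–3300 cm⁻¹ at 3.5 cm⁻¹ steps, plus additive Gaussian
noise (default sd 0.6 a.u. = 2% of the largest band amplitude). Preset
amplitudes were fixed once so the phenotypes are separable by the gate with
margin: every cell preset has Pc ≈ 1.63 against the medium preset (margin
requirement ≥ 1.5) and the debris preset 0.40 (≤ 0.5); the endospore preset
has P_CaDPA ≈ 1.98 in max mode (≥ 1.3) while every other cell preset sits at
≈ 0.50 (≤ 0.9). Population generation draws one lognormal amplitude
multiplier per spectrum (default relative sd 0.1, unit mean), emulating the
strong cell-to-cell intensity variation of real spores; each spectrum's
random stream is keyed by `(seed, index)` so adding phenotypes to a
population does not perturb existing members.

What the spectrum generator does **not** emulate: fluorescence baselines and
their drift, cosmic-ray spikes, detector nonlinearity, resonance-Raman
lineshapes (the akinete preset's carotenoid dominance is phenomenological),
and real amplitude ratios — no published numeric intensities exist for these
spectra, so all amplitudes are stand-ins. Passing gate tests therefore show
the gate logic is correct under separable conditions, not that real samples
are separable at these margins.

**Band images** emulate an envelope cross-section: a straight dark strip of
known physical width (default greys 60 on 160) rendered with the analytic
Gaussian-blurred strip profile — error functions of the signed perpendicular
distance to the centerline — plus per-pixel Gaussian noise (defaults: blur
σ = 8 nm, noise sd 5 grey units = 5% of the contrast, 256×256 px at
2 nm/px). With zero blur the strip membership is the half-open interval
[−W/2, W/2), so an axis-aligned band of integer pixel width covers exactly
that many columns. Real micrographs differ in every way that matters for
segmentation — multi-layered envelopes, curvature, knife marks, crevasses —
which is why automatic envelope detection is out of scope and profile lines
are user-supplied.

## Problem sizes

The verification suite uses 20 seeded populations of 50 spectra per
phenotype (8 phenotypes) for the sorting check, 100 seeded band images with
true widths spanning 30–250 nm for the morphometry check, and 100 seeded
random spectra for the homogeneity/scale-invariance identities; these sizes
give stable medians and exercise the full width range while keeping the
whole suite in the seconds range.

## Known limitations

* Pc requires a medium spectrum measured under the same acquisition settings;
  nothing validates that the settings actually match.
* The half-depth width of a blurred band overestimates the true width as the
  band narrows toward the blur scale (≈4% at 30 nm with σ = 8 nm); at the
  published envelope widths (≥ 30 nm) this stays inside the 5% acceptance
  band.
* `detect_peaks` reports sample positions without sub-sample refinement; on
  the 3.5 cm⁻¹ axis a detected position can be up to half a step from the
  true band center, which the 10 cm⁻¹ matching half-window absorbs.
* The signature score is a fraction of markers found; it does not penalize
  extra peaks, so it is a presence screen, not a spectral classifier.
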