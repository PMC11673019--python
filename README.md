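# voct — vibrational-OCT corneal biomechanics

`voct` is a Python toolkit for the computational chain behind vibrational
optical coherence tomography (VOCT) studies of corneal biomechanics. VOCT
drives the cornea with audible sound (50–300 Hz) while imaging it with OCT
and records the in-phase transverse displacement per driving frequency.
The resulting *weighted displacement versus frequency* spectrum shows
resonance peaks attributable to distinct tissue components — epithelial
cells/keratocytes (~80 Hz), anterior collagen lamellae together with
Bowman's layer (110–120 Hz), posterior/central lamellae (140–150 Hz), and
the limbus–sclera junction (240–250 Hz).

The package is aimed at researchers who want to reproduce, probe or extend
this analysis chain without access to a measured dataset. It provides:

- **`voct.simulate`** — a synthetic-data generator for speaker baselines,
  single spectra, control/keratoconus cohorts (41 + 22 eyes, KC stages
  I–IV counted 2/9/3/8) and human/porcine species cohorts in which only
  the 110 Hz (Bowman's layer) peak differs between species.
- **`voct.spectra`** — speaker normalisation, unit-max normalisation,
  grid-resolution peak detection, and component-band assignment.
- **`voct.calibration`** — the empirical resonance→modulus calibration

  ```
  E · d = 0.0651 · fn² + 233.1
  ```

  (E in MPa for thickness d in µm; fn in Hz), its inverse, interval
  propagation of the ±10 Hz grid accuracy, and the peak-height-weighted
  average corneal modulus Σhᵢ·Eᵢ / Σhᵢ.
- **`voct.localization`** — the two machine-learning procedures that
  localize the Bowman's-layer resonance from human/porcine spectra: a
  per-frequency variational Bayesian Gaussian-mixture two-cluster accuracy
  scan (argmax) and a leave-one-frequency-out SVC ablation with repeated
  stratified 5-fold cross-validation (argmin).
- **`voct.fem`** — an axisymmetric linear-elastic finite-element model of
  the cornea (meniscus-shaped section, clamped periphery, uniform 2000 Pa
  posterior pressure, 9-node quadrilaterals, ~1024 elements) producing the
  deflection map and the keratoconic/healthy central-deflection ratio.
- **`voct.pipeline` / the `voct` CLI** — end-to-end orchestration
  (simulate → normalize → peaks → moduli → localize → FEM) from one YAML
  config, with per-stage seeds and a deterministic aggregated report.

## Worked example

`examples/` contains one short script per capability. For instance,
localizing the Bowman's-layer frequency on a synthetic 20 + 20 cohort
(`python examples/03_localize_bowman_layer.py`):

```
mixture scan:  argmax accuracy at 110 Hz (1.000 +/- 0.000)
SVC ablation:  argmin accuracy at 110 Hz (0.925 +/- 0.087 when excluded)
```

Both procedures point at 110 Hz: the per-frequency clustering separates
human from porcine eyes best there, and excluding that frequency costs
the supervised classifier the most accuracy — the synthetic cohort's
species contrast (Bowman's layer present vs absent) sits entirely in that
band.

Solving the corneal deformation models
(`python examples/04_fem_deflection_ratio.py`):

```
healthy apex deflection: 30.6 um
KC apex deflection:      41.2 um
KC / healthy ratio:      1.345
max deflection at r = 0.0 mm (the apex) for both models
```

The keratoconic cornea (softer, centrally thinner) deflects most at its
centre and roughly 1.35× more than the healthy one — maximum deformation
where keratoconic cones actually form.

The full pipeline with default settings:

```bash
voct report --seed 0 --out-dir out/
```

writes cohort/peak/modulus/accuracy CSVs, deflection fields, and a single
`report.json` aggregating the localized frequency, per-band moduli,
weighted-average moduli and the deflection ratio.

## Layout

```
src/voct/        library (simulate, spectra, calibration, localization, fem, pipeline, cli)
examples/        narrative scripts, one per capability
tests/           pytest suite (unit, property and end-to-end checks)
scripts/         acceptance.py
docs/methods.md  model assumptions, parameters, numerical choices, limitations
```
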