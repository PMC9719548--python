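# ssfm — spectral-shift fluorescence microscopy

`ssfm` processes raster-scanned per-pixel fluorescence spectra of
rhodamine-6G (Rd6G) stained skin tissue into three co-registered
micrographs — signal intensity, peak emission wavelength, and fluorophore
concentration — and classifies each pixel into a tissue class
(melanoma / BCC / SCC / normal / benign nevus) from its spectral band.
It is aimed at people building or analyzing laser-scanning spectral
microscopes: each 16 μm pixel of an m×n scan (60×30 = 1800 pixels by
default) carries a full spectrum on a 0.4 nm grid, recorded under 532 nm
excitation behind a dichroic that blocks the laser line.

## The method

For a cube of spectra `S_ij(λ)` the pipeline builds the matrices

- `[I_ij]` — peak signal intensity per pixel,
- `[λ_ij]` — peak emission wavelength per pixel, refined below the
  0.4 nm grid by a three-point quadratic fit to log intensity (exact for
  Gaussian lineshapes),
- `[Δλ_ij] = [λ_ij] − λ_L` — spectral shift against the laser line
  (λ_L = 532 nm),
- `[c_ij]` — Rd6G concentration, obtained from `[λ_ij]` through a strictly
  monotone calibration of the concentration-dependent reabsorption
  redshift, anchored at the class pairings (2 μM → 550 nm, 8 → 555,
  10 → 563, 16 → 570).

The wavelength route to concentration is the point of the method: the
emitted intensity follows the quenched curve `I(c) = a·c·e^(−c/κ)` with
κ = 30/ln 4 ≈ 21.64 μM, which is two-valued in its inverse — a 10 μM and
a 40 μM sample emit identically — while λ(c) is monotone. Tissue classes
then separate by spectral band: melanoma ≈ 550 nm (18 nm shift from the
laser line), BCC ≈ 555 (23), SCC ≈ 563 (31), normal ≈ 570 (37), nevus
≈ 581 nm (49 nm, driven by melanin autofluorescence rather than Rd6G).

A forward simulator (`ssfm.simulate`) generates labeled tissue phantoms
with class-specific Gaussian lineshapes, quenched amplitudes, and
Gaussian or Rician detector noise, so every pipeline stage is testable
against known ground truth.

## Worked example

```sh
ssfm simulate --seed 7 --out sim          # uniform normal-tissue phantom
ssfm process sim/cube.h5 --out run        # full pipeline
ssfm report run/summary.json
```

prints

```
# SSFM class report (laser 532 nm)

| class | pixels | fraction | λ range (nm) | width (nm) | modal shift (nm) | conc (μM) |
|---|---|---|---|---|---|---|
| melanoma | 0 | 0.000 | — | — | — | — (absent) |
| bcc | 0 | 0.000 | — | — | — | — (absent) |
| scc | 0 | 0.000 | — | — | — | — (absent) |
| normal | 1800 | 1.000 | 567.95–572.05 | 4.09 | 37.95 | 16 |
| nevus | 0 | 0.000 | — | — | — | — (absent) |
| unclassified | 0 | 0.000 | — | — | — | — (absent) |
```

All 1800 pixels of the healthy-tissue phantom land in the normal band
(566–575.5 nm); the recovered per-pixel peak range (width 4.09 nm)
matches the simulated class spread of 4.1 nm, the modal redshift against
the laser line is ~38 nm for the 570 nm class center, and the class
concentration is the calibration pairing 16 μM. `run/` also contains the
four false-color micrographs (intensity, shift, concentration, labels),
the per-map CSV/TIFF exports, the per-pixel scatter table and a
reproducibility manifest. The same functions are importable directly —
see `ssfm.build_maps`, `ssfm.apply_k`, `ssfm.classify_map`.

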