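# Methods

## Signal model

Each scan pixel (i, j) of an m×n raster carries one fluorescence
spectrum on a shared, strictly increasing wavelength grid (default
500–650 nm at the spectrometer's 0.4 nm resolution, 376 samples). The
pixel's emission is modeled as a Gaussian lineshape

    S_ij(λ) = A_ij · exp(−(λ − λ*_ij)² / 2σ_line²)

with a per-pixel true peak λ*_ij and amplitude A_ij, plus detector
noise, with zero response at and below the dichroic cutoff that blocks
the 532 nm excitation line. The pipeline estimates λ*_ij and A_ij per
pixel and derives every downstream product from them.

Two physical effects drive the science:

* **Reabsorption redshift** — the peak emission wavelength of Rd6G
  increases monotonically with concentration. The calibration table
  encodes λ(c) through the anchor pairings (2 μM, 550 nm), (8, 555),
  (10, 563), (16, 570) with a monotone piecewise-cubic (PCHIP)
  interpolant; monotone-cubic rather than linear to avoid derivative
  kinks at anchors (a linear mode is retained as a cross-check).
  Inversion is by bracketed root-finding (Brent) on the forward curve,
  exact at anchors and round-tripping to 1e-9 relative.
* **Quenching** — emitted intensity follows I(c) = a·c·e^(−c/κ), rising
  to a single maximum at c = κ and falling again. κ is fixed at
  30/ln 4 ≈ 21.6404 μM, the unique value for which a 10 μM and a 40 μM
  sample emit identically; the two-valued inverse is exposed by
  root-finding on each monotone branch over [0, 200] μM. This is why
  concentration maps are computed from wavelength, never intensity.

The nevus class is deliberately off the calibration curve: its extreme
redshift (~581 nm center, 576–588 nm band) is attributed to melanin
autofluorescence, not Rd6G density. The simulator assigns its center and
spread directly, curve inversion at nevus pixels flags them missing, and
the class's 12 μM is reported only by class-table lookup.

## Preprocessing

Fixed stage order per spectrum: **mask → debias → smooth**.

* Dichroic mask: intensities at λ ≤ cutoff are zeroed. Default cutoff
  535 nm = laser 532 nm + margin, so smoothing cannot leak residual
  laser energy into the emission band. Masking precedes smoothing for
  the same reason; the order is part of the contract, not a config knob.
* Rician debias: magnitude detection of a noisy signal satisfies
  E[M²] = A² + 2σ², so each sample is replaced by
  sqrt(max(M² − 2σ², 0)); σ = 0 disables the stage. The correction is
  effective where the bias is large — the low-SNR baseline between
  peaks (at A = 0 it cuts the Rayleigh floor by ~3×) — while at high
  SNR both raw and corrected magnitudes carry a residual ~σ²/2A bias of
  opposite sign; near strong peaks the net effect on peak location is
  negligible, which is what the recovery tests measure.
* Gaussian spectral smoothing: discrete convolution along the
  wavelength axis, kernel σ given in nm and converted to grid samples
  (default 1.0 nm), truncated at 4σ, reflective boundaries. The kernel
  is normalized, conserving total intensity to <0.1% for peaks ≥3σ
  inside the grid. Edge policy is second-order because emission peaks
  sit mid-grid. Only spectral filtering is implemented; the optional
  3×3 modal filter on label maps is the spatial counterpart.

## Peak detection and maps

The grid argmax (first maximum, i.e. lowest wavelength on ties — a
deterministic tie-break) is refined by a quadratic fit to log intensity
at the three samples around the maximum. Because log of a Gaussian is a
parabola on a uniform grid, the refinement is exact for noise-free
Gaussian lineshapes (≤1e-6 nm in tests; smoothing with a normalized
Gaussian kernel preserves this to ~1e-10 nm since a Gaussian smoothed by
a Gaussian stays Gaussian-shaped). The fit falls back to the raw grid
wavelength when a neighbor is non-positive, the parabola is non-concave,
the vertex lands beyond one grid step, or the argmax touches a band
edge. The refined vertex also supplies the peak intensity.

Pixels with no usable signal are *missing* — NaN in every map, never
zero — and more than 10% missing pixels (configurable) aborts the run.
Two shift conventions are kept as separate named constants and never
reconciled, because both printed values cannot be exact against a
532 nm laser: the classification center of normal tissue is 570 nm,
while relative blue shifts are quoted from a 569 nm healthy reference
(569 − 532 = 37 nm; 569 − {563, 555, 550} = 6/14/19 nm).

## Classification and summaries

Decision bands are closed-open intervals with lower-edge inclusion:
melanoma [548, 553), BCC [553, 559), SCC [559, 566), normal
[566, 575.5), nevus [575.5, 588); outside → unclassified, missing stays
missing. Interior boundaries are midpoints between the printed class
centers; the source material prints class *ranges*, not decision
boundaries, so the bands are an editorial default and fully
config-overridable.

Per-class summaries report counts, fractions (over non-missing pixels,
summing to 1), the member wavelength range and its width max−min, the
modal laser-line shift and the class's table concentration. The **modal
shift is estimated by the member median**: the simulator's per-class
peak distributions are flat-topped (uniform over center ± spread/2), for
which a binned histogram mode is ill-posed (for a 4 nm spread the three
central integer-nm bins carry equal mass), while the median coincides
with the center of symmetry and is stable to ≈ spread/(2√n) ≈ 0.05 nm at
n = 1800. Class widths are per-pixel ranges over a region; with the
uniform spread model the expected range is spread·(n−1)/(n+1), i.e. the
estimator bias is negligible at n = 1800.

## Simulator

`simulate_cube` draws, per pixel, λ* ~ Uniform(center ± spread/2) — so
the recovered range equals the class spread, matching the published
scatter-width statistic; a Gaussian option (σ = spread/2) exists for
sensitivity studies. Amplitude is I(c_class) from the quench model at
the class's typical concentration {melanoma 2, BCC 8, SCC 10, normal 16,
nevus 12 μM} (the printed nevi/healthy "12, and 16 μM" ordering is
ambiguous; 16 is assigned to normal tissue, which carries the dense
active-fluorophore content, 12 to nevus). Lineshape σ defaults to 6 nm,
chosen so a 550–588 nm peak range yields a visible 540–600 nm emission
envelope; it is not a printed value. Noise is additive Gaussian or
Rician (magnitude of a complex Gaussian perturbation of the clean
signal). Determinism contract: one PCG64 generator seeded from the run
seed, fixed draw order (peak field, then noise), so equal seeds give
byte-identical cubes across platforms.

What the simulator does *not* emulate — optical point-spread/pixel
crosstalk, photobleaching, depth sectioning, autofluorescence background
other than the nevus center offset, baseline drift, wavelength-dependent
detector response. Passing tests therefore demonstrate the algorithmic
chain (conditioning, sub-grid peak recovery, calibration inversion, band
segmentation, rendering) under the stated statistical model, not
robustness to every artifact of real stained-tissue scans.

## Numerical and design choices

* Per-pixel wavelength grids are rejected, not resampled (one
  spectrometer per instrument; resampling silently moves peaks).
* Negative intensities are clipped at zero on ingest with a logged
  count (baseline-subtracted real spectra dip below zero); non-finite
  values are errors.
* Calibration span checks use a 1e-6 nm tolerance at the anchor
  endpoints so float jitter at an exact anchor (e.g. a noise-free
  550.0 nm melanoma pixel) stays in span.
* The characteristic operator linking [λ] to [c] is applied per pixel:
  a scalar for homogeneous bare fluorophore (c = k·λ) and the monotone
  table for stained tissue. A non-diagonal operator (spatial
  cross-talk) has no defined construction and raises an error.
* Rendering maps 548–588 nm linearly onto a five-stop blue→green→
  orange→red→dark-red ramp anchored at the class centers. Only channel
  dominance per class is contractual (blue-dominant melanoma,
  green-dominant BCC, red-dominant normal/nevus); exact RGB values are
  a documented default replacing an unavailable original color table,
  overridable by a JSON ramp file. The mapping is sequential in
  wavelength, not perceptually uniform.
* Problem sizes: tests and the acceptance script use the instrument's
  default 60×30 scan (1800 pixels, 376-sample spectra); the stochastic
  width-recovery study averages 10 seeds. A full pipeline pass takes
  well under a second per cube on one CPU.

## Known limitations

* Decision-band boundaries are an editorial reconstruction from printed
  class ranges; real inter-class boundaries may differ per instrument.
* The calibration anchors come from printed class pairings, not from a
  digitized bare-dye curve; between anchors the interpolant is a
  modeling choice (monotone cubic).
* Concentration maps are only defined inside the 550–570 nm calibration
  span; nevus and out-of-span pixels are flagged missing rather than
  extrapolated (an explicit `extrapolate=True` clamps to span edges).
* No multi-peak decomposition: overlapping fluorophores within one
  pixel are reported as a single peak.
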