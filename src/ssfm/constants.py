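"""Instrument and convention constants.

The excitation laser line sits at 532 nm; a dichroic filter transmits only
longer wavelengths, so the pipeline masks everything at or below a cutoff a
small margin above the laser line (535 nm by default) before peak detection.

Two "normal tissue" wavelengths coexist deliberately and are never
reconciled: the classification band is centered at 570 nm, while relative
blue shifts against healthy tissue are quoted from a 569 nm reference (the
value consistent with the printed 37 nm normal redshift against 532 nm).
Both are config-overridable.
"""

import numpy as np

#: Excitation laser line (nm).
LASER_NM = 532.0

#: Default dichroic/laser-line mask cutoff (nm): laser line + margin.
DICHROIC_CUTOFF_NM = 535.0

#: Normal-tissue emission center used for band classification (nm).
NORMAL_CENTER_NM = 570.0

#: Normal-tissue reference for relative blue-shift reporting (nm).
#: 569 - 532 = 37 nm, consistent with the quoted healthy-tissue redshift,
#: and 569 - {563, 555, 550} reproduces the 6/14/19 nm blue-shift triple.
NORMAL_REFERENCE_NM = 569.0

#: Quench constant (μM) of the intensity-vs-concentration model
#: I(c) = a * c * exp(-c / kappa).  Chosen so that I(10 μM) == I(40 μM)
#: exactly: solving 10 e^{-10/k} = 40 e^{-40/k} gives kappa = 30 / ln 4.
KAPPA_UM = 30.0 / np.log(4.0)

#: Rd6G emission band that any usable grid must cover (nm).
EMISSION_BAND_NM = (540.0, 600.0)

#: Spectrometer hard limits (nm).
SPECTROMETER_RANGE_NM = (200.0, 1100.0)

#: Spectrometer resolution / default grid step (nm).
GRID_STEP_NM = 0.4

#: Default scan geometry: m rows x n columns of 16 μm pixels.
DEFAULT_ROWS = 60
DEFAULT_COLS = 30
DEFAULT_PIXEL_UM = 16.0
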