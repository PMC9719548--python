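"""Forward model of the spectral-shift fluorescence microscope.

The instrument raster-scans Rd6G-stained skin tissue with a 532 nm laser
and records one fluorescence spectrum per 16 μm pixel on a 0.4 nm grid.
The simulator emulates exactly the statistical structure the pipeline
assumes:

* each tissue class emits a Gaussian lineshape whose per-pixel peak
  wavelength is drawn from Uniform(center ± spread/2) — so the recovered
  full range of peaks equals the class "spectral width" scatter statistic;
* the emission amplitude follows the quenched intensity model
  ``I(c) = a · c · exp(−c/κ)`` evaluated at the class's typical Rd6G
  concentration;
* optional additive Gaussian or Rician (magnitude of a complex Gaussian
  perturbation) detector noise;
* zero response at and below the dichroic cutoff that blocks the laser.

Class defaults come from the printed tissue characterizations: emission
centers {melanoma 550, BCC 555, SCC 563, normal 570, nevus 581} nm,
spreads {2, 4, 3.3, 4.1, 14.8} nm, typical concentrations {2, 8, 10, 16,
12} μM. The nevus class is deliberately *not* tied to the Rd6G
calibration curve: its extreme redshift is attributed to melanin
autofluorescence rather than fluorophore density, so the simulator
assigns its center and spread directly.

Determinism contract: all randomness flows through one
``numpy.random.Generator`` (PCG64) seeded from the supplied integer; the
draw order is fixed (per-pixel peak wavelengths first, then the noise
field), so equal seeds give byte-identical cubes on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DEFAULT_COLS,
    DEFAULT_PIXEL_UM,
    DEFAULT_ROWS,
    DICHROIC_CUTOFF_NM,
    EMISSION_BAND_NM,
    GRID_STEP_NM,
    KAPPA_UM,
    LASER_NM,
)
from .errors import ConfigError, CoverageError, RangeError, ValidationError
from .model_io import LabelMap, PixelMaps, SpectralCube, WavelengthGrid

__all__ = [
    "TissueClassParams",
    "NoiseModel",
    "PhantomSpec",
    "Region",
    "default_class_table",
    "default_grid",
    "class_by_label",
    "intensity_vs_concentration",
    "wavelength_vs_concentration",
    "make_phantom",
    "simulate_cube",
]

#: Default Gaussian emission lineshape sigma (nm): wide enough that peaks
#: at 550-588 nm produce a visible 540-600 nm envelope.
DEFAULT_LINESHAPE_SIGMA_NM = 6.0


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueClassParams:
    """Spectral parameters of one tissue class."""

    label: str
    center_nm: float
    spread_nm: float
    band_lo_nm: float
    band_hi_nm: float
    typ_conc_uM: float
    lineshape_sigma_nm: float = DEFAULT_LINESHAPE_SIGMA_NM

    def __post_init__(self) -> None:
        if not (self.band_lo_nm < self.center_nm < self.band_hi_nm):
            raise ValidationError(
                f"{self.label}: band [{self.band_lo_nm}, {self.band_hi_nm}) "
                f"must bracket center {self.center_nm}"
            )
        if self.spread_nm < 0:
            raise ValidationError(f"{self.label}: spread must be >= 0")
        if self.typ_conc_uM <= 0:
            raise ValidationError(f"{self.label}: typical concentration must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: none, additive Gaussian, or Rician magnitude noise."""

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise ConfigError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ConfigError("noise sigma must be >= 0")


@dataclass(frozen=True)
class Region:
    """Half-open pixel rectangle [x0, x1) x [y0, y1); x = row i, y = col j."""

    x0: int
    y0: int
    x1: int
    y1: int
    label: str


@dataclass(frozen=True)
class PhantomSpec:
    """Labeled tissue layout: a background class painted over by regions."""

    m: int = DEFAULT_ROWS
    n: int = DEFAULT_COLS
    pixel_um: float = DEFAULT_PIXEL_UM
    background: str = "normal"
    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.m <= 0 or self.n <= 0:
            raise ConfigError("phantom grid dimensions must be positive")
        object.__setattr__(self, "regions", tuple(self.regions))

    @classmethod
    def from_dict(cls, payload: dict) -> "PhantomSpec":
        regions = tuple(
            Region(int(r["x0"]), int(r["y0"]), int(r["x1"]), int(r["y1"]), str(r["label"]))
            for r in payload.get("regions", ())
        )
        return cls(
            m=int(payload.get("m", DEFAULT_ROWS)),
            n=int(payload.get("n", DEFAULT_COLS)),
            pixel_um=float(payload.get("pixel_um", DEFAULT_PIXEL_UM)),
            background=str(payload.get("background", "normal")),
            regions=regions,
        )


# --------------------------------------------------------------------------
# Class table and calibration-facing curves
# --------------------------------------------------------------------------

def default_class_table() -> list[TissueClassParams]:
    """The five skin-tissue classes with their printed spectral defaults.

    Band limits match the classifier's default decision bands; the nevus
    spread (14.8 nm) is the scatter statistic — the class's other printed
    widths (10 nm, ~12 nm) are narrower verbal ranges and are not used.
    """
    return [
        TissueClassParams("melanoma", 550.0, 2.0, 548.0, 553.0, 2.0),
        TissueClassParams("bcc", 555.0, 4.0, 553.0, 559.0, 8.0),
        TissueClassParams("scc", 563.0, 3.3, 559.0, 566.0, 10.0),
        TissueClassParams("normal", 570.0, 4.1, 566.0, 575.5, 16.0),
        TissueClassParams("nevus", 581.0, 14.8, 575.5, 588.0, 12.0),
    ]


def class_by_label(
    classes: list[TissueClassParams] | None = None,
) -> dict[str, TissueClassParams]:
    return {c.label: c for c in (classes or default_class_table())}


def default_grid() -> WavelengthGrid:
    """500-650 nm at the instrument's 0.4 nm resolution: 376 samples."""
    n = int(round((650.0 - 500.0) / GRID_STEP_NM)) + 1
    return WavelengthGrid(np.linspace(500.0, 650.0, n), step=GRID_STEP_NM)


def intensity_vs_concentration(
    c, amplitude: float = 1.0, quench_uM: float = KAPPA_UM
):
    """Quenched fluorescence output ``a · c · exp(−c/κ)`` (a.u.).

    Linear at dilute concentrations, quenched at dense ones, with a single
    interior maximum at c = κ. With the default κ = 30/ln 4 ≈ 21.64 μM the
    curve takes exactly the same value at 10 μM and 40 μM — the intensity
    ambiguity that makes wavelength, not intensity, the concentration probe.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise RangeError("concentration must be >= 0")
    if amplitude <= 0 or quench_uM <= 0:
        raise RangeError("amplitude and quench constant must be > 0")
    out = amplitude * c * np.exp(-c / quench_uM)
    return float(out) if out.ndim == 0 else out


def wavelength_vs_concentration(c, table):
    """Peak emission wavelength (nm) of bare Rd6G at concentration c (μM).

    Monotone non-decreasing in c (reabsorption redshift with density);
    delegates to the calibration table's anchor interpolant. Raises outside
    the anchor span rather than extrapolating.
    """
    return table.lambda_of_c(c)


# --------------------------------------------------------------------------
# Phantoms and cube synthesis
# --------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> LabelMap:
    """Paint the background, then regions in list order (later wins)."""
    labels = np.full((spec.m, spec.n), spec.background, dtype="U16")
    for region in spec.regions:
        if not (
            0 <= region.x0 < region.x1 <= spec.m
            and 0 <= region.y0 < region.y1 <= spec.n
        ):
            raise ConfigError(
                f"region {region} outside the {spec.m}x{spec.n} grid"
            )
        labels[region.x0:region.x1, region.y0:region.y1] = region.label
    return LabelMap(labels)


def simulate_cube(
    labels: LabelMap,
    classes: list[TissueClassParams] | None = None,
    grid: WavelengthGrid | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    *,
    laser_nm: float = LASER_NM,
    dichroic_cutoff_nm: float = DICHROIC_CUTOFF_NM,
    pixel_um: float = DEFAULT_PIXEL_UM,
    spread_dist: str = "uniform",
) -> tuple[SpectralCube, PixelMaps]:
    """Synthesize a spectral cube plus its ground-truth pixel maps.

    Per pixel: draw the true peak λ* from the class's peak distribution,
    set the amplitude from the quenched intensity model at the class's
    typical concentration, sample the Gaussian lineshape on the grid, add
    noise, and zero the response at and below the dichroic cutoff. The
    ground-truth maps record λ*, the noise-free amplitude, and the true
    concentration.

    ``spread_dist`` is "uniform" (default: full range equals the class
    spread) or "gaussian" (σ = spread/2) for sensitivity studies.
    """
    grid = grid or default_grid()
    if not grid.covers(*EMISSION_BAND_NM):
        raise CoverageError(
            f"grid {grid.span} nm does not cover the Rd6G emission band "
            f"{EMISSION_BAND_NM} nm"
        )
    if spread_dist not in ("uniform", "gaussian"):
        raise ConfigError(f"unknown spread distribution {spread_dist!r}")
    table = class_by_label(classes)
    missing = sorted(set(labels.labels.ravel()) - set(table))
    if missing:
        raise ConfigError(f"labels not present in the class table: {missing}")

    m, n = labels.shape
    rng = np.random.default_rng(seed)

    centers = np.empty((m, n))
    spreads = np.empty((m, n))
    sigmas = np.empty((m, n))
    concs = np.empty((m, n))
    for label, params in table.items():
        mask = labels.labels == label
        centers[mask] = params.center_nm
        spreads[mask] = params.spread_nm
        sigmas[mask] = params.lineshape_sigma_nm
        concs[mask] = params.typ_conc_uM

    # Draw order fixed: peak field first, then noise (determinism contract).
    if spread_dist == "uniform":
        lam_true = centers + spreads * (rng.random((m, n)) - 0.5)
    else:
        lam_true = centers + (spreads / 2.0) * rng.standard_normal((m, n))

    amplitude = intensity_vs_concentration(concs)
    wl = grid.values[np.newaxis, np.newaxis, :]
    clean = amplitude[..., None] * np.exp(
        -((wl - lam_true[..., None]) ** 2) / (2.0 * sigmas[..., None] ** 2)
    )

    if noise.kind == "none" or noise.sigma == 0.0:
        data = clean
    elif noise.kind == "gaussian":
        data = clean + noise.sigma * rng.standard_normal(clean.shape)
    else:  # rician: magnitude of a complex Gaussian perturbation
        re = clean + noise.sigma * rng.standard_normal(clean.shape)
        im = noise.sigma * rng.standard_normal(clean.shape)
        data = np.hypot(re, im)

    data = np.clip(data, 0.0, None)
    data[:, :, grid.values <= dichroic_cutoff_nm] = 0.0

    cube = SpectralCube(
        grid=grid,
        data=data,
        pixel_um=pixel_um,
        laser_nm=laser_nm,
        notes=f"synthetic phantom, noise={noise.kind}, seed={seed}",
    )
    truth = PixelMaps(
        intensity_map=amplitude.copy(),
        wavelength_map=lam_true.copy(),
        shift_map=lam_true - laser_nm,
        laser_nm=laser_nm,
        concentration_map=concs.copy(),
    )
    return cube, truth
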