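"""Domain types and readers/writers for spectral cubes and pixel maps.

A *spectral cube* is an m x n raster scan in which every pixel carries a
full fluorescence spectrum sampled on one shared wavelength grid — an
(m, n, W) intensity array plus a length-W wavelength axis. Two on-disk
dialects are supported:

* ``longcsv`` — UTF-8 text, header ``i,j,wavelength_nm,intensity``, one row
  per (pixel, wavelength) sample, pixel indices 1-based for readability.
* ``container`` — HDF5 with datasets ``/grid/wavelength_nm`` (float64, W)
  and ``/cube/intensity`` (float64, m x n x W), root attributes
  ``laser_nm``, ``pixel_um``, ``created_by``.

Internally pixel indexing is (i, j) = (row, column), 0-based, row-major
raster order. Per-pixel wavelength grids are rejected rather than
resampled: the instrument has one spectrometer, and resampling would
silently move peak positions. Negative intensities (baseline-subtracted
real spectra dip below zero) are clipped at zero on ingest with a logged
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
import tifffile

from .constants import SPECTROMETER_RANGE_NM
from .errors import FormatError, GridMismatchError, ValidationError

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectralCube",
    "PixelMaps",
    "LabelMap",
    "ValidationReport",
    "read_cube",
    "write_cube",
    "validate_cube",
    "export_map_csv",
    "export_map_tiff",
    "read_map_csv",
]

logger = logging.getLogger("ssfm")

CREATED_BY = "ssfm"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Shared spectral axis: strictly increasing wavelengths in nm."""

    values: np.ndarray
    step: float = field(default=0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 8:
            raise ValidationError("wavelength grid must be 1-D with >= 8 samples")
        diffs = np.diff(values)
        if not np.all(diffs > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        lo, hi = SPECTROMETER_RANGE_NM
        if values[0] <= lo or values[-1] >= hi:
            raise ValidationError(
                f"grid [{values[0]:.1f}, {values[-1]:.1f}] nm outside the "
                f"spectrometer range ({lo:.0f}, {hi:.0f}) nm"
            )
        object.__setattr__(self, "values", values)
        step = float(np.median(diffs)) if self.step <= 0 else float(self.step)
        object.__setattr__(self, "step", step)

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.values[0] <= lo and hi <= self.values[-1]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass wants one
        return hash((self.values.tobytes(), self.step))


@dataclass(frozen=True)
class Spectrum:
    """One pixel's fluorescence spectrum on a shared grid (a.u.)."""

    grid: WavelengthGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.shape != (len(self.grid),):
            raise ValidationError(
                f"intensity length {intensity.shape} does not match grid "
                f"length {len(self.grid)}"
            )
        if not np.all(np.isfinite(intensity)):
            raise ValidationError("spectrum contains non-finite intensities")
        n_neg = int(np.sum(intensity < 0))
        if n_neg:
            logger.debug("clipped %d negative intensity samples to zero", n_neg)
            intensity = np.clip(intensity, 0.0, None)
        object.__setattr__(self, "intensity", intensity)

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, intensity)


@dataclass(frozen=True)
class SpectralCube:
    """m x n raster of spectra sharing one wavelength grid.

    ``data`` has shape (m, n, W); ``laser_nm`` records the excitation line,
    which must sit within or below the grid coverage.
    """

    grid: WavelengthGrid
    data: np.ndarray
    pixel_um: float = 16.0
    laser_nm: float = 532.0
    notes: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[2] != len(self.grid):
            raise ValidationError(
                f"cube data shape {data.shape} incompatible with grid length "
                f"{len(self.grid)}"
            )
        if not np.all(np.isfinite(data)):
            raise ValidationError("cube contains non-finite intensities")
        if self.laser_nm > self.grid.span[1]:
            raise ValidationError(
                "laser line lies above the grid coverage; the dichroic "
                "geometry requires it within or below the recorded band"
            )
        n_neg = int(np.sum(data < 0))
        if n_neg:
            logger.info("clipped %d negative cube samples to zero", n_neg)
            data = np.clip(data, 0.0, None)
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def spectrum(self, i: int, j: int) -> Spectrum:
        return Spectrum(self.grid, self.data[i, j])


@dataclass
class PixelMaps:
    """The co-registered per-pixel matrices of the imaging formalism.

    intensity_map [I_ij] (a.u.), wavelength_map [λ_ij] (nm, sub-grid
    refined), shift_map [Δλ_ij] = λ_ij − λ_L (nm), and, once calibration
    has been applied, concentration_map [c_ij] (μM). Missing pixels are
    NaN in every map.
    """

    intensity_map: np.ndarray
    wavelength_map: np.ndarray
    shift_map: np.ndarray
    laser_nm: float = 532.0
    concentration_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.intensity_map.shape
        for name in ("wavelength_map", "shift_map"):
            if getattr(self, name).shape != shape:
                raise ValidationError(f"{name} shape differs from intensity_map")
        if self.concentration_map is not None and (
            self.concentration_map.shape != shape
        ):
            raise ValidationError("concentration_map shape differs from maps")
        both = np.isfinite(self.wavelength_map) & np.isfinite(self.shift_map)
        if not np.allclose(
            self.shift_map[both],
            self.wavelength_map[both] - self.laser_nm,
        ):
            raise ValidationError("shift_map != wavelength_map - laser_nm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity_map.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.wavelength_map)

    def with_concentration(self, concentration: np.ndarray) -> "PixelMaps":
        return replace(self, concentration_map=concentration)


@dataclass
class LabelMap:
    """Per-pixel tissue-class assignment (unicode labels, 'missing' for NaN)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U16")
        if self.labels.ndim != 2:
            raise ValidationError("label map must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def counts(self) -> dict[str, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {str(v): int(c) for v, c in zip(values, counts)}


@dataclass
class ValidationReport:
    """Report-only outcome of cube validation: ok iff no issues."""

    issues: list[tuple[tuple[int, int] | None, str, str]] = field(
        default_factory=list
    )

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, pixel: tuple[int, int] | None, code: str, message: str) -> None:
        self.issues.append((pixel, code, message))


# --------------------------------------------------------------------------
# Cube I/O
# --------------------------------------------------------------------------

def read_cube(path, format: str = "container") -> SpectralCube:
    """Read a spectral cube from one of the two documented dialects.

    Missing pixels (a declared scan grid with absent (i, j) keys) are an
    error naming the offenders, never a silent fill.
    """
    if format == "longcsv":
        return _read_longcsv(path)
    if format == "container":
        return _read_container(path)
    raise FormatError(f"unknown cube format {format!r}")


def write_cube(cube: SpectralCube, path, format: str = "container"):
    """Write a cube; the emitted file re-reads to an equal cube."""
    if format == "longcsv":
        _write_longcsv(cube, path)
    elif format == "container":
        _write_container(cube, path)
    else:
        raise FormatError(f"unknown cube format {format!r}")
    return path


def _read_longcsv(path) -> SpectralCube:
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse long-CSV cube {path}: {exc}") from exc
    required = ["i", "j", "wavelength_nm", "intensity"]
    if list(frame.columns[:4]) != required:
        raise FormatError(
            f"long-CSV header must start with {required}, got "
            f"{list(frame.columns)}"
        )
    if frame.empty:
        raise FormatError("long-CSV cube contains no rows")

    m = int(frame["i"].max())
    n = int(frame["j"].max())
    present = set(zip(frame["i"].astype(int), frame["j"].astype(int)))
    declared = {(i, j) for i in range(1, m + 1) for j in range(1, n + 1)}
    absent = sorted(declared - present)
    if absent:
        raise FormatError(
            f"cube declares a {m}x{n} scan but pixels missing (1-based): "
            f"{absent[:10]}{' ...' if len(absent) > 10 else ''}"
        )

    pivot = frame.pivot_table(
        index=["i", "j"], columns="wavelength_nm", values="intensity",
        aggfunc="first", sort=True,
    )
    grid_values = pivot.columns.to_numpy(dtype=float)
    if pivot.isna().any().any():
        bad = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise GridMismatchError(
            f"pixels sampled on inconsistent wavelength vectors: {bad[:10]}"
        )
    counts = frame.groupby(["i", "j"]).size()
    if counts.nunique() != 1 or counts.iloc[0] != grid_values.size:
        raise GridMismatchError(
            "pixels carry different numbers of wavelength samples"
        )
    grid = WavelengthGrid(grid_values)
    data = pivot.to_numpy(dtype=float).reshape(m, n, len(grid))
    return SpectralCube(grid=grid, data=data)


def _write_longcsv(cube: SpectralCube, path) -> None:
    m, n, w = cube.shape
    ii, jj, kk = np.meshgrid(
        np.arange(1, m + 1), np.arange(1, n + 1), np.arange(w), indexing="ij"
    )
    frame = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "wavelength_nm": cube.grid.values[kk.ravel()],
            "intensity": cube.data.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def _read_container(path) -> SpectralCube:
    try:
        with h5py.File(path, "r") as handle:
            if "grid/wavelength_nm" not in handle or "cube/intensity" not in handle:
                raise FormatError(
                    f"{path}: container missing /grid/wavelength_nm or "
                    "/cube/intensity"
                )
            grid_values = handle["grid/wavelength_nm"][()]
            data = handle["cube/intensity"][()]
            laser = float(handle.attrs.get("laser_nm", 532.0))
            pixel = float(handle.attrs.get("pixel_um", 16.0))
            notes = str(handle.attrs.get("notes", ""))
    except OSError as exc:
        raise FormatError(f"cannot open container cube {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"/cube/intensity must be 3-D, got shape {data.shape}")
    return SpectralCube(
        grid=WavelengthGrid(np.asarray(grid_values, dtype=float)),
        data=np.asarray(data, dtype=float),
        pixel_um=pixel,
        laser_nm=laser,
        notes=notes,
    )


def _write_container(cube: SpectralCube, path) -> None:
    with h5py.File(path, "w") as handle:
        handle.create_dataset("grid/wavelength_nm", data=cube.grid.values)
        handle.create_dataset("cube/intensity", data=cube.data)
        handle.attrs["laser_nm"] = cube.laser_nm
        handle.attrs["pixel_um"] = cube.pixel_um
        handle.attrs["created_by"] = CREATED_BY
        if cube.notes:
            handle.attrs["notes"] = cube.notes


def validate_cube(cube: SpectralCube) -> ValidationReport:
    """Report-only validation: empty spectra, NaNs, non-monotone grids.

    Construction already enforces most invariants; this re-checks them on
    the stored arrays so that files produced elsewhere can be screened.
    """
    report = ValidationReport()
    diffs = np.diff(cube.grid.values)
    if not np.all(diffs > 0):
        report.add(None, "grid_not_increasing", "wavelength grid is not strictly increasing")
    if not np.all(np.isfinite(cube.data)):
        bad = np.argwhere(~np.isfinite(cube.data).all(axis=2))
        for i, j in bad:
            report.add((int(i), int(j)), "non_finite", "pixel has non-finite samples")
    if np.any(cube.data < 0):
        bad = np.argwhere((cube.data < 0).any(axis=2))
        for i, j in bad:
            report.add((int(i), int(j)), "negative_intensity", "pixel has negative samples")
    empty = np.argwhere(~np.any(cube.data > 0, axis=2))
    for i, j in empty:
        report.add((int(i), int(j)), "empty_spectrum", "pixel spectrum is all zeros")
    return report


# --------------------------------------------------------------------------
# Map export
# --------------------------------------------------------------------------

def export_map_csv(map_array: np.ndarray, path) -> None:
    """Write one m x n map as long CSV ``i,j,value`` (1-based indices)."""
    m, n = map_array.shape
    ii, jj = np.meshgrid(np.arange(1, m + 1), np.arange(1, n + 1), indexing="ij")
    pd.DataFrame(
        {"i": ii.ravel(), "j": jj.ravel(), "value": map_array.ravel()}
    ).to_csv(path, index=False)


def read_map_csv(path) -> np.ndarray:
    frame = pd.read_csv(path)
    if list(frame.columns) != ["i", "j", "value"]:
        raise FormatError(f"map CSV header must be i,j,value, got {list(frame.columns)}")
    m, n = int(frame["i"].max()), int(frame["j"].max())
    out = np.full((m, n), np.nan)
    out[frame["i"].to_numpy() - 1, frame["j"].to_numpy() - 1] = frame["value"].to_numpy()
    return out


def export_map_tiff(map_array: np.ndarray, path) -> None:
    """Write one map as lossless float32 TIFF."""
    tifffile.imwrite(path, map_array.astype(np.float32))
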