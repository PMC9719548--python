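"""False-color micrograph rendering from pixel maps and label maps.

The published verbal color convention maps the 548-588 nm peak-emission
window onto a blue-to-red sequence: melanoma (~550 nm) blue, BCC
(~555 nm) green, SCC (~563 nm) yellow/orange, normal tissue (~570 nm)
vivid red, nevus (~581 nm) dark red. The original per-bin RGB table is
not available, so the default ramp anchors those verbal colors at the
class centers and interpolates linearly in wavelength (sequential order,
not perceptually uniform). Only channel *dominance* is contractual;
exact RGB values are a documented default, overridable by a user ramp.

Render modes: ``intensity`` (grayscale over [0, max]), ``shift`` (the
spectral ramp on the wavelength map), ``concentration`` (concentrations
routed through their calibration-anchor wavelengths and then the same
spectral ramp, so the two micrographs share spectral color features) and
``labels`` (flat class colors). Missing pixels render black. Rendering
is a pure per-pixel function: two renders of the same maps are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image

from .calibrate import CalibrationTable
from .classify import MISSING, UNCLASSIFIED
from .errors import ConfigError, ValidationError
from .model_io import LabelMap, PixelMaps

__all__ = [
    "ColorRamp",
    "default_spectral_ramp",
    "default_class_colors",
    "wavelength_to_rgb",
    "render_map",
    "write_image",
    "read_image",
]

MISSING_RGB = (0, 0, 0)
UNCLASSIFIED_RGB = (128, 128, 128)


@dataclass(frozen=True)
class ColorRamp:
    """Piecewise-linear RGB ramp over a [lo, hi] domain in map units."""

    domain: tuple[float, float]
    stops: tuple[tuple[float, tuple[int, int, int]], ...]
    out_of_range: str = "clamp"

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ConfigError("ramp domain must satisfy lo < hi")
        fracs = [f for f, _ in self.stops]
        if len(fracs) < 2 or fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ConfigError("ramp stops must run from fraction 0 to 1")
        if not all(a < b for a, b in zip(fracs, fracs[1:])):
            raise ConfigError("ramp stop fractions must be strictly increasing")
        if self.out_of_range not in ("clamp", "missing-color"):
            raise ConfigError(f"unknown out-of-range policy {self.out_of_range!r}")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Map values (any shape) to uint8 RGB; NaN renders black."""
        values = np.asarray(values, dtype=float)
        lo, hi = self.domain
        frac = (values - lo) / (hi - lo)
        nan_mask = ~np.isfinite(frac)
        oob = (~nan_mask) & ((frac < 0) | (frac > 1))
        frac = np.clip(np.where(nan_mask, 0.0, frac), 0.0, 1.0)
        xs = np.array([f for f, _ in self.stops])
        rgb_stops = np.array([c for _, c in self.stops], dtype=float)
        out = np.stack(
            [np.interp(frac, xs, rgb_stops[:, ch]) for ch in range(3)], axis=-1
        )
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        out[nan_mask] = MISSING_RGB
        if self.out_of_range == "missing-color":
            out[oob] = MISSING_RGB
        return out

    def to_json(self, path) -> None:
        payload = {
            "domain": list(self.domain),
            "stops": [[f, list(c)] for f, c in self.stops],
            "out_of_range": self.out_of_range,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)

    @classmethod
    def from_json(cls, path) -> "ColorRamp":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(
            domain=tuple(payload["domain"]),
            stops=tuple(
                (float(f), tuple(int(v) for v in c)) for f, c in payload["stops"]
            ),
            out_of_range=str(payload.get("out_of_range", "clamp")),
        )


def default_spectral_ramp() -> ColorRamp:
    """Five-stop blue-to-dark-red ramp over 548-588 nm.

    Stops sit at the class centers (550 blue is reached just inside the
    domain edge): 548 blue, 555 green, 563 orange, 570 vivid red, 588
    dark red, linear in wavelength between stops.
    """
    lo, hi = 548.0, 588.0

    def frac(nm: float) -> float:
        return (nm - lo) / (hi - lo)

    return ColorRamp(
        domain=(lo, hi),
        stops=(
            (0.0, (0, 0, 255)),          # 548 nm: blue (melanoma side)
            (frac(555.0), (0, 200, 0)),  # BCC: green
            (frac(563.0), (255, 165, 0)),  # SCC: yellow/orange
            (frac(570.0), (255, 0, 0)),  # normal: vivid red
            (1.0, (80, 0, 0)),           # 588 nm: dark red (nevus side)
        ),
    )


def default_class_colors() -> dict[str, tuple[int, int, int]]:
    """Flat label colors: each class center through the spectral ramp."""
    ramp = default_spectral_ramp()
    centers = {
        "melanoma": 550.0,
        "bcc": 555.0,
        "scc": 563.0,
        "normal": 570.0,
        "nevus": 581.0,
    }
    colors = {
        label: tuple(int(v) for v in ramp(np.array(center)))
        for label, center in centers.items()
    }
    colors[UNCLASSIFIED] = UNCLASSIFIED_RGB
    colors[MISSING] = MISSING_RGB
    return colors


def wavelength_to_rgb(lambda_nm, ramp: ColorRamp | None = None):
    """Peak wavelength (nm) -> uint8 RGB via the spectral ramp."""
    ramp = ramp or default_spectral_ramp()
    out = ramp(np.asarray(lambda_nm, dtype=float))
    return tuple(int(v) for v in out) if out.ndim == 1 else out


def render_map(
    source: PixelMaps | LabelMap,
    mode: str,
    ramp: ColorRamp | None = None,
    upscale: int = 1,
    calibration: CalibrationTable | None = None,
    class_colors: dict[str, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Render one micrograph as an (m*upscale, n*upscale, 3) uint8 array.

    Modes: intensity | shift | concentration | labels. The concentration
    mode needs a calibration table to route concentrations back through
    their anchor wavelengths onto the spectral ramp.
    """
    if upscale < 1:
        raise ConfigError("upscale must be a positive integer")
    if mode == "labels":
        if not isinstance(source, LabelMap):
            raise ValidationError("labels mode requires a LabelMap")
        colors = class_colors or default_class_colors()
        rgb = np.zeros(source.shape + (3,), dtype=np.uint8)
        for label, color in colors.items():
            rgb[source.labels == label] = color
        return _upscale(rgb, upscale)

    if not isinstance(source, PixelMaps):
        raise ValidationError(f"{mode} mode requires PixelMaps")
    if mode == "intensity":
        values = source.intensity_map
        finite = np.isfinite(values)
        top = values[finite].max() if finite.any() else 1.0
        gray = np.zeros(values.shape + (3,), dtype=np.uint8)
        scaled = np.clip(
            np.rint(255.0 * np.where(finite, values, 0.0) / (top or 1.0)), 0, 255
        ).astype(np.uint8)
        gray[..., 0] = gray[..., 1] = gray[..., 2] = scaled
        gray[~finite] = MISSING_RGB
        return _upscale(gray, upscale)

    ramp = ramp or default_spectral_ramp()
    if mode == "shift":
        return _upscale(ramp(source.wavelength_map), upscale)
    if mode == "concentration":
        if source.concentration_map is None:
            raise ValidationError("concentration mode: no concentration map present")
        calibration = calibration or _default_calibration()
        conc = source.concentration_map
        lam = np.full(conc.shape, np.nan)
        valid = np.isfinite(conc)
        if valid.any():
            lam[valid] = np.atleast_1d(calibration.lambda_of_c(conc[valid]))
        return _upscale(ramp(lam), upscale)
    raise ConfigError(f"unknown render mode {mode!r}")


def _default_calibration() -> CalibrationTable:
    from .calibrate import default_calibration

    return default_calibration()


def _upscale(rgb: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return rgb
    return np.repeat(np.repeat(rgb, factor, axis=0), factor, axis=1)


def write_image(image: np.ndarray, path, format: str | None = None):
    """Lossless encode to PNG or TIFF; re-reads pixel-identical."""
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "png":
        Image.fromarray(image, mode="RGB").save(path, format="PNG")
    elif fmt in ("tif", "tiff"):
        tifffile.imwrite(path, image)
    else:
        raise ConfigError(f"unsupported image format {fmt!r}")
    return path


def read_image(path) -> np.ndarray:
    fmt = str(path).rsplit(".", 1)[-1].lower()
    if fmt == "png":
        return np.asarray(Image.open(path).convert("RGB"))
    return tifffile.imread(path)
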