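"""Wavelength <-> Rd6G concentration calibration.

The reabsorption redshift makes the peak emission wavelength of Rd6G a
monotone function of its concentration, so the wavelength map — not the
intensity map — determines the concentration map. The calibration is a
strictly monotone anchor table linking concentration (μM) to peak
wavelength (nm); the default anchors follow the printed class pairings
(2 → 550, 8 → 555, 10 → 563, 16 → 570). The nevus emission (581 nm) is
deliberately outside the span: its redshift comes from melanin
autofluorescence, not Rd6G density, so curve inversion at nevus pixels is
refused and the class's 12 μM is only ever reported by table lookup.

Concentration from *intensity* is fundamentally ambiguous: the quenched
output I(c) = a·c·exp(−c/κ) rises to a single maximum at c = κ and falls
again, so one intensity maps to up to two concentrations (with the
default κ = 30/ln 4, the 10 μM and 40 μM samples emit identically).
``concentration_candidates_from_intensity`` exposes that two-valued
inverse by bracketed root-finding on the two monotone branches.

The characteristic operator connecting [λ_ij] to [c_ij] is implemented
per pixel: a scalar proportionality for bare homogeneous fluorophore
(c = k·λ) and the nonlinear monotone table for stained tissue. A
non-diagonal operator (spatial cross-talk) has no defined construction
and is refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .constants import KAPPA_UM
from .errors import (
    ConfigError,
    RangeError,
    UnsupportedOperationError,
    ValidationError,
)
from .model_io import PixelMaps

__all__ = [
    "CalibrationTable",
    "KOperator",
    "default_calibration",
    "wavelength_to_concentration",
    "apply_k",
    "concentration_candidates_from_intensity",
]

#: Wavelengths within this distance of the span edge are treated as
#: in-span (guards float jitter at the anchor endpoints).
SPAN_TOL_NM = 1e-6

#: Upper concentration bound (μM) searched by the intensity inverse —
#: the instrument's stated concentration display range.
CONC_SEARCH_MAX_UM = 200.0


@dataclass(frozen=True)
class CalibrationTable:
    """Monotone anchors (c_k, λ_k) plus the quenched intensity parameters."""

    anchors: np.ndarray
    amplitude: float = 1.0
    quench_uM: float = KAPPA_UM
    interpolation: str = "monotone"
    _lam_of_c: PchipInterpolator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        anchors = np.asarray(self.anchors, dtype=float)
        if anchors.ndim != 2 or anchors.shape[1] != 2 or anchors.shape[0] < 2:
            raise ValidationError("calibration needs >= 2 (conc, wavelength) anchors")
        if not (np.all(np.diff(anchors[:, 0]) > 0) and np.all(np.diff(anchors[:, 1]) > 0)):
            raise ValidationError("anchors must be strictly increasing in both coordinates")
        if self.quench_uM <= 0 or self.amplitude <= 0:
            raise ValidationError("amplitude and quench constant must be > 0")
        if self.interpolation not in ("monotone", "linear"):
            raise ConfigError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "anchors", anchors)
        if self.interpolation == "monotone":
            object.__setattr__(
                self, "_lam_of_c", PchipInterpolator(anchors[:, 0], anchors[:, 1])
            )

    # -- spans ------------------------------------------------------------

    @property
    def conc_span(self) -> tuple[float, float]:
        return float(self.anchors[0, 0]), float(self.anchors[-1, 0])

    @property
    def lambda_span(self) -> tuple[float, float]:
        return float(self.anchors[0, 1]), float(self.anchors[-1, 1])

    # -- forward and inverse curves ---------------------------------------

    def lambda_of_c(self, c):
        """Peak wavelength (nm) at concentration c (μM); in-span only."""
        c_arr = np.asarray(c, dtype=float)
        lo, hi = self.conc_span
        if np.any(c_arr < lo - SPAN_TOL_NM) or np.any(c_arr > hi + SPAN_TOL_NM):
            raise RangeError(
                f"concentration outside calibration span [{lo}, {hi}] μM"
            )
        c_arr = np.clip(c_arr, lo, hi)
        if self.interpolation == "monotone":
            out = self._lam_of_c(c_arr)
        else:
            out = np.interp(c_arr, self.anchors[:, 0], self.anchors[:, 1])
        return float(out) if out.ndim == 0 else out

    def c_of_lambda(self, lam):
        """Inverse of the anchor curve; exact at anchors."""
        lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
        lo, hi = self.lambda_span
        if np.any(lam_arr < lo - SPAN_TOL_NM) or np.any(lam_arr > hi + SPAN_TOL_NM):
            bad = lam_arr[(lam_arr < lo - SPAN_TOL_NM) | (lam_arr > hi + SPAN_TOL_NM)]
            raise RangeError(
                f"wavelength {bad[:5]} nm outside calibration span [{lo}, {hi}] nm"
            )
        lam_arr = np.clip(lam_arr, lo, hi)
        if self.interpolation == "linear":
            out = np.interp(lam_arr, self.anchors[:, 1], self.anchors[:, 0])
        else:
            c_lo, c_hi = self.conc_span
            out = np.empty_like(lam_arr)
            for idx, value in np.ndenumerate(lam_arr):
                if value <= lo:
                    out[idx] = c_lo
                elif value >= hi:
                    out[idx] = c_hi
                else:
                    out[idx] = brentq(
                        lambda c, v=value: float(self._lam_of_c(c)) - v,
                        c_lo, c_hi, xtol=1e-13, rtol=1e-15,
                    )
        out = out.reshape(np.shape(lam))
        return float(out) if out.ndim == 0 else out

    def in_lambda_span(self, lam) -> np.ndarray:
        lo, hi = self.lambda_span
        lam = np.asarray(lam, dtype=float)
        return (lam >= lo - SPAN_TOL_NM) & (lam <= hi + SPAN_TOL_NM)

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "anchors": self.anchors.tolist(),
            "amplitude": self.amplitude,
            "kappa_uM": self.quench_uM,
            "interpolation": self.interpolation,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(
            anchors=np.asarray(payload["anchors"], dtype=float),
            amplitude=float(payload.get("amplitude", 1.0)),
            quench_uM=float(payload.get("kappa_uM", KAPPA_UM)),
            interpolation=str(payload.get("interpolation", "monotone")),
        )


@dataclass(frozen=True)
class KOperator:
    """Characteristic operator linking [λ_ij] to [c_ij], applied per pixel."""

    kind: str = "table"
    scalar: float = 1.0
    table: CalibrationTable | None = None

    def __post_init__(self) -> None:
        if self.kind == "identity-scalar":
            return
        if self.kind == "table":
            if self.table is None:
                raise ConfigError("table KOperator requires a CalibrationTable")
            return
        if self.kind == "non-diagonal":
            raise UnsupportedOperationError(
                "a non-diagonal characteristic operator (pixel cross-talk) "
                "has no defined construction and is unsupported"
            )
        raise ConfigError(f"unknown KOperator kind {self.kind!r}")


def default_calibration() -> CalibrationTable:
    """Anchor table from the printed class pairings (nevus excluded)."""
    return CalibrationTable(
        anchors=np.array(
            [[2.0, 550.0], [8.0, 555.0], [10.0, 563.0], [16.0, 570.0]]
        )
    )


def wavelength_to_concentration(
    lambda_nm, table: CalibrationTable, extrapolate: bool = False
):
    """Invert the anchor curve: peak wavelength (nm) -> concentration (μM).

    With ``extrapolate=False`` (the default) wavelengths outside the anchor
    span raise RangeError; with ``extrapolate=True`` they clamp to the span
    edge concentration.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if extrapolate:
        lo, hi = table.lambda_span
        lam = np.clip(lam, lo, hi)
    return table.c_of_lambda(lam)


def apply_k(maps: PixelMaps, op: KOperator) -> PixelMaps:
    """Produce the concentration map [c_ij] from the wavelength map.

    identity-scalar: c_ij = k·λ_ij (the bare-fluorophore simplification);
    table: monotone inversion per pixel, with out-of-span pixels (nevus by
    design) flagged missing. Missing wavelengths propagate.
    """
    lam = maps.wavelength_map
    if lam is None:
        raise ValidationError("wavelength map absent; build maps first")
    valid = np.isfinite(lam)
    conc = np.full(lam.shape, np.nan)
    if op.kind == "identity-scalar":
        conc[valid] = op.scalar * lam[valid]
    else:
        in_span = valid & op.table.in_lambda_span(np.where(valid, lam, 0.0))
        if np.any(in_span):
            conc[in_span] = np.atleast_1d(op.table.c_of_lambda(lam[in_span]))
    return maps.with_concentration(conc)


def concentration_candidates_from_intensity(
    intensity: float, table: CalibrationTable
) -> list[float]:
    """All concentrations on [0, 200] μM emitting the given intensity.

    The quenched output rises on [0, κ] and falls on [κ, 200]; bracketed
    root-finding on each monotone branch yields 0, 1 or 2 candidates (the
    curve maximum yields exactly one, at κ). Intensity zero maps to {0}.
    """
    if intensity < 0:
        raise RangeError("intensity must be >= 0")
    a, kappa = table.amplitude, table.quench_uM

    def f(c: float) -> float:
        return a * c * np.exp(-c / kappa) - intensity

    if intensity == 0:
        return [0.0]
    peak = a * kappa * np.exp(-1.0)
    rel = intensity / peak
    if rel > 1.0 + 1e-12:
        return []
    if rel >= 1.0 - 1e-12:
        return [float(kappa)]
    roots: list[float] = []
    roots.append(float(brentq(f, 0.0, kappa, xtol=1e-12, rtol=1e-14)))
    if f(CONC_SEARCH_MAX_UM) <= 0:  # falling branch re-crosses within range
        roots.append(
            float(brentq(f, kappa, CONC_SEARCH_MAX_UM, xtol=1e-12, rtol=1e-14))
        )
    return roots
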