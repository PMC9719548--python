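"""Spectral-band segmentation of the wavelength map and class summaries.

Tissue classes occupy disjoint peak-emission-wavelength bands: melanoma
near 550 nm, BCC near 555 nm, SCC near 563 nm, normal tissue near 570 nm
and nevus above 575 nm. The default decision bands place boundaries at
the midpoints between printed class centers (553, 559, 566 nm) and split
normal from nevus at 575.5 nm; every interval is closed-open [lo, hi)
with lower-edge inclusion, so boundary wavelengths classify
deterministically. Wavelengths outside all bands are "unclassified",
missing pixels stay "missing". The bands are an editorial default and
fully overridable.

Per-class summaries report pixel counts and fractions, the wavelength
range of member pixels (whose width max−min matches the scatter
statistic of each class when the phantom spread equals it), the modal
laser-line shift, and the class's typical Rd6G concentration by table
lookup — the only route by which the nevus 12 μM is ever reported, since
nevus sits outside the calibration span.

The modal shift is estimated by the member-pixel *median*: the per-class
peak distributions are symmetric (flat-topped uniform in the simulator),
for which a binned histogram mode is ill-posed while the median coincides
with the center of symmetry and is stable to ~spread/(2√n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import LASER_NM
from .errors import ConfigError, ValidationError
from .model_io import LabelMap, PixelMaps
from .simulate import TissueClassParams, class_by_label

__all__ = [
    "TISSUE_LABELS",
    "ClassBands",
    "ClassStats",
    "ClassSummary",
    "default_bands",
    "classify_map",
    "summarize",
    "export_scatter",
]

#: The five tissue classes, in ascending band order.
TISSUE_LABELS = ("melanoma", "bcc", "scc", "normal", "nevus")

UNCLASSIFIED = "unclassified"
MISSING = "missing"


@dataclass(frozen=True)
class ClassBands:
    """Ordered disjoint closed-open wavelength intervals per label (nm)."""

    intervals: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        intervals = tuple(
            (str(label), float(lo), float(hi)) for label, lo, hi in self.intervals
        )
        if not intervals:
            raise ConfigError("at least one band required")
        for label, lo, hi in intervals:
            if not lo < hi:
                raise ConfigError(f"band {label}: lo {lo} must be < hi {hi}")
        ordered = sorted(intervals, key=lambda t: t[1])
        for (_, _, hi_prev), (label, lo, _) in zip(ordered, ordered[1:]):
            if lo < hi_prev:
                raise ConfigError(f"band {label} overlaps its predecessor")
        object.__setattr__(self, "intervals", tuple(ordered))

    def lookup(self, lambda_nm: float) -> str:
        for label, lo, hi in self.intervals:
            if lo <= lambda_nm < hi:
                return label
        return UNCLASSIFIED

    def to_json(self, path) -> None:
        payload = {
            "bands": [
                {"label": label, "lo_nm": lo, "hi_nm": hi}
                for label, lo, hi in self.intervals
            ]
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClassBands":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(
            tuple(
                (b["label"], b["lo_nm"], b["hi_nm"]) for b in payload["bands"]
            )
        )


def default_bands() -> ClassBands:
    """Midpoint boundaries between class centers; nevus above 575.5 nm."""
    return ClassBands(
        (
            ("melanoma", 548.0, 553.0),
            ("bcc", 553.0, 559.0),
            ("scc", 559.0, 566.0),
            ("normal", 566.0, 575.5),
            ("nevus", 575.5, 588.0),
        )
    )


def classify_map(
    wavelength_map: np.ndarray,
    bands: ClassBands | None = None,
    spatial_median: bool = False,
) -> LabelMap:
    """Per-pixel closed-open interval lookup on the wavelength map.

    ``spatial_median=True`` applies a 3x3 modal (majority-vote) filter on
    the labels — the spatial counterpart of the spectral smoothing stage;
    ties keep the original label, missing pixels are never altered.
    """
    bands = bands or default_bands()
    lam = np.asarray(wavelength_map, dtype=float)
    labels = np.full(lam.shape, UNCLASSIFIED, dtype="U16")
    for label, lo, hi in bands.intervals:
        labels[(lam >= lo) & (lam < hi)] = label
    labels[~np.isfinite(lam)] = MISSING
    if spatial_median:
        labels = _modal_filter(labels)
    return LabelMap(labels)


def _modal_filter(labels: np.ndarray) -> np.ndarray:
    """3x3 majority vote; ties (or a strict tie with the center) keep
    the original label; 'missing' neither votes nor changes."""
    m, n = labels.shape
    out = labels.copy()
    for i in range(m):
        for j in range(n):
            if labels[i, j] == MISSING:
                continue
            window = labels[max(0, i - 1): i + 2, max(0, j - 1): j + 2].ravel()
            window = window[window != MISSING]
            values, counts = np.unique(window, return_counts=True)
            top = counts.max()
            winners = values[counts == top]
            if winners.size == 1 and winners[0] != labels[i, j]:
                out[i, j] = winners[0]
    return out


@dataclass(frozen=True)
class ClassStats:
    """Summary of one class's member pixels; NaN fields mark empty classes."""

    label: str
    count: int
    fraction: float
    mean_lambda_nm: float
    min_lambda_nm: float
    max_lambda_nm: float
    width_nm: float
    modal_shift_nm: float
    typ_conc_uM: float


@dataclass
class ClassSummary:
    """Per-class statistics over a segmented map."""

    stats: dict[str, ClassStats] = field(default_factory=dict)
    laser_nm: float = LASER_NM

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stats.values()])

    def to_json(self, path) -> None:
        payload = {
            "laser_nm": self.laser_nm,
            "classes": {label: vars(s) for label, s in self.stats.items()},
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, allow_nan=True)

    @classmethod
    def from_json(cls, path) -> "ClassSummary":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        stats = {
            label: ClassStats(**entry)
            for label, entry in payload["classes"].items()
        }
        return cls(stats=stats, laser_nm=float(payload["laser_nm"]))


def summarize(
    labels: LabelMap,
    maps: PixelMaps,
    classes: list[TissueClassParams] | None = None,
) -> ClassSummary:
    """Per-class counts, wavelength range/width, modal shift, concentration.

    Fractions are over non-missing pixels and sum to 1 across the reported
    labels (the five classes plus 'unclassified'). The width is the range
    max−min of the refined member wavelengths; the modal shift is the
    member-pixel median of λ − λ_L.
    """
    if labels.shape != maps.shape:
        raise ValidationError("label map and pixel maps are not co-registered")
    table = class_by_label(classes)
    lam = maps.wavelength_map
    non_missing = int(np.sum(labels.labels != MISSING))
    summary = ClassSummary(laser_nm=maps.laser_nm)
    for label in TISSUE_LABELS + (UNCLASSIFIED,):
        member = (labels.labels == label) & np.isfinite(lam)
        count = int(member.sum())
        typ_conc = table[label].typ_conc_uM if label in table else float("nan")
        if count == 0:
            summary.stats[label] = ClassStats(
                label, 0, 0.0, float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"), typ_conc,
            )
            continue
        values = lam[member]
        shifts = values - maps.laser_nm
        summary.stats[label] = ClassStats(
            label=label,
            count=count,
            fraction=count / non_missing if non_missing else 0.0,
            mean_lambda_nm=float(values.mean()),
            min_lambda_nm=float(values.min()),
            max_lambda_nm=float(values.max()),
            width_nm=float(values.max() - values.min()),
            modal_shift_nm=float(np.median(shifts)),
            typ_conc_uM=typ_conc,
        )
    return summary


def export_scatter(
    labels: LabelMap,
    maps: PixelMaps,
) -> pd.DataFrame:
    """Long-format per-pixel table: one row per non-missing pixel.

    Columns ``i,j,label,lambda_nm,shift_nm,conc_uM`` (1-based indices),
    suitable for the class scatter plot; conc is NaN where calibration
    has not been applied or the pixel is out of span.
    """
    if labels.shape != maps.shape:
        raise ValidationError("label map and pixel maps are not co-registered")
    m, n = maps.shape
    ii, jj = np.meshgrid(np.arange(1, m + 1), np.arange(1, n + 1), indexing="ij")
    conc = (
        maps.concentration_map
        if maps.concentration_map is not None
        else np.full((m, n), np.nan)
    )
    frame = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "label": labels.labels.ravel(),
            "lambda_nm": maps.wavelength_map.ravel(),
            "shift_nm": maps.shift_map.ravel(),
            "conc_uM": conc.ravel(),
        }
    )
    return frame[frame["label"] != MISSING].reset_index(drop=True)
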