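"""HU -> relative iodine concentration mapping and its spatial/temporal
summaries.

A linear relation between CT attenuation and iodine concentration is
assumed, anchored by two reference attenuations: the baseline (no iodine)
and the attenuation at the concentration ceiling c_max = 40 mg/mL. Only
*relative* concentration is recoverable this way — the mapping is fully
determined by the user-supplied reference pair, never by an absolute gel HU.

Summaries:
  * per-range cross-sectional areas at the 7 / 13.4 / 27 / 40 mg/mL
    boundaries (half-open low, closed top), in cm^2;
  * trapezoidal AUC of those areas over minutes;
  * 1D concentration profiles along a line whose length is normalized to one
    unit, with trapezoidal AUC over normalized distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidSpec

__all__ = [
    "C_MAX",
    "DEFAULT_RANGES",
    "IodineMap",
    "RangeAreaSet",
    "LineProfile",
    "baseline_from_roi",
    "hu_to_iodine",
    "range_areas",
    "line_profile",
    "temporal_range_auc",
    "save_contour_png",
]

C_MAX = 40.0  # mg/mL iodine ceiling
# (low, high) boundaries in mg/mL; half-open low edge, closed top edge
DEFAULT_RANGES: tuple[tuple[float, float], ...] = ((7.0, 13.4), (13.4, 27.0), (27.0, 40.0))


@dataclass
class IodineMap:
    """Per-voxel (3D) or per-pixel (2D) iodine concentration in mg/mL."""

    concentration: np.ndarray
    spacing: tuple  # mm per axis, array order
    hu_baseline: float
    hu_at_cmax: float
    c_max: float = C_MAX

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.min() < -1e-9 or self.concentration.max() > self.c_max + 1e-9:
            raise InvalidSpec("concentrations must lie in [0, c_max]")


@dataclass
class RangeAreaSet:
    """Cross-sectional areas per concentration range at one timepoint."""

    timepoint_min: float
    ranges: tuple[tuple[float, float], ...]
    areas_cm2: tuple[float, ...]

    def __post_init__(self) -> None:
        for (lo, hi), (lo2, _) in zip(self.ranges[:-1], self.ranges[1:]):
            if not np.isclose(hi, lo2):
                raise InvalidSpec("ranges must be contiguous and non-overlapping")
        if any(a < 0 for a in self.areas_cm2):
            raise InvalidSpec("areas must be non-negative")


@dataclass
class LineProfile:
    """Concentration along a segment rescaled to unit length."""

    positions: np.ndarray  # in [0, 1], strictly increasing
    concentrations: np.ndarray  # mg/mL
    auc: float  # mg/mL x normalized distance

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        d = np.diff(self.positions)
        if not (np.all(d > 0) and np.isclose(self.positions[0], 0.0) and np.isclose(self.positions[-1], 1.0)):
            raise InvalidSpec("positions must increase strictly from 0 to 1")


def baseline_from_roi(values: np.ndarray, roi_mask: np.ndarray) -> float:
    """Default HU baseline: the median attenuation of a user-supplied
    background (no-iodine) region."""
    values = np.asarray(values, dtype=float)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if values.shape != roi_mask.shape:
        raise InvalidSpec("values and ROI mask shapes differ")
    if not roi_mask.any():
        raise InvalidSpec("background ROI is empty")
    return float(np.median(values[roi_mask]))


def hu_to_iodine(
    values: np.ndarray,
    hu_baseline: float,
    hu_at_cmax: float,
    spacing: tuple = (1.0, 1.0),
    c_max: float = C_MAX,
) -> IodineMap:
    """c = c_max (HU - hu_baseline) / (hu_at_cmax - hu_baseline), clipped to
    [0, c_max]. Monotone in HU; idempotent on already-clipped values."""
    if hu_at_cmax <= hu_baseline:
        raise InvalidSpec("hu_at_cmax must exceed hu_baseline")
    values = np.asarray(values, dtype=float)
    conc = c_max * (values - hu_baseline) / (hu_at_cmax - hu_baseline)
    conc = np.clip(conc, 0.0, c_max)
    return IodineMap(conc, tuple(spacing), hu_baseline, hu_at_cmax, c_max)


def range_areas(
    map_slice: IodineMap,
    timepoint_min: float = 0.0,
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES,
) -> RangeAreaSet:
    """Pixel-count areas (cm^2) of a 2D map within each concentration range.

    Each range is half-open at its low edge; the topmost range additionally
    includes its upper boundary so the ceiling value is counted.
    """
    conc = map_slice.concentration
    if conc.ndim != 2:
        raise InvalidSpec("range areas are defined on 2D maps")
    if len(map_slice.spacing) != 2:
        raise InvalidSpec("2D map needs a 2-axis pixel spacing")
    pixel_area_cm2 = float(np.prod(map_slice.spacing)) / 100.0
    areas = []
    top = max(hi for _, hi in ranges)
    for lo, hi in ranges:
        if np.isclose(hi, top):
            n = int(((conc >= lo) & (conc <= hi)).sum())
        else:
            n = int(((conc >= lo) & (conc < hi)).sum())
        areas.append(n * pixel_area_cm2)
    return RangeAreaSet(timepoint_min, tuple(ranges), tuple(areas))


def line_profile(
    map_slice: IodineMap,
    endpoints_mm: tuple[tuple[float, float], tuple[float, float]],
    n_samples: int = 100,
) -> LineProfile:
    """Bilinear samples along a segment, positions normalized to [0, 1],
    trapezoidal AUC over normalized distance.

    ``endpoints_mm`` are two (row_mm, col_mm) points in the slice's physical
    frame (array-axis order times spacing).
    """
    if n_samples < 2:
        raise InvalidSpec("need at least two samples")
    conc = map_slice.concentration
    if conc.ndim != 2:
        raise InvalidSpec("line profiles are defined on 2D maps")
    p0 = np.asarray(endpoints_mm[0], dtype=float)
    p1 = np.asarray(endpoints_mm[1], dtype=float)
    if np.allclose(p0, p1):
        raise InvalidSpec("profile endpoints coincide")
    spacing = np.asarray(map_slice.spacing, dtype=float)
    for p in (p0, p1):
        idx = p / spacing
        if np.any(idx < 0) or np.any(idx > np.asarray(conc.shape) - 1):
            raise InvalidSpec("profile endpoints must lie inside the slice")
    s = np.linspace(0.0, 1.0, n_samples)
    pts_mm = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    idx = (pts_mm / spacing).T
    samples = ndimage.map_coordinates(conc, idx, order=1, mode="nearest")
    auc = float(np.trapezoid(samples, s))
    return LineProfile(positions=s, concentrations=samples, auc=auc)


def temporal_range_auc(series: list[RangeAreaSet]) -> dict[tuple[float, float], float]:
    """Trapezoidal AUC over minutes of each range's area curve (area x min,
    reported as a.u.)."""
    if len(series) < 2:
        raise InvalidSpec("need at least two timepoints")
    times = np.asarray([s.timepoint_min for s in series], dtype=float)
    if not np.all(np.diff(times) > 0):
        raise InvalidSpec("timepoints must be strictly increasing")
    ranges = series[0].ranges
    for s in series[1:]:
        if s.ranges != ranges:
            raise InvalidSpec("all timepoints must share the same ranges")
    out = {}
    for k, rng in enumerate(ranges):
        areas = np.asarray([s.areas_cm2[k] for s in series], dtype=float)
        out[rng] = float(np.trapezoid(areas, times))
    return out


def save_contour_png(
    map_slice: IodineMap,
    path,
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES,
    title: str | None = None,
) -> None:
    """Color-coded contour plot of a 2D concentration map at the range
    boundaries (the familiar per-range overlay figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conc = map_slice.concentration
    if conc.ndim != 2:
        raise InvalidSpec("contour export is defined on 2D maps")
    levels = sorted({lo for lo, _ in ranges} | {hi for _, hi in ranges})
    fig, ax = plt.subplots(figsize=(4, 4))
    cs = ax.contourf(conc, levels=[0.0] + levels, cmap="inferno")
    fig.colorbar(cs, ax=ax, label="iodine (mg/mL)")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
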