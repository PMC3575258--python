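"""Map normalisation, inter-subject averaging and spatial statistics.

Subjects differ in limb size and array placement, so maps are first mapped
to limb-relative coordinates (x in fractions of segment circumference, y in
fractions of segment length, origin at the anatomical reference electrode),
resampled onto a shared grid by separable cubic splines, and then averaged
pixel-wise.  Inter-subject variability is the pixel-wise std divided by the
mean-map intensity.  Spatial distribution is summarised by the medians
(mu_x, mu_y) of the per-axis maxima profiles of the segmented map, and
intensity by the mean RMS over the segmented area (RMS_av-HD) or by the RMS
of a single differential channel pair (RMS_av-bip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .features import EpochingSpec, epoch_segments
from .grids import ElectrodeGrid, GridRecording
from .mapping import ActivationMap, FilterSpec, bandpass_zero_phase
from .segmentation import NoRegionError, SegmentedMap

__all__ = [
    "NormalizedMap",
    "Projection",
    "normalize_map_coords",
    "common_coordinates",
    "resample_common_grid",
    "average_maps",
    "variability_summary",
    "project_map",
    "projection_median",
    "region_mean_intensity",
    "bipolar_rms",
]


@dataclass
class NormalizedMap:
    """Intensity image on limb-relative coordinates."""

    intensity: np.ndarray
    x: np.ndarray  # fractions of segment circumference
    y: np.ndarray  # fractions of segment length
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensity.shape != (self.y.size, self.x.size):
            raise ValueError("coordinate vectors do not match intensity shape")
        for v in (self.x, self.y):
            if v.size > 1 and not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
                raise ValueError("coordinates must be strictly monotone")


@dataclass
class Projection:
    """Per-axis maxima profile Q of a segmented map."""

    dim: str  # 'x' or 'y'
    coords: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.dim not in ("x", "y"):
            raise ValueError("dim must be 'x' or 'y'")
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.shape != self.values.shape:
            raise ValueError("coords and values differ in length")


def normalize_map_coords(amap: ActivationMap, grid: ElectrodeGrid) -> NormalizedMap:
    """Limb-relative coordinates; intensities untouched."""
    if grid.circumference_mm <= 0 or grid.segment_length_mm <= 0:
        raise ValueError("grid is missing circumference/length metadata")
    cols = np.arange(grid.n_cols)
    rows = np.arange(grid.n_rows)
    x = (cols - grid.origin_col) * grid.pitch_mm / grid.circumference_mm
    y = (rows - grid.origin_row) * grid.pitch_mm / grid.segment_length_mm
    return NormalizedMap(amap.intensity.copy(), x, y,
                         meta={"pitch_mm": grid.pitch_mm,
                               "circumference_mm": grid.circumference_mm,
                               "segment_length_mm": grid.segment_length_mm})


def common_coordinates(maps: list[NormalizedMap], oversample: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Shared coordinate vectors: ``oversample`` times the densest source
    resolution over the intersection of all coordinate ranges (so no map is
    extrapolated)."""
    if not maps:
        raise ValueError("no maps")
    x_lo = max(m.x.min() for m in maps)
    x_hi = min(m.x.max() for m in maps)
    y_lo = max(m.y.min() for m in maps)
    y_hi = min(m.y.max() for m in maps)
    if x_lo >= x_hi or y_lo >= y_hi:
        raise ValueError("map coordinate ranges do not overlap")
    nx = max(int(m.x.size) for m in maps) * oversample
    ny = max(int(m.y.size) for m in maps) * oversample
    return np.linspace(x_lo, x_hi, nx), np.linspace(y_lo, y_hi, ny)


def resample_common_grid(nmap: NormalizedMap, x_new: np.ndarray, y_new: np.ndarray) -> NormalizedMap:
    """Separable cubic-spline interpolation onto shared coordinates."""
    x_new = np.asarray(x_new, dtype=float)
    y_new = np.asarray(y_new, dtype=float)
    eps = 1e-12
    if (x_new.min() < nmap.x.min() - eps or x_new.max() > nmap.x.max() + eps
            or y_new.min() < nmap.y.min() - eps or y_new.max() > nmap.y.max() + eps):
        raise ValueError("target coordinates extrapolate beyond the source map")
    kx = min(3, nmap.x.size - 1)
    ky = min(3, nmap.y.size - 1)
    spline = RectBivariateSpline(nmap.y, nmap.x, nmap.intensity, kx=ky, ky=kx)
    vals = spline(y_new, x_new)
    return NormalizedMap(np.maximum(vals, 0.0), x_new, y_new, dict(nmap.meta))


def average_maps(maps: list[NormalizedMap]) -> tuple[NormalizedMap, np.ndarray]:
    """Pixel-wise mean map and variability map (std / mean intensity).

    Variability is NaN where the mean intensity is zero.  Uses the n-1 std
    convention.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to average")
    x0, y0 = maps[0].x, maps[0].y
    for m in maps[1:]:
        if not (np.array_equal(m.x, x0) and np.array_equal(m.y, y0)):
            raise ValueError("maps are not on a common grid")
    stack = np.stack([m.intensity for m in maps])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        variability = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), np.nan)
    return NormalizedMap(mean, x0, y0, {"n_subjects": len(maps)}), variability


def variability_summary(variability: np.ndarray, region: np.ndarray | None = None) -> tuple[float, float, float]:
    """(mean, min, max) of the variability map over a region mask."""
    v = np.asarray(variability, dtype=float)
    if region is not None:
        v = v[np.asarray(region, dtype=bool)]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("variability has no finite values in the region")
    return float(v.mean()), float(v.min()), float(v.max())


def project_map(seg: SegmentedMap, dim: str, coords: np.ndarray | None = None,
                restrict_to_selected: bool = True) -> Projection:
    """Maxima profile of the segmented dome image along one axis.

    ``Q_k`` is the maximum over the orthogonal dimension at coordinate k,
    restricted to the selected region when one is set.
    """
    if dim not in ("x", "y"):
        raise ValueError("dim must be 'x' or 'y'")
    dome = seg.dome
    if restrict_to_selected:
        m = seg.selected_mask()
        if not m.any():
            raise NoRegionError("selected region is empty")
        dome = np.where(m, dome, 0.0)
    values = dome.max(axis=0) if dim == "x" else dome.max(axis=1)
    if coords is None:
        if seg.source is not None:
            coords = seg.source.x_mm if dim == "x" else seg.source.y_mm
        else:
            coords = np.arange(values.size, dtype=float)
    return Projection(dim, np.asarray(coords, dtype=float), values)


def projection_median(proj: Projection) -> float:
    """Coordinate splitting the area under Q into two equal halves.

    Q is treated as a piecewise-constant density over cells whose edges are
    the midpoints between coordinates; the half-total crossing is inverted
    with linear interpolation, giving sub-grid resolution.
    """
    q = proj.values
    c = proj.coords
    total = q.sum()
    if total <= 0:
        raise ValueError("projection has zero total; median undefined")
    if c.size == 1:
        return float(c[0])
    edges = np.empty(c.size + 1)
    edges[1:-1] = (c[:-1] + c[1:]) / 2.0
    edges[0] = c[0] - (c[1] - c[0]) / 2.0
    edges[-1] = c[-1] + (c[-1] - c[-2]) / 2.0
    cum = np.concatenate([[0.0], np.cumsum(q)])
    target = total / 2.0
    k = int(np.searchsorted(cum, target, side="left")) - 1
    k = max(0, min(k, q.size - 1))
    while q[k] == 0 and cum[k] < target:
        k += 1
    frac = (target - cum[k]) / q[k] if q[k] > 0 else 0.5
    return float(edges[k] + frac * (edges[k + 1] - edges[k]))


def region_mean_intensity(amap: ActivationMap, seg: SegmentedMap) -> float:
    """RMS_av-HD: mean source-map intensity over the selected region."""
    m = seg.selected_mask()
    if not m.any():
        raise NoRegionError("selected region is empty")
    if m.shape != amap.shape:
        raise ValueError("segmentation does not match map shape")
    return float(amap.intensity[m].mean())


def bipolar_rms(
    rec: GridRecording,
    ch_a: tuple[int, int],
    ch_b: tuple[int, int],
    start_sample: int = 0,
    epoching: EpochingSpec = EpochingSpec(),
    filt: FilterSpec = FilterSpec(),
) -> float:
    """RMS_av-bip: epoch-averaged RMS of the single differential signal
    between two adjacent electrodes along the fiber direction."""
    if ch_a == ch_b:
        raise ValueError("bipolar pair must use two distinct electrodes")
    a = rec.channel(*ch_a)
    b = rec.channel(*ch_b)
    diff = bandpass_zero_phase(a - b, rec.fs_hz, filt)
    epochs = epoch_segments(diff, rec.fs_hz, epoching, start_sample)
    return float(np.sqrt((epochs**2).mean(axis=-1)).mean())
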