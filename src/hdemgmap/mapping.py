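"""RMS activation maps from filtered grid recordings.

The map intensity of channel (i, j) is the mean over M = 6 non-overlapping
500 ms epochs of the epoch RMS, computed after zero-phase 12-350 Hz
band-pass filtering over a 3 s window of steady force.  Channels flagged as
low quality are replaced by triangle-based cubic surface interpolation
(Clough-Tocher on the Delaunay triangulation of the remaining electrodes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata
from scipy.signal import butter, sosfiltfilt

from .detection import ArtifactMask
from .features import EpochingSpec, epoch_segments
from .grids import GridRecording

__all__ = [
    "FilterSpec",
    "ActivationMap",
    "InterpolationInfeasibleError",
    "bandpass_zero_phase",
    "select_steady_segment",
    "compute_map",
    "replace_artifact_values",
]


class InterpolationInfeasibleError(RuntimeError):
    """Too many flagged channels for surface interpolation."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass (effective order doubles)."""

    low_hz: float = 12.0
    high_hz: float = 350.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs_hz: float):
        if self.high_hz >= fs_hz / 2:
            raise ValueError(f"high_hz {self.high_hz} must be below Nyquist {fs_hz / 2}")
        return butter(self.order, (self.low_hz, self.high_hz), btype="bandpass",
                      fs=fs_hz, output="sos")


@dataclass
class ActivationMap:
    """2-D RMS intensity image on the electrode grid.

    ``x_mm``/``y_mm`` are the physical coordinates of columns/rows relative
    to electrode (0, 0); ``provenance`` records how the map was computed,
    including any interpolated channels.
    """

    intensity: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if (self.intensity < 0).any():
            raise ValueError("map intensity must be non-negative")
        if self.intensity.shape != (len(self.y_mm), len(self.x_mm)):
            raise ValueError("coordinate vectors do not match intensity shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy(self) -> "ActivationMap":
        return ActivationMap(self.intensity.copy(), np.array(self.x_mm),
                             np.array(self.y_mm), dict(self.provenance))


def bandpass_zero_phase(signal: np.ndarray, fs_hz: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Forward-backward band-pass; magnitude response is the squared
    single-pass response, net phase zero."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] <= 3 * spec.order:
        raise ValueError("signal too short for the filter order")
    sos = spec.sos(fs_hz)
    if spec.zero_phase:
        return sosfiltfilt(sos, signal, axis=-1)
    from scipy.signal import sosfilt

    return sosfilt(sos, signal, axis=-1)


def select_steady_segment(
    force: np.ndarray,
    fs_hz: float,
    duration_s: float = 3.0,
    stride_ms: float = 100.0,
) -> int:
    """Start sample of the ``duration_s`` window with minimal force variance
    (sliding search, earliest window on ties)."""
    force = np.asarray(force, dtype=float)
    n_win = int(round(duration_s * fs_hz))
    if force.size < n_win:
        raise ValueError(f"force record shorter than {duration_s} s window")
    stride = max(1, int(round(stride_ms * fs_hz / 1000.0)))
    starts = np.arange(0, force.size - n_win + 1, stride)
    # cumulative sums make each window variance O(1)
    c1 = np.concatenate([[0.0], np.cumsum(force)])
    c2 = np.concatenate([[0.0], np.cumsum(force**2)])
    s1 = c1[starts + n_win] - c1[starts]
    s2 = c2[starts + n_win] - c2[starts]
    var = s2 / n_win - (s1 / n_win) ** 2
    return int(starts[int(np.argmin(np.round(var, 12)))])


def compute_map(
    rec: GridRecording,
    start_sample: int = 0,
    epoching: EpochingSpec = EpochingSpec(),
    filt: FilterSpec = FilterSpec(),
) -> ActivationMap:
    """Filter, epoch and average per-epoch RMS into an activation map."""
    filtered = bandpass_zero_phase(rec.samples, rec.fs_hz, filt)
    epochs = epoch_segments(filtered, rec.fs_hz, epoching, start_sample)
    intensity = np.sqrt((epochs**2).mean(axis=-1)).mean(axis=-1).reshape(rec.grid.shape)
    y_mm, x_mm = (np.arange(rec.grid.n_rows) * rec.grid.pitch_mm,
                  np.arange(rec.grid.n_cols) * rec.grid.pitch_mm)
    return ActivationMap(
        intensity,
        x_mm=x_mm,
        y_mm=y_mm,
        provenance={
            "fs_hz": rec.fs_hz,
            "start_sample": start_sample,
            "epoch_ms": epoching.epoch_ms,
            "n_epochs": epoching.n_epochs,
            "filter": (filt.low_hz, filt.high_hz, filt.order, filt.zero_phase),
            "interpolated": [],
        },
    )


def replace_artifact_values(amap: ActivationMap, mask: ArtifactMask | np.ndarray) -> ActivationMap:
    """Replace flagged map cells by triangle-based cubic interpolation.

    Cells outside the convex hull of the remaining electrodes fall back to
    the nearest valid neighbour.  Non-flagged cells are bit-unchanged; an
    empty mask returns an identical copy.
    """
    flags = mask.flags if isinstance(mask, ArtifactMask) else np.asarray(mask, dtype=bool)
    if flags.shape != amap.shape:
        raise ValueError("mask shape does not match map")
    out = amap.copy()
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        return out
    n_total = flags.size
    if n_flagged / n_total >= 0.5 or (n_total - n_flagged) < 3:
        raise InterpolationInfeasibleError(
            f"{n_flagged}/{n_total} channels flagged; surface interpolation not possible"
        )
    yy, xx = np.meshgrid(amap.y_mm, amap.x_mm, indexing="ij")
    good = ~flags
    pts = np.column_stack([xx[good], yy[good]])
    vals = amap.intensity[good]
    targets = np.column_stack([xx[flags], yy[flags]])
    est = griddata(pts, vals, targets, method="cubic")
    hull_misses = np.isnan(est)
    if hull_misses.any():
        est[hull_misses] = griddata(pts, vals, targets[hull_misses], method="nearest")
    out.intensity[flags] = np.maximum(est, 0.0)
    out.provenance = dict(out.provenance)
    out.provenance["interpolated"] = [tuple(map(int, rc)) for rc in zip(*np.nonzero(flags))]
    return out
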