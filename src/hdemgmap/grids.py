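"""Electrode-grid geometry and grid-bound multichannel recordings.

A high-density surface EMG (HD-EMG) array is a rectangular grid of
monopolar electrodes with a fixed inter-electrode pitch.  Rows run along
the proximal-distal (fiber, *y*) direction and columns along the
medial-lateral (*x*) direction.  Channels are stored row-major over
``(row, col)``: channel index ``row * n_cols + col``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ElectrodeGrid",
    "GridRecording",
    "ArtifactLabel",
    "GroundTruth",
    "ARTIFACT_KINDS",
]

#: Recognised artifact classes: low-frequency drift, power-line pickup and
#: isolated amplitude anomalies (a channel much weaker/stronger than its
#: neighbourhood).
ARTIFACT_KINDS = ("drift", "powerline", "isolated_amplitude")


@dataclass(frozen=True)
class ElectrodeGrid:
    """Geometry of a rectangular HD-EMG electrode array.

    Parameters
    ----------
    n_rows, n_cols:
        Array shape; rows are proximal-distal, columns medial-lateral.
    pitch_mm:
        Inter-electrode distance, identical in both directions.
    origin_row, origin_col:
        Grid coordinates of the anatomical reference electrode (the
        electrode placed over the recommended landmark); used as origin
        for limb-relative coordinate normalisation.
    circumference_mm, segment_length_mm:
        Limb-segment circumference (x-normalisation) and muscle/segment
        length (y-normalisation).
    """

    n_rows: int
    n_cols: int
    pitch_mm: float = 10.0
    origin_row: int = 0
    origin_col: int = 0
    circumference_mm: float = 250.0
    segment_length_mm: float = 250.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows * self.n_cols < 4:
            raise ValueError("grid must contain at least 4 electrodes")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")
        if not (0 <= self.origin_row < self.n_rows and 0 <= self.origin_col < self.n_cols):
            raise ValueError("origin electrode must lie inside the grid")
        if self.circumference_mm <= 0 or self.segment_length_mm <= 0:
            raise ValueError("circumference_mm and segment_length_mm must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def channel_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"electrode ({row}, {col}) outside {self.shape} grid")
        return row * self.n_cols + col

    def positions_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel (y_mm, x_mm) coordinate grids relative to electrode (0, 0)."""
        ii, jj = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        return ii * self.pitch_mm, jj * self.pitch_mm


@dataclass
class GridRecording:
    """Multichannel monopolar time series bound to an :class:`ElectrodeGrid`.

    ``samples`` has shape ``(n_channels, n_samples)`` in millivolt-equivalent
    units, channels ordered row-major over ``(row, col)``.
    """

    samples: np.ndarray
    fs_hz: float
    grid: ElectrodeGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x samples) array")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.shape[0] != self.grid.n_channels:
            raise ValueError(
                f"{self.samples.shape[0]} channels but grid declares {self.grid.n_channels}"
            )
        if self.samples.shape[1] < 0.5 * self.fs_hz:
            raise ValueError("recording must cover at least one 500 ms epoch")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, row: int, col: int) -> np.ndarray:
        return self.samples[self.grid.channel_index(row, col)]

    def copy(self) -> "GridRecording":
        return GridRecording(self.samples.copy(), self.fs_hz, self.grid, dict(self.meta))


@dataclass(frozen=True)
class ArtifactLabel:
    """One injected (or annotated) low-quality channel."""

    row: int
    col: int
    kind: str
    severity: float

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}; expected one of {ARTIFACT_KINDS}")


@dataclass
class GroundTruth:
    """Known generation parameters of a synthetic recording.

    ``artifacts`` lists injected bad channels; ``task``/``effort``/``subject``
    identify the simulated condition where applicable.
    """

    grid: ElectrodeGrid
    artifacts: list[ArtifactLabel] = field(default_factory=list)
    task: str | None = None
    effort_pct: float | None = None
    subject: int | None = None

    def mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) grid of artifact channels."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for a in self.artifacts:
            m[a.row, a.col] = True
        return m

    def with_artifact(self, label: ArtifactLabel) -> "GroundTruth":
        out = GroundTruth(self.grid, list(self.artifacts) + [label],
                          self.task, self.effort_pct, self.subject)
        return out
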