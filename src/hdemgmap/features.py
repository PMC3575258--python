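"""Per-channel detection features: P_l/t, P_line/t and RMS.

Three features discriminate low-quality channels: the fraction of signal
power below 12 Hz (movement artifact / baseline drift), the fraction of
power in narrow bands around the mains frequency and its harmonics
(capacitive pickup), and the plain RMS amplitude (contact problems).
All three are computed per 500 ms epoch from the FFT periodogram of the
raw monopolar signal and averaged over six consecutive epochs (3 s of
steady contraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridRecording

__all__ = [
    "EpochingSpec",
    "epoch_segments",
    "band_power_fraction",
    "channel_features",
    "ChannelFeatureTable",
    "line_bands",
]


@dataclass(frozen=True)
class EpochingSpec:
    """Non-overlapping epoch layout for feature estimation."""

    epoch_ms: float = 500.0
    n_epochs: int = 6

    def __post_init__(self) -> None:
        if self.epoch_ms <= 0 or self.n_epochs < 1:
            raise ValueError("epoch_ms and n_epochs must be positive")

    def epoch_samples(self, fs_hz: float) -> int:
        return int(round(self.epoch_ms * fs_hz / 1000.0))


@dataclass
class ChannelFeatureTable:
    """Per-channel feature grids (shape ``n_rows x n_cols``)."""

    p_lt: np.ndarray
    p_linet: np.ndarray
    rms: np.ndarray
    grid_shape: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.meshgrid(
            np.arange(self.grid_shape[0]), np.arange(self.grid_shape[1]), indexing="ij"
        )
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "p_lt": self.p_lt.ravel(),
                "p_linet": self.p_linet.ravel(),
                "rms": self.rms.ravel(),
            }
        )


def epoch_segments(
    signal: np.ndarray,
    fs_hz: float,
    spec: EpochingSpec = EpochingSpec(),
    start_sample: int = 0,
) -> np.ndarray:
    """Split ``signal`` into ``n_epochs`` contiguous non-overlapping epochs.

    Returns an array of shape ``(n_epochs, epoch_samples)``.  Raises
    ``ValueError`` when the signal is too short from ``start_sample`` on.
    """
    signal = np.asarray(signal, dtype=float)
    n_ep = spec.epoch_samples(fs_hz)
    needed = start_sample + spec.n_epochs * n_ep
    if start_sample < 0 or signal.shape[-1] < needed:
        raise ValueError(
            f"need {needed} samples for {spec.n_epochs} epochs of {n_ep}, have {signal.shape[-1]}"
        )
    seg = signal[..., start_sample:needed]
    return seg.reshape(*signal.shape[:-1], spec.n_epochs, n_ep)


def line_bands(mains_hz: float = 50.0, n_lines: int = 5, half_bw_hz: float = 2.0) -> list[tuple[float, float]]:
    """Narrow bands around the mains frequency and its first harmonics."""
    return [(k * mains_hz - half_bw_hz, k * mains_hz + half_bw_hz) for k in range(1, n_lines + 1)]


def _periodogram(epochs: np.ndarray, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared FFT of rectangular-windowed epochs; DC excluded."""
    n = epochs.shape[-1]
    psd = np.abs(np.fft.rfft(epochs, axis=-1)) ** 2
    psd[..., 0] = 0.0  # total power over (0, fs/2]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    return freqs, psd


def band_power_fraction(
    epoch: np.ndarray,
    fs_hz: float,
    bands: list[tuple[float, float]],
) -> float | np.ndarray:
    """Fraction of (0, fs/2] signal power inside ``bands``.

    A frequency bin counts when its centre lies in any band (inclusive
    bounds).  Zero-power epochs yield a fraction of 0 so that dead channels
    are handled by the amplitude rule rather than the spectral ones.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[-1] == 0:
        raise ValueError("empty epoch")
    for lo, hi in bands:
        if not (0 <= lo < hi <= fs_hz / 2):
            raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist)")
    freqs, psd = _periodogram(epoch, fs_hz)
    mask = np.zeros_like(freqs, dtype=bool)
    for lo, hi in bands:
        mask |= (freqs >= lo) & (freqs <= hi)
    total = psd.sum(axis=-1)
    inband = psd[..., mask].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, inband / np.where(total > 0, total, 1.0), 0.0)
    return float(frac) if frac.ndim == 0 else frac


def channel_features(
    rec: GridRecording,
    spec: EpochingSpec = EpochingSpec(),
    start_sample: int = 0,
    mains_hz: float = 50.0,
    n_lines: int = 5,
    half_bw_hz: float = 2.0,
    low_band_hz: float = 12.0,
) -> ChannelFeatureTable:
    """Mean-over-epochs (P_l/t, P_line/t, RMS) for every grid channel."""
    epochs = epoch_segments(rec.samples, rec.fs_hz, spec, start_sample)
    freqs, psd = _periodogram(epochs, rec.fs_hz)
    total = psd.sum(axis=-1)
    safe_total = np.where(total > 0, total, 1.0)

    low_mask = (freqs > 0) & (freqs <= low_band_hz)
    line_mask = np.zeros_like(freqs, dtype=bool)
    for lo, hi in line_bands(mains_hz, n_lines, half_bw_hz):
        line_mask |= (freqs >= lo) & (freqs <= hi)

    p_lt = np.where(total > 0, psd[..., low_mask].sum(axis=-1) / safe_total, 0.0).mean(axis=-1)
    p_linet = np.where(total > 0, psd[..., line_mask].sum(axis=-1) / safe_total, 0.0).mean(axis=-1)
    rms = np.sqrt((epochs**2).mean(axis=-1)).mean(axis=-1)

    shape = rec.grid.shape
    return ChannelFeatureTable(
        p_lt=p_lt.reshape(shape),
        p_linet=p_linet.reshape(shape),
        rms=rms.reshape(shape),
        grid_shape=shape,
    )
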