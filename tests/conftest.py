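import numpy as np
import pytest

from hdemgmap import (
    ActivationBlob,
    ElectrodeGrid,
    GridRecording,
    generate_recording,
)

FS = 2048.0


@pytest.fixture(scope="session")
def small_grid() -> ElectrodeGrid:
    return ElectrodeGrid(6, 17, origin_row=2, origin_col=8)


@pytest.fixture(scope="session")
def center_blob_recording(small_grid) -> GridRecording:
    """Single 1.0 mV blob at the grid centre over a 0.01 floor, 3 s."""
    blob = ActivationBlob(x=8.0, y=2.5, peak=1.0, sd_x=3.0, sd_y=2.5)
    return generate_recording(small_grid, [blob], duration_s=3.0, fs_hz=FS, seed=7)


def sine_recording(grid: ElectrodeGrid, freq_hz: float, amplitude: float = 1.0,
                   duration_s: float = 3.0, fs: float = FS) -> GridRecording:
    t = np.arange(int(duration_s * fs)) / fs
    wave = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return GridRecording(np.tile(wave, (grid.n_channels, 1)), fs, grid)
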