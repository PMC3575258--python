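"""Synthetic HD-EMG grid recordings with known ground truth.

Signal model
------------
Surface EMG electrodes a centimetre apart see largely the *same* motor-unit
activity through volume conduction, so neighbouring monopolar channels are
strongly correlated.  The generator therefore builds each recording from a
small number of *latent sources* -- zero-mean Gaussian noise band-limited to
the EMG band (15-350 Hz) -- mixed onto the grid through smooth spatial gain
profiles.  Channel ``i`` is::

    v_i(t) = sqrt(1-beta) * sum_b g_b(i) s_b(t)  +  sqrt(beta) * r_i o_i(t)

where ``g_b`` is the gain of source ``b`` at the electrode position,
``r_i = sqrt(sum_b g_b(i)^2)`` and ``o_i`` is a channel-private source with
the same spectrum.  ``beta`` controls along-fiber decorrelation: ``beta = 0``
is the fully volume-conducted limit, ``beta ~ 0.3`` reproduces the ~0.85
adjacent-channel correlation seen in real monopolar arrays and gives
non-degenerate single-differential (bipolar) signals.  The channel RMS is
``r_i`` for every ``beta``, so the target spatial profile is exact by
construction; independent sources add in quadrature.

Three artifact classes can be injected: low-frequency drift, power-line
pickup (50 Hz and four harmonics) and isolated amplitude anomalies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .grids import ARTIFACT_KINDS, ArtifactLabel, ElectrodeGrid, GridRecording, GroundTruth

__all__ = [
    "ActivationBlob",
    "band_limited_noise",
    "generate_from_gains",
    "generate_recording",
    "inject_artifact",
    "qc_benchmark_set",
    "TaskModel",
    "ConditionRecord",
    "simulate_task_dataset",
    "iter_task_dataset",
    "MUSCLES",
    "TASKS",
    "EFFORTS",
]

MUSCLES = ("biceps", "triceps", "brachioradialis", "anconeus", "pronator_teres")
TASKS = ("flexion", "extension", "pronation", "supination")
EFFORTS = (10, 30, 50)

#: Relative drive of each muscle per task (rows follow TASKS, cols MUSCLES);
#: qualitative co-activation pattern of elbow tasks: agonists near 1, main
#: synergist 0.7-0.8, antagonists low.
CO_ACTIVATION = {
    "flexion": (1.00, 0.10, 0.80, 0.15, 0.20),
    "extension": (0.10, 1.00, 0.15, 0.70, 0.10),
    "pronation": (0.10, 0.10, 0.15, 0.80, 1.00),
    "supination": (0.70, 0.10, 0.20, 1.00, 0.15),
}


@dataclass(frozen=True)
class ActivationBlob:
    """2-D Gaussian activation profile on the grid.

    ``x`` (column) and ``y`` (row) are grid coordinates in pitch units;
    ``peak`` is the RMS amplitude at the centre; ``sd_x``/``sd_y`` the
    spatial spread.  ``sd_y = inf`` gives a fiber-uniform stripe.
    """

    x: float
    y: float
    peak: float
    sd_x: float
    sd_y: float | None = None

    def __post_init__(self) -> None:
        if self.peak <= 0:
            raise ValueError("blob peak must be positive")
        if self.sd_x <= 0 or (self.sd_y is not None and self.sd_y <= 0):
            raise ValueError("blob spatial sd must be positive")

    def gain(self, grid: ElectrodeGrid) -> np.ndarray:
        ii, jj = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
        sdy = self.sd_x if self.sd_y is None else self.sd_y
        g = (jj - self.x) ** 2 / (2.0 * self.sd_x**2)
        if np.isfinite(sdy):
            g = g + (ii - self.y) ** 2 / (2.0 * sdy**2)
        return self.peak * np.exp(-g)


def band_limited_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs_hz: float,
    band: tuple[float, float] = (15.0, 350.0),
    order: int = 4,
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited by a zero-phase Butterworth filter."""
    sos = butter(order, band, btype="bandpass", fs=fs_hz, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def generate_from_gains(
    grid: ElectrodeGrid,
    gains: list[np.ndarray],
    duration_s: float = 3.0,
    fs_hz: float = 2048.0,
    seed: int | np.random.Generator = 0,
    beta: float = 0.0,
    band: tuple[float, float] = (15.0, 350.0),
) -> GridRecording:
    """Latent-source recording from explicit per-source gain maps."""
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration_s and fs_hz must be positive")
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0, 1)")
    if not gains:
        raise ValueError("at least one gain map required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    G = np.stack([np.asarray(g, dtype=float).reshape(grid.n_channels) for g in gains])
    sources = band_limited_noise(rng, (len(gains), n), fs_hz, band)
    shared = G.T @ sources
    if beta > 0.0:
        r = np.sqrt((G**2).sum(axis=0))[:, None]
        own = band_limited_noise(rng, (grid.n_channels, n), fs_hz, band)
        samples = math.sqrt(1.0 - beta) * shared + math.sqrt(beta) * r * own
    else:
        samples = shared
    return GridRecording(samples, fs_hz, grid)


def generate_recording(
    grid: ElectrodeGrid,
    activation: list[ActivationBlob],
    duration_s: float = 3.0,
    fs_hz: float = 2048.0,
    seed: int | np.random.Generator = 0,
    floor: float = 0.01,
    beta: float = 0.0,
    band: tuple[float, float] = (15.0, 350.0),
) -> GridRecording:
    """Grid recording whose channel RMS follows the blob profiles.

    The baseline ``floor`` is a spatially uniform far-field source (distant
    muscle activity); each blob is one latent source.  With an empty blob
    list all channels sit at the floor level.  Identical ``(grid, seed)``
    produce bit-identical output.
    """
    gains = [b.gain(grid) for b in activation]
    gains.append(np.full(grid.shape, float(floor)))
    return generate_from_gains(grid, gains, duration_s, fs_hz, seed, beta, band)


# ---------------------------------------------------------------------------
# artifact injection

_LINE_WEIGHTS = np.array([1.0, 0.5, 0.3, 0.2, 0.15])
_LINE_WEIGHTS = _LINE_WEIGHTS / np.sqrt((_LINE_WEIGHTS**2).sum())


def inject_artifact(
    rec: GridRecording,
    row: int,
    col: int,
    kind: str,
    severity: float,
    seed: int | np.random.Generator = 0,
    truth: GroundTruth | None = None,
    mains_hz: float = 50.0,
) -> tuple[GridRecording, GroundTruth]:
    """Corrupt one channel in place of a copy and record it in the truth.

    ``severity`` is the RMS of the added component relative to the channel's
    clean RMS for ``drift`` and ``powerline``, and the multiplicative scale
    factor for ``isolated_amplitude`` (e.g. 0.05 for a near-dead contact,
    20 for a saturating one).
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected one of {ARTIFACT_KINDS}")
    if severity <= 0:
        raise ValueError("severity must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rec.copy()
    ch = rec.grid.channel_index(row, col)
    s = out.samples[ch]
    r = float(np.sqrt((s**2).mean()))
    t = np.arange(rec.n_samples) / rec.fs_hz
    if kind == "drift":
        f0 = rng.uniform(1.0, 4.0)
        s += severity * r * math.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    elif kind == "powerline":
        for harmonic, w in zip(mains_hz * np.arange(1, 6), _LINE_WEIGHTS):
            s += (severity * r * math.sqrt(2.0) * w
                  * np.sin(2 * np.pi * harmonic * t + rng.uniform(0, 2 * np.pi)))
    else:  # isolated_amplitude
        out.samples[ch] = severity * s
    truth = truth if truth is not None else GroundTruth(rec.grid)
    return out, truth.with_artifact(ArtifactLabel(row, col, kind, severity))


# ---------------------------------------------------------------------------
# QC benchmark sets (detector study conditions)

_PAIR_OFFSETS = [(-1, 0), (1, 0), (-1, -1), (1, 1), (1, -1), (-1, 1)]


def _mirror(idx: int, n: int) -> int:
    if idx < 0:
        return -idx
    if idx >= n:
        return 2 * n - 2 - idx
    return idx


def _qc_gain_maps(grid: ElectrodeGrid, amplitude: float, centre_x: float,
                  floor: float, iz_curvature: float) -> list[np.ndarray]:
    """Single broad activation hump, concave across the full column range,
    with a gentle innervation-zone-style concave modulation along rows on
    interior columns (flat on the two outermost columns each side, whose
    mirror-degenerate neighbour pairs rely on exact within-column ties)."""
    ii, jj = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    mid = (grid.n_rows - 1) / 2.0
    yprof = 1.0 + iz_curvature * (mid**2 - (ii - mid) ** 2)
    yprof[:, [0, 1, grid.n_cols - 2, grid.n_cols - 1]] = 1.0
    sd_x = 0.6 * grid.n_cols  # concave over the whole grid width
    hump = amplitude * np.exp(-((jj - centre_x) ** 2) / (2 * sd_x**2)) * yprof
    return [hump, np.full(grid.shape, floor * amplitude)]


def qc_benchmark_set(
    seed: int,
    grid: ElectrodeGrid | None = None,
    duration_s: float = 3.0,
    fs_hz: float = 2048.0,
    max_prevalence: float = 0.13,
    floor: float = 0.01,
    iz_curvature: float = 6e-4,
) -> tuple[GridRecording, GroundTruth]:
    """One labelled signal set for detector training/validation.

    Emulates a forearm-array recording during an isometric contraction with
    a random number of artifacts (prevalence 0 .. ``max_prevalence``) of the
    three classes.  High-RMS artifacts (drift, power-line) are kept away
    from the rows adjacent to the array borders and no channel ever has
    three corrupted neighbours, so every clean channel retains a clean
    neighbour pair for the amplitude rule; severities put each artifact
    clearly past the default spectral thresholds while inflating channel
    RMS by less than ~30%.
    """
    grid = grid or ElectrodeGrid(6, 17, origin_row=2, origin_col=8)
    rng = np.random.default_rng(seed)
    amplitude = rng.uniform(0.5, 1.5)
    centre_x = (grid.n_cols - 1) / 2.0 + rng.uniform(-0.5, 0.5)
    gains = _qc_gain_maps(grid, amplitude, centre_x, floor, iz_curvature)
    rec = generate_from_gains(grid, gains, duration_s, fs_hz, rng, beta=0.0)
    truth = GroundTruth(grid)

    n_art = int(rng.integers(0, int(max_prevalence * grid.n_channels) + 1))
    flagged = np.zeros(grid.shape, dtype=bool)
    ok_rows = {0, grid.n_rows - 1} | set(range(2, grid.n_rows - 2))
    lo_col, hi_col = 4, grid.n_cols - 5

    def admissible(r_: int, c_: int) -> bool:
        if r_ not in ok_rows or not (lo_col <= c_ <= hi_col) or flagged[r_, c_]:
            return False
        # adding (r_, c_) must leave every channel with < 3 flagged neighbours
        trial = flagged.copy()
        trial[r_, c_] = True
        for vr in range(grid.n_rows):
            for vc in range(grid.n_cols):
                cnt = sum(
                    trial[_mirror(vr + dr, grid.n_rows), _mirror(vc + dc, grid.n_cols)]
                    for dr, dc in _PAIR_OFFSETS
                )
                if cnt >= 3:
                    return False
        return True

    order = rng.permutation(grid.n_channels)
    for kind in rng.choice(["drift", "powerline", "isolated_amplitude"], size=n_art):
        site = next(((ch // grid.n_cols, ch % grid.n_cols) for ch in order
                     if admissible(ch // grid.n_cols, ch % grid.n_cols)), None)
        if site is None:
            break
        r_, c_ = site
        flagged[r_, c_] = True
        if kind == "drift":
            sev = rng.uniform(0.5, 0.8)
        elif kind == "powerline":
            sev = rng.uniform(0.65, 0.85)
        else:
            sev = 0.05
        rec, truth = inject_artifact(rec, r_, c_, str(kind), sev, rng, truth)
    return rec, truth


# ---------------------------------------------------------------------------
# task / effort / subject simulation

@dataclass(frozen=True)
class TaskModel:
    """Study-design parameters of the simulated task dataset.

    Effort scales source amplitude linearly with %MVC; subjects carry
    multiplicative log-normal gains per muscle (``subject_sd`` is the sd of
    log gain, targeting inter-subject map variability in the 10-30% range);
    ``placement_sd`` jitters each subject's array laterally (pitch units),
    emulating electrode-positioning error between subjects;
    ``effort_shift`` moves the activation centre laterally per effort step
    (pitch units), used to probe spatial-shift recovery.
    """

    muscles: tuple[str, ...] = MUSCLES
    tasks: tuple[str, ...] = TASKS
    efforts: tuple[int, ...] = EFFORTS
    co_activation: dict = field(default_factory=lambda: dict(CO_ACTIVATION))
    subject_sd: float = 0.25
    placement_sd: float = 1.25
    effort_shift: float = 0.0
    beta: float = 0.3
    floor: float = 0.01
    duration_s: float = 3.0
    fs_hz: float = 2048.0


@dataclass
class ConditionRecord:
    """All muscle-array recordings of one (subject, task, effort) trial."""

    subject: int
    task: str
    effort_pct: int
    recordings: dict[str, GridRecording]
    truths: dict[str, GroundTruth]


def _muscle_grid(muscle: str) -> ElectrodeGrid:
    # upper-arm arrays 8x15, forearm arrays 6x17 (10 mm pitch)
    if muscle in ("biceps", "triceps"):
        return ElectrodeGrid(8, 15, origin_row=3, origin_col=7,
                             circumference_mm=280.0, segment_length_mm=300.0)
    return ElectrodeGrid(6, 17, origin_row=2, origin_col=8,
                         circumference_mm=250.0, segment_length_mm=230.0)


def iter_task_dataset(
    n_subjects: int,
    tasks: tuple[str, ...] = TASKS,
    efforts: tuple[int, ...] = EFFORTS,
    model: TaskModel | None = None,
    seed: int = 0,
):
    """Yield ``n_subjects x len(tasks) x len(efforts)`` condition records.

    Per muscle array the activation is a blob whose amplitude is the
    task's co-activation weight times a linear effort gain times the
    subject's log-normal muscle gain; the blob centre carries the subject's
    placement error and an optional per-effort lateral shift.  Streaming
    generation keeps only one condition's recordings in memory.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not tasks or not efforts:
        raise ValueError("tasks and efforts must be non-empty")
    model = model or TaskModel(tasks=tuple(tasks), efforts=tuple(efforts))
    for t in tasks:
        if t not in model.co_activation:
            raise ValueError(f"no co-activation weights for task {t!r}")
    root = np.random.SeedSequence(seed)
    for subj, subj_seq in enumerate(root.spawn(n_subjects)):
        srng = np.random.default_rng(subj_seq)
        gains_subj = np.exp(srng.normal(0.0, model.subject_sd, size=len(model.muscles)))
        placement = srng.normal(0.0, model.placement_sd, size=len(model.muscles))
        for task in tasks:
            weights = model.co_activation[task]
            for k_eff, eff in enumerate(efforts):
                recs: dict[str, GridRecording] = {}
                truths: dict[str, GroundTruth] = {}
                for m, muscle in enumerate(model.muscles):
                    grid = _muscle_grid(muscle)
                    amp = weights[m] * (eff / max(efforts)) * gains_subj[m]
                    centre = ((grid.n_cols - 1) / 2.0 + placement[m]
                              + model.effort_shift * k_eff)
                    blob = ActivationBlob(
                        x=centre, y=(grid.n_rows - 1) / 2.0, peak=amp,
                        sd_x=2.5, sd_y=0.8 * grid.n_rows,
                    )
                    gmaps = [blob.gain(grid), np.full(grid.shape, model.floor * amp)]
                    recs[muscle] = generate_from_gains(
                        grid, gmaps, model.duration_s, model.fs_hz, srng, beta=model.beta
                    )
                    truths[muscle] = GroundTruth(grid, task=task, effort_pct=eff, subject=subj)
                yield ConditionRecord(subj, task, eff, recs, truths)


def simulate_task_dataset(
    n_subjects: int,
    tasks: tuple[str, ...] = TASKS,
    efforts: tuple[int, ...] = EFFORTS,
    model: TaskModel | None = None,
    seed: int = 0,
) -> list[ConditionRecord]:
    """Materialised form of :func:`iter_task_dataset` (memory grows with
    the design size; prefer the iterator for 12-subject studies)."""
    return list(iter_task_dataset(n_subjects, tasks, efforts, model, seed))
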