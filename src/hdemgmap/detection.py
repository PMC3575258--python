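"""Threshold expert system for low-quality channel detection.

Channels are flagged by three OR-combined rules derived from a robust
*reference* subset of the array:

* low-frequency rule -- ``P_l/t`` above ``k1 * median + 1.5 IQR`` of the
  reference channels;
* power-line rule -- ``P_line/t`` above ``k_line * median + 1.5 IQR``,
  capped at 0.85 (a channel with >85% of its power in mains bands is an
  artifact regardless of the reference statistics);
* amplitude rule -- RMS below a neighbourhood threshold built from three
  electrode pairs straddling the channel: the longitudinal pair
  ``[RMS(i-1,j), RMS(i+1,j)]`` and the two diagonal pairs, combined as
  ``min(pair means) + k2 * max(pair stds)``.  The pair structure follows
  the spatial propagation of motor-unit potentials: a genuinely inactive
  region (innervation zone, inactive muscle) offers at least one direction
  of low, consistent neighbours, while an isolated bad contact is below
  all of them.

Also provided: detection scoring (confusion counts and S/SP/P/Acc),
operating-point tuning of ``(k1, k2)`` on labelled sets by ROC or
precision-recall distance, and expert-label utilities (majority vote,
Fleiss' kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ChannelFeatureTable

__all__ = [
    "DetectorConfig",
    "ReferenceSet",
    "Thresholds",
    "ArtifactMask",
    "DetectionPerformance",
    "NoReferenceError",
    "UndefinedNeighborhoodError",
    "TuningFailedError",
    "select_reference",
    "compute_global_thresholds",
    "neighbor_rms_threshold",
    "neighbor_rms_threshold_grid",
    "classify_channels",
    "evaluate_detection",
    "tune_constants",
    "majority_vote",
    "fleiss_kappa",
]


class NoReferenceError(ValueError):
    """No channel qualifies for the reference subset."""


class UndefinedNeighborhoodError(ValueError):
    """The grid is too small to form neighbour pairs."""


class TuningFailedError(RuntimeError):
    """No tuning grid point yields defined performance indexes."""


@dataclass(frozen=True)
class DetectorConfig:
    """Constants of the expert system (defaults: precision-recall optimum
    of the original tuning, k_line from its sensitivity analysis)."""

    k1: float = 11.2
    k2: float = 0.2
    k_line: float = 2.5
    line_cap: float = 0.85
    iqr_mult: float = 1.5
    rms_rule_direction: str = "below"  # below | above | both
    k_scales_whole_expression: bool = False

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k_line, self.iqr_mult) <= 0:
            raise ValueError("detector constants must be positive")
        if not (0 < self.line_cap <= 1):
            raise ValueError("line_cap must be in (0, 1]")
        if self.rms_rule_direction not in ("below", "above", "both"):
            raise ValueError("rms_rule_direction must be below/above/both")


@dataclass
class ReferenceSet:
    """Channels whose spectral features sit in the bulk of the array."""

    member_mask: np.ndarray  # boolean grid
    median_p_lt: float
    iqr_p_lt: float
    median_p_linet: float
    iqr_p_linet: float

    @property
    def n_members(self) -> int:
        return int(self.member_mask.sum())


@dataclass
class Thresholds:
    thresh_lt: float
    thresh_linet: float
    thresh_rms: np.ndarray  # per-channel grid


@dataclass
class ArtifactMask:
    """Flagged channels plus the rule(s) that triggered each flag."""

    flags: np.ndarray  # boolean grid
    rules: dict = field(default_factory=dict)  # (row, col) -> tuple of rule names
    thresholds: Thresholds | None = None

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


@dataclass
class DetectionPerformance:
    tp: int
    fp: int
    tn: int
    fn: int

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)


def _iqr(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def select_reference(features: ChannelFeatureTable, iqr_mult: float = 1.5) -> ReferenceSet:
    """Channels within ``iqr_mult * IQR`` of the set median on both spectral
    features.  A zero IQR degrades the comparison to equality with the
    median, so a perfectly homogeneous array keeps all channels."""
    p_lt, p_linet = features.p_lt.ravel(), features.p_linet.ravel()
    if p_lt.size < 4:
        raise ValueError("need at least 4 channels")

    def within(v: np.ndarray) -> np.ndarray:
        med, iqr = np.median(v), _iqr(v)
        return np.abs(v - med) < iqr_mult * iqr if iqr > 0 else v == med

    member = within(p_lt) & within(p_linet)
    if not member.any():
        raise NoReferenceError("reference subset is empty")
    mask = member.reshape(features.grid_shape)
    return ReferenceSet(
        member_mask=mask,
        median_p_lt=float(np.median(p_lt[member])),
        iqr_p_lt=_iqr(p_lt[member]),
        median_p_linet=float(np.median(p_linet[member])),
        iqr_p_linet=_iqr(p_linet[member]),
    )


def compute_global_thresholds(ref: ReferenceSet, cfg: DetectorConfig) -> tuple[float, float]:
    """Spectral thresholds from the reference statistics (line threshold
    capped at ``cfg.line_cap``)."""
    if ref.n_members == 0:
        raise NoReferenceError("reference subset is empty")
    if cfg.k_scales_whole_expression:
        t_lt = cfg.k1 * (ref.median_p_lt + cfg.iqr_mult * ref.iqr_p_lt)
        t_line = cfg.k_line * (ref.median_p_linet + cfg.iqr_mult * ref.iqr_p_linet)
    else:
        t_lt = cfg.k1 * ref.median_p_lt + cfg.iqr_mult * ref.iqr_p_lt
        t_line = cfg.k_line * ref.median_p_linet + cfg.iqr_mult * ref.iqr_p_linet
    return t_lt, min(cfg.line_cap, t_line)


def _mirror_pad(rms: np.ndarray) -> np.ndarray:
    return np.pad(rms, 1, mode="reflect")


def neighbor_rms_threshold_grid(rms: np.ndarray, k2: float) -> np.ndarray:
    """Amplitude threshold for every channel (vectorised form).

    Neighbour pairs are taken from the mirror-padded RMS grid; each pair's
    std is the sample standard deviation (n-1), i.e. ``|a - b| / sqrt(2)``.
    """
    rms = np.asarray(rms, dtype=float)
    if rms.ndim != 2 or min(rms.shape) < 2:
        raise UndefinedNeighborhoodError("need at least a 2 x 2 grid for neighbour pairs")
    p = _mirror_pad(rms)
    R, C = rms.shape

    def at(di: int, dj: int) -> np.ndarray:
        return p[1 + di : 1 + di + R, 1 + dj : 1 + dj + C]

    pairs = [(at(-1, 0), at(1, 0)), (at(-1, -1), at(1, 1)), (at(1, -1), at(-1, 1))]
    means = np.stack([(a + b) / 2.0 for a, b in pairs])
    stds = np.stack([np.abs(a - b) / math.sqrt(2.0) for a, b in pairs])
    return means.min(axis=0) + k2 * stds.max(axis=0)


def neighbor_rms_threshold(features: ChannelFeatureTable, row: int, col: int, k2: float) -> float:
    """Amplitude threshold of one channel (scalar convenience wrapper)."""
    grid = neighbor_rms_threshold_grid(features.rms, k2)
    if not (0 <= row < grid.shape[0] and 0 <= col < grid.shape[1]):
        raise ValueError(f"channel ({row}, {col}) outside grid {grid.shape}")
    return float(grid[row, col])


def classify_channels(features: ChannelFeatureTable, cfg: DetectorConfig = DetectorConfig()) -> ArtifactMask:
    """One-shot decision cascade: thresholds are frozen from the reference
    subset, then every channel is tested against all three rules."""
    ref = select_reference(features, cfg.iqr_mult)
    t_lt, t_line = compute_global_thresholds(ref, cfg)
    t_rms = neighbor_rms_threshold_grid(features.rms, cfg.k2)

    low = features.p_lt > t_lt
    line = features.p_linet > t_line
    if cfg.rms_rule_direction == "below":
        amp = features.rms < t_rms
    elif cfg.rms_rule_direction == "above":
        amp = features.rms > _upper_rms_threshold(features.rms, t_rms)
    else:
        amp = (features.rms < t_rms) | (features.rms > _upper_rms_threshold(features.rms, t_rms))

    flags = low | line | amp
    rules: dict = {}
    for r, c in zip(*np.nonzero(flags)):
        hit = []
        if low[r, c]:
            hit.append("lowfreq")
        if line[r, c]:
            hit.append("line")
        if amp[r, c]:
            hit.append("rms")
        rules[(int(r), int(c))] = tuple(hit)
    return ArtifactMask(flags=flags, rules=rules, thresholds=Thresholds(t_lt, t_line, t_rms))


def _upper_rms_threshold(rms: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """Lower bound reflected about the six-neighbour mean, for channels with
    much *higher* energy than their surroundings."""
    p = _mirror_pad(np.asarray(rms, dtype=float))
    R, C = rms.shape
    acc = np.zeros_like(rms, dtype=float)
    for di, dj in [(-1, 0), (1, 0), (-1, -1), (1, 1), (1, -1), (-1, 1)]:
        acc += p[1 + di : 1 + di + R, 1 + dj : 1 + dj + C]
    mean6 = acc / 6.0
    return 2.0 * mean6 - lower


def evaluate_detection(mask: ArtifactMask | np.ndarray, truth: np.ndarray) -> DetectionPerformance:
    """Exact confusion counts of a mask against ground-truth labels."""
    flags = mask.flags if isinstance(mask, ArtifactMask) else np.asarray(mask, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if flags.shape != truth.shape:
        raise ValueError(f"shape mismatch: mask {flags.shape} vs truth {truth.shape}")
    tp = int((flags & truth).sum())
    fp = int((flags & ~truth).sum())
    tn = int((~flags & ~truth).sum())
    fn = int((~flags & truth).sum())
    return DetectionPerformance(tp, fp, tn, fn)


DEFAULT_K1_GRID = (4.0, 7.1, 11.2, 16.0, 22.0)
DEFAULT_K2_GRID = (0.001, 0.002, 0.005, 0.01, 0.05, 0.2)


def tune_constants(
    labeled_sets: list[tuple[ChannelFeatureTable, np.ndarray]],
    k1_grid: tuple[float, ...] = DEFAULT_K1_GRID,
    k2_grid: tuple[float, ...] = DEFAULT_K2_GRID,
    criterion: str = "pr",
    base_config: DetectorConfig = DetectorConfig(),
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Select ``(k1, k2)`` on labelled sets by operating-point distance.

    ``criterion='roc'`` minimises the distance of ``(1-SP, S)`` to the ideal
    point ``(0, 1)``; ``criterion='pr'`` minimises the distance of
    ``(SP, P)`` to ``(1, 1)``.  Confusion counts are pooled over sets.
    Ties break by higher accuracy, then smaller k1, then smaller k2.
    Returns the optimum and the full performance curve.
    """
    if criterion not in ("roc", "pr"):
        raise ValueError("criterion must be 'roc' or 'pr'")
    if not k1_grid or not k2_grid:
        raise ValueError("empty tuning grid")
    if not labeled_sets:
        raise ValueError("no labelled sets")
    if not any(np.asarray(t, dtype=bool).any() for _, t in labeled_sets):
        raise ValueError("no positive labels in any set")

    rows = []
    for k1 in k1_grid:
        for k2 in k2_grid:
            cfg = DetectorConfig(
                k1=k1, k2=k2, k_line=base_config.k_line, line_cap=base_config.line_cap,
                iqr_mult=base_config.iqr_mult,
                rms_rule_direction=base_config.rms_rule_direction,
                k_scales_whole_expression=base_config.k_scales_whole_expression,
            )
            tp = fp = tn = fn = 0
            for feats, truth in labeled_sets:
                perf = evaluate_detection(classify_channels(feats, cfg), truth)
                tp, fp, tn, fn = tp + perf.tp, fp + perf.fp, tn + perf.tn, fn + perf.fn
            perf = DetectionPerformance(tp, fp, tn, fn)
            s, sp, p, acc = perf.sensitivity, perf.specificity, perf.precision, perf.accuracy
            if criterion == "roc":
                dist = math.hypot(1.0 - sp, 1.0 - s) if not (math.isnan(s) or math.isnan(sp)) else math.inf
            else:
                dist = math.hypot(1.0 - sp, 1.0 - p) if not (math.isnan(p) or math.isnan(sp)) else math.inf
            rows.append({"k1": k1, "k2": k2, "S": s, "SP": sp, "P": p, "Acc": acc,
                         "distance": dist})
    curve = pd.DataFrame(rows)
    if not np.isfinite(curve["distance"]).any():
        raise TuningFailedError("all grid points have undefined performance indexes")
    best = curve.sort_values(
        by=["distance", "Acc", "k1", "k2"], ascending=[True, False, True, True]
    ).iloc[0]
    return (float(best["k1"]), float(best["k2"])), curve


# ---------------------------------------------------------------------------
# expert-label utilities

def majority_vote(labels: np.ndarray) -> np.ndarray:
    """Per-item mode of binary rater labels (odd number of raters >= 3)."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 2:
        raise ValueError("labels must be raters x items")
    n_raters = labels.shape[0]
    if n_raters < 3 or n_raters % 2 == 0:
        raise ValueError("majority vote requires an odd number of raters >= 3")
    return (labels.sum(axis=0) * 2 > n_raters).astype(int)


def fleiss_kappa(labels: np.ndarray) -> float:
    """Fleiss' kappa of a raters x items binary label matrix.

    1 for perfect agreement, ~0 for independent random raters; NaN when all
    raters use a single category on every item (no chance variance).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 2 or labels.shape[0] < 2 or labels.shape[1] < 2:
        raise ValueError("need >= 2 raters and >= 2 items")
    if len(np.unique(labels)) < 2:
        return math.nan
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

    table, _ = aggregate_raters(labels.T)
    return float(_sm_fleiss(table))
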