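"""File formats and configuration.

Native signal format: a delimited text (or flat little-endian float32)
channel x sample matrix plus a JSON sidecar describing grid geometry,
sampling rate and units.  Maps and QC reports are TSV, feature tables and
labels CSV, statistics and configuration JSON.  EDF import is optional and
goes through :mod:`mne` when available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import ArtifactMask, DetectorConfig
from .features import ChannelFeatureTable, EpochingSpec
from .grids import ArtifactLabel, ElectrodeGrid, GridRecording, GroundTruth
from .mapping import ActivationMap, FilterSpec
from .segmentation import SegmentationConfig, SegmentedMap

__all__ = [
    "PipelineConfig",
    "write_recording",
    "read_recording",
    "read_recording_edf",
    "write_truth",
    "read_truth",
    "write_qc_report",
    "write_map",
    "read_map",
    "write_segmented",
    "render_map_png",
]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Serialisable bundle of every stage's parameters."""

    epoching: EpochingSpec = EpochingSpec()
    filter: FilterSpec = FilterSpec()
    detector: DetectorConfig = DetectorConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    oversample: int = 2
    mains_hz: float = 50.0
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "epoching": dataclasses.asdict(self.epoching),
            "filter": dataclasses.asdict(self.filter),
            "detector": dataclasses.asdict(self.detector),
            "segmentation": dataclasses.asdict(self.segmentation),
            "oversample": self.oversample,
            "mains_hz": self.mains_hz,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        src = str(source)
        text = Path(src).read_text() if ("{" not in src and Path(src).exists()) else src
        payload = json.loads(text)
        return cls(
            epoching=EpochingSpec(**payload["epoching"]),
            filter=FilterSpec(**payload["filter"]),
            detector=DetectorConfig(**payload["detector"]),
            segmentation=SegmentationConfig(**payload["segmentation"]),
            oversample=int(payload.get("oversample", 2)),
            mains_hz=float(payload.get("mains_hz", 50.0)),
            seed=int(payload.get("seed", 0)),
        )


def _sidecar(rec: GridRecording, fmt: str) -> dict:
    g = rec.grid
    return {
        "format": fmt,
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "pitch_mm": g.pitch_mm,
        "origin_row": g.origin_row,
        "origin_col": g.origin_col,
        "circumference_mm": g.circumference_mm,
        "segment_length_mm": g.segment_length_mm,
        "fs_hz": rec.fs_hz,
        "n_samples": rec.n_samples,
        "units": rec.meta.get("units", "mV"),
        "channel_order": "row_major",
    }


def write_recording(rec: GridRecording, path: str | Path, fmt: str = "tsv") -> Path:
    """Write samples plus JSON sidecar ``<path>.json``; returns the sidecar path."""
    path = Path(path)
    if fmt == "tsv":
        np.savetxt(path, rec.samples, delimiter="\t")
    elif fmt == "f32":
        rec.samples.astype("<f4").tofile(path)
    else:
        raise ValueError("fmt must be 'tsv' or 'f32'")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(_sidecar(rec, fmt), indent=2))
    return sidecar


def _grid_from_sidecar(meta: dict) -> ElectrodeGrid:
    return ElectrodeGrid(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        pitch_mm=float(meta.get("pitch_mm", 10.0)),
        origin_row=int(meta.get("origin_row", 0)),
        origin_col=int(meta.get("origin_col", 0)),
        circumference_mm=float(meta.get("circumference_mm", 250.0)),
        segment_length_mm=float(meta.get("segment_length_mm", 250.0)),
    )


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> GridRecording:
    """Read a matrix + sidecar recording, validating dimensions."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    grid = _grid_from_sidecar(meta)
    fmt = meta.get("format", "tsv")
    if fmt == "tsv":
        samples = np.loadtxt(path, delimiter="\t", ndmin=2)
    elif fmt == "f32":
        flat = np.fromfile(path, dtype="<f4").astype(float)
        n_samples = int(meta["n_samples"])
        if flat.size != grid.n_channels * n_samples:
            raise ValueError(
                f"file holds {flat.size} values, sidecar declares "
                f"{grid.n_channels} channels x {n_samples} samples"
            )
        samples = flat.reshape(grid.n_channels, n_samples)
    else:
        raise ValueError(f"unknown format {fmt!r} in sidecar")
    if samples.shape[0] != grid.n_channels:
        raise ValueError(
            f"file has {samples.shape[0]} channels, sidecar declares {grid.n_channels}"
        )
    return GridRecording(samples, float(meta["fs_hz"]), grid, {"units": meta.get("units", "mV")})


def read_recording_edf(path: str | Path, sidecar: str | Path) -> GridRecording:
    """Import an EDF file; the sidecar supplies grid geometry and the
    ``channel_map`` list of EDF channel names in row-major grid order."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    meta = json.loads(Path(sidecar).read_text())
    grid = _grid_from_sidecar(meta)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = meta.get("channel_map", raw.ch_names[: grid.n_channels])
    if len(names) != grid.n_channels:
        raise ValueError("channel_map length does not match grid size")
    data = np.stack([raw.get_data(picks=[nm])[0] for nm in names])
    return GridRecording(data, float(raw.info["sfreq"]), grid, {"units": "V"})


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    pd.DataFrame(
        [{"row": a.row, "col": a.col, "kind": a.kind, "severity": a.severity}
         for a in truth.artifacts],
        columns=["row", "col", "kind", "severity"],
    ).to_csv(path, index=False)


def read_truth(path: str | Path, grid: ElectrodeGrid) -> GroundTruth:
    df = pd.read_csv(path)
    labels = [ArtifactLabel(int(r.row), int(r.col), str(r.kind), float(r.severity))
              for r in df.itertuples()]
    return GroundTruth(grid, labels)


def write_qc_report(features: ChannelFeatureTable, mask: ArtifactMask, path: str | Path) -> None:
    df = features.to_frame()
    df["flagged"] = mask.flags.ravel().astype(int)
    df["rules"] = [
        "+".join(mask.rules.get((int(r), int(c)), ())) for r, c in zip(df["row"], df["col"])
    ]
    df.to_csv(path, sep="\t", index=False)


def write_map(amap: ActivationMap, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, amap.intensity, delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "x_mm": list(map(float, amap.x_mm)),
        "y_mm": list(map(float, amap.y_mm)),
        "provenance": _jsonable(amap.provenance),
    }, indent=2))
    return sidecar


def read_map(path: str | Path) -> ActivationMap:
    path = Path(path)
    intensity = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    x = np.asarray(meta.get("x_mm", np.arange(intensity.shape[1]) * 10.0), dtype=float)
    y = np.asarray(meta.get("y_mm", np.arange(intensity.shape[0]) * 10.0), dtype=float)
    return ActivationMap(intensity, x, y, meta.get("provenance", {}))


def write_segmented(seg: SegmentedMap, stem: str | Path) -> None:
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".dome.tsv"), seg.dome, delimiter="\t")
    np.savetxt(stem.with_suffix(".labels.tsv"), seg.labels, fmt="%d", delimiter="\t")
    stem.with_suffix(".regions.json").write_text(json.dumps({
        "selected": seg.selected,
        "regions": _jsonable(seg.region_table),
    }, indent=2))


def render_map_png(amap: ActivationMap, path: str | Path, db_floor: float = -20.0) -> None:
    """Optional display rendering in dB relative to the map maximum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    peak = amap.intensity.max()
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(np.where(amap.intensity > 0, amap.intensity / peak, np.nan))
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(db, origin="upper", aspect="equal", vmin=db_floor, vmax=0.0,
                   extent=(amap.x_mm[0], amap.x_mm[-1], amap.y_mm[-1], amap.y_mm[0]))
    fig.colorbar(im, ax=ax, label="dB re max")
    ax.set_xlabel("x (mm, medial-lateral)")
    ax.set_ylabel("y (mm, proximal-distal)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
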