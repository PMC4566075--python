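"""Readers and writers for the on-disk formats of the pipeline.

Movies are multi-frame TIFF (one page per frame, 16-bit unsigned); the
current trace is a two-column CSV (``time_s,current_pA``); ground truth is
JSON; tables (events, waves, participation, intervals) are CSV with '.'
decimals and times in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import (
    EphysTrace,
    GroundTruth,
    MovieStack,
    ParticipationSummary,
    RoiMap,
    TransientEvent,
    WaveEpoch,
)

EVENT_COLUMNS = ["roi_id", "onset_s", "peak_s", "offset_s", "peak_dff", "duration_s"]
WAVE_COLUMNS = ["onset_s", "offset_s", "peak_current_pA", "charge_pC"]


def save_movie(movie: MovieStack, path: str | Path) -> None:
    data = movie.data
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"frame_rate_hz": movie.frame_rate_hz, "t0_s": movie.t0_s})


def load_movie(path: str | Path, frame_rate_hz: float | None = None) -> MovieStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except Exception as exc:  # truncated / malformed TIFF
        raise ValueError(f"cannot parse TIFF movie {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    rate = frame_rate_hz if frame_rate_hz is not None else float(meta.get("frame_rate_hz", 1.0))
    return MovieStack(data=data, frame_rate_hz=rate, t0_s=float(meta.get("t0_s", 0.0)))


def save_ephys(trace: EphysTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.current_pA}).to_csv(path, index=False)


def load_ephys(path: str | Path) -> EphysTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ephys file not found: {path}")
    try:
        frame = pd.read_csv(path)
        t = frame["time_s"].to_numpy()
        i_pa = frame["current_pA"].to_numpy()
    except (KeyError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot parse ephys CSV {path}: {exc}") from exc
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return EphysTrace(time_s=t, current_pA=i_pa, sample_rate_hz=rate)


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "wave_onsets_s": [float(x) for x in truth.wave_onsets_s],
        "recruited": [sorted(int(i) for i in s) for s in truth.recruited],
        "event_onsets": {str(k): [float(x) for x in v] for k, v in truth.event_onsets.items()},
        "n_rois": truth.n_rois,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        wave_onsets_s=np.asarray(payload["wave_onsets_s"]),
        recruited=[set(s) for s in payload["recruited"]],
        event_onsets={int(k): list(v) for k, v in payload["event_onsets"].items()},
        n_rois=int(payload["n_rois"]),
    )


def save_roimap(rois: RoiMap, tif_path: str | Path, table_path: str | Path | None = None) -> None:
    tifffile.imwrite(tif_path, rois.labels.astype(np.uint16))
    if table_path is not None:
        pd.DataFrame(
            [
                {"roi_id": r.id, "shape_class": r.shape_class, "circularity": r.circularity, "area_px": r.area}
                for r in rois.rois
            ]
        ).to_csv(table_path, index=False)


def load_roimap(tif_path: str | Path, table_path: str | Path | None = None) -> RoiMap:
    labels = tifffile.imread(tif_path).astype(np.int32)
    classes: dict[int, str] | None = None
    if table_path is not None:
        frame = pd.read_csv(table_path)
        classes = dict(zip(frame["roi_id"].astype(int), frame["shape_class"]))
    return RoiMap.from_labels(labels, shape_classes=classes)


def events_to_frame(events: list[TransientEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": e.roi_id,
                "onset_s": e.onset_s,
                "peak_s": e.peak_s,
                "offset_s": e.offset_s,
                "peak_dff": e.peak_dff,
                "duration_s": e.duration_s,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


def frame_to_events(frame: pd.DataFrame) -> list[TransientEvent]:
    return [
        TransientEvent(
            roi_id=int(r.roi_id),
            onset_s=float(r.onset_s),
            peak_s=float(r.peak_s),
            offset_s=float(r.offset_s),
            peak_dff=float(r.peak_dff),
        )
        for r in frame.itertuples()
    ]


def save_events(events: list[TransientEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def load_events(path: str | Path) -> list[TransientEvent]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events file not found: {path}")
    return frame_to_events(pd.read_csv(path))


def save_waves(waves: list[WaveEpoch], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": w.onset_s,
                "offset_s": w.offset_s,
                "peak_current_pA": w.peak_current_pA,
                "charge_pC": w.charge_pC,
            }
            for w in waves
        ],
        columns=WAVE_COLUMNS,
    ).to_csv(path, index=False)


def load_waves(path: str | Path) -> list[WaveEpoch]:
    frame = pd.read_csv(path)
    return [
        WaveEpoch(
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
            peak_current_pA=float(r.peak_current_pA),
            charge_pC=float(r.charge_pC),
        )
        for r in frame.itertuples()
    ]


def save_participation(summary: ParticipationSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "condition": [summary.condition] * summary.n_waves,
            "wave_index": np.arange(summary.n_waves),
            "pct_responsive": summary.per_wave_pct,
            "n_rois": [summary.n_rois] * summary.n_waves,
        }
    ).to_csv(path, index=False)
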